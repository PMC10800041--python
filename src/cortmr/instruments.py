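"""Instrument selection, LD clumping, proxy search, allele harmonization
and instrument-strength filtering.

The pipeline mirrors standard two-sample MR practice: genome-wide
significant exposure variants (p < 5e-8) are pruned to approximate
pairwise independence (r² < 0.001 within a 10 Mb window), matched into
the outcome GWAS (with LD proxies at r² >= 0.8 when a variant is
absent), aligned to a shared effect allele with palindromic variants
removed, and finally filtered on per-variant instrument strength
F > 10, where

    R²_j = 2 beta_j² eaf_j (1 - eaf_j)
    F_j  = R²_j (N - k - 1) / ((1 - R²_j) k),   k = 1 per variant.

The joint F over the retained set (k = number of SNPs) is reported as
well, but retention is governed by the per-variant statistic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CortMRError, NoInstrumentsError
from .gwas_io import LDTable

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Columns of a harmonized instrument table.
HARMONIZED_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "eaf_exp", "beta_out", "se_out",
    "r2_exp", "f_stat", "flipped", "proxy_of",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection."""
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    proxy_r2: float = 0.8
    proxy_window_bp: int = 1_000_000
    f_min: float = 10.0

    def __post_init__(self):
        if self.p_threshold <= 0 or self.clump_window_bp <= 0 or self.f_min < 0:
            raise CortMRError("selection thresholds must be positive")
        if not (0 < self.clump_r2 <= 1) or not (0 < self.proxy_r2 <= 1):
            raise CortMRError("clump_r2 and proxy_r2 must be in (0,1]")


def extract_significant(exposure: pd.DataFrame,
                        config: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """Rows with exposure p-value below the significance threshold, order kept."""
    out = exposure.loc[exposure["pval"] < config.p_threshold].reset_index(drop=True)
    if len(out) == 0:
        raise NoInstrumentsError(
            f"no variant passes p < {config.p_threshold:g}")
    return out


def clump(table: pd.DataFrame, ld: LDTable,
          config: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """Greedy LD clumping.

    Repeatedly takes the unclaimed variant with the lowest p-value
    (variant-ID tie-break) as an index SNP and discards every unclaimed
    variant on the same chromosome within ``clump_window_bp`` whose r²
    with the index is >= ``clump_r2``.  The result is invariant to input
    row order; output rows keep the index SNPs sorted by (p, ID).
    """
    order = table.sort_values(
        ["pval", "variant_id"], kind="mergesort").reset_index(drop=True)
    claimed: set[str] = set()
    kept_rows = []
    vid = order["variant_id"].to_numpy()
    chrom = order["chrom"].to_numpy()
    pos = order["pos"].to_numpy()
    for i in range(len(order)):
        if vid[i] in claimed:
            continue
        kept_rows.append(i)
        claimed.add(vid[i])
        near = (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= config.clump_window_bp)
        for j in np.flatnonzero(near):
            if vid[j] in claimed:
                continue
            if ld.r2(vid[i], vid[j]) >= config.clump_r2:
                claimed.add(vid[j])
    return order.iloc[kept_rows].reset_index(drop=True)


def find_proxy(variant: pd.Series, outcome: pd.DataFrame, ld: LDTable,
               config: SelectionConfig = SelectionConfig()) -> str | None:
    """Best LD proxy for a variant absent from the outcome table.

    Among outcome variants with r² >= ``proxy_r2`` to the target (same
    chromosome, within ``proxy_window_bp``), returns the one with the
    highest r²; ties broken by smallest base-pair distance, then
    lexicographic ID.  ``None`` when no candidate qualifies.
    """
    target = str(variant["variant_id"])
    cands = outcome.loc[
        (outcome["chrom"].astype(str) == str(variant["chrom"]))
        & ((outcome["pos"] - int(variant["pos"])).abs() <= config.proxy_window_bp)
        & (outcome["variant_id"] != target)]
    best = None
    for _, row in cands.iterrows():
        r2 = ld.r2(target, str(row["variant_id"]))
        if r2 < config.proxy_r2:
            continue
        key = (-r2, abs(int(row["pos"]) - int(variant["pos"])), str(row["variant_id"]))
        if best is None or key < best[0]:
            best = (key, str(row["variant_id"]))
    return None if best is None else best[1]


def is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(exp_row: pd.Series, out_row: pd.Series):
    """Align an outcome record to the exposure's effect allele.

    Returns ``(record_dict, None)`` on success, or ``(None, reason)``
    where reason is ``"palindrome"`` or ``"allele_mismatch"``.  Swapped
    allele order negates the outcome beta; a strand-complement coding
    (possibly plus swap) is resolved first.  Palindromic (A/T, G/C)
    variants are dropped unconditionally, since strand cannot be
    resolved from alleles alone.
    """
    ea, oa = exp_row["effect_allele"], exp_row["other_allele"]
    if is_palindromic(ea, oa):
        return None, "palindrome"
    ea_o, oa_o = out_row["effect_allele"], out_row["other_allele"]
    beta_out = float(out_row["beta"])
    flipped = False
    if (ea_o, oa_o) == (ea, oa):
        pass
    elif (ea_o, oa_o) == (oa, ea):
        beta_out, flipped = -beta_out, True
    elif (_COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)) == (ea, oa):
        pass
    elif (_COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)) == (oa, ea):
        beta_out, flipped = -beta_out, True
    else:
        return None, "allele_mismatch"
    rec = {
        "variant_id": exp_row["variant_id"],
        "chrom": exp_row["chrom"],
        "pos": int(exp_row["pos"]),
        "effect_allele": ea,
        "other_allele": oa,
        "beta_exp": float(exp_row["beta"]),
        "se_exp": float(exp_row["se"]),
        "eaf_exp": float(exp_row["eaf"]) if pd.notna(exp_row["eaf"]) else np.nan,
        "beta_out": beta_out,
        "se_out": float(out_row["se"]),
        "flipped": flipped,
        "proxy_of": "",
    }
    return rec, None


def compute_strength(beta: float, eaf: float, n_exposure: int, k: int = 1):
    """Per-variant variance explained and F-statistic.

    R² = 2 beta² (1-eaf) eaf;  F = R² (N-k-1) / ((1-R²) k).
    """
    if not np.isfinite(eaf):
        raise CortMRError(
            "compute_strength requires the effect-allele frequency; variants "
            "with missing eaf must be excluded beforehand (reason missing_eaf)")
    r2 = 2.0 * beta * beta * (1.0 - eaf) * eaf
    f = r2 * (n_exposure - k - 1) / ((1.0 - r2) * k)
    return r2, f


def joint_strength(r2_values: np.ndarray, n_exposure: int):
    """Joint R² (sum over instruments) and F with k = number of SNPs."""
    k = len(r2_values)
    r2 = float(np.sum(r2_values))
    if k == 0 or r2 >= 1:
        return r2, np.inf if r2 >= 1 else 0.0
    return r2, r2 * (n_exposure - k - 1) / ((1.0 - r2) * k)


@dataclass
class InstrumentSelection:
    """Harmonized instrument table plus a per-step attrition log."""
    table: pd.DataFrame
    attrition: dict = field(default_factory=dict)
    joint_r2: float = 0.0
    joint_f: float = 0.0

    @property
    def empty(self) -> bool:
        return len(self.table) == 0


def build_instruments(exposure: pd.DataFrame, outcome: pd.DataFrame,
                      ld: LDTable, config: SelectionConfig = SelectionConfig(),
                      n_exposure: int | None = None) -> InstrumentSelection:
    """Run the full selection pipeline: extract -> clump -> match/proxy ->
    harmonize -> strength filter.

    Never raises on an empty final set; the returned
    :class:`InstrumentSelection` has ``empty=True`` and the attrition log
    explains where variants were lost.
    """
    attrition: dict = {"input": len(exposure)}
    if n_exposure is None:
        n_exposure = int(exposure["n"].iloc[0])
    try:
        sig = extract_significant(exposure, config)
    except NoInstrumentsError:
        attrition["significant"] = 0
        return InstrumentSelection(_empty_table(), attrition)
    attrition["significant"] = len(sig)

    clumped = clump(sig, ld, config)
    attrition["clumped"] = len(clumped)

    out_by_id = {str(v): i for i, v in enumerate(outcome["variant_id"])}
    drop_reasons: dict[str, int] = {}
    records = []
    for _, exp_row in clumped.iterrows():
        vid = str(exp_row["variant_id"])
        proxy_of = ""
        if vid in out_by_id:
            out_row = outcome.iloc[out_by_id[vid]]
        else:
            proxy = find_proxy(exp_row, outcome, ld, config)
            if proxy is None:
                drop_reasons["no_outcome_match"] = \
                    drop_reasons.get("no_outcome_match", 0) + 1
                continue
            out_row = outcome.iloc[out_by_id[proxy]]
            proxy_of = vid
        rec, reason = harmonize(exp_row, out_row)
        if rec is None:
            drop_reasons[reason] = drop_reasons.get(reason, 0) + 1
            continue
        if proxy_of:
            rec["proxy_of"] = proxy_of
        records.append(rec)
    attrition["harmonized"] = len(records)
    attrition["drop_reasons"] = drop_reasons

    kept = []
    for rec in records:
        if not np.isfinite(rec["eaf_exp"]):
            drop_reasons["missing_eaf"] = drop_reasons.get("missing_eaf", 0) + 1
            continue
        r2, f = compute_strength(rec["beta_exp"], rec["eaf_exp"], n_exposure)
        if f <= config.f_min:
            drop_reasons["weak_instrument"] = \
                drop_reasons.get("weak_instrument", 0) + 1
            continue
        rec["r2_exp"], rec["f_stat"] = r2, f
        kept.append(rec)
    attrition["strong"] = len(kept)

    table = pd.DataFrame(kept, columns=HARMONIZED_COLUMNS) if kept \
        else _empty_table()
    jr2, jf = joint_strength(table["r2_exp"].to_numpy(), n_exposure) \
        if kept else (0.0, 0.0)
    if not kept:
        logger.warning("instrument selection produced an empty set: %s", attrition)
    return InstrumentSelection(table, attrition, jr2, jf)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=HARMONIZED_COLUMNS)
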