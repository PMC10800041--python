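"""Sensitivity diagnostics for a harmonized instrument table and the
survive/fail verdict applied to nominally significant causal estimates.

The battery comprises Cochran's Q heterogeneity test, the MR-Egger
intercept test for directional pleiotropy, a simulation-based residual
sum and outlier (MR-PRESSO style) test with outlier-corrected
re-estimation, the Steiger directionality test, leave-one-out influence
analysis, and a secondary-phenotype confounder screen.  A nominal result
fails the battery when directional pleiotropy is detected, when removing
confounder-linked variants overturns it, or when the inferred causal
direction is wrong; heterogeneity alone never fails a result, because
the primary random-effects IVW estimator already accommodates it.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CortMRError, InsufficientInstrumentsError, \
    PressoNotApplicableError
from .estimators import MRResult, ivw, ivw_internals, egger

VERDICTS = ("survive", "fail_pleiotropy", "fail_confounder", "fail_other")


@dataclass(frozen=True)
class CochranQ:
    q: float
    df: int
    pval: float


def cochran_q(table) -> CochranQ:
    """Cochran's Q heterogeneity statistic over the Wald ratios.

    Q = sum w_j (r_j - theta_FE)² with IVW weights; p from the upper tail
    of chi²(n-1).
    """
    n = len(table)
    if n < 2:
        raise InsufficientInstrumentsError(2, n, "Cochran's Q")
    inner = ivw_internals(table)
    p = float(stats.chi2.sf(inner.q, inner.df))
    return CochranQ(inner.q, inner.df, max(p, np.nextafter(0, 1)))


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_pvals: pd.Series          # Bonferroni-adjusted, indexed by variant
    outliers: list[str]
    outliers_identified: bool
    corrected: MRResult | None
    distortion_pval: float | None


def _variant_rng(seed: int, variant_id: str) -> np.random.Generator:
    # draws are keyed to (seed, variant ID), never to row position
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF,
                                zlib.crc32(variant_id.encode())]))


def _loo_theta(w_num, w):
    """Leave-one-out IVW fixed-effects estimates, vectorised over rows.

    ``w_num`` is w*r elementwise; returns theta_(-j) for each column j.
    """
    S = np.sum(w_num, axis=-1, keepdims=True)
    W = np.sum(w, axis=-1, keepdims=True)
    return (S - w_num) / (W - w)


def mr_presso(table, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoResult:
    """Residual-sum-and-outlier test with parametric null simulation.

    The observed residual sum of squares is
    RSS = sum_j (beta_out_j - theta_(-j) beta_exp_j)², with theta_(-j)
    the leave-one-out IVW fixed-effects estimate.  The null distribution
    comes from ``n_sim`` parametric draws beta*_exp ~ N(beta_exp, se_exp²),
    beta*_out ~ N(theta_(-j) beta_exp, se_out²); the global p-value is
    (1 + #{RSS* >= RSS}) / (1 + n_sim), never exactly zero.  Per-variant
    outlier p-values compare each observed squared residual with its own
    simulated distribution and are Bonferroni-adjusted by the number of
    instruments.  When the global test is significant but no adjusted
    outlier p-value passes ``outlier_alpha``, outliers exist but cannot
    be identified and no corrected estimate is produced; otherwise the
    corrected estimate is the IVW fit without the outliers and a
    distortion p-value compares the original and corrected estimates
    against a subset-resampling distribution.
    """
    n = len(table)
    if n < 4:
        raise PressoNotApplicableError(n)
    if n_sim < 100:
        raise CortMRError("mr_presso needs n_sim >= 100")
    vids = [str(v) for v in table["variant_id"]]
    bx = table["beta_exp"].to_numpy(dtype=float)
    by = table["beta_out"].to_numpy(dtype=float)
    sx = table["se_exp"].to_numpy(dtype=float)
    sy = table["se_out"].to_numpy(dtype=float)

    w = (bx / sy) ** 2
    r = by / bx
    w_num = w * r
    theta_loo = (np.sum(w_num) - w_num) / (np.sum(w) - w)
    resid_obs = by - theta_loo * bx
    rss_obs = float(np.sum(resid_obs ** 2))

    # simulate per variant with a stream keyed to (seed, variant ID) so
    # results are invariant to row order
    bxs = np.empty((n_sim, n))
    bys = np.empty((n_sim, n))
    for j, vid in enumerate(vids):
        rng = _variant_rng(seed, vid)
        bxs[:, j] = bx[j] + sx[j] * rng.standard_normal(n_sim)
        bys[:, j] = theta_loo[j] * bx[j] + sy[j] * rng.standard_normal(n_sim)
    bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
    ws = (bxs / sy) ** 2
    rs = bys / bxs
    wn = ws * rs
    theta_loo_s = _loo_theta(wn, ws)
    resid_s = bys - theta_loo_s * bxs
    rss_s = np.sum(resid_s ** 2, axis=1)
    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (1 + n_sim))

    raw = (1 + np.sum(resid_s ** 2 >= resid_obs[None, :] ** 2, axis=0)) \
        / (1 + n_sim)
    adj = np.minimum(raw * n, 1.0)
    outlier_pvals = pd.Series(adj, index=vids)
    outliers = [vid for vid, p in outlier_pvals.items() if p < outlier_alpha]

    corrected = None
    distortion_p = None
    identified = bool(outliers)
    if global_p < 0.05 and not outliers:
        identified = False
    elif outliers:
        keep = table.loc[~table["variant_id"].astype(str).isin(outliers)]
        if len(keep) >= 2:
            corrected = ivw(keep)
            distortion_p = _distortion_pval(table, keep, corrected.beta,
                                            n_sim, seed)
    return PressoResult(rss_obs, global_p, outlier_pvals, outliers,
                        identified, corrected, distortion_p)


def _distortion_pval(full, kept, theta_corr, n_sim, seed):
    """Two-estimate bootstrap comparison of original vs corrected IVW.

    Resamples instrument subsets of the corrected size from the full
    table and asks how often a random subset moves the estimate at least
    as far from the corrected value as the full-set estimate does.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        0xD157]))
    bx = full["beta_exp"].to_numpy(dtype=float)
    by = full["beta_out"].to_numpy(dtype=float)
    sy = full["se_out"].to_numpy(dtype=float)
    w = (bx / sy) ** 2
    r = by / bx
    theta_full = float(np.sum(w * r) / np.sum(w))
    d_obs = abs(theta_full - theta_corr)
    m = len(kept)
    count = 0
    for _ in range(n_sim):
        idx = rng.choice(len(full), size=m, replace=False)
        th = float(np.sum(w[idx] * r[idx]) / np.sum(w[idx]))
        if abs(th - theta_corr) >= d_obs:
            count += 1
    return float((1 + count) / (1 + n_sim))


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    pval: float


def steiger(table, n_exposure: int, n_outcome: int) -> SteigerResult:
    """Directionality test comparing variance explained on each side.

    R² on each side sums 2 beta² eaf (1-eaf) over the instruments; the
    inferred direction is exposure -> outcome when the exposure R² is the
    larger.  The p-value is from the independent-samples z-test of the
    two correlations sqrt(R²) after Fisher transformation.
    """
    eaf = table["eaf_exp"].to_numpy(dtype=float)
    if not np.all(np.isfinite(eaf)):
        raise CortMRError("steiger requires eaf for every instrument")
    bx = table["beta_exp"].to_numpy(dtype=float)
    by = table["beta_out"].to_numpy(dtype=float)
    r2x = float(np.sum(2.0 * bx ** 2 * eaf * (1 - eaf)))
    r2y = float(np.sum(2.0 * by ** 2 * eaf * (1 - eaf)))
    rx, ry = np.sqrt(min(r2x, 1.0)), np.sqrt(min(r2y, 1.0))
    denom = np.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    z = (np.arctanh(min(rx, 0.999999)) - np.arctanh(min(ry, 0.999999))) / denom
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(r2x, r2y, r2x > r2y, max(p, np.nextafter(0, 1)))


@dataclass
class LeaveOneOut:
    results: pd.DataFrame   # variant_id, beta, se, pval of IVW without it
    driven_by_single_snp: bool


def leave_one_out(table, alpha: float = 0.05) -> LeaveOneOut:
    """IVW re-estimated with each instrument omitted in turn.

    Flags the analysis as driven by a single variant when any omission
    flips the sign of the estimate or moves its p-value across ``alpha``.
    """
    n = len(table)
    if n < 3:
        raise InsufficientInstrumentsError(3, n, "leave-one-out")
    full = ivw(table)
    rows = []
    flag = False
    for i in range(n):
        sub = table.drop(table.index[i])
        res = ivw(sub)
        rows.append((str(table["variant_id"].iloc[i]), res.beta, res.se,
                     res.pval))
        if np.sign(res.beta) != np.sign(full.beta) or \
                (res.pval < alpha) != (full.pval < alpha):
            flag = True
    return LeaveOneOut(
        pd.DataFrame(rows, columns=["variant_id", "beta", "se", "pval"]),
        flag)


def confounder_screen(table, annotation: dict[str, list[str]],
                      confounder_traits) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Remove instruments annotated to any listed confounder trait.

    Matching is case-insensitive substring of each listed trait against
    the variant's annotated secondary phenotypes.  Returns the filtered
    table and the removed variants with their matched traits.
    """
    traits = [t.lower() for t in confounder_traits]
    removed: dict[str, list[str]] = {}
    if not annotation or not traits:
        return table, removed
    keep_mask = []
    for vid in table["variant_id"].astype(str):
        hits = [a for a in annotation.get(vid, [])
                if any(t in a.lower() or a.lower() in t for t in traits)]
        if hits:
            removed[vid] = hits
            keep_mask.append(False)
        else:
            keep_mask.append(True)
    return table.loc[keep_mask].reset_index(drop=True), removed


@dataclass
class SensitivityReport:
    """Collected diagnostics for one exposure/outcome analysis."""
    cochran: CochranQ | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    presso: PressoResult | None = None
    steiger: SteigerResult | None = None
    loo: LeaveOneOut | None = None
    removed_confounder_variants: dict = field(default_factory=dict)
    post_screen_ivw: MRResult | None = None
    verdict: str = "survive"
    verdict_reason: str = ""


def apply_verdict(result: MRResult, report: SensitivityReport,
                  alpha: float = 0.05) -> tuple[str, str]:
    """Survive/fail decision for a nominally significant estimate.

    Directional pleiotropy (Egger intercept p < alpha) fails the result;
    a confounder screen that moves the re-estimated p-value above alpha
    when the original was below fails it; a wrong Steiger direction
    fails it.  Heterogeneity alone never does: the random-effects IVW
    standard error already absorbs it.
    """
    if report.egger_intercept_pval is not None \
            and report.egger_intercept_pval < alpha:
        return ("fail_pleiotropy",
                f"Egger intercept p = {report.egger_intercept_pval:.4g} < {alpha}")
    if report.post_screen_ivw is not None and result.pval < alpha \
            and report.post_screen_ivw.pval >= alpha:
        return ("fail_confounder",
                f"IVW p moved from {result.pval:.4g} to "
                f"{report.post_screen_ivw.pval:.4g} after removing "
                f"confounder-linked variants")
    if report.steiger is not None and not report.steiger.correct_direction:
        return ("fail_other", "Steiger test favours the reverse direction")
    return "survive", ""


def run_sensitivity(table, n_exposure: int, n_outcome: int,
                    mr_result: MRResult | None = None,
                    annotation: dict | None = None,
                    confounder_traits=(), alpha: float = 0.05,
                    n_sim: int = 1000, seed: int = 0) -> SensitivityReport:
    """Run the full battery and attach the verdict.

    Diagnostics that need more instruments than available are skipped
    (left as ``None`` in the report); the verdict uses whatever ran.
    """
    report = SensitivityReport()
    n = len(table)
    if n >= 2:
        report.cochran = cochran_q(table)
    if n >= 3:
        e = egger(table)
        report.egger_intercept = e.intercept
        report.egger_intercept_se = e.intercept_se
        report.egger_intercept_pval = e.intercept_pval
        report.loo = leave_one_out(table, alpha=alpha)
    if n >= 4:
        report.presso = mr_presso(table, n_sim=n_sim, seed=seed)
    if np.all(np.isfinite(table["eaf_exp"].to_numpy(dtype=float))):
        report.steiger = steiger(table, n_exposure, n_outcome)
    if annotation and mr_result is not None and mr_result.pval < alpha:
        filtered, removed = confounder_screen(table, annotation,
                                              confounder_traits)
        report.removed_confounder_variants = removed
        if removed and len(filtered) >= 2:
            report.post_screen_ivw = ivw(filtered)
    if mr_result is not None:
        report.verdict, report.verdict_reason = apply_verdict(
            mr_result, report, alpha=alpha)
    return report
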