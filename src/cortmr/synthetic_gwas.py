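"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data layout of a binary-exposure /
brain-morphometry two-sample MR study: an exposure GWAS with a set of
genome-wide-significant instruments plus null background SNPs, and one or
more outcome GWAS sharing the same variants.  The generative model is the
standard summary-level instrumental-variable model

    gamma_j        true exposure effect of variant j (0 for null SNPs)
    alpha_j        true direct (pleiotropic) effect on the outcome
    Gamma_j = theta * gamma_j + alpha_j      true outcome effect
    beta_hat ~ Normal(truth, se^2),  se = 1 / sqrt(2 N eaf (1 - eaf))

with theta the causal effect of the exposure on the outcome.  Direct
effects are drawn as Normal(mu_alpha, sigma_alpha) on a configurable
fraction of instruments; `inside_violation` induces a correlation between
instrument strength gamma_j and alpha_j, violating the InSiDE assumption
that the Egger model requires.

Variants are laid out in LD blocks; within a block the r² between
variants i and j is (rho^|i-j|)², reported as a pairwise table.  A
configurable fraction of variants gets palindromic (A/T or G/C) allele
coding, and the outcome table re-expresses a fraction of rows with
swapped allele order and/or on the opposite strand, so that allele
harmonization is exercised end to end.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .gwas_io import SUMSTAT_COLUMNS, LDTable

#: z threshold corresponding to two-sided p = 5e-8
Z_GENOME_WIDE = float(stats.norm.isf(5e-8 / 2))

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-sample GWAS generator.

    Defaults mirror the study design the package targets: an
    autoimmune-disease exposure GWAS of 38,589 subjects, a cortical
    morphometry outcome GWAS of 51,665 subjects, a few dozen independent
    genome-wide-significant instruments on a background of null SNPs.
    """
    n_instruments: int = 50
    n_null_snps: int = 200
    theta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 0.0
    inside_violation: float = 0.0
    n_exposure: int = 38589
    n_outcome: int = 51665
    eaf_range: tuple[float, float] = (0.05, 0.95)
    palindrome_frac: float = 0.1
    ld_block_size: int = 5
    ld_rho: float = 0.8
    seed: int = 0
    # representation noise in the outcome table (harmonization must undo it)
    swap_frac: float = 0.25
    complement_frac: float = 0.25
    # optional confounder-linked instruments (secondary-trait annotation)
    confounder_frac: float = 0.0
    confounder_traits: tuple[str, ...] = ("body mass index", "smoking")
    effect_scale: str = "standardized"  # label only; the MR math is scale-free

    def validate(self) -> None:
        for name in ("pleiotropy_frac", "palindrome_frac", "swap_frac",
                     "complement_frac", "confounder_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if not -1.0 <= self.inside_violation <= 1.0:
            raise ConfigError("inside_violation must be in [-1,1]")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("eaf_range must be strictly inside (0,1)")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ConfigError("sample sizes must be >= 2")
        if self.n_instruments < 0 or self.n_null_snps < 0:
            raise ConfigError("variant counts must be nonnegative")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigError("ld_rho must be in [0,1)")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        # Each instrument needs per-variant R^2 of about z^2/N to reach
        # genome-wide significance; the total variance explained cannot
        # exceed 1, which bounds the number of supportable instruments.
        budget = self.n_instruments * (Z_GENOME_WIDE + 1.0) ** 2 / self.n_exposure
        if budget >= 1.0:
            raise ConfigError(
                f"signal too weak: {self.n_instruments} genome-wide-significant "
                f"instruments would require total variance explained "
                f"~{budget:.2f} >= 1 at n_exposure={self.n_exposure}; reduce "
                f"n_instruments or increase n_exposure")


@dataclass
class SimulationTruth:
    """Ground truth accompanying one simulated exposure/outcome pair."""
    variant_id: list[str]
    gamma: np.ndarray            # true exposure effects
    alpha: np.ndarray            # true direct (pleiotropic) effects
    theta: float
    palindromes: list[str]
    confounder_linked: list[str]
    is_instrument: np.ndarray

    @property
    def true_outcome_effect(self) -> np.ndarray:
        return self.theta * self.gamma + self.alpha

    def to_json(self) -> str:
        return json.dumps({
            "theta": self.theta,
            "variant_id": list(self.variant_id),
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "palindromes": list(self.palindromes),
            "confounder_linked": list(self.confounder_linked),
            "is_instrument": self.is_instrument.astype(int).tolist(),
        }, indent=1)


def _layout(config: SimulationConfig):
    """Assign variants to LD blocks, chromosomes and positions.

    One instrument is placed at the head of each successive block so
    that, with the default block size, instruments are mutually
    independent; blocks are spaced 20 Mb apart (beyond the clumping
    window) across chromosomes 1..22.
    """
    n = config.n_instruments + config.n_null_snps
    bs = config.ld_block_size
    n_blocks = max(config.n_instruments,
                   int(np.ceil(n / bs)) if bs else n)
    block_of = np.empty(n, dtype=int)
    idx_in_block = np.empty(n, dtype=int)
    # instruments first, one per block head
    counts = np.zeros(n_blocks, dtype=int)
    for j in range(config.n_instruments):
        b = j % n_blocks
        block_of[j] = b
        idx_in_block[j] = counts[b]
        counts[b] += 1
    b = 0
    for j in range(config.n_instruments, n):
        while counts[b] >= bs and b < n_blocks - 1:
            b += 1
        block_of[j] = b
        idx_in_block[j] = counts[b]
        counts[b] += 1
    chrom = np.array([str(bk % 22 + 1) for bk in block_of])
    pos = 1_000_000 + (block_of // 22) * 20_000_000 + idx_in_block * 5_000
    return block_of, idx_in_block, chrom, pos.astype(int)


def _draw_instrument_effects(rng, se_exp, config):
    """Instrument effect sizes: truncated normal on the |z| scale.

    gamma_j / se_j is drawn from a normal centred a few units above the
    genome-wide z threshold, truncated below at one unit above it, so
    that observed p-values can pass 5e-8 at the configured sample size.
    Effects are positive: the effect allele is coded as the
    exposure-increasing allele, the convention under which a nonzero
    mean direct effect is directional pleiotropy.
    """
    k = len(se_exp)
    lo, mu, sd = Z_GENOME_WIDE + 1.0, Z_GENOME_WIDE + 4.0, 2.0
    z = stats.truncnorm.rvs((lo - mu) / sd, np.inf, loc=mu, scale=sd,
                            size=k, random_state=rng)
    return z * se_exp


def _draw_alphas(rng, gamma, config):
    """Direct effects with optional instrument-strength correlation."""
    k = len(gamma)
    alpha = np.zeros(k)
    if config.pleiotropy_frac <= 0 or k == 0:
        return alpha
    n_pleio = int(round(config.pleiotropy_frac * k))
    which = rng.choice(k, size=n_pleio, replace=False) if n_pleio < k \
        else np.arange(k)
    rho = config.inside_violation
    g = np.abs(gamma[which])
    gs = (g - g.mean()) / g.std() if n_pleio > 1 and g.std() > 0 else np.zeros(n_pleio)
    z = rng.standard_normal(n_pleio)
    mix = rho * gs + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z
    alpha[which] = config.pleiotropy_mean + config.pleiotropy_sd * mix
    return alpha


def _assign_alleles(rng, n, palindrome_frac):
    n_pal = int(round(palindrome_frac * n))
    is_pal = np.zeros(n, dtype=bool)
    if n_pal:
        is_pal[rng.choice(n, size=n_pal, replace=False)] = True
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for j in range(n):
        pool = _PALINDROMIC if is_pal[j] else _NONPALINDROMIC
        ea[j], oa[j] = pool[rng.integers(len(pool))]
    return ea, oa, is_pal


def _se(n, eaf):
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _pval(beta, se):
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def _outcome_frame(rng, truth_Gamma, base, config):
    """Observed outcome table, with representation noise in allele coding."""
    n = len(base)
    eaf = base["eaf"].to_numpy()
    se_out = _se(config.n_outcome, eaf)
    beta = truth_Gamma + rng.standard_normal(n) * se_out
    ea = base["effect_allele"].to_numpy(copy=True)
    oa = base["other_allele"].to_numpy(copy=True)
    out_eaf = eaf.copy()
    swap = rng.random(n) < config.swap_frac
    comp = rng.random(n) < config.complement_frac
    beta = np.where(swap, -beta, beta)
    out_eaf = np.where(swap, 1.0 - out_eaf, out_eaf)
    ea2 = np.where(swap, oa, ea)
    oa2 = np.where(swap, ea, oa)
    ea3 = np.array([_COMPLEMENT[a] if c else a for a, c in zip(ea2, comp)],
                   dtype=object)
    oa3 = np.array([_COMPLEMENT[a] if c else a for a, c in zip(oa2, comp)],
                   dtype=object)
    return pd.DataFrame({
        "variant_id": base["variant_id"],
        "chrom": base["chrom"],
        "pos": base["pos"],
        "effect_allele": ea3,
        "other_allele": oa3,
        "eaf": out_eaf,
        "beta": beta,
        "se": se_out,
        "pval": _pval(beta, se_out),
        "n": config.n_outcome,
    })[SUMSTAT_COLUMNS]


def simulate_pair(config: SimulationConfig):
    """Simulate one exposure/outcome GWAS pair with LD and ground truth.

    Returns
    -------
    (exposure, outcome, ld, truth)
        ``exposure`` and ``outcome`` are summary-statistic DataFrames in
        the canonical column layout, ``ld`` an :class:`~cortmr.gwas_io.LDTable`
        of within-block r², and ``truth`` a :class:`SimulationTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_instruments + config.n_null_snps
    block_of, idx_in_block, chrom, pos = _layout(config)
    vid = [f"rs{j + 1:06d}" for j in range(n)]
    lo, hi = config.eaf_range
    eaf = rng.uniform(lo, hi, size=n)
    ea, oa, is_pal = _assign_alleles(rng, n, config.palindrome_frac)

    se_exp = _se(config.n_exposure, eaf)
    gamma = np.zeros(n)
    is_instr = np.zeros(n, dtype=bool)
    is_instr[:config.n_instruments] = True
    gamma[is_instr] = _draw_instrument_effects(
        rng, se_exp[:config.n_instruments], config)
    alpha = np.zeros(n)
    alpha[is_instr] = _draw_alphas(rng, gamma[is_instr], config)

    beta_exp = gamma + rng.standard_normal(n) * se_exp
    exposure = pd.DataFrame({
        "variant_id": vid, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta_exp, "se": se_exp, "pval": _pval(beta_exp, se_exp),
        "n": config.n_exposure,
    })[SUMSTAT_COLUMNS]

    Gamma = config.theta * gamma + alpha
    outcome = _outcome_frame(rng, Gamma, exposure, config)

    ld = LDTable()
    for b in np.unique(block_of):
        members = np.flatnonzero(block_of == b)
        order = members[np.argsort(idx_in_block[members])]
        for x in range(len(order)):
            for y in range(x + 1, len(order)):
                r = config.ld_rho ** (idx_in_block[order[y]] - idx_in_block[order[x]])
                r2 = r * r
                if r2 > 1e-6:
                    ld.add(vid[order[x]], vid[order[y]], r2)

    n_conf = int(round(config.confounder_frac * config.n_instruments))
    conf_ids: list[str] = []
    if n_conf:
        which = rng.choice(config.n_instruments, size=n_conf, replace=False)
        conf_ids = sorted(vid[j] for j in which)

    truth = SimulationTruth(
        variant_id=vid, gamma=gamma, alpha=alpha, theta=config.theta,
        palindromes=[vid[j] for j in range(n) if is_pal[j]],
        confounder_linked=conf_ids, is_instrument=is_instr)
    return exposure, outcome, ld, truth


def confounder_annotation(truth: SimulationTruth, config: SimulationConfig,
                          ) -> dict[str, list[str]]:
    """Secondary-trait annotation linking planted variants to confounder traits."""
    traits = list(config.confounder_traits) or ["body mass index"]
    return {vid: [traits[i % len(traits)]]
            for i, vid in enumerate(truth.confounder_linked)}


def simulate_outcome_grid(config: SimulationConfig, grid,
                          thetas: dict | None = None):
    """Simulate one exposure GWAS and one outcome GWAS per grid cell.

    All cells share the exposure table, LD and exposure-side truth;
    per-cell causal effects may be planted via ``thetas`` (mapping from
    cell to theta; default ``config.theta`` everywhere).  Each cell's
    outcome noise comes from an independent stream spawned from the
    single configured seed, so the whole grid is reproducible.

    Returns
    -------
    (exposure, ld, outcomes, truths)
        ``outcomes`` and ``truths`` map each grid cell to its outcome
        table and :class:`SimulationTruth`.
    """
    cells = list(getattr(grid, "cells", grid))
    if not cells:
        raise ConfigError("grid must be nonempty")
    exposure, _, ld, base_truth = simulate_pair(config)
    streams = np.random.SeedSequence(config.seed).spawn(len(cells) + 1)
    outcomes, truths = {}, {}
    for i, cell in enumerate(cells):
        th = config.theta if thetas is None else thetas.get(cell, config.theta)
        rng = np.random.default_rng(streams[i + 1])
        Gamma = th * base_truth.gamma + base_truth.alpha
        outcomes[cell] = _outcome_frame(rng, Gamma, exposure, config)
        truths[cell] = replace_theta(base_truth, th)
    return exposure, ld, outcomes, truths


def replace_theta(truth: SimulationTruth, theta: float) -> SimulationTruth:
    return SimulationTruth(
        variant_id=truth.variant_id, gamma=truth.gamma, alpha=truth.alpha,
        theta=theta, palindromes=truth.palindromes,
        confounder_linked=truth.confounder_linked,
        is_instrument=truth.is_instrument)
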