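"""Causal-effect estimators on a harmonized instrument table.

All estimators work on per-variant Wald ratios r_j = beta_out_j /
beta_exp_j with first-order standard errors se_j = se_out_j /
|beta_exp_j|:

* ``ivw`` — inverse-variance weighted mean of the ratios.  The primary
  analysis uses the multiplicative random-effects form: the
  fixed-effects standard error is inflated by sqrt(Q / (n-1)) whenever
  Cochran's Q exceeds its degrees of freedom (floored at 1).
* ``egger`` — weighted regression of beta_out on beta_exp with an
  intercept; the slope is the causal estimate and a nonzero intercept
  indicates directional pleiotropy.  Instruments are first oriented so
  every beta_exp >= 0 (the model is not invariant to allele
  re-orientation).
* ``weighted_median`` — the 50% quantile of the ratio distribution under
  IVW weights; consistent when at least half the weight comes from valid
  instruments.  Standard error by parametric bootstrap.
* ``simple_mode`` / ``weighted_mode`` — the mode of a normal-kernel
  density over the ratios (equal or IVW weights); consistent when the
  largest homogeneous cluster of instruments is valid.

P-values are two-sided normal for IVW/median/mode and t(n-2) for the
Egger slope and intercept.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import CortMRError, InsufficientInstrumentsError

_Z95 = 1.96

METHODS = ("wald_ratio", "ivw_re", "egger", "weighted_median",
           "simple_mode", "weighted_mode")


@dataclass(frozen=True)
class MRResult:
    """One estimator's causal estimate."""
    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    ci_low: float = None  # type: ignore[assignment]
    ci_high: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.ci_low is None:
            object.__setattr__(self, "ci_low", self.beta - _Z95 * self.se)
        if self.ci_high is None:
            object.__setattr__(self, "ci_high", self.beta + _Z95 * self.se)

    def to_dict(self) -> dict:
        return asdict(self)


def _ratios(table):
    bx = table["beta_exp"].to_numpy(dtype=float)
    by = table["beta_out"].to_numpy(dtype=float)
    sy = table["se_out"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise CortMRError("beta_exp = 0 is not a usable instrument")
    return by / bx, sy / np.abs(bx)


def wald_ratio(instrument) -> tuple[float, float]:
    """Single-variant Wald ratio and its first-order standard error."""
    bx = float(instrument["beta_exp"])
    if bx == 0:
        raise CortMRError("beta_exp = 0: Wald ratio undefined")
    return float(instrument["beta_out"]) / bx, float(instrument["se_out"]) / abs(bx)


@dataclass(frozen=True)
class IVWInternals:
    """Fixed-effects quantities reused by the sensitivity diagnostics."""
    theta_fe: float
    se_fe: float
    q: float
    df: int
    ratios: np.ndarray
    weights: np.ndarray


def ivw_internals(table) -> IVWInternals:
    r, s = _ratios(table)
    w = 1.0 / s ** 2
    theta = float(np.sum(w * r) / np.sum(w))
    se_fe = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (r - theta) ** 2))
    return IVWInternals(theta, se_fe, q, len(r) - 1, r, w)


def ivw(table, random_effects: bool = True) -> MRResult:
    """Inverse-variance weighted estimate (multiplicative random effects).

    theta = sum(w r) / sum(w) with w = 1/se_ratio²; the reported standard
    error is the fixed-effects one multiplied by max(1, sqrt(Q/(n-1))).
    """
    n = len(table)
    if n < 2:
        raise InsufficientInstrumentsError(2, n, "IVW")
    inner = ivw_internals(table)
    scale = max(1.0, np.sqrt(inner.q / inner.df)) if random_effects else 1.0
    se = inner.se_fe * scale
    p = 2.0 * stats.norm.sf(abs(inner.theta_fe) / se) if se > 0 else 1.0
    return MRResult("ivw_re" if random_effects else "ivw_fe", n,
                    inner.theta_fe, se, max(p, np.nextafter(0, 1)))


@dataclass(frozen=True)
class EggerResult:
    slope: MRResult
    intercept: float
    intercept_se: float
    intercept_pval: float


def egger(table) -> EggerResult:
    """MR-Egger weighted regression with an intercept.

    Weighted least squares of beta_out on beta_exp (weights 1/se_out²)
    after orienting instruments to beta_exp >= 0; slope and intercept
    standard errors are multiplied by max(1, residual scale) and tested
    against a t-distribution with n-2 degrees of freedom.
    """
    n = len(table)
    if n < 3:
        raise InsufficientInstrumentsError(3, n, "MR-Egger")
    bx = table["beta_exp"].to_numpy(dtype=float)
    by = table["beta_out"].to_numpy(dtype=float)
    sy = table["se_out"].to_numpy(dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(n), bx])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid ** 2) / (n - 2))
    scale = max(1.0, np.sqrt(sigma2))
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    df = n - 2
    p_slope = 2.0 * stats.t.sf(abs(coef[1]) / se[1], df) if se[1] > 0 else 1.0
    p_int = 2.0 * stats.t.sf(abs(coef[0]) / se[0], df) if se[0] > 0 else 1.0
    slope = MRResult("egger", n, float(coef[1]), float(se[1]),
                     max(p_slope, np.nextafter(0, 1)))
    return EggerResult(slope, float(coef[0]), float(se[0]),
                       max(p_int, np.nextafter(0, 1)))


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order]
    wn = w / np.sum(w)
    s = np.cumsum(wn) - wn / 2.0
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _parametric_boot(table, point_fn, n_boot, seed):
    bx = table["beta_exp"].to_numpy(dtype=float)
    by = table["beta_out"].to_numpy(dtype=float)
    sx = table["se_exp"].to_numpy(dtype=float)
    sy = table["se_out"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(len(bx))
        bys = by + sy * rng.standard_normal(len(by))
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        r = bys / bxs
        w = (bxs / sy) ** 2
        est[b] = point_fn(r, w)
    return float(np.std(est, ddof=1))


def weighted_median(table, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median estimate; bootstrap standard error.

    The point estimate interpolates the ordered ratios against the
    cumulative-midpoint weights at 0.5; the standard error is the spread
    of the estimate over ``n_boot`` parametric resamples of the summary
    statistics.
    """
    n = len(table)
    if n < 3:
        raise InsufficientInstrumentsError(3, n, "weighted median")
    r, s = _ratios(table)
    w = 1.0 / s ** 2
    beta = _weighted_median_point(r, w)
    se = _parametric_boot(table, _weighted_median_point, n_boot, seed)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return MRResult("weighted_median", n, beta, se, max(p, np.nextafter(0, 1)))


def _mode_point(ratios: np.ndarray, weights: np.ndarray,
                bandwidth_factor: float = 1.0) -> float:
    n = len(ratios)
    sd = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    h = bandwidth_factor * 0.9 * min(sd, mad) * n ** (-1 / 5) \
        if min(sd, mad) > 0 else 0.0
    if h <= 0:
        # degenerate spread: the mode is the heaviest ratio value
        vals, idx = np.unique(ratios, return_inverse=True)
        mass = np.bincount(idx, weights=weights)
        return float(vals[np.argmax(mass)])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = np.sum(weights[:, None]
                  * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
                  axis=0)
    return float(grid[np.argmax(dens)])


def mode_estimate(table, weighted: bool = False, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Simple- or weighted-mode estimate from a kernel density over the ratios.

    Bandwidth is ``bandwidth_factor`` times the modified Silverman value
    0.9 min(sd, mad) n^(-1/5); the density argmax is taken over a
    512-point grid spanning [min - 3h, max + 3h].  Standard error by
    parametric bootstrap as for the weighted median.
    """
    n = len(table)
    if n < 3:
        raise InsufficientInstrumentsError(3, n, "mode estimator")
    r, s = _ratios(table)
    w = 1.0 / s ** 2 if weighted else np.ones(n)

    def point(rr, ww):
        return _mode_point(rr, ww if weighted else np.ones(len(rr)),
                           bandwidth_factor)

    beta = point(r, w)
    se = _parametric_boot(table, point, n_boot, seed)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return MRResult("weighted_mode" if weighted else "simple_mode", n,
                    beta, se, max(p, np.nextafter(0, 1)))


def run_all(table, n_boot: int = 1000, seed: int = 0,
            methods=("ivw_re", "egger", "weighted_median",
                     "simple_mode", "weighted_mode")) -> dict[str, MRResult]:
    """Run the requested estimators; estimators short of instruments are skipped."""
    out: dict[str, MRResult] = {}
    for m in methods:
        try:
            if m == "ivw_re":
                out[m] = ivw(table)
            elif m == "egger":
                out[m] = egger(table).slope
            elif m == "weighted_median":
                out[m] = weighted_median(table, n_boot=n_boot, seed=seed)
            elif m == "simple_mode":
                out[m] = mode_estimate(table, weighted=False,
                                       n_boot=n_boot, seed=seed)
            elif m == "weighted_mode":
                out[m] = mode_estimate(table, weighted=True,
                                       n_boot=n_boot, seed=seed)
            else:
                raise CortMRError(f"unknown method: {m}")
        except InsufficientInstrumentsError:
            continue
    return out
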