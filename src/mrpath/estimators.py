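"""Causal-effect estimators for two-sample MR.

Given J harmonized instruments with exposure effects bx_j (SE sx_j) and
outcome effects by_j (SE sy_j), the per-SNP Wald ratio by_j / bx_j estimates
the causal effect under the instrumental-variable assumptions.  The suite
combines the ratios five ways:

* **IVW** (multiplicative random effects) — weighted regression of by on bx
  through the origin with weights 1/sy^2; the primary method.  The reported
  SE is the fixed-effect SE inflated by the square root of the residual
  overdispersion phi = Q/(J-1), floored at 1, so heterogeneity widens but
  never narrows the interval.
* **MR Egger** — the same regression with an intercept; the slope remains
  consistent under directional pleiotropy (given InSIDE), and the intercept
  estimates the average direct effect.
* **Weighted median** — the ratio at cumulative weight 1/2; consistent when
  instruments carrying at least half the weight are valid.
* **Simple / weighted mode** — the peak of a kernel density over the ratios;
  consistent when the largest group of instruments shares the true effect.

Median and mode SEs come from a parametric bootstrap (normal resampling of
bx and by from their reported SEs).  Benjamini-Hochberg FDR adjustment is
provided for multiple exposures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateInstrumentError,
    EmptyInstrumentError,
    InsufficientInstrumentsError,
)
from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

#: row order of the method suite, as results tables conventionally print it
SUITE_ORDER = ("MR Egger", "Weighted median", "IVW", "Simple mode", "Weighted mode")


@dataclass(slots=True)
class RatioEstimate:
    """Per-SNP Wald ratio with first-order SE and inverse-variance weight."""

    snp_id: str
    ratio: float
    se_ratio: float
    weight: float


@dataclass(slots=True)
class MREstimate:
    """One method's causal estimate with 95% CI and p-value."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    scale_phi: float | None = None


@dataclass
class MethodConfig:
    """Settings shared by the bootstrap-based estimators."""

    bootstrap_B: int = 1000
    seed: int = 0
    phi: float = 1.0  # mode bandwidth multiplier
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.bootstrap_B < 100:
            raise ValueError(f"bootstrap_B must be >= 100, got {self.bootstrap_B}")
        if not self.phi > 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")


def _clamp_p(p: float) -> float:
    return float(max(p, np.finfo(float).tiny))


def wald_ratio(bx: float, sx: float, by: float, sy: float, snp_id: str = "?") -> RatioEstimate:
    """Per-SNP causal estimate by/bx with first-order SE sy/|bx|."""
    if bx == 0:
        raise DegenerateInstrumentError(f"SNP {snp_id}: exposure effect is zero")
    se = sy / abs(bx)
    return RatioEstimate(snp_id=snp_id, ratio=by / bx, se_ratio=se, weight=1.0 / se**2)


def ratio_estimates(hset: HarmonizedSet) -> list[RatioEstimate]:
    return [wald_ratio(p.bx, p.sx, p.by, p.sy, p.snp_id) for p in hset.pairs]


def _require(hset: HarmonizedSet, minimum: int, method: str) -> None:
    if len(hset) < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {minimum} instruments, got {len(hset)}"
        )


def ivw_multiplicative_re(hset: HarmonizedSet, alpha: float = 0.05) -> MREstimate:
    """Multiplicative random-effects inverse-variance-weighted estimate.

    Weighted least squares of by on bx through the origin, weights 1/sy^2.
    With one instrument this reduces exactly to the Wald ratio.
    """
    if len(hset) == 0:
        raise EmptyInstrumentError("IVW needs at least one instrument")
    bx, _, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise DegenerateInstrumentError("IVW: an instrument has zero exposure effect")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fe = sxx ** -0.5
    J = len(hset)
    if J > 1:
        phi = float(np.sum(w * (by - beta * bx) ** 2)) / (J - 1)
    else:
        phi = 1.0
    se = se_fe * max(1.0, phi) ** 0.5
    z = stats.norm.ppf(1 - alpha / 2)
    pval = _clamp_p(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate(
        method="IVW",
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        pval=pval,
        nsnp=J,
        scale_phi=phi,
    )


def _egger_fit(hset: HarmonizedSet, alpha: float = 0.05):
    """Oriented weighted Egger regression; returns (slope est, intercept est, x, y, w)."""
    _require(hset, 3, "MR Egger")
    bx, _, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise DegenerateInstrumentError("MR Egger: an instrument has zero exposure effect")
    sign = np.sign(bx)
    x, y = bx * sign, by * sign  # orient so every exposure effect is positive
    w = 1.0 / sy**2
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    J = len(hset)
    df = J - 2
    sigma2 = float(res.scale)  # weighted residual variance
    # SEs use the residual scale floored at 1 (never narrower than fixed-effect)
    scale = max(1.0, sigma2) / sigma2
    se = np.asarray(res.bse) * scale**0.5
    params = np.asarray(res.params)
    tq = stats.t.ppf(1 - alpha / 2, df)
    ests = []
    for i, name in enumerate(("intercept", "slope")):
        t = params[i] / se[i]
        ests.append(
            dict(
                name=name,
                beta=float(params[i]),
                se=float(se[i]),
                ci_low=float(params[i] - tq * se[i]),
                ci_high=float(params[i] + tq * se[i]),
                pval=_clamp_p(2 * stats.t.sf(abs(t), df)),
            )
        )
    return ests[1], ests[0], x, y, w


def mr_egger(hset: HarmonizedSet, alpha: float = 0.05) -> MREstimate:
    """MR Egger regression: slope = causal effect, intercept = mean pleiotropy.

    Pairs are oriented so bx_j > 0 first (the estimate is not invariant to
    allele coding, so a deterministic convention is required); p-values use
    the t distribution with J-2 df.
    """
    slope, intercept, *_ = _egger_fit(hset, alpha)
    return MREstimate(
        method="MR Egger",
        beta=slope["beta"],
        se=slope["se"],
        ci_low=slope["ci_low"],
        ci_high=slope["ci_high"],
        pval=slope["pval"],
        nsnp=len(hset),
        intercept=intercept["beta"],
        intercept_se=intercept["se"],
        intercept_pval=intercept["pval"],
    )


def _weighted_median_point(values: np.ndarray, weights: np.ndarray) -> float:
    """Value at cumulative weight 1/2 with linear interpolation."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, v))


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float, grid_points: int = 2001) -> float:
    """Argmax of a Gaussian kernel density over the per-SNP ratios.

    Bandwidth h = phi * 0.9 * min(SD, 1.4826*MAD) * J^(-1/5); when one of
    SD/MAD degenerates to zero the other is used, and if both are zero the
    common ratio is returned directly.
    """
    J = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if J > 1 else 0.0
    mad = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    candidates = [s for s in (sd, mad) if s > 0]
    if not candidates:
        return float(ratios[0])
    h = phi * 0.9 * min(candidates) * J ** (-1 / 5)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_points)
    wn = weights / weights.sum()
    dens = (wn * stats.norm.pdf((grid[:, None] - ratios[None, :]) / h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def _bootstrap_se(hset: HarmonizedSet, cfg: MethodConfig, point_fn) -> float:
    """Parametric bootstrap SD of a ratio-based point estimator.

    Resamples bx_j ~ N(bx_j, sx_j^2) and by_j ~ N(by_j, sy_j^2), recomputes
    the estimator on the resampled ratios with refreshed first-order
    weights, and returns the SD over B draws.
    """
    bx, sx, by, sy = hset.arrays()
    rng = np.random.default_rng(cfg.seed)
    B = cfg.bootstrap_B
    bxs = rng.normal(bx, sx, size=(B, len(bx)))
    bys = rng.normal(by, sy, size=(B, len(by)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = bys / bxs
        weights = (bxs / sy) ** 2
    est = np.empty(B)
    for b in range(B):
        r, w = ratios[b], weights[b]
        ok = np.isfinite(r)
        est[b] = point_fn(r[ok], w[ok])
    return float(np.std(est, ddof=1))


def _normal_estimate(method: str, beta: float, se: float, nsnp: int, alpha: float) -> MREstimate:
    z = stats.norm.ppf(1 - alpha / 2)
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        pval=_clamp_p(2 * stats.norm.sf(abs(beta / se))) if se > 0 else _clamp_p(0.0),
        nsnp=nsnp,
    )


def weighted_median(hset: HarmonizedSet, cfg: MethodConfig | None = None) -> MREstimate:
    """Weighted-median estimator (valid with up to 50% invalid weight)."""
    cfg = cfg or MethodConfig()
    _require(hset, 3, "Weighted median")
    rats = ratio_estimates(hset)
    values = np.array([r.ratio for r in rats])
    weights = np.array([r.weight for r in rats])
    beta = _weighted_median_point(values, weights)
    se = _bootstrap_se(hset, cfg, _weighted_median_point)
    return _normal_estimate("Weighted median", beta, se, len(hset), cfg.alpha)


def mode_based(hset: HarmonizedSet, weighted: bool, cfg: MethodConfig | None = None) -> MREstimate:
    """Mode-based estimator; ``weighted`` selects inverse-variance kernel weights."""
    cfg = cfg or MethodConfig()
    method = "Weighted mode" if weighted else "Simple mode"
    _require(hset, 3, method)
    rats = ratio_estimates(hset)
    values = np.array([r.ratio for r in rats])
    weights = np.array([r.weight for r in rats]) if weighted else np.ones(len(rats))

    def point(v, w):
        return _mode_point(v, w if weighted else np.ones_like(v), cfg.phi)

    beta = _mode_point(values, weights, cfg.phi)
    se = _bootstrap_se(hset, cfg, point)
    return _normal_estimate(method, beta, se, len(hset), cfg.alpha)


def run_method_suite(hset: HarmonizedSet, cfg: MethodConfig | None = None) -> list[MREstimate]:
    """Run the five-method suite (or a logged downgrade when J < 3).

    With one instrument only the Wald ratio is estimable; with two, only
    IVW.  Results come back in :data:`SUITE_ORDER` for the full suite.
    """
    cfg = cfg or MethodConfig()
    J = len(hset)
    if J == 0:
        raise EmptyInstrumentError("method suite needs at least one instrument")
    if J == 1:
        logger.warning("only 1 instrument: downgrading suite to the Wald ratio")
        p = hset.pairs[0]
        r = wald_ratio(p.bx, p.sx, p.by, p.sy, p.snp_id)
        return [_normal_estimate("Wald ratio", r.ratio, r.se_ratio, 1, cfg.alpha)]
    if J == 2:
        logger.warning("only 2 instruments: downgrading suite to IVW")
        return [ivw_multiplicative_re(hset, cfg.alpha)]
    return [
        mr_egger(hset, cfg.alpha),
        weighted_median(hset, cfg),
        ivw_multiplicative_re(hset, cfg.alpha),
        mode_based(hset, weighted=False, cfg=cfg),
        mode_based(hset, weighted=True, cfg=cfg),
    ]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, original order preserved."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]
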