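"""Heterogeneity, pleiotropy and outlier diagnostics.

Three families of checks accompany the causal estimates:

* **Cochran's Q** in the IVW framework and **Rucker's Q'** in the Egger
  framework quantify excess dispersion of the per-SNP ratios beyond what
  their SEs explain; p < 0.05 flags heterogeneity.
* The **Egger intercept** tests for directional pleiotropy (a nonzero mean
  direct effect of the instruments on the outcome).
* **MR-PRESSO** compares the observed leave-one-out residual sum of squares
  against its Monte-Carlo distribution under the no-pleiotropy model
  (global test), localizes the signal to individual SNPs (outlier test,
  Bonferroni-adjusted), and asks whether removing the flagged SNPs changes
  the IVW estimate (distortion test), reporting an outlier-corrected
  estimate.

All Monte-Carlo p-values use the add-one convention, so they are bounded
below by 1/(nb_sim + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateCorrectionError, InsufficientInstrumentsError
from .estimators import MREstimate, _egger_fit, ivw_multiplicative_re, mr_egger
from .harmonize import HarmonizedSet


@dataclass(slots=True)
class HeterogeneityResult:
    framework: str  # "IVW" or "Egger"
    Q: float
    df: int
    pval: float


@dataclass(slots=True)
class PleiotropyResult:
    intercept: float
    intercept_se: float
    pval: float


@dataclass
class PressoConfig:
    nb_sim: int = 1000
    seed: int = 0
    sig_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.nb_sim < 100:
            raise ValueError(f"nb_sim must be >= 100, got {self.nb_sim}")


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    nb_sim: int
    outlier_pvals: dict[str, float] = field(default_factory=dict)
    outliers: list[str] = field(default_factory=list)
    distortion_pval: float | None = None
    corrected: MREstimate | None = None
    # per-SNP observed statistics and their simulated counterparts, retained
    # so the outlier test can reuse the global test's draws
    _obs_stats: np.ndarray | None = None
    _sim_stats: np.ndarray | None = None


def _ratio_weights(hset: HarmonizedSet):
    bx, _, by, sy = hset.arrays()
    w = bx**2 / sy**2  # first-order weights of the per-SNP ratios
    ratios = by / bx
    return ratios, w


def cochran_q_ivw(hset: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q about the fixed-effect IVW estimate; df = J - 1."""
    if len(hset) < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 instruments, got {len(hset)}")
    ratios, w = _ratio_weights(hset)
    theta_fe = float(np.sum(w * ratios) / np.sum(w))
    Q = float(np.sum(w * (ratios - theta_fe) ** 2))
    df = len(hset) - 1
    return HeterogeneityResult("IVW", Q, df, float(stats.chi2.sf(Q, df)))


def rucker_q_egger(hset: HarmonizedSet) -> HeterogeneityResult:
    """Rucker's Q' about the (oriented) Egger fit; df = J - 2."""
    if len(hset) < 3:
        raise InsufficientInstrumentsError(f"Rucker's Q' needs >= 3 instruments, got {len(hset)}")
    slope, intercept, x, y, w = _egger_fit(hset)
    resid = y - intercept["beta"] - slope["beta"] * x
    Q = float(np.sum(w * resid**2))
    df = len(hset) - 2
    return HeterogeneityResult("Egger", Q, df, float(stats.chi2.sf(Q, df)))


def egger_intercept_test(hset: HarmonizedSet) -> PleiotropyResult:
    """Directional-pleiotropy test from the Egger intercept (t, J-2 df)."""
    est = mr_egger(hset)
    return PleiotropyResult(est.intercept, est.intercept_se, est.intercept_pval)


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, one per SNP, via sum updates."""
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx * bx)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


def presso_global(hset: HarmonizedSet, cfg: PressoConfig | None = None) -> PressoResult:
    """MR-PRESSO global test.

    Observed statistic: RSS = sum_j w_j (by_j - theta_{-j} bx_j)^2 with
    w_j = 1/sy_j^2 and theta_{-j} the leave-one-out IVW estimate.  The null
    distribution is built by redrawing by*_j ~ N(theta_{-j} bx_j, sy_j^2)
    nb_sim times and recomputing the statistic (including the leave-one-out
    fits) on each draw.
    """
    cfg = cfg or PressoConfig()
    J = len(hset)
    if J < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {J}")
    bx, _, by, sy = hset.arrays()
    w = 1.0 / sy**2
    theta_loo = _loo_ivw(bx, by, w)
    obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(obs.sum())

    rng = np.random.default_rng(cfg.seed)
    bys = rng.normal(theta_loo * bx, sy, size=(cfg.nb_sim, J))
    s2_minus = np.sum(w * bx * bx) - w * bx * bx  # constant across draws
    s1 = (w * bx * bys).sum(axis=1)
    theta_loo_sim = (s1[:, None] - w * bx * bys) / s2_minus
    sim = w * (bys - theta_loo_sim * bx) ** 2  # (nb_sim, J)
    rss_sim = sim.sum(axis=1)
    global_pval = (1 + int(np.sum(rss_sim >= rss_obs))) / (cfg.nb_sim + 1)
    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        nb_sim=cfg.nb_sim,
        _obs_stats=obs,
        _sim_stats=sim,
    )


def presso_outlier_test(
    hset: HarmonizedSet,
    cfg: PressoConfig | None = None,
    global_result: PressoResult | None = None,
) -> PressoResult:
    """Per-SNP outlier test reusing the global test's simulated draws.

    Each SNP's observed residual statistic is compared with its simulated
    distribution; p-values are Bonferroni-adjusted by J and SNPs with
    adjusted p below the significance threshold are flagged.
    """
    cfg = cfg or PressoConfig()
    res = global_result if global_result is not None else presso_global(hset, cfg)
    obs, sim = res._obs_stats, res._sim_stats
    J = len(hset)
    pvals = {}
    flagged = []
    for j, snp in enumerate(hset.snp_ids):
        p = (1 + int(np.sum(sim[:, j] >= obs[j]))) / (cfg.nb_sim + 1)
        p_adj = min(1.0, p * J)
        pvals[snp] = p_adj
        if p_adj < cfg.sig_threshold:
            flagged.append(snp)
    res.outlier_pvals = pvals
    res.outliers = flagged
    return res


def presso_distortion_test(
    hset: HarmonizedSet,
    outliers: list[str],
    cfg: PressoConfig | None = None,
) -> tuple[float, MREstimate]:
    """Distortion test and outlier-corrected IVW estimate.

    The observed distortion (theta_all - theta_corrected)/|theta_corrected|
    is compared with a bootstrap distribution obtained by removing random
    subsets of the same size and re-estimating.
    """
    cfg = cfg or PressoConfig()
    if not outliers:
        raise ValueError("distortion test requires a non-empty outlier set")
    keep_ids = [s for s in hset.snp_ids if s not in set(outliers)]
    if len(keep_ids) < 2:
        raise DegenerateCorrectionError(
            f"removing {len(outliers)} outlier(s) leaves {len(keep_ids)} instrument(s)"
        )
    corrected = ivw_multiplicative_re(hset.subset(keep_ids))
    theta_all = ivw_multiplicative_re(hset).beta
    d_obs = (theta_all - corrected.beta) / abs(corrected.beta)

    bx, _, by, sy = hset.arrays()
    w = 1.0 / sy**2
    J = len(hset)
    n_out = len(set(outliers) & set(hset.snp_ids))
    rng = np.random.default_rng(cfg.seed + 1)
    d_boot = np.empty(cfg.nb_sim)
    for b in range(cfg.nb_sim):
        drop = rng.choice(J, size=n_out, replace=False)
        mask = np.ones(J, dtype=bool)
        mask[drop] = False
        theta_b = float(
            np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)
        )
        d_boot[b] = (theta_all - theta_b) / abs(theta_b)
    pval = (1 + int(np.sum(np.abs(d_boot) >= abs(d_obs)))) / (cfg.nb_sim + 1)
    return pval, corrected


def run_presso(hset: HarmonizedSet, cfg: PressoConfig | None = None) -> PressoResult:
    """Global + outlier tests, plus distortion/correction when outliers exist."""
    cfg = cfg or PressoConfig()
    res = presso_outlier_test(hset, cfg)
    if res.outliers and len(hset) - len(res.outliers) >= 2:
        res.distortion_pval, res.corrected = presso_distortion_test(hset, res.outliers, cfg)
    return res
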