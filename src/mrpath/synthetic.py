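"""Synthetic GWAS summary statistics with known causal structure.

The generator emulates the summary-level structure a two-sample MR with
mediation consumes: three GWAS tables (exposure X, mediator M, outcome Y)
sharing J instruments with per-SNP true exposure effects gamma_j.  Effects
and SEs follow the standard summary-statistic model for a standardized
quantitative trait:

    se_j = (2 n p_j (1 - p_j))^(-1/2)        (per study sample size n)
    bx_j ~ N(gamma_j, se_x,j^2)
    bm_j ~ N(kappa * gamma_j, se_m,j^2)
    by_j ~ N((theta_direct + kappa * theta_med) * gamma_j + alpha_j, se_y,j^2)

where kappa is the X -> M effect, theta_med the M -> Y effect and
theta_direct the unmediated X -> Y effect, so the total effect is
theta_total = theta_direct + kappa * theta_med and the true proportion
mediated is kappa * theta_med / theta_total.  alpha_j encodes horizontal
pleiotropy: zero, balanced N(0, tau^2), directional N(mu, tau^2), or
correlated with gamma_j at rho (an InSIDE violation).  True effects are
rescaled so the instruments jointly explain ``r2_total`` of the exposure
variance; p-values are exactly consistent with beta/se.

The three studies are generated with independent noise (no sample
overlap), and instruments are unlinked by default; an optional block mode
places consecutive SNPs close together and emits a matching LD table so
clumping can be exercised.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .gwas_io import SummaryRecord, SummaryTable, write_summary_table
from .instruments import LDTable

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "inside_violated")


@dataclass
class SimulationConfig:
    J: int = 26
    n_x: int = 90_000
    n_m: int = 90_000
    n_y: int = 30_000
    theta_direct: float = 0.0
    theta_med: float = 0.0
    kappa: float = 0.0
    r2_total: float = 0.01
    pleiotropy: str = "none"
    pleio_mu: float = 0.0
    pleio_tau: float = 0.0
    pleio_rho: float = 0.0
    eaf_range: tuple[float, float] = (0.05, 0.95)
    palindromic_fraction: float = 0.0
    ld_block_size: int = 1  # >1 emits a block-correlated LD table
    ld_block_r2: float = 0.9
    snp_offset: int = 0  # offsets snp_ids/positions so two studies can be merged
    seed: int = 0

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.kappa * self.theta_med

    @property
    def true_proportion_mediated(self) -> float:
        return self.kappa * self.theta_med / self.theta_total

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ConfigurationError(f"J must be >= 1, got {self.J}")
        if not 0 < self.r2_total < 1:
            raise ConfigurationError(f"r2_total must be in (0,1), got {self.r2_total}")
        for name, n in (("n_x", self.n_x), ("n_m", self.n_m), ("n_y", self.n_y)):
            if n <= self.J + 1:
                raise ConfigurationError(f"{name} must exceed J + 1 (got {n}, J={self.J})")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ConfigurationError(
                f"pleiotropy must be one of {PLEIOTROPY_REGIMES}, got {self.pleiotropy!r}"
            )
        lo, hi = self.eaf_range
        if not 0 < lo < hi < 1:
            raise ConfigurationError(f"eaf_range must satisfy 0 < lo < hi < 1, got {self.eaf_range}")
        if not 0 <= self.palindromic_fraction <= 1:
            raise ConfigurationError("palindromic_fraction must be in [0,1]")


@dataclass
class SimulationTruth:
    """Everything needed to score an estimator against the generator."""

    snp_ids: list[str]
    gamma: np.ndarray  # true per-SNP exposure effects
    alpha: np.ndarray  # per-SNP pleiotropic outcome effects
    eaf: np.ndarray
    theta_total: float
    theta_direct: float
    theta_med: float
    kappa: float
    config: SimulationConfig


@dataclass
class SimulatedStudy:
    exposure: SummaryTable
    mediator: SummaryTable
    outcome: SummaryTable
    truth: SimulationTruth
    ld: LDTable | None = None


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    # exact two-sided normal p, floored to keep the (0,1] invariant
    return np.maximum(2 * stats.norm.sf(np.abs(beta / se)), 1e-300)


def _table(label, snp_ids, chrom, pos, alleles, eaf, beta, se, n) -> SummaryTable:
    recs = [
        SummaryRecord(
            snp_id=snp_ids[j],
            chrom=chrom[j],
            pos_bp=int(pos[j]),
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(p),
            n=int(n),
        )
        for j, p in enumerate(_pvals(beta, se))
    ]
    return SummaryTable(label, recs, sample_size=n)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Draw one exposure/mediator/outcome study triple (fully seeded)."""
    rng = np.random.default_rng(cfg.seed)
    J = cfg.J

    eaf = rng.uniform(*cfg.eaf_range, size=J)
    # Effects are drawn on the standardized-genotype scale (per-allele effect
    # ~ 1/sqrt(2pq), the empirically observed MAF-effect relationship), so
    # each SNP contributes a comparable share of r2_total regardless of its
    # frequency; magnitudes spread moderately around a common scale (enough
    # between-SNP spread for slope identification in Egger regression).
    # Effect alleles are reported as the exposure-increasing allele
    # (gamma_j > 0), the usual convention for curated instrument lists.
    b_raw = rng.uniform(0.6, 1.4, size=J)
    b_std = b_raw * np.sqrt(cfg.r2_total / np.sum(b_raw**2))
    gamma = b_std / np.sqrt(2 * eaf * (1 - eaf))

    if cfg.pleiotropy == "none":
        alpha = np.zeros(J)
    elif cfg.pleiotropy == "balanced":
        alpha = rng.normal(0.0, cfg.pleio_tau, size=J)
    elif cfg.pleiotropy == "directional":
        alpha = rng.normal(cfg.pleio_mu, cfg.pleio_tau, size=J)
    else:  # inside_violated: alpha correlated with instrument strength
        eps = rng.normal(size=J)
        g_std = (gamma - gamma.mean()) / (gamma.std() if gamma.std() > 0 else 1.0)
        alpha = cfg.pleio_tau * (cfg.pleio_rho * g_std + np.sqrt(1 - cfg.pleio_rho**2) * eps)

    se_x = (2 * cfg.n_x * eaf * (1 - eaf)) ** -0.5
    se_m = (2 * cfg.n_m * eaf * (1 - eaf)) ** -0.5
    se_y = (2 * cfg.n_y * eaf * (1 - eaf)) ** -0.5
    bx = rng.normal(gamma, se_x)
    bm = rng.normal(cfg.kappa * gamma, se_m)
    by = rng.normal(cfg.theta_total * gamma + alpha, se_y)

    off = cfg.snp_offset
    snp_ids = [f"rs{off + j + 1:06d}" for j in range(J)]
    if cfg.ld_block_size > 1:
        # blocks of consecutive SNPs: same chromosome, 10 kb apart
        block = off + np.arange(J) // cfg.ld_block_size
        chrom = [str(b % 22 + 1) for b in block]
        pos = 1_000_000 + 20_000_000 * (block // 22) + 10_000 * (np.arange(J) % cfg.ld_block_size)
        ld_pairs = {}
        for j in range(J):
            for k in range(j + 1, J):
                if block[j] == block[k]:
                    ld_pairs[(snp_ids[j], snp_ids[k])] = cfg.ld_block_r2
        ld = LDTable(ld_pairs)
    else:
        chrom = [str((off + j) % 22 + 1) for j in range(J)]
        pos = 1_000_000 * (off + np.arange(J) + 1)  # same-chrom SNPs > 10 Mb apart
        ld = None

    n_pal = int(round(cfg.palindromic_fraction * J))
    pal_idx = set(rng.choice(J, size=n_pal, replace=False).tolist()) if n_pal else set()
    alleles = [
        _PALINDROMIC[int(rng.integers(len(_PALINDROMIC)))]
        if j in pal_idx
        else _NONPALINDROMIC[int(rng.integers(len(_NONPALINDROMIC)))]
        for j in range(J)
    ]

    truth = SimulationTruth(
        snp_ids=snp_ids,
        gamma=gamma,
        alpha=alpha,
        eaf=eaf,
        theta_total=cfg.theta_total,
        theta_direct=cfg.theta_direct,
        theta_med=cfg.theta_med,
        kappa=cfg.kappa,
        config=cfg,
    )
    return SimulatedStudy(
        exposure=_table("exposure", snp_ids, chrom, pos, alleles, eaf, bx, se_x, cfg.n_x),
        mediator=_table("mediator", snp_ids, chrom, pos, alleles, eaf, bm, se_m, cfg.n_m),
        outcome=_table("outcome", snp_ids, chrom, pos, alleles, eaf, by, se_y, cfg.n_y),
        truth=truth,
        ld=ld,
    )


def preset_paper_scale(seed: int = 0, **overrides) -> SimulationConfig:
    """Study conditions matching the headline coffee -> CAC analysis scale.

    J=26 instruments; total effect 0.79 decomposed as direct 0.4755 plus
    kappa=0.85 times theta_med=0.37 through the mediator (true proportion
    mediated ~ 0.398); sample sizes and r2_total give per-SNP F around 30.
    """
    base = dict(
        J=26,
        n_x=90_000,
        n_m=90_000,
        n_y=30_000,
        theta_direct=0.79 - 0.85 * 0.37,
        theta_med=0.37,
        kappa=0.85,
        r2_total=0.01,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write the three summary TSVs, a truth manifest, and any LD table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_summary_table(study.exposure, outdir / "exposure.tsv")
    write_summary_table(study.mediator, outdir / "mediator.tsv")
    write_summary_table(study.outcome, outdir / "outcome.tsv")
    t = study.truth
    manifest = {
        "snp_ids": t.snp_ids,
        "gamma": t.gamma.tolist(),
        "alpha": t.alpha.tolist(),
        "eaf": t.eaf.tolist(),
        "theta_total": t.theta_total,
        "theta_direct": t.theta_direct,
        "theta_med": t.theta_med,
        "kappa": t.kappa,
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(t.config).items()},
    }
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2))
    if study.ld is not None:
        study.ld.to_frame().to_csv(outdir / "ld.tsv", sep="\t", index=False)
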