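"""Two-step MR mediation.

For an exposure X, mediator M and outcome Y, two-step MR estimates
beta1 (X -> M), beta2 (M -> Y) and beta3 (X -> Y, the total effect) by
separate two-sample MR analyses.  The indirect effect through M is
beta1 * beta2 and the proportion of the total effect mediated is
beta1 * beta2 / beta3.  Uncertainty comes from a parametric bootstrap:
the three effects are redrawn independently from normal distributions
centred on their estimates with their reported SEs (summary-level data
admit no individual-level resampling), the derived quantities are
recomputed per draw, SEs are the draw SDs and CIs the 2.5/97.5
percentiles.  The pathway p-value tests the indirect effect (z = point
estimate over bootstrap SE); the proportion's own distribution is
heavy-tailed when beta3 is imprecise, so it is not used for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import ivw_multiplicative_re
from .harmonize import HarmonizedSet


@dataclass
class MediationInput:
    """The three pathway effects with their SEs."""

    beta1: float  # exposure -> mediator
    se1: float
    beta2: float  # mediator -> outcome
    se2: float
    beta3: float  # exposure -> outcome (total)
    se3: float
    exposure_label: str = "exposure"
    mediator_label: str = "mediator"
    outcome_label: str = "outcome"

    @property
    def pathway(self) -> str:
        return f"{self.exposure_label} -> {self.outcome_label} via {self.mediator_label}"


@dataclass
class MediationResult:
    pathway: str
    indirect: float
    proportion: float
    se_indirect: float
    se_proportion: float
    ci_indirect: tuple[float, float]
    ci_proportion: tuple[float, float]
    pval: float
    B: int
    seed: int
    unstable_proportion: bool = False


def indirect_effect(beta1: float, beta2: float) -> float:
    """Indirect (mediated) effect beta1 * beta2."""
    return beta1 * beta2


def proportion_mediated(beta1: float, beta2: float, beta3: float) -> float:
    """Proportion of the total effect mediated, beta1 * beta2 / beta3."""
    if beta3 == 0:
        raise ValueError("total effect beta3 must be nonzero")
    return beta1 * beta2 / beta3


def bootstrap_mediation(inp: MediationInput, B: int = 10_000, seed: int = 0) -> MediationResult:
    """Parametric bootstrap for the indirect effect and proportion mediated."""
    rng = np.random.default_rng(seed)
    b1 = rng.normal(inp.beta1, inp.se1, size=B)
    b2 = rng.normal(inp.beta2, inp.se2, size=B)
    b3 = rng.normal(inp.beta3, inp.se3, size=B)

    ind = b1 * b2
    near_zero = np.abs(b3) < 1e-8
    unstable = bool(np.mean(near_zero) > 0.01)
    if unstable:
        warnings.warn(
            f"{inp.pathway}: >1% of bootstrap draws have |beta3| ~ 0; "
            "proportion-mediated interval is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(near_zero, np.nan, ind / b3)
    prop = prop[np.isfinite(prop)]

    point_ind = indirect_effect(inp.beta1, inp.beta2)
    point_prop = proportion_mediated(inp.beta1, inp.beta2, inp.beta3)
    se_ind = float(np.std(ind, ddof=1))
    se_prop = float(np.std(prop, ddof=1)) if prop.size > 1 else 0.0
    ci_ind = (float(np.percentile(ind, 2.5)), float(np.percentile(ind, 97.5)))
    if prop.size:
        ci_prop = (float(np.percentile(prop, 2.5)), float(np.percentile(prop, 97.5)))
    else:
        ci_prop = (float("nan"), float("nan"))
    if se_ind > 0:
        pval = float(2 * stats.norm.sf(abs(point_ind / se_ind)))
    else:
        pval = 1.0 if point_ind == 0 else float(np.finfo(float).tiny)
    return MediationResult(
        pathway=inp.pathway,
        indirect=point_ind,
        proportion=point_prop,
        se_indirect=se_ind,
        se_proportion=se_prop,
        ci_indirect=ci_ind,
        ci_proportion=ci_prop,
        pval=max(pval, float(np.finfo(float).tiny)),
        B=B,
        seed=seed,
        unstable_proportion=unstable,
    )


def run_two_step(
    exposure_mediator: HarmonizedSet,
    mediator_outcome: HarmonizedSet,
    exposure_outcome: HarmonizedSet,
    B: int = 10_000,
    seed: int = 0,
) -> MediationResult:
    """Estimate beta1/beta2/beta3 by IVW from three harmonized sets, then bootstrap."""
    e1 = ivw_multiplicative_re(exposure_mediator)
    e2 = ivw_multiplicative_re(mediator_outcome)
    e3 = ivw_multiplicative_re(exposure_outcome)
    inp = MediationInput(
        beta1=e1.beta,
        se1=e1.se,
        beta2=e2.beta,
        se2=e2.se,
        beta3=e3.beta,
        se3=e3.se,
        exposure_label=exposure_mediator.exposure_label,
        mediator_label=exposure_mediator.outcome_label,
        outcome_label=exposure_outcome.outcome_label,
    )
    return bootstrap_mediation(inp, B=B, seed=seed)
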