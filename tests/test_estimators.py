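"""The five-method estimator suite, Wald ratios, and BH-FDR."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import hset_from_arrays
from mrpath.errors import DegenerateInstrumentError, InsufficientInstrumentsError
from mrpath.estimators import (
    MethodConfig,
    _mode_point,
    _weighted_median_point,
    bh_fdr,
    ivw_multiplicative_re,
    mode_based,
    mr_egger,
    run_method_suite,
    wald_ratio,
    weighted_median,
)
from mrpath.harmonize import HarmonizedSet
from mrpath.synthetic import SimulationConfig, simulate_study


def _flip(hset, idx):
    """Joint sign flip of (bx, by) for the given pair indices (allele recoding)."""
    import dataclasses

    pairs = [
        dataclasses.replace(p, bx=-p.bx, by=-p.by) if j in idx else p
        for j, p in enumerate(hset.pairs)
    ]
    return HarmonizedSet(hset.exposure_label, hset.outcome_label, pairs)


def test_wald_ratio_arithmetic_and_symmetry():
    r = wald_ratio(bx=0.5, sx=0.05, by=0.4, sy=0.1)
    assert r.ratio == pytest.approx(0.8)
    assert r.se_ratio == pytest.approx(0.2)
    assert wald_ratio(0.5, 0.05, 0.0, 0.1).ratio == 0.0
    flipped = wald_ratio(-0.5, 0.05, -0.4, 0.1)
    assert flipped.ratio == pytest.approx(0.8)
    with pytest.raises(DegenerateInstrumentError):
        wald_ratio(0.0, 0.05, 0.4, 0.1)


def test_ivw_single_pair_reduces_to_wald():
    h = hset_from_arrays([0.5], [0.4], [0.1])
    est = ivw_multiplicative_re(h)
    assert est.beta == pytest.approx(0.8)
    assert est.se == pytest.approx(0.2)
    assert est.nsnp == 1


def test_ivw_zero_heterogeneity_floors_phi():
    bx = np.array([0.1, 0.2, 0.3])
    h = hset_from_arrays(bx, 0.5 * bx, [0.01, 0.02, 0.03])
    est = ivw_multiplicative_re(h)
    assert est.beta == pytest.approx(0.5)
    assert est.scale_phi == pytest.approx(0.0)
    fixed_se = float(np.sum((bx / np.array([0.01, 0.02, 0.03])) ** 2)) ** -0.5
    assert est.se == pytest.approx(fixed_se)  # floor active


def test_ivw_matches_wls_oracle(five_pair_hset):
    """IVW equals weighted regression through the origin with residual scaling."""
    bx, _, by, sy = five_pair_hset.arrays()
    res = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
    est = ivw_multiplicative_re(five_pair_hset)
    assert est.beta == pytest.approx(float(res.params[0]), abs=1e-10)
    se_fixed = float(res.bse[0]) / float(res.scale) ** 0.5
    expected_se = se_fixed * max(1.0, float(res.scale)) ** 0.5
    assert est.se == pytest.approx(expected_se, abs=1e-10)
    assert est.scale_phi == pytest.approx(float(res.scale), abs=1e-10)


def test_estimators_invariant_to_order_and_joint_sign_flips(five_pair_hset):
    cfg = MethodConfig(seed=11, bootstrap_B=100)
    base = {
        "ivw": ivw_multiplicative_re(five_pair_hset).beta,
        "egger": mr_egger(five_pair_hset).beta,
        "median": weighted_median(five_pair_hset, cfg).beta,
        "mode": mode_based(five_pair_hset, weighted=True, cfg=cfg).beta,
    }
    flipped = _flip(five_pair_hset, {0, 2})
    assert ivw_multiplicative_re(flipped).beta == pytest.approx(base["ivw"])
    assert mr_egger(flipped).beta == pytest.approx(base["egger"])
    assert weighted_median(flipped, cfg).beta == pytest.approx(base["median"])
    assert mode_based(flipped, weighted=True, cfg=cfg).beta == pytest.approx(base["mode"])
    reordered = HarmonizedSet(
        five_pair_hset.exposure_label,
        five_pair_hset.outcome_label,
        list(reversed(five_pair_hset.pairs)),
    )
    assert ivw_multiplicative_re(reordered).beta == pytest.approx(base["ivw"])
    assert _weighted_median_point(*_ratios(reordered)) == pytest.approx(base["median"])


def _ratios(hset):
    bx, _, by, sy = hset.arrays()
    return by / bx, (bx / sy) ** 2


def test_weighted_median_middle_element():
    h = hset_from_arrays([1.0, 1.0, 1.0], [0.2, 0.8, 1.4], [0.1, 0.1, 0.1])
    assert weighted_median(h, MethodConfig(seed=0, bootstrap_B=100)).beta == pytest.approx(0.8)


def test_weighted_median_dominant_weight():
    # one SNP carries > 50% of total weight -> its ratio is the estimate
    h = hset_from_arrays([1.0, 1.0, 1.0], [0.2, 0.9, 1.4], [0.01, 1.0, 1.0])
    # interpolation leaves the estimate within the dominant SNP's half-weight step
    assert weighted_median(h, MethodConfig(seed=0, bootstrap_B=100)).beta == pytest.approx(0.2, abs=1e-3)


def test_weighted_median_matches_interpolation_oracle():
    values = np.array([0.1, 0.5, 0.9, 1.5])
    weights = np.array([1.0, 2.0, 3.0, 4.0])
    # brute-force: cumulative weight midpoints, then linear interpolation
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / w.sum()
    k = np.searchsorted(cum, 0.5)
    expected = v[k - 1] + (0.5 - cum[k - 1]) * (v[k] - v[k - 1]) / (cum[k] - cum[k - 1])
    assert _weighted_median_point(values, weights) == pytest.approx(expected)


def test_weighted_median_equal_weights_is_plain_median():
    vals = np.array([0.3, 1.2, 0.7, 0.9])
    assert _weighted_median_point(vals, np.ones(4)) == pytest.approx(np.median(vals))


def test_mode_degenerate_returns_common_ratio():
    h = hset_from_arrays([1.0, 2.0, 4.0], [0.5, 1.0, 2.0], [0.1, 0.1, 0.1])
    est = mode_based(h, weighted=False, cfg=MethodConfig(seed=0, bootstrap_B=100))
    assert est.beta == pytest.approx(0.5)


def test_mode_finds_cluster_within_bandwidth():
    ratios = np.array([0.79, 0.80, 0.81, 5.0])
    sd = np.std(ratios, ddof=1)
    mad = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
    h_bw = 0.9 * min(sd, mad) * 4 ** (-1 / 5)
    est = _mode_point(ratios, np.ones(4), phi=1.0)
    assert abs(est - 0.80) < h_bw


def test_weighted_vs_simple_mode_differ_under_weight_concentration():
    ratios = np.array([0.2, 0.21, 0.22, 1.0, 1.01])
    weights = np.array([1.0, 1.0, 1.0, 500.0, 500.0])
    simple = _mode_point(ratios, np.ones(5), phi=1.0)
    weighted = _mode_point(ratios, weights, phi=1.0)
    assert abs(simple - 0.21) < 0.1
    assert abs(weighted - 1.0) < 0.1


def test_egger_needs_three_instruments():
    h = hset_from_arrays([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
    with pytest.raises(InsufficientInstrumentsError):
        mr_egger(h)


def test_egger_recovers_injected_intercept():
    """Constant pleiotropy shifts the intercept, not the slope (200 replicates).

    Run at large exposure-GWAS size so regression dilution of the Egger
    slope (finite I^2_GX) is negligible relative to Monte-Carlo error.
    """
    slopes, intercepts = [], []
    alpha = 0.05
    for seed in range(200):
        study = simulate_study(
            SimulationConfig(J=26, n_x=4_000_000, theta_direct=0.5,
                             pleiotropy="directional", pleio_mu=alpha,
                             pleio_tau=0.0, seed=seed)
        )
        bx, _, by, sy = _study_arrays(study)
        est = mr_egger(hset_from_arrays(bx, by, sy))
        slopes.append(est.beta)
        intercepts.append(est.intercept)
    for values, target in ((slopes, 0.5), (intercepts, alpha)):
        mc_se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(np.mean(values) - target) < 2 * mc_se


def _study_arrays(study):
    bx = np.array([r.beta for r in study.exposure.records])
    by = np.array([r.beta for r in study.outcome.records])
    sy = np.array([r.se for r in study.outcome.records])
    return bx, None, by, sy


def test_suite_order_downgrades_and_determinism(five_pair_hset):
    cfg = MethodConfig(seed=3, bootstrap_B=100)
    suite = run_method_suite(five_pair_hset, cfg)
    assert [e.method for e in suite] == [
        "MR Egger", "Weighted median", "IVW", "Simple mode", "Weighted mode",
    ]
    again = run_method_suite(five_pair_hset, MethodConfig(seed=3, bootstrap_B=100))
    assert [(e.beta, e.se, e.pval) for e in suite] == [(e.beta, e.se, e.pval) for e in again]

    single = HarmonizedSet("X", "Y", five_pair_hset.pairs[:1])
    only = run_method_suite(single, cfg)
    assert [e.method for e in only] == ["Wald ratio"]
    double = HarmonizedSet("X", "Y", five_pair_hset.pairs[:2])
    assert [e.method for e in run_method_suite(double, cfg)] == ["IVW"]


def test_bh_fdr_reproduces_stepup_arithmetic():
    adjusted = bh_fdr([0.022, 0.056, 0.008, 0.005])
    # manual step-up: sorted p (.005,.008,.022,.056) -> (.016,.016,.0293,.056)
    assert adjusted[0] == pytest.approx(0.022 * 4 / 3)
    assert round(float(adjusted[0]), 3) == 0.029
    assert adjusted[1] == pytest.approx(0.056)
    assert bh_fdr([0.03])[0] == pytest.approx(0.03)
    assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)
    assert len(bh_fdr([])) == 0


@given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=20))
@settings(max_examples=50, deadline=None)
def test_bh_fdr_properties(pvals):
    adj = bh_fdr(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-15)
    assert np.all(adj <= 1.0 + 1e-15)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in raw p
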