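"""Instrument selection: thresholding, clumping, and strength filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record, make_table
from mrpath.errors import ConfigurationError, EmptyInstrumentError
from mrpath.instruments import (
    LDTable,
    SelectionConfig,
    f_statistic,
    filter_weak,
    greedy_clump,
    instrument_strength,
    select_by_pvalue,
    variance_explained,
)


def test_select_by_pvalue_is_strict():
    t = make_table([
        make_record("rs1", pval=1e-9),
        make_record("rs2", pval=5e-8),
        make_record("rs3", pval=1e-7),
    ])
    kept = select_by_pvalue(t, 5e-8)
    assert kept.snp_ids == ["rs1"]
    assert select_by_pvalue(t, 1.0).snp_ids == ["rs1", "rs2", "rs3"]


def test_select_by_pvalue_empty_reports_threshold():
    t = make_table([make_record("rs1", pval=0.5)])
    with pytest.raises(EmptyInstrumentError, match="5e-08"):
        select_by_pvalue(t, 5e-8)


def _snp(i, chrom, pos, pval):
    return make_record(f"rs{i}", chrom=chrom, pos_bp=pos, pval=pval)


def test_clump_removes_linked_neighbour():
    t = make_table([_snp(1, "1", 1000, 1e-10), _snp(2, "1", 2000, 1e-9)])
    ld = LDTable({("rs1", "rs2"): 0.5})
    kept = greedy_clump(t, ld, SelectionConfig(clump_r2=0.001))
    assert kept.snp_ids == ["rs1"]


def test_clump_keeps_below_threshold_pairs():
    t = make_table([_snp(1, "1", 1000, 1e-10), _snp(2, "1", 2000, 1e-9)])
    ld = LDTable({("rs1", "rs2"): 0.0005})
    assert greedy_clump(t, ld, SelectionConfig(clump_r2=0.001)).snp_ids == ["rs1", "rs2"]


def test_clump_respects_window():
    # linked but far apart on the same chromosome: both kept
    t = make_table([_snp(1, "1", 1000, 1e-10), _snp(2, "1", 2_000_000_0 + 1000, 1e-9)])
    ld = LDTable({("rs1", "rs2"): 0.9})
    assert len(greedy_clump(t, ld, SelectionConfig(clump_window_kb=10_000))) == 2


def test_clump_missing_positions_is_configuration_error():
    t = make_table([make_record("rs1", pval=1e-9)])
    with pytest.raises(ConfigurationError, match="pos_bp"):
        greedy_clump(t, None, SelectionConfig())


def _oracle_clump(records, ld, r2_thr, window_bp):
    """Step-by-step greedy simulation, kept independent of production code."""
    remaining = {r.snp_id: r for r in records}
    kept = []
    while remaining:
        lead = sorted(
            remaining.values(), key=lambda r: (r.pval, r.pos_bp, r.snp_id)
        )[0]
        kept.append(lead.snp_id)
        for other in list(remaining.values()):
            if other.snp_id == lead.snp_id:
                continue
            if (
                other.chrom == lead.chrom
                and abs(other.pos_bp - lead.pos_bp) <= window_bp
                and ld.r2(lead.snp_id, other.snp_id) >= r2_thr
            ):
                del remaining[other.snp_id]
        del remaining[lead.snp_id]
    return set(kept)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_clump_matches_brute_force_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = 8
    records = [
        _snp(i, chrom=str(rng.integers(1, 3)), pos=int(rng.integers(0, 5_000_000)),
             pval=float(rng.uniform(1e-12, 1e-6)))
        for i in range(n)
    ]
    pairs = {}
    ids = [r.snp_id for r in records]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                pairs[(ids[i], ids[j])] = float(rng.uniform(0, 1))
    ld = LDTable(pairs)
    cfg = SelectionConfig(clump_r2=0.2, clump_window_kb=1000)
    kept = greedy_clump(make_table(records), ld, cfg)
    assert set(kept.snp_ids) == _oracle_clump(records, ld, 0.2, 1_000_000)
    # retained set is an independent set under (linked AND close)
    for a in kept.records:
        for b in kept.records:
            if a.snp_id < b.snp_id and a.chrom == b.chrom:
                assert not (
                    abs(a.pos_bp - b.pos_bp) <= 1_000_000
                    and ld.r2(a.snp_id, b.snp_id) >= 0.2
                )


def test_clump_invariant_under_row_permutation():
    rng = np.random.default_rng(5)
    records = [
        _snp(i, "1", pos=int(i * 1000), pval=float(rng.uniform(1e-10, 1e-6)))
        for i in range(6)
    ]
    ld = LDTable({(f"rs{i}", f"rs{j}"): 0.8 for i in range(6) for j in range(i + 1, 6) if j - i <= 2})
    cfg = SelectionConfig(clump_r2=0.5, clump_window_kb=10)
    base = set(greedy_clump(make_table(records), ld, cfg).snp_ids)
    perm = [records[i] for i in rng.permutation(6)]
    assert set(greedy_clump(make_table(perm), ld, cfg).snp_ids) == base


@pytest.mark.parametrize(
    "beta,eaf,expected",
    [(0.1, 0.5, 0.005), (0.1, 0.0, 0.0), (0.2, 0.25, 0.015)],
)
def test_variance_explained_arithmetic(beta, eaf, expected):
    assert variance_explained(beta, eaf) == pytest.approx(expected)


@given(beta=st.floats(-2, 2), eaf=st.floats(0, 1))
@settings(max_examples=50, deadline=None)
def test_variance_explained_symmetry_and_maximum(beta, eaf):
    assert variance_explained(beta, eaf) == pytest.approx(variance_explained(beta, 1 - eaf))
    assert variance_explained(beta, eaf) <= variance_explained(beta, 0.5) + 1e-15


def test_f_statistic_arithmetic():
    assert f_statistic(0.01, 1002, 1) == pytest.approx(1000 * 0.01 / 0.99)
    assert f_statistic(0.0, 100, 1) == 0.0
    assert f_statistic(0.1, 101, 10) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        f_statistic(0.1, 11, 10)
    with pytest.raises(ValueError):
        f_statistic(1.0, 100, 1)


@given(
    r2=st.floats(0.001, 0.5), n=st.integers(100, 10_000),
    dr=st.floats(0.001, 0.2), dn=st.integers(1, 1000),
)
@settings(max_examples=50, deadline=None)
def test_f_statistic_monotone_in_r2_and_n(r2, n, dr, dn):
    k = 5
    assert f_statistic(min(r2 + dr, 0.9), n, k) > f_statistic(r2, n, k)
    assert f_statistic(r2, n + dn, k) > f_statistic(r2, n, k)


def _record_with_f(snp_id, f_target, n=1000):
    # invert F = (n-2) R2/(1-R2) with R2 = beta^2/2 at eaf=0.5
    r2 = f_target / (n - 2 + f_target)
    beta = math.sqrt(2 * r2)
    return make_record(snp_id, beta=beta, eaf=0.5, n=n)


def test_filter_weak_strict_boundary():
    weak = _record_with_f("rs_weak", 9.9)
    strong = _record_with_f("rs_strong", 10.5)
    t = make_table([weak, strong])
    strength = instrument_strength(t)
    assert strength.f_per_snp["rs_weak"] == pytest.approx(9.9)
    kept = filter_weak(t, f_min=10.0)
    assert kept.snp_ids == ["rs_strong"]
    # all strong -> unchanged
    t2 = make_table([_record_with_f("rs1", 30), _record_with_f("rs2", 50)])
    assert filter_weak(t2, 10.0).snp_ids == ["rs1", "rs2"]


def test_filter_weak_all_dropped_raises():
    t = make_table([_record_with_f("rs1", 2.0), _record_with_f("rs2", 1.0)])
    with pytest.raises(EmptyInstrumentError):
        filter_weak(t, 10.0)


def test_ld_table_round_trip(tmp_path):
    ld = LDTable({("rs1", "rs2"): 0.5, ("rs2", "rs3"): 0.1})
    path = tmp_path / "ld.tsv"
    ld.to_frame().to_csv(path, sep="\t", index=False)
    back = LDTable.from_tsv(path)
    assert back.r2("rs2", "rs1") == 0.5  # symmetric lookup
    assert back.r2("rs1", "rs3") == 0.0  # absent pair unlinked
    assert back.r2("rs1", "rs1") == 1.0
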