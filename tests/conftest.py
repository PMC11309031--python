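"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mrpath.gwas_io import SummaryRecord, SummaryTable
from mrpath.harmonize import HarmonizedPair, HarmonizedSet


def make_record(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=1e-10,
    **kw,
):
    return SummaryRecord(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pval=pval,
        **kw,
    )


def make_table(records, label="trait", sample_size=None):
    return SummaryTable(label, list(records), sample_size=sample_size)


def hset_from_arrays(bx, by, sy, sx=None, exposure="X", outcome="Y"):
    """Build a HarmonizedSet directly from effect/SE arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    pairs = [
        HarmonizedPair(
            snp_id=f"rs{j + 1}",
            effect_allele="A",
            other_allele="G",
            bx=float(bx[j]),
            sx=float(sx[j]),
            by=float(by[j]),
            sy=float(sy[j]),
        )
        for j in range(len(bx))
    ]
    return HarmonizedSet(exposure_label=exposure, outcome_label=outcome, pairs=pairs)


@pytest.fixture
def five_pair_hset():
    """A small heterogeneous instrument set for estimator oracles."""
    rng = np.random.default_rng(42)
    bx = rng.uniform(0.05, 0.15, 5)
    sy = rng.uniform(0.01, 0.05, 5)
    by = 0.5 * bx + rng.normal(0, sy)
    return hset_from_arrays(bx, by, sy, sx=np.full(5, 0.005))


def write_tsv(path, header, rows):
    lines = ["\t".join(header)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
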