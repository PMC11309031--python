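"""Instrument selection: p-value thresholding, LD clumping, strength filtering.

Instruments are genome-wide-significant SNPs (p < 5e-8 by convention, with
per-exposure relaxation when too few variants qualify), pruned to approximate
independence by greedy LD clumping (keep the most significant SNP, discard
correlated neighbours within a window, repeat), and screened for weak-
instrument bias through the F statistic

    F = (N - K - 1) / K * R^2 / (1 - R^2),

where R^2, the variance in the exposure explained by the K instruments, is
the sum of per-SNP contributions R^2_j = 2 * beta_j^2 * EAF_j * (1 - EAF_j).
SNPs with per-SNP F below 10 are conventionally excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, EmptyInstrumentError
from .gwas_io import SummaryRecord, SummaryTable

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if not 0 <= self.clump_r2 <= 1:
            raise ConfigurationError(f"clump_r2 must be in [0,1], got {self.clump_r2}")
        if not self.clump_window_kb > 0:
            raise ConfigurationError(f"clump_window_kb must be > 0, got {self.clump_window_kb}")
        if self.f_min < 0:
            raise ConfigurationError(f"f_min must be >= 0, got {self.f_min}")


class LDTable:
    """Symmetric pairwise r-squared lookup; absent pairs are unlinked (r2=0)."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            if not 0 <= r2 <= 1:
                raise ConfigurationError(f"r2 for ({a},{b}) out of [0,1]: {r2}")
            self._r2[frozenset((a, b))] = r2

    @classmethod
    def from_tsv(cls, path) -> "LDTable":
        """Load a 3-column (snp_a, snp_b, r2) headered TSV."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        cols = list(df.columns)
        if len(cols) < 3:
            raise ConfigurationError(f"{path}: LD table needs 3 columns (snp_a, snp_b, r2)")
        return cls({(str(a), str(b)): float(r) for a, b, r in df.iloc[:, :3].itertuples(index=False)})

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"snp_a": min(k), "snp_b": max(k), "r2": v} for k, v in sorted(self._r2.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


@dataclass
class InstrumentStrength:
    """Per-SNP and joint explained variance and F statistics."""

    r2_per_snp: dict[str, float]
    f_per_snp: dict[str, float]
    r2_total: float
    k: int
    n: int
    f_joint: float


def select_by_pvalue(table: SummaryTable, threshold: float) -> SummaryTable:
    """Retain rows with p strictly below ``threshold``."""
    kept = [r for r in table.records if r.pval < threshold]
    if not kept:
        raise EmptyInstrumentError(
            f"{table.trait_label!r}: no SNP passes p < {threshold:g} "
            f"(min p = {min(r.pval for r in table.records):g})"
        )
    return SummaryTable(table.trait_label, kept, sample_size=table.sample_size)


def greedy_clump(
    table: SummaryTable,
    ld: LDTable | None = None,
    config: SelectionConfig | None = None,
) -> SummaryTable:
    """Greedy LD clumping.

    Repeatedly keep the remaining SNP with the lowest p-value (ties broken
    by genomic position then snp_id) and discard every remaining SNP on the
    same chromosome within the window that has r2 >= ``clump_r2`` with it.
    Output preserves the input row order.
    """
    config = config or SelectionConfig()
    window_bp = config.clump_window_kb * 1000.0
    finite_window = math.isfinite(window_bp)
    if finite_window:
        missing = [r.snp_id for r in table.records if r.chrom is None or r.pos_bp is None]
        if missing:
            raise ConfigurationError(
                "clumping with a finite window needs chrom and pos_bp on every row; "
                f"missing for: {', '.join(missing[:5])}"
            )
    ld = ld or LDTable()

    def pick_key(r: SummaryRecord):
        return (r.pval, r.pos_bp if r.pos_bp is not None else math.inf, r.snp_id)

    remaining = list(table.records)
    kept_ids: set[str] = set()
    while remaining:
        lead = min(remaining, key=pick_key)
        kept_ids.add(lead.snp_id)
        pruned = []
        for r in remaining:
            if r is lead:
                continue
            close = (
                not finite_window
                or (r.chrom == lead.chrom and abs(r.pos_bp - lead.pos_bp) <= window_bp)
            )
            if close and ld.r2(lead.snp_id, r.snp_id) >= config.clump_r2:
                continue  # clumped away
            pruned.append(r)
        remaining = pruned

    kept = [r for r in table.records if r.snp_id in kept_ids]
    return SummaryTable(table.trait_label, kept, sample_size=table.sample_size)


def variance_explained(beta: float, eaf: float | None, snp_id: str = "?") -> float:
    """Per-SNP explained variance R^2_j = 2 * beta^2 * EAF * (1 - EAF)."""
    if eaf is None:
        raise ConfigurationError(f"SNP {snp_id}: eaf required to compute explained variance")
    return 2.0 * beta * beta * eaf * (1.0 - eaf)


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Instrument-strength F = (N - K - 1)/K * R^2/(1 - R^2)."""
    if not 0 <= r2_total < 1:
        raise ValueError(f"r2_total must be in [0,1), got {r2_total}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    return (n - k - 1) / k * r2_total / (1.0 - r2_total)


def _record_n(rec: SummaryRecord, table: SummaryTable) -> int:
    n = rec.n if rec.n is not None else table.sample_size
    if n is None:
        raise ConfigurationError(f"SNP {rec.snp_id}: sample size required for F statistic")
    return n


def instrument_strength(table: SummaryTable) -> InstrumentStrength:
    """Per-SNP (K=1) and joint F statistics for an instrument set."""
    r2_per: dict[str, float] = {}
    f_per: dict[str, float] = {}
    ns = []
    for rec in table.records:
        r2_j = variance_explained(rec.beta, rec.eaf, rec.snp_id)
        n_j = _record_n(rec, table)
        r2_per[rec.snp_id] = r2_j
        f_per[rec.snp_id] = f_statistic(r2_j, n_j, 1)
        ns.append(n_j)
    k = len(table)
    n = table.sample_size if table.sample_size is not None else min(ns)
    r2_total = sum(r2_per.values())
    return InstrumentStrength(
        r2_per_snp=r2_per,
        f_per_snp=f_per,
        r2_total=r2_total,
        k=k,
        n=n,
        f_joint=f_statistic(r2_total, n, k),
    )


def filter_weak(
    table: SummaryTable,
    f_min: float = 10.0,
    strength: InstrumentStrength | None = None,
) -> SummaryTable:
    """Drop SNPs whose per-SNP F (K=1) is strictly below ``f_min``."""
    strength = strength or instrument_strength(table)
    kept, dropped = [], []
    for rec in table.records:
        if strength.f_per_snp[rec.snp_id] >= f_min:
            kept.append(rec)
        else:
            dropped.append(rec.snp_id)
    if dropped:
        logger.info(
            "%s: excluded %d weak instrument(s) with F < %g: %s",
            table.trait_label,
            len(dropped),
            f_min,
            ", ".join(dropped),
        )
    if not kept:
        raise EmptyInstrumentError(
            f"{table.trait_label!r}: all {len(table)} instruments have F < {f_min:g}"
        )
    return SummaryTable(table.trait_label, kept, sample_size=table.sample_size)
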