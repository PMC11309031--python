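"""Reading, validating and writing GWAS summary-statistic tables.

A summary table holds one row per SNP with the association of that variant
with a single trait: effect/other allele, effect-allele frequency (EAF),
per-allele effect estimate ``beta`` with its standard error, p-value, and
sample size.  Files are headered TSV by default (the conventional dialect
for GWAS summary downloads); arbitrary column names are absorbed through a
role -> column name mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import pandas as pd

from .errors import ConfigurationError, TableValidationError

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: canonical column names, one per role
ROLES = (
    "snp_id",
    "chrom",
    "pos_bp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)
MANDATORY_ROLES = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

_FLOAT_ROLES = ("eaf", "beta", "se", "pval")
_INT_ROLES = ("pos_bp", "n")


@dataclass(slots=True)
class SummaryRecord:
    """One SNP-trait association.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (trait units or log-odds); ``eaf`` is the effect-allele frequency.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos_bp: int | None = None
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        # alleles are normalized to upper case before any comparison
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        out: list[str] = []
        if self.effect_allele not in NUCLEOTIDES:
            out.append(f"{self.snp_id}: effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in NUCLEOTIDES:
            out.append(f"{self.snp_id}: other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            out.append(f"{self.snp_id}: effect_allele equals other_allele")
        if not self.se > 0:
            out.append(f"{self.snp_id}: se must be > 0 (got {self.se})")
        if not 0 < self.pval <= 1:
            out.append(f"{self.snp_id}: pval must be in (0, 1] (got {self.pval})")
        if self.eaf is not None and not 0 <= self.eaf <= 1:
            out.append(f"{self.snp_id}: eaf must be in [0, 1] (got {self.eaf})")
        if self.n is not None and self.n <= 0:
            out.append(f"{self.snp_id}: n must be positive (got {self.n})")
        return out


@dataclass
class SummaryTable:
    """An ordered collection of :class:`SummaryRecord` for one trait."""

    trait_label: str
    records: list[SummaryRecord]
    sample_size: int | None = None  # table-level default for per-SNP n

    def __post_init__(self) -> None:
        if not self.records:
            raise TableValidationError(f"summary table {self.trait_label!r} is empty")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def record(self, snp_id: str) -> SummaryRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [{f.name: getattr(r, f.name) for f in fields(SummaryRecord)} for r in self.records]
        return pd.DataFrame(rows, columns=list(ROLES))


def validate_table(table: SummaryTable) -> list[str]:
    """Collect invariant violations for every record plus table-level checks.

    Never raises: returns an empty list iff the table is fully valid.  The
    violation set is independent of record order.
    """
    out: list[str] = []
    for rec in table.records:
        out.extend(rec.violations())
    seen: dict[str, int] = {}
    for rec in table.records:
        seen[rec.snp_id] = seen.get(rec.snp_id, 0) + 1
    for snp, count in seen.items():
        if count > 1:
            out.append(f"table: duplicate snp_id {snp} ({count} rows)")
    return sorted(out)


def _parse_row(raw: dict[str, str], line: int) -> SummaryRecord:
    kwargs: dict[str, object] = {}
    for role, value in raw.items():
        if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
            kwargs[role] = None
            continue
        try:
            if role in _FLOAT_ROLES:
                kwargs[role] = float(value)
            elif role in _INT_ROLES:
                kwargs[role] = int(float(value))
            else:
                kwargs[role] = str(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {line}: cannot parse {role}={value!r}") from exc
    for role in MANDATORY_ROLES:
        if kwargs.get(role) is None:
            raise ValueError(f"line {line}: missing value for mandatory column role {role!r}")
    return SummaryRecord(**kwargs)  # type: ignore[arg-type]


def read_summary_table(
    path,
    column_map: dict[str, str] | None = None,
    trait_label: str | None = None,
    *,
    delimiter: str = "\t",
    sample_size: int | None = None,
    strict: bool = False,
) -> SummaryTable:
    """Read a headered delimited file into a validated :class:`SummaryTable`.

    Parameters
    ----------
    column_map
        Mapping from role (``snp_id``, ``beta``, ...) to the column name in
        the file.  Defaults to the identity mapping on the canonical role
        names.  Must cover at least the mandatory roles.
    strict
        When True any invalid row aborts the read; otherwise invalid rows
        are dropped and reported through the module logger.
    """
    column_map = dict(column_map) if column_map else {r: r for r in ROLES}
    missing_roles = [r for r in MANDATORY_ROLES if r not in column_map]
    if missing_roles:
        raise ConfigurationError(
            f"column_map is missing mandatory role(s): {', '.join(missing_roles)}"
        )

    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing_cols = [c for r, c in column_map.items() if r in MANDATORY_ROLES and c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"{path}: mandatory column(s) not found in file: {', '.join(missing_cols)}"
        )
    present = {role: col for role, col in column_map.items() if col in df.columns}

    records: list[SummaryRecord] = []
    issues: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        line = i + 2  # header is line 1
        try:
            rec = _parse_row({role: row_d[col] for role, col in present.items()}, line)
        except ValueError as exc:
            issues.append(str(exc))
            continue
        bad = rec.violations()
        if bad:
            issues.append(f"line {line}: " + "; ".join(bad))
            continue
        records.append(rec)

    if issues:
        if strict:
            raise TableValidationError(f"{path}: {len(issues)} invalid row(s): " + " | ".join(issues))
        for msg in issues:
            logger.warning("%s: rejected row: %s", path, msg)
    if not records:
        raise TableValidationError(f"{path}: no valid rows after parsing")
    label = trait_label if trait_label is not None else str(path)
    return SummaryTable(trait_label=label, records=records, sample_size=sample_size)


def write_summary_table(table: SummaryTable, path) -> None:
    """Write a table as canonical headered TSV.

    Optional columns whose value is absent on every record are omitted, so
    a read -> write -> read cycle is the identity on all fields.
    """
    df = table.to_frame()
    df = df.drop(columns=[c for c in ("chrom", "pos_bp", "eaf", "n") if df[c].isna().all()])
    for col in ("pos_bp", "n"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    df.to_csv(path, sep="\t", index=False)
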