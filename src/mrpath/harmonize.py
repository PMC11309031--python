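"""Harmonization of exposure and outcome summary statistics.

Two-sample MR needs the outcome effect of every instrument expressed on the
*exposure's* effect allele.  Alleles may be reported in swapped order or on
the opposite strand between studies, so each exposure/outcome record pair is
aligned by comparing allele pairs up to reverse complement.  Palindromic
variants (A/T or C/G) carry no strand information in their allele letters;
they are resolved through allele-frequency concordance when frequencies are
informative, and dropped as ambiguous otherwise.  Instruments absent from
the outcome study are dropped rather than proxied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .errors import EmptyInstrumentError
from .gwas_io import SummaryRecord, SummaryTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: palindromic SNPs with either study's EAF inside this closed band are
#: considered strand-ambiguous and dropped
DEFAULT_AMBIGUITY_BAND = (0.30, 0.70)

RETAINED_ACTIONS = frozenset({"kept", "flipped"})


@dataclass(slots=True)
class HarmonizedPair:
    """Exposure/outcome effects for one SNP on a shared effect allele.

    ``bx``/``sx`` are the exposure effect and SE, ``by``/``sy`` the outcome
    effect and SE after alignment.  ``action`` records what alignment did;
    only ``kept`` and ``flipped`` pairs enter estimation.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    bx: float
    sx: float
    by: float
    sy: float
    eaf_x: float | None = None
    eaf_y: float | None = None
    action: str = "kept"


@dataclass
class HarmonizedSet:
    """Retained harmonized pairs plus a complete exclusion log."""

    exposure_label: str
    outcome_label: str
    pairs: list[HarmonizedPair]
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(bx, sx, by, sy) as float arrays, in pair order."""
        return (
            np.array([p.bx for p in self.pairs], dtype=float),
            np.array([p.sx for p in self.pairs], dtype=float),
            np.array([p.by for p in self.pairs], dtype=float),
            np.array([p.sy for p in self.pairs], dtype=float),
        )

    def subset(self, snp_ids) -> "HarmonizedSet":
        keep = set(snp_ids)
        return HarmonizedSet(
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            pairs=[p for p in self.pairs if p.snp_id in keep],
            exclusion_log=list(self.exclusion_log),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in fields(HarmonizedPair)]
        return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in self.pairs], columns=cols)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is A/T or C/G (strand-ambiguous)."""
    pair = {a1.upper(), a2.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _in_band(eaf: float, band: tuple[float, float]) -> bool:
    return band[0] <= eaf <= band[1]


def align_record(
    exp: SummaryRecord,
    out: SummaryRecord,
    ambiguity_band: tuple[float, float] = DEFAULT_AMBIGUITY_BAND,
) -> HarmonizedPair:
    """Align one outcome record onto the exposure record's effect allele.

    The outcome effect is negated (and its EAF reflected) once per allele
    flip; an odd number of flips yields action ``flipped``.  Palindromic
    SNPs are aligned through minor/major frequency status when both EAFs
    are informative (outside ``ambiguity_band``), otherwise dropped.
    """
    if exp.snp_id != out.snp_id:
        raise ValueError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")

    ea, oa = exp.effect_allele, exp.other_allele
    by, eaf_y = out.beta, out.eaf
    o_ea, o_oa = out.effect_allele, out.other_allele
    flips = 0
    action = None

    if is_palindromic(ea, oa):
        if {o_ea, o_oa} != {ea, oa}:
            action = "dropped_mismatch"
        elif exp.eaf is None or out.eaf is None:
            action = "dropped_palindromic"
        elif _in_band(exp.eaf, ambiguity_band) or _in_band(out.eaf, ambiguity_band):
            action = "dropped_palindromic"
        else:
            if o_ea != ea:  # letters reported in swapped order
                by, eaf_y = -by, 1 - eaf_y
                flips += 1
            if (exp.eaf < 0.5) != (eaf_y < 0.5):  # opposite strand: frequency disagrees
                by, eaf_y = -by, 1 - eaf_y
                flips += 1
    else:
        c_ea, c_oa = COMPLEMENT[ea], COMPLEMENT[oa]
        if (o_ea, o_oa) in ((ea, oa), (c_ea, c_oa)):
            pass
        elif (o_ea, o_oa) in ((oa, ea), (c_oa, c_ea)):
            by = -by
            if eaf_y is not None:
                eaf_y = 1 - eaf_y
            flips += 1
        else:
            action = "dropped_mismatch"

    if action is None:
        action = "flipped" if flips % 2 else "kept"
    return HarmonizedPair(
        snp_id=exp.snp_id,
        effect_allele=ea,
        other_allele=oa,
        bx=exp.beta,
        sx=exp.se,
        by=by,
        sy=out.se,
        eaf_x=exp.eaf,
        eaf_y=eaf_y,
        action=action,
    )


def harmonize_tables(
    exposure: SummaryTable,
    outcome: SummaryTable,
    ambiguity_band: tuple[float, float] = DEFAULT_AMBIGUITY_BAND,
) -> HarmonizedSet:
    """Harmonize every exposure SNP against the outcome table.

    Exposure SNPs absent from the outcome are logged as ``dropped_absent``
    (no proxy substitution).  Every exposure SNP appears either in ``pairs``
    or in ``exclusion_log``.
    """
    by_id: dict[str, SummaryRecord] = {}
    for rec in outcome.records:
        by_id.setdefault(rec.snp_id, rec)

    pairs: list[HarmonizedPair] = []
    log: list[tuple[str, str]] = []
    for rec in exposure.records:
        out = by_id.get(rec.snp_id)
        if out is None:
            log.append((rec.snp_id, "dropped_absent"))
            continue
        pair = align_record(rec, out, ambiguity_band)
        if pair.action in RETAINED_ACTIONS:
            pairs.append(pair)
        else:
            log.append((pair.snp_id, pair.action))

    if not pairs:
        raise EmptyInstrumentError(
            f"no instruments retained harmonizing {exposure.trait_label!r} "
            f"against {outcome.trait_label!r} ({len(log)} excluded)"
        )
    return HarmonizedSet(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        pairs=pairs,
        exclusion_log=log,
    )
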