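"""Orchestration of the three-stage analysis from a config file.

Stage 1 (univariable): per exposure, select instruments by p-value, clump,
filter weak instruments, harmonize against the outcome, run the five-method
estimator suite plus the sensitivity battery, then BH-FDR-adjust the
configured p-value family across exposures.  Stage 2 (two-step mediation):
screen mediators for a significant (and non-pleiotropic) effect on the
outcome, estimate exposure -> mediator effects for the exposures that were
significant on the outcome after FDR, and bootstrap the indirect effect and
proportion mediated per surviving pathway.  Per-exposure and per-pathway
failures are logged and contained; config-level errors abort.

All randomness descends deterministically from the single config seed, so
identical inputs, config and seed give byte-identical report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, MRError
from .estimators import MethodConfig, bh_fdr, ivw_multiplicative_re, run_method_suite
from .gwas_io import SummaryTable, read_summary_table
from .harmonize import harmonize_tables
from .instruments import LDTable, SelectionConfig, filter_weak, greedy_clump, select_by_pvalue
from .mediation import MediationInput, bootstrap_mediation
from .sensitivity import (
    PressoConfig,
    cochran_q_ivw,
    egger_intercept_test,
    rucker_q_egger,
    run_presso,
)

logger = logging.getLogger(__name__)

UNIVARIABLE_COLUMNS = [
    "exposure", "outcome", "nsnp", "method", "beta", "se",
    "ci_low", "ci_high", "pval", "pval_fdr",
]
SENSITIVITY_COLUMNS = [
    "exposure", "outcome", "nsnp", "q_ivw", "q_ivw_df", "q_ivw_pval",
    "q_egger", "q_egger_df", "q_egger_pval",
    "egger_intercept", "egger_intercept_se", "egger_intercept_pval",
    "presso_global_pval", "n_outliers", "distortion_pval",
]
MEDIATION_COLUMNS = [
    "pathway", "beta1", "beta2", "beta3", "indirect", "indirect_ci_low",
    "indirect_ci_high", "proportion", "proportion_ci_low", "proportion_ci_high", "pval",
]


@dataclass
class TraitSpec:
    """One summary-statistics source."""

    label: str
    path: str
    p_threshold: float = 5e-8
    column_map: dict | None = None
    sample_size: int | None = None


@dataclass
class AnalysisConfig:
    exposures: list[TraitSpec]
    outcome: TraitSpec
    mediators: list[TraitSpec] = field(default_factory=list)
    ld_path: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    method: MethodConfig = field(default_factory=MethodConfig)
    presso: PressoConfig = field(default_factory=PressoConfig)
    mediation_B: int = 10_000
    fdr_family: str = "ivw"
    screen_alpha: float = 0.05
    outdir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.exposures:
            raise ConfigurationError("at least one exposure is required")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError as exc:
            raise ConfigurationError(f"config file not found: {path}") from exc
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")

        def trait(d) -> TraitSpec:
            if not isinstance(d, dict) or "label" not in d or "path" not in d:
                raise ConfigurationError(f"{path}: trait entries need 'label' and 'path': {d!r}")
            return TraitSpec(**d)

        try:
            kwargs = dict(
                exposures=[trait(e) for e in raw.get("exposures", [])],
                outcome=trait(raw["outcome"]),
                mediators=[trait(m) for m in raw.get("mediators", [])],
                ld_path=raw.get("ld_table"),
                selection=SelectionConfig(**raw.get("selection", {})),
                method=MethodConfig(**raw.get("methods", {})),
                presso=PressoConfig(**raw.get("presso", {})),
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: missing required section {exc}") from exc
        except TypeError as exc:
            raise ConfigurationError(f"{path}: bad config key: {exc}") from exc
        for key in ("mediation_B", "fdr_family", "screen_alpha", "outdir", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        logging verbosity excluded, since they cannot affect the results)."""

        def default(o):
            return {k: v for k, v in o.__dict__.items() if k not in ("outdir", "log_level")}

        blob = json.dumps(self, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultsReport:
    univariable: pd.DataFrame
    sensitivity: pd.DataFrame
    mediation: pd.DataFrame
    failures: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.univariable.to_csv(outdir / "univariable.tsv", sep="\t", index=False)
        self.sensitivity.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
        self.mediation.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
        meta = dict(self.metadata)
        meta["failures"] = self.failures
        (outdir / "run.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def derive_seed(master: int, tag: str) -> int:
    """Deterministic per-component seed from the master seed and a label."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


def _read_trait(spec: TraitSpec) -> SummaryTable:
    return read_summary_table(
        spec.path,
        column_map=spec.column_map,
        trait_label=spec.label,
        sample_size=spec.sample_size,
    )


def prepare_instruments(
    table: SummaryTable,
    p_threshold: float,
    selection: SelectionConfig,
    ld: LDTable | None,
) -> SummaryTable:
    """select_by_pvalue -> greedy_clump -> weak-instrument filter."""
    selected = select_by_pvalue(table, p_threshold)
    logger.info("%s: %d SNP(s) pass p < %g", table.trait_label, len(selected), p_threshold)
    clumped = greedy_clump(selected, ld, selection)
    logger.info("%s: %d SNP(s) after clumping", table.trait_label, len(clumped))
    strong = filter_weak(clumped, selection.f_min)
    logger.info("%s: %d SNP(s) after F >= %g filter", table.trait_label, len(strong), selection.f_min)
    return strong


def _sensitivity_row(hset, presso_cfg: PressoConfig) -> dict:
    row: dict = {"exposure": hset.exposure_label, "outcome": hset.outcome_label, "nsnp": len(hset)}
    if len(hset) >= 2:
        q = cochran_q_ivw(hset)
        row.update(q_ivw=q.Q, q_ivw_df=q.df, q_ivw_pval=q.pval)
    if len(hset) >= 3:
        qe = rucker_q_egger(hset)
        pl = egger_intercept_test(hset)
        row.update(
            q_egger=qe.Q, q_egger_df=qe.df, q_egger_pval=qe.pval,
            egger_intercept=pl.intercept, egger_intercept_se=pl.intercept_se,
            egger_intercept_pval=pl.pval,
        )
    if len(hset) >= 4:
        pr = run_presso(hset, presso_cfg)
        row.update(
            presso_global_pval=pr.global_pval,
            n_outliers=len(pr.outliers),
            distortion_pval=pr.distortion_pval,
        )
    return row


def _estimate_pathway_leg(cfg: AnalysisConfig, exposure_spec: TraitSpec, target: SummaryTable, ld):
    """Instrument the exposure and IVW-estimate its effect on ``target``."""
    table = _read_trait(exposure_spec)
    instruments = prepare_instruments(table, exposure_spec.p_threshold, cfg.selection, ld)
    hset = harmonize_tables(instruments, target)
    return ivw_multiplicative_re(hset, cfg.method.alpha), hset


def run_univariable(cfg: AnalysisConfig) -> ResultsReport:
    """Stage 1: every exposure against the outcome, plus sensitivity tests."""
    ld = LDTable.from_tsv(cfg.ld_path) if cfg.ld_path else None
    outcome = _read_trait(cfg.outcome)

    uni_rows: list[dict] = []
    sens_rows: list[dict] = []
    failures: list[dict] = []
    for spec in cfg.exposures:
        try:
            table = _read_trait(spec)
            instruments = prepare_instruments(table, spec.p_threshold, cfg.selection, ld)
            hset = harmonize_tables(instruments, outcome)
            mcfg = MethodConfig(
                bootstrap_B=cfg.method.bootstrap_B,
                seed=derive_seed(cfg.seed, f"suite:{spec.label}"),
                phi=cfg.method.phi,
                alpha=cfg.method.alpha,
            )
            for est in run_method_suite(hset, mcfg):
                uni_rows.append(
                    dict(
                        exposure=spec.label, outcome=cfg.outcome.label, nsnp=est.nsnp,
                        method=est.method, beta=est.beta, se=est.se,
                        ci_low=est.ci_low, ci_high=est.ci_high, pval=est.pval,
                        pval_fdr=np.nan,
                    )
                )
            pcfg = PressoConfig(
                nb_sim=cfg.presso.nb_sim,
                seed=derive_seed(cfg.seed, f"presso:{spec.label}"),
                sig_threshold=cfg.presso.sig_threshold,
            )
            sens_rows.append(_sensitivity_row(hset, pcfg))
        except MRError as exc:
            logger.warning("exposure %s failed: %s", spec.label, exc)
            failures.append({"exposure": spec.label, "stage": "univariable", "reason": str(exc)})

    uni = pd.DataFrame(uni_rows, columns=UNIVARIABLE_COLUMNS)
    if cfg.fdr_family == "ivw" and len(uni):
        mask = uni["method"].isin(["IVW", "Wald ratio"])
        if mask.any():
            uni.loc[mask, "pval_fdr"] = bh_fdr(uni.loc[mask, "pval"])
    elif len(uni):  # adjust every reported p-value jointly
        uni["pval_fdr"] = bh_fdr(uni["pval"])

    sens = pd.DataFrame(sens_rows, columns=SENSITIVITY_COLUMNS)
    meta = {
        "mrpath_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_exposures": len(cfg.exposures),
    }
    return ResultsReport(
        univariable=uni,
        sensitivity=sens,
        mediation=pd.DataFrame(columns=MEDIATION_COLUMNS),
        failures=failures,
        metadata=meta,
    )


def run_two_step(cfg: AnalysisConfig, report: ResultsReport | None = None) -> ResultsReport:
    """Stage 2: two-step MR mediation for significant exposure/mediator pairs."""
    report = report if report is not None else run_univariable(cfg)
    ld = LDTable.from_tsv(cfg.ld_path) if cfg.ld_path else None
    outcome = _read_trait(cfg.outcome)

    uni = report.univariable
    ivw = uni[uni["method"].isin(["IVW", "Wald ratio"])]
    sig_exposures = [
        spec
        for spec in cfg.exposures
        if not ivw[(ivw["exposure"] == spec.label) & (ivw["pval_fdr"] < cfg.screen_alpha)].empty
    ]
    if not sig_exposures:
        logger.info("no exposure significant on the outcome after FDR; mediation skipped")
        return report

    med_rows: list[dict] = []
    for mspec in cfg.mediators:
        try:
            e2, h_my = _estimate_pathway_leg(cfg, mspec, outcome, ld)
            if e2.pval >= cfg.screen_alpha:
                logger.info("mediator %s not significant on outcome (p=%.3g); skipped", mspec.label, e2.pval)
                continue
            if len(h_my) >= 3 and egger_intercept_test(h_my).pval < cfg.screen_alpha:
                logger.info("mediator %s shows directional pleiotropy on outcome; excluded", mspec.label)
                continue
        except MRError as exc:
            logger.warning("mediator %s failed: %s", mspec.label, exc)
            report.failures.append({"mediator": mspec.label, "stage": "mediator_screen", "reason": str(exc)})
            continue

        mediator_table = _read_trait(mspec)
        for espec in sig_exposures:
            try:
                e1, _ = _estimate_pathway_leg(cfg, espec, mediator_table, ld)
                if e1.pval >= cfg.screen_alpha:
                    logger.info(
                        "exposure %s not significant on mediator %s (p=%.3g); pathway skipped",
                        espec.label, mspec.label, e1.pval,
                    )
                    continue
                row3 = ivw[(ivw["exposure"] == espec.label)].iloc[0]
                inp = MediationInput(
                    beta1=e1.beta, se1=e1.se,
                    beta2=e2.beta, se2=e2.se,
                    beta3=float(row3["beta"]), se3=float(row3["se"]),
                    exposure_label=espec.label,
                    mediator_label=mspec.label,
                    outcome_label=cfg.outcome.label,
                )
                res = bootstrap_mediation(
                    inp, B=cfg.mediation_B,
                    seed=derive_seed(cfg.seed, f"mediation:{espec.label}:{mspec.label}"),
                )
                med_rows.append(
                    dict(
                        pathway=res.pathway, beta1=inp.beta1, beta2=inp.beta2, beta3=inp.beta3,
                        indirect=res.indirect,
                        indirect_ci_low=res.ci_indirect[0], indirect_ci_high=res.ci_indirect[1],
                        proportion=res.proportion,
                        proportion_ci_low=res.ci_proportion[0], proportion_ci_high=res.ci_proportion[1],
                        pval=res.pval,
                    )
                )
            except MRError as exc:
                logger.warning("pathway %s via %s failed: %s", espec.label, mspec.label, exc)
                report.failures.append(
                    {"exposure": espec.label, "mediator": mspec.label, "stage": "two_step", "reason": str(exc)}
                )

    report.mediation = pd.DataFrame(med_rows, columns=MEDIATION_COLUMNS)
    return report


def run_all(cfg: AnalysisConfig) -> ResultsReport:
    """Full pipeline: univariable stage then two-step mediation."""
    return run_two_step(cfg, run_univariable(cfg))
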