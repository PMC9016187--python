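"""End-to-end orchestration: tables in, estimates + diagnostics + files out.

Stage order is fixed: significance filter → LD clumping → harmonization →
weak-instrument (F) filter → Steiger directionality filter → estimation →
sensitivity.  A run manifest records the SNP count surviving each stage so
the instrument trail can be audited.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .estimators import EstimatorConfig, MRAnalysis, run_all_estimators
from .sensitivity import SensitivityConfig, SensitivityReport, run_sensitivity
from .summary_data import (GwasSummaryTable, HarmonizationLog,
                           HarmonizedInstrument, filter_strong, harmonize,
                           instruments_to_frame, ld_clump,
                           read_summary_table, select_significant,
                           steiger_filter)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs, loadable from YAML or JSON."""

    exposure_path: str
    outcome_path: str
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    exposure_columns: dict | None = None
    outcome_columns: dict | None = None
    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    window_kb: float = 250.0
    ld_path: str | None = None  # TSV: snp_a, snp_b, r2
    f_threshold: float = 10.0
    palindromic_eaf_window: float = 0.08
    r2_method: str = "beta_se"
    ivw_model: str = "multiplicative_random"
    phi: float = 1.0
    n_boot: int = 1000
    k_sim: int = 1000
    outlier_alpha: float = 0.05
    run_presso: bool = True
    seed: int = 20220405
    out_dir: str = "mr_output"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ConfigurationError("p_threshold must be in (0, 1]")
        if not (0 < self.r2_threshold < 1):
            raise ConfigurationError("r2_threshold must be in (0, 1)")
        if self.f_threshold < 0:
            raise ConfigurationError("f_threshold must be non-negative")
        if self.seed is None:
            raise ConfigurationError("seed is required")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path} does not contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def estimator_config(self) -> EstimatorConfig:
        return EstimatorConfig(ivw_model=self.ivw_model, phi=self.phi,
                               n_boot=self.n_boot, seed=self.seed)

    def sensitivity_config(self) -> SensitivityConfig:
        return SensitivityConfig(k_sim=self.k_sim, seed=self.seed,
                                 outlier_alpha=self.outlier_alpha,
                                 run_presso=self.run_presso,
                                 ivw_model=self.ivw_model)


STAGES = ("input_exposure", "significant", "clumped", "harmonized",
          "f_passed", "steiger_passed")


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config: dict
    version: str
    counts: dict[str, int]
    started: str = ""
    finished: str = ""
    harmonization_actions: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


def load_ld_table(path) -> dict[tuple[str, str], float]:
    """Read a pairwise LD table (columns snp_a, snp_b, r2) into a lookup."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise ConfigurationError(f"LD table {path} lacks column {col!r}")
    return {(a, b): float(r)
            for a, b, r in zip(df["snp_a"], df["snp_b"], df["r2"])}


def build_instruments(exposure: GwasSummaryTable, outcome: GwasSummaryTable,
                      config: AnalysisConfig, ld=None,
                      ) -> tuple[list[HarmonizedInstrument], dict[str, int],
                                 HarmonizationLog]:
    """Run the filtering stages and return the surviving instrument set."""
    counts = {"input_exposure": len(exposure)}
    sig = select_significant(exposure, config.p_threshold)
    counts["significant"] = len(sig)
    if len(sig) == 0:
        return [], counts, HarmonizationLog()
    clumped = ld_clump(sig, config.r2_threshold, ld=ld,
                       window_kb=config.window_kb)
    counts["clumped"] = len(clumped)
    harmonized, log = harmonize(clumped, outcome,
                                config.palindromic_eaf_window,
                                config.r2_method)
    counts["harmonized"] = len(harmonized)
    strong, weak = filter_strong(harmonized, config.f_threshold)
    counts["f_passed"] = len(strong)
    kept, dropped = steiger_filter(strong)
    counts["steiger_passed"] = len(kept)
    if weak:
        logger.info("dropped %d weak instruments (F < %g)", len(weak),
                    config.f_threshold)
    if dropped:
        logger.info("Steiger filter removed %d SNPs", len(dropped))
    return kept, counts, log


@dataclass
class PipelineResult:
    estimates: MRAnalysis
    sensitivity: SensitivityReport | None
    manifest: RunManifest
    harmonization_log: HarmonizationLog
    instruments: list[HarmonizedInstrument]


def _version() -> str:
    from . import __version__
    return __version__


def run_tables(exposure: GwasSummaryTable, outcome: GwasSummaryTable,
               config: AnalysisConfig, ld=None) -> PipelineResult:
    """Run the full analysis on in-memory tables."""
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    instruments, counts, log = build_instruments(exposure, outcome, config,
                                                 ld)
    manifest = RunManifest(config=config.to_dict(), version=_version(),
                           counts=counts, started=started,
                           harmonization_actions=log.counts())
    if len(instruments) < 1:
        manifest.finished = datetime.datetime.now(
            datetime.timezone.utc).isoformat()
        raise PipelineDataError(
            "no instrument survives the filtering stages", manifest)
    estimates = run_all_estimators(instruments, config.estimator_config())
    sens = None
    if len(instruments) >= 3:
        sens = run_sensitivity(instruments, config.sensitivity_config())
    manifest.finished = datetime.datetime.now(
        datetime.timezone.utc).isoformat()
    return PipelineResult(estimates, sens, manifest, log, instruments)


class PipelineDataError(DataError):
    """Data error carrying the manifest so failed runs stay auditable."""

    def __init__(self, message: str, manifest: RunManifest):
        super().__init__(message)
        self.manifest = manifest


def write_outputs(result: PipelineResult, out_dir,
                  make_plots: bool = False) -> dict[str, str]:
    """Serialize a pipeline result into its output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(name: str, writer) -> None:
        p = out / name
        writer(p)
        paths[name] = str(p)

    _save("results.tsv", lambda p: result.estimates.to_frame().to_csv(
        p, sep="\t", index=False))
    _save("forest.tsv", lambda p: result.estimates.forest_frame().to_csv(
        p, sep="\t", index=False))
    _save("instruments.tsv", lambda p: instruments_to_frame(
        result.instruments).to_csv(p, sep="\t", index=False))
    _save("harmonization_log.tsv", result.harmonization_log.write)
    _save("manifest.json", result.manifest.write)
    if result.sensitivity is not None:
        sens = result.sensitivity
        _save("sensitivity.json", lambda p: Path(p).write_text(
            json.dumps(sens.to_json_dict(), indent=1)))
        _save("funnel.tsv", lambda p: sens.funnel.to_csv(
            p, sep="\t", index=False))
        _save("loo.tsv", lambda p: sens.loo.table.to_csv(
            p, sep="\t", index=False))
        if make_plots:
            from . import plots
            _save("forest.svg", lambda p: plots.forest_plot(
                result.estimates.forest_frame(),
                result.estimates.to_frame(), p))
            _save("funnel.svg", lambda p: plots.funnel_plot(
                sens.funnel, result.estimates.results["ivw"].beta, p))
            _save("loo.svg", lambda p: plots.loo_plot(
                sens.loo.table, sens.loo.full, p))
    return paths


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Read the configured input files, run the analysis, write outputs.

    On a run where every instrument is filtered away, the manifest is still
    written to the output directory before the error propagates.
    """
    exposure = read_summary_table(config.exposure_path,
                                  config.exposure_label,
                                  config.exposure_columns)
    outcome = read_summary_table(config.outcome_path, config.outcome_label,
                                 config.outcome_columns)
    ld = load_ld_table(config.ld_path) if config.ld_path else None
    try:
        result = run_tables(exposure, outcome, config, ld)
    except PipelineDataError as err:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        err.manifest.write(out / "manifest.json")
        raise
    write_outputs(result, config.out_dir, config.make_plots)
    return result
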