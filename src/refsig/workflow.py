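"""End-to-end orchestration of the discovery / validation / testing phases.

``run_experiment`` executes the whole methodology on a list of loaded
datasets: pick the discovery dataset (shortest median ASV length), run
REFS on it, validate the selected signature and the full feature table,
then for every testing dataset search the signature by containment,
validate the matched sub-table, and run the K-Best and random-selection
baselines with matched sizes (k = REFS signature size; m = number of REFS
features found in that testing dataset). The result is a per-dataset
comparison table of classifier x {AUC, MCC} blocks plus a reproducibility
manifest (config hash, seeds, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .baselines import BaselineResult, kbest_select, random_select
from .cross_dataset import SignatureMatch, match_signature, test_signature
from .data_model import (
    AbundanceDataset,
    DatasetError,
    FeatureSignature,
    load_abundance_dataset,
    select_discovery_dataset,
    write_signature,
)
from .refs import RefsConfig, RefsResult, refs_select
from .validation import ValidationReport, validate_features

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "TestingComparison",
    "run_experiment",
    "load_experiment_config",
    "run_experiment_from_config",
    "write_experiment_bundle",
]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """File-level description of a full experiment (YAML-loadable)."""

    datasets: list[dict]  # each: {name, counts, fasta, labels}
    refs: RefsConfig = field(default_factory=RefsConfig)
    validation_runs: int = 10
    seed: int = 0
    match_mode: str = "forward"
    run_baselines: bool = True
    random_runs: int = 10
    n_folds: int = 10
    discovery_override: str | None = None
    allow_fewer_datasets: bool = False
    output_dir: str = "refsig_out"

    def validate(self) -> None:
        if len(self.datasets) < 3 and not self.allow_fewer_datasets:
            raise DatasetError(
                "the methodology recommends at least three datasets "
                "(one discovery, two testing); set allow_fewer_datasets to override"
            )
        for entry in self.datasets:
            for key in ("counts", "fasta", "labels"):
                if key not in entry:
                    raise DatasetError(f"dataset entry missing {key!r}: {entry}")
                if not Path(entry[key]).exists():
                    raise DatasetError(f"missing file: {entry[key]}")
        self.refs.validate()

    def content_hash(self) -> str:
        blob = json.dumps(
            {
                "datasets": self.datasets,
                "refs": vars(self.refs),
                "validation_runs": self.validation_runs,
                "seed": self.seed,
                "match_mode": self.match_mode,
                "run_baselines": self.run_baselines,
                "random_runs": self.random_runs,
                "n_folds": self.n_folds,
                "discovery_override": self.discovery_override,
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class TestingComparison:
    """All method results on one testing dataset."""

    dataset_name: str
    refs_match: SignatureMatch
    refs_report: ValidationReport
    kbest_match: SignatureMatch | None = None
    kbest_report: ValidationReport | None = None
    random_result: BaselineResult | None = None


@dataclass
class ExperimentReport:
    discovery_name: str
    discovery_index: int
    refs_result: RefsResult
    discovery_reports: dict[str, ValidationReport]
    kbest_signature: FeatureSignature | None
    testing: list[TestingComparison]
    manifest: dict


# ---------------------------------------------------------------------------
# comparison-table assembly
# ---------------------------------------------------------------------------


def comparison_table(blocks: dict[str, ValidationReport | BaselineResult]) -> pd.DataFrame:
    """Classifier x {AUC, MCC} table with one block per method and an
    Average row equal to the mean of the five classifier rows."""
    columns: dict[tuple[str, str], list[float]] = {}
    index: list[str] | None = None
    for method, rep in blocks.items():
        if isinstance(rep, BaselineResult):
            names = [c.name for c in rep.reports[0].per_classifier]
            aucs = [
                float(pd.Series([r.per_classifier[i].mean_auc for r in rep.reports]).mean())
                for i in range(len(names))
            ]
            mccs = [
                float(pd.Series([r.per_classifier[i].mcc for r in rep.reports]).mean())
                for i in range(len(names))
            ]
        else:
            names = [c.name for c in rep.per_classifier]
            aucs = [c.mean_auc for c in rep.per_classifier]
            mccs = [c.mcc for c in rep.per_classifier]
        index = index or names
        columns[(method, "AUC")] = aucs
        columns[(method, "MCC")] = mccs
    table = pd.DataFrame(columns, index=index)
    table.loc["Average"] = table.mean(axis=0)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["method", "metric"])
    return table


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_experiment(
    datasets: list[AbundanceDataset],
    refs_config: RefsConfig | None = None,
    validation_runs: int = 10,
    seed: int = 0,
    match_mode: str = "forward",
    run_baselines: bool = True,
    random_runs: int = 10,
    n_folds: int = 10,
    discovery_override: int | None = None,
    allow_fewer: bool = False,
    manifest_extra: dict | None = None,
) -> ExperimentReport:
    """Execute the full methodology on already-loaded datasets."""
    refs_config = refs_config or RefsConfig(seed=seed)
    stage = "discovery selection"
    try:
        if discovery_override is None:
            disc_idx = select_discovery_dataset(datasets, allow_fewer=allow_fewer)
        else:
            disc_idx = discovery_override
            if len(datasets) < 3 and not allow_fewer:
                raise DatasetError("need >= 3 datasets (override with allow_fewer)")
        discovery = datasets[disc_idx]
        testing_sets = [d for i, d in enumerate(datasets) if i != disc_idx]
        logger.info("discovery dataset: %s", discovery.name)

        stage = "REFS feature selection"
        refs_result = refs_select(discovery, refs_config)
        logger.info(
            "REFS selected %d / %d features",
            refs_result.selected.size,
            discovery.n_features,
        )

        stage = "discovery validation"
        discovery_reports = {
            "refs": validate_features(
                discovery, refs_result.selected, n_runs=validation_runs,
                seed=seed, n_folds=n_folds,
            ),
            "all": validate_features(
                discovery, "all", n_runs=validation_runs, seed=seed, n_folds=n_folds
            ),
        }

        kbest_sig: FeatureSignature | None = None
        if run_baselines:
            stage = "K-Best baseline (discovery)"
            kbest_sig = kbest_select(discovery, refs_result.selected.size)
            discovery_reports["kbest"] = validate_features(
                discovery, kbest_sig, n_runs=validation_runs, seed=seed, n_folds=n_folds
            )

        testing_results: list[TestingComparison] = []
        for ds in testing_sets:
            stage = f"testing phase on {ds.name}"
            refs_match, refs_report = test_signature(
                refs_result.selected, ds, n_runs=validation_runs,
                seed=seed, mode=match_mode, n_folds=n_folds,
            )
            comp = TestingComparison(
                dataset_name=ds.name, refs_match=refs_match, refs_report=refs_report
            )
            if run_baselines and kbest_sig is not None:
                stage = f"K-Best testing on {ds.name}"
                comp.kbest_match, comp.kbest_report = test_signature(
                    kbest_sig, ds, n_runs=validation_runs,
                    seed=seed, mode=match_mode, n_folds=n_folds,
                )
                stage = f"random baseline on {ds.name}"
                comp.random_result = random_select(
                    ds, m=refs_match.matched_count, n_runs=random_runs,
                    seed=seed, n_folds=n_folds,
                )
            testing_results.append(comp)
    except Exception as exc:
        raise RuntimeError(f"experiment failed during stage: {stage}") from exc

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "refs_config": vars(refs_config),
        "validation_runs": validation_runs,
        "match_mode": match_mode,
        "n_folds": n_folds,
        "discovery": discovery.name,
        "datasets": [d.name for d in datasets],
        **(manifest_extra or {}),
    }
    return ExperimentReport(
        discovery_name=discovery.name,
        discovery_index=disc_idx,
        refs_result=refs_result,
        discovery_reports=discovery_reports,
        kbest_signature=kbest_sig,
        testing=testing_results,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# file-facing layer
# ---------------------------------------------------------------------------


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    refs_cfg = RefsConfig(**raw.pop("refs", {}))
    cfg = ExperimentConfig(refs=refs_cfg, **raw)
    cfg.validate()
    return cfg


def _report_to_frame(report: ValidationReport) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "classifier": [c.name for c in report.per_classifier],
            "AUC": [c.mean_auc for c in report.per_classifier],
            "AUC_std": [c.auc_std for c in report.per_classifier],
            "MCC": [c.mcc for c in report.per_classifier],
        }
    )
    frame.loc[len(frame)] = [
        "Average", report.average_auc, float("nan"), report.average_mcc
    ]
    return frame


def write_experiment_bundle(report: ExperimentReport, outdir: str | Path,
                            plots: bool = True) -> None:
    """Persist the full report bundle as TSV / FASTA / JSON (+ PNG plots)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    traj = pd.DataFrame(
        {
            "step": range(len(report.refs_result.trajectory)),
            "n_features": [s.n_features for s in report.refs_result.trajectory],
            "mean_accuracy": [s.mean_accuracy for s in report.refs_result.trajectory],
            "accuracy_std": [s.accuracy_std for s in report.refs_result.trajectory],
        }
    )
    traj.to_csv(outdir / "trajectory.tsv", sep="\t", index=False, float_format="%.6f")
    write_signature(report.refs_result.selected, outdir / "signature.fasta")
    pd.DataFrame(
        sorted(report.refs_result.run_agreement.items()),
        columns=["sequence", "run_agreement"],
    ).to_csv(outdir / "run_agreement.tsv", sep="\t", index=False, float_format="%.3f")

    for method, rep in report.discovery_reports.items():
        _report_to_frame(rep).to_csv(
            outdir / f"discovery_validation_{method}.tsv",
            sep="\t", index=False, float_format="%.6f",
        )
    disc_blocks: dict[str, ValidationReport | BaselineResult] = {
        f"REFS ({report.refs_result.selected.size} features)": report.discovery_reports["refs"],
        "all features": report.discovery_reports["all"],
    }
    if "kbest" in report.discovery_reports:
        disc_blocks[f"SelectKBest (k={report.refs_result.selected.size})"] = (
            report.discovery_reports["kbest"]
        )
    comparison_table(disc_blocks).to_csv(
        outdir / f"comparison_{report.discovery_name}.tsv", sep="\t", float_format="%.6f"
    )

    for comp in report.testing:
        tag = comp.dataset_name
        comp.refs_match.report_frame().to_csv(
            outdir / f"match_refs_{tag}.tsv", sep="\t", index=False
        )
        _report_to_frame(comp.refs_report).to_csv(
            outdir / f"testing_validation_refs_{tag}.tsv",
            sep="\t", index=False, float_format="%.6f",
        )
        blocks: dict[str, ValidationReport | BaselineResult] = {
            f"REFS ({comp.refs_match.matched_count} of "
            f"{comp.refs_match.signature.size} found)": comp.refs_report
        }
        if comp.kbest_report is not None and comp.kbest_match is not None:
            comp.kbest_match.report_frame().to_csv(
                outdir / f"match_kbest_{tag}.tsv", sep="\t", index=False
            )
            _report_to_frame(comp.kbest_report).to_csv(
                outdir / f"testing_validation_kbest_{tag}.tsv",
                sep="\t", index=False, float_format="%.6f",
            )
            blocks[
                f"SelectKBest ({comp.kbest_match.matched_count} of "
                f"{comp.kbest_match.signature.size} found)"
            ] = comp.kbest_report
        if comp.random_result is not None:
            blocks["random selection"] = comp.random_result
            per_run = pd.DataFrame(
                {
                    "run": range(len(comp.random_result.reports)),
                    "AUC": [r.average_auc for r in comp.random_result.reports],
                    "MCC": [r.average_mcc for r in comp.random_result.reports],
                }
            )
            per_run.to_csv(
                outdir / f"random_baseline_{tag}.tsv",
                sep="\t", index=False, float_format="%.6f",
            )
        comparison_table(blocks).to_csv(
            outdir / f"comparison_{tag}.tsv", sep="\t", float_format="%.6f"
        )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)

    if plots:
        from .plots import plot_mean_roc, plot_trajectory

        plot_trajectory(report.refs_result, outdir / "trajectory.png")
        plot_mean_roc(report.discovery_reports["refs"], outdir / "roc_discovery_refs.png")
        for comp in report.testing:
            plot_mean_roc(comp.refs_report, outdir / f"roc_refs_{comp.dataset_name}.png")


def run_experiment_from_config(config: ExperimentConfig) -> ExperimentReport:
    """Load datasets from the config's file triples and run the pipeline."""
    config.validate()
    datasets = [
        load_abundance_dataset(
            e["counts"], e["fasta"], e["labels"], name=e.get("name")
        )
        for e in config.datasets
    ]
    override = None
    if config.discovery_override is not None:
        names = [d.name for d in datasets]
        if config.discovery_override not in names:
            raise DatasetError(
                f"discovery_override {config.discovery_override!r} not among {names}"
            )
        override = names.index(config.discovery_override)
    report = run_experiment(
        datasets,
        refs_config=config.refs,
        validation_runs=config.validation_runs,
        seed=config.seed,
        match_mode=config.match_mode,
        run_baselines=config.run_baselines,
        random_runs=config.random_runs,
        n_folds=config.n_folds,
        discovery_override=override,
        allow_fewer=config.allow_fewer_datasets,
        manifest_extra={"config_hash": config.content_hash()},
    )
    write_experiment_bundle(report, config.output_dir)
    return report
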