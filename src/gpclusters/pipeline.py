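"""End-to-end orchestration: clean -> annotate -> measures -> cluster ->
validate -> describe, with seeded reproducibility and a manifest.

Configuration is one YAML file (see :class:`PipelineConfig.from_yaml`);
every stage writes its artefacts under ``out_dir`` and the manifest echoes
the config, seeds and row counts so a run is fully determined by it.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_counts, load_annotation_dictionary
from .describe import compare_groups, summarise_clusters
from .ensemble import BASE_METHODS, ConsensusClustering, ConsensusResult
from .ingest import (
    CleaningConfig,
    CleaningReport,
    filter_practices,
    load_standard_categories,
    read_appointments,
    read_registry,
)
from .measures import (
    MEASURE_COLUMNS,
    average_window,
    compute_measures_table,
    scale_matrix,
)
from .validate import StabilityReport, stability_report


class MissingArtifactError(RuntimeError):
    """An upstream artefact is absent; names the subcommand producing it."""

    def __init__(self, artefact: Path, producer: str):
        super().__init__(
            f"missing artefact {artefact}; run the `{producer}` subcommand first"
        )
        self.producer = producer


@dataclass
class PipelineConfig:
    """Paths, window, thresholds and ensemble protocol for one run."""

    appointments: dict[str, str]  # month -> csv path
    registry: str
    annotation_dictionary: str
    standard_categories: str
    out_dir: str
    holdout_appointments: dict[str, str] = field(default_factory=dict)
    window_months: list[str] | None = None
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    k: int = 2
    methods: tuple[str, ...] = BASE_METHODS
    reps_per_method: int = 100
    subsample_fraction: float = 0.8
    scaling: str = "per_dataset"  # or "reuse_training"
    include_home_visits: bool = True
    # Holdout validation default: assign holdout vectors to the trained
    # consensus centroids. Re-clustering the holdout month from scratch is
    # available (assign_only=False) but conflates cluster stability with
    # month-resolution artefacts: measures defined per month (the 0/1
    # triage flag) become binary on a single held-out month and can
    # dominate a fresh clustering.
    assign_only: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_months is None:
            self.window_months = sorted(self.appointments)
        overlap = set(self.window_months) & set(self.holdout_appointments)
        if overlap:
            raise ValueError(f"holdout month(s) {sorted(overlap)} inside the window")
        if self.scaling not in ("per_dataset", "reuse_training"):
            raise ValueError("scaling must be per_dataset|reuse_training")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cleaning = CleaningConfig(**raw.pop("cleaning", {}))
        ens = raw.pop("ensemble", {})
        raw.update(
            {
                k: ens[k]
                for k in ("k", "reps_per_method", "subsample_fraction", "methods")
                if k in ens
            }
        )
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        raw.update(overrides)
        return cls(cleaning=cleaning, **raw)

    def to_dict(self) -> dict:
        d = {
            "appointments": dict(self.appointments),
            "holdout_appointments": dict(self.holdout_appointments),
            "registry": self.registry,
            "annotation_dictionary": self.annotation_dictionary,
            "standard_categories": self.standard_categories,
            "out_dir": self.out_dir,
            "window_months": list(self.window_months),
            "cleaning": vars(self.cleaning),
            "k": self.k,
            "methods": list(self.methods),
            "reps_per_method": self.reps_per_method,
            "subsample_fraction": self.subsample_fraction,
            "scaling": self.scaling,
            "include_home_visits": self.include_home_visits,
            "assign_only": self.assign_only,
            "master_seed": self.master_seed,
        }
        return d


def _prepare(
    config: PipelineConfig,
    appointment_paths: dict[str, str],
    months: list[str],
):
    """Ingest, annotate and quality-filter one dataset (window or holdout)."""
    frames = [read_appointments(appointment_paths[m]) for m in sorted(months)]
    rows = pd.concat(frames, ignore_index=True)
    registry = read_registry(config.registry)
    dictionary = load_annotation_dictionary(config.annotation_dictionary)
    categories = load_standard_categories(config.standard_categories)
    annotated = annotate_counts(rows, dictionary)
    included, report = filter_practices(
        annotated, registry, months, config.cleaning, categories
    )
    return annotated, registry, included, report


def _measure(config: PipelineConfig, annotated, registry, included, months):
    kept = annotated[annotated["practice_id"].isin(included)]
    monthly = compute_measures_table(
        kept, registry, months, include_home_visits=config.include_home_visits
    )
    return average_window(monthly)


@dataclass
class PipelineResult:
    """All fitted objects and artefact paths from one run."""

    config: PipelineConfig
    cleaning_report: CleaningReport
    measures: pd.DataFrame
    consensus: ConsensusResult
    stability: StabilityReport | None
    holdout_cleaning_report: CleaningReport | None
    artefacts: dict[str, Path]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the whole pipeline and write every artefact.

    Identical config and seed give identical outputs. A stage failure
    leaves a ``FAILED`` marker naming the stage next to any partial
    outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, Path] = {}
    stage = "clean"
    try:
        annotated, registry, included, report = _prepare(
            config, config.appointments, config.window_months
        )
        report.to_frame().to_csv(out / "cleaning_report.csv", index=False)
        (out / "cleaning_log.txt").write_text(report.to_log() + "\n")
        artefacts["cleaning_report"] = out / "cleaning_report.csv"

        stage = "measures"
        vectors = _measure(config, annotated, registry, included, config.window_months)
        vectors.to_csv(out / "measures.csv", float_format="%.8g")
        scaled = scale_matrix(vectors)
        scaled.values.to_csv(out / "measures_scaled.csv", float_format="%.8g")
        (out / "measures_minmax.json").write_text(
            json.dumps(scaled.column_ranges, indent=1)
        )
        artefacts["measures"] = out / "measures.csv"
        artefacts["measures_scaled"] = out / "measures_scaled.csv"

        stage = "cluster"
        model = ConsensusClustering(
            scaled.values,
            k=config.k,
            methods=config.methods,
            reps_per_method=config.reps_per_method,
            subsample_fraction=config.subsample_fraction,
        )
        consensus = model.fit(master_seed=config.master_seed)
        consensus.to_frame().to_csv(
            out / "consensus.csv", index=False, float_format="%.8g"
        )
        (out / "consensus_diagnostics.json").write_text(
            json.dumps(consensus.diagnostics(), indent=1)
        )
        artefacts["consensus"] = out / "consensus.csv"

        stability = None
        holdout_report = None
        if config.holdout_appointments:
            stage = "validate"
            stability, holdout_report = _validate_holdout(
                config, consensus, scaled, out
            )
            artefacts["stability"] = out / "stability.json"

        stage = "describe"
        labels = pd.Series(
            consensus.labels, index=consensus.item_ids, name="cluster"
        )
        summary = summarise_clusters(registry, labels, vectors)
        summary.measure_stats.to_csv(out / "summary_measures.csv", float_format="%.6g")
        summary.workforce.to_csv(out / "summary_workforce.csv", float_format="%.6g")
        (out / "summary_report.md").write_text(summary.to_markdown() + "\n")
        artefacts["summary"] = out / "summary_report.md"
        in_vs_out = pd.Series(
            ["included" if p in included else "excluded"
             for p in registry["practice_id"]],
            index=registry["practice_id"],
        )
        if in_vs_out.nunique() > 1:
            excl = compare_groups(registry.set_index("practice_id", drop=False), in_vs_out)
            (out / "included_vs_excluded.md").write_text(excl.to_markdown() + "\n")

        stage = "manifest"
        manifest = {
            "gpclusters_version": __version__,
            "python": platform.python_version(),
            "config": config.to_dict(),
            "n_input_practices": report.n_input,
            "n_included": report.n_included,
            "n_rows": int(len(annotated)),
            "mean_pairwise_ari": consensus.mean_pairwise_ari,
            "cluster_sizes": consensus.cluster_sizes(),
            "stability_agreement": stability.agreement if stability else None,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        artefacts["manifest"] = out / "manifest.json"
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return PipelineResult(
        config=config,
        cleaning_report=report,
        measures=vectors,
        consensus=consensus,
        stability=stability,
        holdout_cleaning_report=holdout_report,
        artefacts=artefacts,
    )


def _validate_holdout(config, consensus, train_scaled, out: Path):
    """Prepare the holdout month identically and test cluster stability."""
    months = sorted(config.holdout_appointments)
    annotated, registry, included, report = _prepare(
        config, config.holdout_appointments, months
    )
    vectors = _measure(config, annotated, registry, included, months)
    # centroid assignment needs the holdout on the training scale
    reuse = config.assign_only or config.scaling == "reuse_training"
    ranges = train_scaled.column_ranges if reuse else None
    scaled = scale_matrix(vectors, column_ranges=ranges)
    train_labels = pd.Series(consensus.labels, index=consensus.item_ids)
    if config.assign_only:
        common = scaled.values.index.intersection(train_labels.index)
        new_labels = pd.Series(
            consensus.predict(scaled.values.loc[common].to_numpy()), index=common
        )
    else:
        model = ConsensusClustering(
            scaled.values,
            k=config.k,
            methods=config.methods,
            reps_per_method=config.reps_per_method,
            subsample_fraction=config.subsample_fraction,
        )
        holdout_consensus = model.fit(master_seed=config.master_seed)
        if len(set(holdout_consensus.labels)) < 2:
            raise ValueError("holdout clustering produced a single cluster")
        new_labels = pd.Series(
            holdout_consensus.labels, index=holdout_consensus.item_ids
        )
    if len(set(train_labels)) < 2:
        raise ValueError("training clustering produced a single cluster")
    stability = stability_report(train_labels, new_labels)
    (out / "stability.json").write_text(json.dumps(stability.to_dict(), indent=1))
    stability.crosstab.to_csv(out / "stability_crosstab.csv")
    return stability, report
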