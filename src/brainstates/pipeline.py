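"""End-to-end orchestration: manifest in, state-dynamics results out.

``run_pipeline`` chains standardize -> concatenate -> PCA -> VB-HMM fit
(or a K scan plus the occupancy-plateau selection) -> temporal statistics
-> covariate-adjusted group tests -> transition thresholding and
community detection -> ROI-space state maps, writing every artifact with
the config hash and seed so outputs are re-derivable from manifest +
config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as bio
from .communities import graph_edge_list, label_modules, newman_modularity, threshold_transitions
from .hmm import fit_hmm, scan_states, select_n_states, state_maps
from .preprocessing import concatenate, fit_pca, project, standardize
from .stats import DEFAULT_COVARIATE_SETS, run_group_analysis
from .temporal import cohort_metrics

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    manifest: str = "manifest.tsv"
    output_dir: str = "results"
    # preprocessing
    variance_target: float = 0.90
    n_components: int | None = None
    # hmm
    n_states: int | None = 5
    k_range: list[int] | None = None
    n_restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    selection_epsilon: float = 0.05
    # stats
    alpha: float = 0.05
    covariate_sets: list[list[str]] = field(
        default_factory=lambda: [list(c) for c in DEFAULT_COVARIATE_SETS]
    )
    case_label: str = "case"
    control_label: str = "control"
    # transitions
    kept_fraction: float = 0.25
    # units
    tr_seconds: float | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.n_states is None and not self.k_range:
            raise ValueError("either n_states or k_range must be set")
        if not (0.0 < self.kept_fraction <= 1.0):
            raise ValueError("kept_fraction must lie in (0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_restarts < 1 or self.max_iter < 1:
            raise ValueError("n_restarts and max_iter must be >= 1")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of artifacts."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("brainstates")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stamp = {"config_hash": config.hash(), "seed": config.seed}
    artifacts: dict[str, Path] = {"log": log_path}
    try:
        logger.info("pipeline start: %s", stamp)

        subjects, manifest = _stage("load")(bio.load_cohort)(config.manifest)
        logger.info("loaded %d subjects", len(subjects))

        @_stage("preprocess")
        def _preprocess():
            std = [standardize(s) for s in subjects]
            stacked, spans = concatenate(std)
            pca = fit_pca(stacked, n_components=config.n_components,
                          variance_target=config.variance_target)
            return project(stacked, pca), spans, pca

        projected, spans, pca = _preprocess()
        lengths = [b - a for a, b in spans]
        logger.info("PCA retained P=%d components (%.4f variance)",
                    pca.n_components_, float(pca.explained_variance_ratio_.sum()))
        bio.save_pca(pca, outdir / "pca.json")
        artifacts["pca"] = outdir / "pca.json"

        @_stage("fit")
        def _fit():
            k = config.n_states
            scan_df = None
            if config.k_range:
                scan_df = scan_states(projected, lengths, config.k_range,
                                      n_restarts=config.n_restarts,
                                      max_iter=config.max_iter, tol=config.tol,
                                      random_state=config.seed)
                sel = select_n_states(scan_df, epsilon=config.selection_epsilon)
                k = sel.n_states
                logger.info("scan selected K*=%d (plateau=%s, free energy monotone=%s)",
                            k, sel.plateau_found, sel.free_energy_monotone)
            model, post = fit_hmm(projected, lengths, n_states=k,
                                  n_restarts=config.n_restarts,
                                  max_iter=config.max_iter, tol=config.tol,
                                  random_state=config.seed)
            return model, post, scan_df

        model, post, scan_df = _fit()
        if scan_df is not None:
            scan_df.to_csv(outdir / "scan.tsv", sep="\t", index=False,
                           float_format="%.10g")
            artifacts["scan"] = outdir / "scan.tsv"
        bio.save_model(model, outdir / "model.json")
        artifacts["model"] = outdir / "model.json"

        @_stage("metrics")
        def _metrics():
            paths = {s.subject_id: p for s, p in zip(subjects, post.paths)}
            return cohort_metrics(paths, model.n_states, manifest=manifest,
                                  tr_seconds=config.tr_seconds)

        metrics = _metrics()
        mpath = outdir / "metrics.tsv"
        metrics.to_csv(mpath, sep="\t", index=False, float_format="%.10g")
        artifacts["metrics"] = mpath

        @_stage("stats")
        def _stats():
            return run_group_analysis(
                metrics, manifest, covariate_sets=config.covariate_sets,
                alpha=config.alpha, case_label=config.case_label,
                control_label=config.control_label,
            )

        results = _stats()
        spath = outdir / "stats.tsv"
        results.to_csv(spath, sep="\t", index=False, float_format="%.10g")
        artifacts["stats"] = spath

        @_stage("modules")
        def _modules():
            graph = threshold_transitions(model.transmat_, config.kept_fraction)
            logger.info("threshold kept %d edges (%d tie(s) at the cut)",
                        graph.n_kept, graph.n_ties_at_cut)
            part = newman_modularity(graph)
            part = label_modules(part, results)
            return graph, part

        graph, partition = _modules()
        graph_edge_list(graph).to_csv(outdir / "transition_edges.tsv", sep="\t",
                                      index=False, float_format="%.10g")
        bio.save_partition(partition, outdir / "partition.json")
        artifacts["edges"] = outdir / "transition_edges.tsv"
        artifacts["partition"] = outdir / "partition.json"

        @_stage("maps")
        def _maps():
            import pandas as pd

            maps = state_maps(model, pca)
            return pd.DataFrame(maps, columns=subjects[0].roi_labels)

        maps_df = _maps()
        maps_df.to_csv(outdir / "state_maps.tsv", sep="\t", index=False,
                       float_format="%.10g")
        artifacts["maps"] = outdir / "state_maps.tsv"

        echo = {**stamp, "config": dataclasses.asdict(config)}
        (outdir / "config_echo.json").write_text(json.dumps(echo, default=str))
        artifacts["config"] = outdir / "config_echo.json"
        logger.info("pipeline done")
        return artifacts
    finally:
        root.removeHandler(handler)
        handler.close()
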