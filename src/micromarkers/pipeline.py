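"""End-to-end pipeline: markers -> classification -> network -> regression
-> stratification, with a reproducibility manifest.

Every stochastic stage derives its seed from the single run seed via
fixed documented offsets (see STAGE_OFFSETS), so a run is reproducible
as a whole while stages stay independently re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classifiers import NNSpec, crossval_evaluate
from .marker_selection import SPECIES_K_GRID, rank_features, topk_sweep
from .network import export_graph, hub_report, infer_adjacency, \
    refine_adjacency, top_edges
from .profiles_io import (PairedDataset, align, read_abundance_table,
                          read_metadata_table, write_abundance_table,
                          write_metadata_table)
from .regression import rank_covariates, regress_covariates
from .stratification import stratify
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

#: per-stage additive seed offsets (mod 2**31) from the run seed
STAGE_OFFSETS = {
    "simulate": 0,
    "classify": 1,
    "rank": 2,
    "sweep": 3,
    "network": 4,
    "regress": 5,
}


def stage_seed(seed: int, stage: str) -> int:
    return (int(seed) + STAGE_OFFSETS[stage]) % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (mirrors the YAML layout)."""

    seed: int
    out_dir: str
    profile_path: str | None = None
    metadata_path: str | None = None
    profile_orientation: str = "samples_as_rows"
    simulate: dict = field(default_factory=dict)
    k_grid: tuple = SPECIES_K_GRID
    nn: dict = field(default_factory=dict)
    rank: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    covariates: tuple = ("fbg", "bmi", "age", "weight")
    stratify_covariate: str = "fbg"
    stratify_probs: tuple = (0.25, 0.5, 0.75)

    def validate(self) -> None:
        if (self.profile_path is None) != (self.metadata_path is None):
            raise ValueError("profile_path and metadata_path must be given "
                             "together")
        for path in (self.profile_path, self.metadata_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default,
                               allow_nan=True) + "\n")


def load_inputs(config: RunConfig):
    """Load the profile/metadata pair from disk, or simulate one."""
    if config.profile_path is not None:
        profile = read_abundance_table(config.profile_path,
                                       orientation=config.profile_orientation)
        metadata = read_metadata_table(config.metadata_path)
        return align(profile, metadata), None
    sim = dict(config.simulate)
    sim.setdefault("seed", stage_seed(config.seed, "simulate"))
    cohort = CohortConfig(**sim)
    profile, metadata, truth = generate_cohort(cohort)
    return PairedDataset(profile, metadata), truth


def full_run(config: RunConfig) -> dict:
    """Execute every stage in order and write all outputs + a manifest.

    Stages: marker selection (RF ranking + top-k sweep) -> marker-set
    cross-validation -> interaction network (infer, refine, top-100,
    hubs, export) -> covariate regression -> covariate stratification.
    Any stage error aborts with the stage name; outputs of completed
    stages are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "load"
    try:
        paired, truth = load_inputs(config)
        X, y = paired.profile.values, paired.labels
        feature_ids = paired.profile.feature_ids
        if truth is not None:
            write_abundance_table(paired.profile, out / "profile.tsv")
            write_metadata_table(paired.metadata, out / "metadata.tsv")
            _write_json(asdict(truth), out / "truth.json")
            outputs["profile"] = out / "profile.tsv"
            outputs["metadata"] = out / "metadata.tsv"
            outputs["truth"] = out / "truth.json"

        stage = "select-markers"
        ranking = rank_features(X, y, feature_ids=feature_ids,
                                seed=stage_seed(config.seed, "rank"),
                                **config.rank)
        nn_spec = NNSpec(seed=stage_seed(config.seed, "sweep"),
                         **config.nn)
        sweep = topk_sweep(ranking, X, y, feature_ids=feature_ids,
                           k_grid=config.k_grid, nn_spec=nn_spec,
                           seed=stage_seed(config.seed, "sweep"))
        _write_json({
            "ranking": {"feature_ids": ranking.feature_ids,
                        "scores": ranking.scores},
            "curve": sweep.curve(),
            "selected_k": sweep.selected_k,
            "markers": sweep.markers,
        }, out / "markers.json")
        outputs["markers"] = out / "markers.json"

        stage = "classify"
        marker_profile = paired.profile.subset_features(sweep.markers)
        cv = crossval_evaluate(
            NNSpec(seed=stage_seed(config.seed, "classify"), **config.nn),
            marker_profile.values, y,
            seed=stage_seed(config.seed, "classify"))
        _write_json({
            "per_fold": [m.as_dict() for m in cv.per_fold],
            "aggregated": cv.aggregated,
            "oof_scores": cv.oof_scores,
            "roc_points": [m.roc_points for m in cv.per_fold],
        }, out / "classify.json")
        outputs["classify"] = out / "classify.json"

        stage = "network"
        net_kwargs = dict(config.network)
        top_n = net_kwargs.pop("top_n", 100)
        adj = infer_adjacency(marker_profile.values,
                              feature_ids=sweep.markers,
                              seed=stage_seed(config.seed, "network"),
                              **net_kwargs)
        refined = refine_adjacency(adj)
        edges = top_edges(refined, n=top_n)
        export_graph(edges, out / "network_edges.tsv", format="tsv")
        export_graph(edges, out / "network.graphml", format="graphml")
        _write_json({str(t): nodes for t, nodes in hub_report(edges).items()},
                    out / "network_hubs.json")
        outputs["network_edges"] = out / "network_edges.tsv"
        outputs["network_graphml"] = out / "network.graphml"
        outputs["network_hubs"] = out / "network_hubs.json"

        stage = "regress"
        cov = {name: paired.covariate(name) for name in config.covariates}
        cov = {k: v for k, v in cov.items() if np.isfinite(v).any()}
        reg = regress_covariates(marker_profile.values, cov,
                                 seed=stage_seed(config.seed, "regress"))
        ranked = rank_covariates(reg)
        _write_json({
            "results": [{"covariate": r.covariate, "r": r.r, "p": r.p,
                         "n": r.n_used} for r in ranked],
            "leading_factor": ranked[0].covariate,
        }, out / "regress.json")
        outputs["regress"] = out / "regress.json"

        stage = "stratify"
        strat = stratify(marker_profile,
                         paired.covariate(config.stratify_covariate), y,
                         probs=config.stratify_probs)
        table = strat.matrix.copy()
        table["significance"] = strat.significance["significance"]
        header = "# boundaries: " + ", ".join(
            f"{b:.6g}" for b in strat.boundaries) + "\n"
        strat_path = out / "stratification.tsv"
        strat_path.write_text(header + table.to_csv(sep="\t",
                                                    float_format="%.12g",
                                                    index_label="feature_id"))
        outputs["stratification"] = strat_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "micromarkers",
        "version": __version__,
        "seed": config.seed,
        "stage_seed_offsets": STAGE_OFFSETS,
        "config": {k: v for k, v in asdict(config).items()},
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)}
                    for k, v in outputs.items()},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
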