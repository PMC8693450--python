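"""Config-driven orchestration of the full analysis.

A run either loads a feature table / metadata / tree from disk or simulates
a cohort, then executes: prevalence filter -> differential screen -> index
fit -> per-sample scoring -> group comparisons -> UniFrac distances, PCoA,
distance-to-controls, PERMANOVA -> clinical-score correlations (and the
taxon-outcome screen when outcomes are present).  Every intermediate is
written as TSV/JSON and a manifest records the config hash, seed, package
version, and a checksum for each output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import score_correlations, taxa_outcome_screen
from .beta_diversity import distance_matrix, distances_to_group, pcoa, permanova
from .differential import differential_genera, fit_index_model
from .dysbiosis_index import compare_index_groups, compute_index_table
from .io_formats import (
    CohortMetadata,
    FeatureTable,
    read_feature_table,
    read_metadata,
    read_tree,
    to_relative_abundance,
    write_metadata,
    write_records,
    write_table,
    write_tree,
)
from .differential import prevalence_filter
from .synthetic_data import (
    default_config,
    generate_cohort,
    generate_scores,
    generate_tree,
    substream,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "StageError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration; carries the full list of problems."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    seed: int
    case: str = "T2D"
    control: str = "control"
    alpha: float = 0.05
    adjustment: str = "none"
    metric: str = "unweighted_unifrac"
    permutations: int = 999
    min_prevalence: float = 0.10
    # exactly one of the two input modes
    table_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    simulate: Mapping[str, Any] | None = None

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v if not isinstance(v, Mapping) else dict(v)
             for k, v in self.__dict__.items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_KNOWN_KEYS = {
    "out_dir", "seed", "case", "control", "alpha", "adjustment", "metric",
    "permutations", "min_prevalence", "inputs", "simulate",
}


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, reporting all errors at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])
    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown key {key!r}")
    inputs = raw.get("inputs")
    simulate = raw.get("simulate")
    if (inputs is None) == (simulate is None):
        errors.append("exactly one of 'inputs' and 'simulate' must be present")
    table_path = metadata_path = tree_path = None
    if inputs is not None:
        if not isinstance(inputs, dict):
            errors.append("'inputs' must be a mapping with table/metadata/tree")
        else:
            for k in ("table", "metadata", "tree"):
                if k not in inputs:
                    errors.append(f"inputs missing {k!r}")
            table_path = inputs.get("table")
            metadata_path = inputs.get("metadata")
            tree_path = inputs.get("tree")
    if simulate is not None and not isinstance(simulate, dict):
        errors.append("'simulate' must be a mapping (may be empty)")
        simulate = None
    alpha = raw.get("alpha", 0.05)
    if not isinstance(alpha, (int, float)) or not 0.0 < alpha < 1.0:
        errors.append("alpha must be in (0,1)")
    adjustment = raw.get("adjustment", "none")
    if adjustment not in ("none", "bonferroni"):
        errors.append("adjustment must be 'none' or 'bonferroni'")
    metric = raw.get("metric", "unweighted_unifrac")
    if metric not in ("unweighted_unifrac", "weighted_unifrac"):
        errors.append("metric must be unweighted_unifrac or weighted_unifrac")
    permutations = raw.get("permutations", 999)
    if not isinstance(permutations, int) or permutations < 1:
        errors.append("permutations must be a positive integer")
    min_prev = raw.get("min_prevalence", 0.10)
    if not isinstance(min_prev, (int, float)) or not 0.0 <= min_prev <= 1.0:
        errors.append("min_prevalence must be in [0,1]")
    if "out_dir" not in raw:
        errors.append("out_dir is required")
    seed = raw.get("seed")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        log.info("no seed given; drew and recorded seed=%d", seed)
    elif not isinstance(seed, int):
        errors.append("seed must be an integer")
        seed = 0
    if errors:
        raise ConfigError(errors)
    return RunConfig(
        out_dir=str(raw["out_dir"]),
        seed=seed,
        case=str(raw.get("case", "T2D")),
        control=str(raw.get("control", "control")),
        alpha=float(alpha),
        adjustment=adjustment,
        metric=metric,
        permutations=permutations,
        min_prevalence=float(min_prev),
        table_path=table_path,
        metadata_path=metadata_path,
        tree_path=tree_path,
        simulate=simulate,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None:
                    raise StageError(name, exc) from exc
                log.info("stage %s: done in %.2fs", name, timings[name])

        return _Ctx()

    truth = None
    with _stage("load"):
        if config.simulate is not None:
            sim = dict(config.simulate)
            n_per_group = sim.get("n_per_group")
            effect_scale = float(sim.get("effect_scale", 1.0))
            syn = default_config(
                seed=config.seed, n_per_group=n_per_group, effect_scale=effect_scale
            )
            table, meta, truth = generate_cohort(syn)
            meta = generate_scores(meta, truth.latent, syn.score_links, seed=config.seed)
            tree = generate_tree(table.taxon_ids, seed=config.seed)
            write_table(table, out / "feature_table.tsv")
            write_metadata(meta, out / "metadata.tsv")
            write_tree(tree, out / "tree.nwk")
            (out / "truth.json").write_text(
                json.dumps(truth.to_json_dict(), indent=2, sort_keys=True)
            )
            outputs["truth.json"] = ""
        else:
            table = read_feature_table(config.table_path)
            meta = read_metadata(config.metadata_path)
            tree = read_tree(config.tree_path)
        if table.unit == "counts":
            rel = to_relative_abundance(table)
        else:
            rel = table
        outputs["feature_table.tsv"] = ""

    with _stage("differential"):
        filtered = prevalence_filter(rel, config.min_prevalence)
        results = differential_genera(
            filtered, meta, config.case, config.control,
            alpha=config.alpha, adjustment=config.adjustment,
        )
        pd.DataFrame([r.__dict__ for r in results]).to_csv(
            out / "differential.tsv", sep="\t", index=False, float_format="%.12g"
        )
        model = fit_index_model(
            results, config.case, config.control,
            alpha=config.alpha, adjustment=config.adjustment,
        )
        (out / "index_model.json").write_text(model.to_json())

    with _stage("scoring"):
        scores = compute_index_table(rel, model)
        scores.write(out / "index_scores.tsv")
        comparisons = []
        present = set(meta.groups.unique())
        for a, b in (("T2D", "control"), ("AIS_T2D", "AIS")):
            if a in present and b in present:
                med_a, med_b, p = compare_index_groups(scores, meta, a, b)
                comparisons.append(
                    {"group_a": a, "group_b": b, "median_a": med_a,
                     "median_b": med_b, "p_value": p}
                )
        pd.DataFrame(comparisons).to_csv(
            out / "index_comparisons.tsv", sep="\t", index=False, float_format="%.12g"
        )

    with _stage("beta_diversity"):
        dm = distance_matrix(rel, tree, metric=config.metric)
        pd.DataFrame(np.asarray(dm.data), index=list(dm.ids), columns=list(dm.ids)).to_csv(
            out / "distance_matrix.tsv", sep="\t", float_format="%.12g"
        )
        ordination = pcoa(dm, k=3)
        ordination.write(out / "pcoa.tsv")
        if config.control in present:
            d2c = distances_to_group(dm, meta, config.control)
            d2c.to_frame().to_csv(out / "distance_to_controls.tsv", sep="\t",
                                  float_format="%.12g")
        f_stat, p_perm = permanova(
            dm, meta, "group", n_permutations=config.permutations,
            seed=int(substream(config.seed, "permanova").integers(2**31)),
        )
        (out / "permanova.json").write_text(
            json.dumps({"pseudo_F": f_stat, "p_value": p_perm,
                        "permutations": config.permutations}, indent=2)
        )

    with _stage("associations"):
        score_cols = [c for c in ("NIHSS", "mRS", "Essen") if c in meta.frame.columns]
        if score_cols:
            records = score_correlations(scores, meta, targets=score_cols,
                                         alpha=config.alpha)
            write_records(records, out / "score_correlations.tsv")
        outcome_cols = [
            c for c in meta.numeric_columns() if c not in ("NIHSS", "mRS", "Essen")
        ]
        if outcome_cols:
            screen = taxa_outcome_screen(rel, meta, alpha=config.alpha)
            write_records(screen, out / "outcome_screen.tsv")

    with _stage("manifest"):
        for name in ("feature_table.tsv", "metadata.tsv", "tree.nwk", "truth.json",
                     "differential.tsv", "index_model.json", "index_scores.tsv",
                     "index_comparisons.tsv", "distance_matrix.tsv", "pcoa.tsv",
                     "distance_to_controls.tsv", "permanova.json",
                     "score_correlations.tsv", "outcome_screen.tsv"):
            p = out / name
            if p.exists():
                outputs[name] = _sha256(p)
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "outputs": outputs,
            "timings_s": timings,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
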