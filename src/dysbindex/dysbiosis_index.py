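"""Apply a fitted index model to samples and compare scores between groups.

The per-sample score is the weighted enriched-minus-depleted sum

    score = sum_{g case-enriched} w_g * a_g  -  sum_{g control-enriched} w_g * a_g

over the model's taxa, with ``a_g`` the sample's relative abundance of
taxon ``g`` and ``w_g = -log10(p_g)`` from the fitting comparison.  The
model is typically fitted on one contrast (T2D vs control) and then applied
to every sample, including groups that played no part in the fit.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .differential import IndexModel, wilcoxon_rank_sum
from .io_formats import CohortMetadata, FeatureTable, FeatureTableError

log = logging.getLogger(__name__)

__all__ = [
    "IndexScoreTable",
    "compute_index",
    "compute_index_table",
    "compare_index_groups",
]


@dataclass(frozen=True)
class IndexScoreTable:
    """One finite score per sample plus a hash of the model that produced it."""

    scores: pd.Series  # index: sample_id, values: float
    model_hash: str

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate sample ids in score table")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("non-finite index score")

    def write(self, path) -> None:
        out = self.scores.rename("dysbiosis_index").to_frame()
        out.index.name = "sample_id"
        out.insert(0, "model_hash", self.model_hash)
        out.to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def read(cls, path) -> "IndexScoreTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        hashes = set(df["model_hash"])
        if len(hashes) != 1:
            raise ValueError("score table mixes models")
        return cls(df["dysbiosis_index"].astype(float), hashes.pop())


def model_hash(model: IndexModel) -> str:
    return hashlib.sha256(model.to_json().encode()).hexdigest()[:16]


def compute_index(abundances: Mapping[str, float], model: IndexModel) -> float:
    """Score one sample; model taxa absent from the mapping contribute 0."""
    if not model.entries:
        raise ValueError("empty index model")
    score = 0.0
    for entry in model.entries:
        a = float(abundances.get(entry.taxon_id, 0.0))
        if entry.direction == "case_enriched":
            score += entry.weight * a
        else:
            score -= entry.weight * a
    return score


def compute_index_table(table: FeatureTable, model: IndexModel) -> IndexScoreTable:
    """Vectorised :func:`compute_index` over every sample of a table."""
    if table.unit != "proportions":
        raise FeatureTableError("index scoring expects relative abundances; normalise first")
    signs = {
        e.taxon_id: (e.weight if e.direction == "case_enriched" else -e.weight)
        for e in model.entries
    }
    absent = [t for t in signs if t not in table.data.columns]
    if absent:
        log.info("model taxa absent from table treated as zero: %s", absent)
    weights = np.array([signs.get(t, 0.0) for t in table.taxon_ids])
    scores = pd.Series(
        table.data.to_numpy(dtype=float) @ weights, index=table.data.index, dtype=float
    )
    return IndexScoreTable(scores=scores, model_hash=model_hash(model))


def compare_index_groups(
    scores: IndexScoreTable,
    meta: CohortMetadata,
    group_a: str,
    group_b: str,
) -> tuple[float, float, float]:
    """Medians of the two groups' scores and the two-sided rank-sum p."""
    ids_a = [s for s in meta.samples_in_group(group_a) if s in scores.scores.index]
    ids_b = [s for s in meta.samples_in_group(group_b) if s in scores.scores.index]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("both groups need >= 2 scored samples")
    a = scores.scores.loc[ids_a].to_numpy(dtype=float)
    b = scores.scores.loc[ids_b].to_numpy(dtype=float)
    _, p = wilcoxon_rank_sum(a, b, mode="auto")
    return float(np.median(a)), float(np.median(b)), p
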