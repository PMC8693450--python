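"""Phylogenetic beta-diversity: UniFrac kernels, PCoA, and PERMANOVA.

Both UniFrac kernels work from a branch decomposition of a rooted tree:
every edge (root edge excluded) is represented by its length and the set of
leaves below it.  Unweighted UniFrac is the fraction of branch length
leading only to leaves present in exactly one of the two samples; weighted
UniFrac moves abundance mass along branches and sums length-weighted
differences.  The pairwise driver is vectorised so full cohort matrices
are cheap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .io_formats import CohortMetadata, FeatureTable

log = logging.getLogger(__name__)

__all__ = [
    "Ordination",
    "tree_branches",
    "unweighted_unifrac",
    "weighted_unifrac",
    "distance_matrix",
    "pcoa",
    "distances_to_group",
    "permanova",
]


def tree_branches(tree: TreeNode) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Decompose a rooted tree into (lengths, leaf-incidence, leaf names).

    Returns branch lengths (one per non-root edge), a boolean matrix
    ``incidence[edge, leaf]`` marking the leaves below each edge, and the
    ordered leaf names.  The root edge is excluded: length shared by every
    community carries no contrast.
    """
    leaves = [t.name for t in tree.tips()]
    leaf_pos = {name: i for i, name in enumerate(leaves)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for node in tree.postorder(include_self=False):
        row = np.zeros(len(leaves), dtype=bool)
        if node.is_tip():
            row[leaf_pos[node.name]] = True
        else:
            for child in node.children:
                row |= child._db_row  # set in this same postorder pass
        node._db_row = row
        lengths.append(float(node.length or 0.0))
        rows.append(row)
    for node in tree.postorder(include_self=False):
        del node._db_row
    return np.array(lengths), np.array(rows), leaves


def _sample_vector(
    abundances: Mapping[str, float] | pd.Series, leaves: Sequence[str]
) -> np.ndarray:
    if isinstance(abundances, pd.Series):
        abundances = abundances.to_dict()
    vec = np.zeros(len(leaves))
    pos = {name: i for i, name in enumerate(leaves)}
    for taxon, value in abundances.items():
        if value == 0:
            continue
        if taxon not in pos:
            raise ValueError(f"taxon {taxon!r} with nonzero abundance missing from tree")
        vec[pos[taxon]] = float(value)
    return vec


def unweighted_unifrac(
    a: Mapping[str, float] | pd.Series,
    b: Mapping[str, float] | pd.Series,
    tree: TreeNode,
) -> float:
    """Presence/absence UniFrac distance in [0, 1].

    Presence is strictly positive abundance.  Distance is the branch length
    unique to one sample divided by the branch length covered by either.
    """
    lengths, incidence, leaves = tree_branches(tree)
    va = _sample_vector(a, leaves) > 0
    vb = _sample_vector(b, leaves) > 0
    if not va.any() or not vb.any():
        raise ValueError("UniFrac undefined for an empty sample")
    in_a = incidence @ va > 0
    in_b = incidence @ vb > 0
    union = float(lengths[in_a | in_b].sum())
    unique = float(lengths[in_a ^ in_b].sum())
    if union == 0:
        return 0.0
    return unique / union


def weighted_unifrac(
    a: Mapping[str, float] | pd.Series,
    b: Mapping[str, float] | pd.Series,
    tree: TreeNode,
    normalized: bool = True,
) -> float:
    """Abundance-weighted UniFrac.

    Sums ``length * |A_e - B_e|`` over branches, where ``A_e`` is the
    fraction of sample A's mass below edge ``e``.  The normalised form
    divides by ``sum(length * (A_e + B_e))`` so the result lies in [0, 1].
    """
    lengths, incidence, leaves = tree_branches(tree)
    va = _sample_vector(a, leaves)
    vb = _sample_vector(b, leaves)
    if va.sum() == 0 or vb.sum() == 0:
        raise ValueError("UniFrac undefined for an empty sample")
    va = va / va.sum()
    vb = vb / vb.sum()
    mass_a = incidence @ va
    mass_b = incidence @ vb
    raw = float((lengths * np.abs(mass_a - mass_b)).sum())
    if not normalized:
        return raw
    denom = float((lengths * (mass_a + mass_b)).sum())
    if denom == 0:
        return 0.0
    return raw / denom


def distance_matrix(
    table: FeatureTable, tree: TreeNode, metric: str = "unweighted_unifrac"
) -> DistanceMatrix:
    """All-pairs UniFrac distances, vectorised over the branch decomposition."""
    lengths, incidence, leaves = tree_branches(tree)
    pos = {name: i for i, name in enumerate(leaves)}
    missing = [t for t in table.taxon_ids if t not in pos]
    if missing:
        nonzero = table.data[missing].to_numpy().sum()
        if nonzero > 0:
            raise ValueError(f"taxa with nonzero abundance missing from tree: {missing[:5]}")
    values = np.zeros((table.n_samples, len(leaves)))
    for j, taxon in enumerate(table.taxon_ids):
        if taxon in pos:
            values[:, pos[taxon]] = table.data.iloc[:, j].to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).any():
        raise ValueError("UniFrac undefined for an empty sample")

    if metric == "unweighted_unifrac":
        present = (values > 0) @ incidence.T > 0  # samples x branches
        x = present.astype(float)
        per_sample = x @ lengths
        cross = (x * lengths) @ x.T
        union = per_sample[:, None] + per_sample[None, :] - cross
        unique = union - cross
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(union > 0, unique / np.maximum(union, 1e-300), 0.0)
    elif metric == "weighted_unifrac":
        props = values / values.sum(axis=1, keepdims=True)
        mass = props @ incidence.T  # samples x branches
        weighted = mass * lengths
        depth = weighted.sum(axis=1)
        n = table.n_samples
        d = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(weighted[i][None, :] - weighted)
            raw = diff.sum(axis=1)
            denom = depth[i] + depth
            with np.errstate(invalid="ignore", divide="ignore"):
                d[i] = np.where(denom > 0, raw / np.maximum(denom, 1e-300), 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# ordination


@dataclass(frozen=True)
class Ordination:
    """PCoA embedding: coordinates, eigenvalues (descending), and the share
    of positive-eigenvalue variance each axis explains."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def write(self, path) -> None:
        out = self.coordinates.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.12g")


def pcoa(dm: DistanceMatrix, k: int | None = None) -> Ordination:
    """Classical principal-coordinates analysis.

    Gower double-centering of ``-D^2/2`` followed by a symmetric
    eigendecomposition; coordinates are eigenvectors scaled by ``sqrt(λ)``
    for positive eigenvalues.  Negative eigenvalues (non-Euclidean input)
    are reported as-is and their axes zeroed — no Lingoes/Cailliez
    correction is applied.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    a = -0.5 * d**2
    row_mean = a.mean(axis=1, keepdims=True)
    col_mean = a.mean(axis=0, keepdims=True)
    b = a - row_mean - col_mean + a.mean()
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    scale = np.sqrt(np.clip(eigval, 0.0, None))
    coords = eigvec * scale[None, :]
    pos_sum = eigval[eigval > 0].sum()
    prop = np.where(eigval > 0, eigval / pos_sum if pos_sum > 0 else 0.0, 0.0)
    if k is not None:
        coords = coords[:, :k]
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return Ordination(coordinates=frame, eigenvalues=eigval, proportion_explained=prop)


# ---------------------------------------------------------------------------
# group summaries and testing


def distances_to_group(
    dm: DistanceMatrix, meta: CohortMetadata, reference: str
) -> pd.Series:
    """Mean distance of every sample to the reference group.

    Non-reference samples average over all reference samples; reference
    samples average over the *other* reference samples (so a reference
    group of one cannot yield within-reference values).
    """
    ids = list(dm.ids)
    ref = [s for s in meta.samples_in_group(reference) if s in ids]
    if not ref:
        raise ValueError(f"reference group {reference!r} has no samples in the matrix")
    d = pd.DataFrame(np.asarray(dm.data), index=ids, columns=ids)
    out = {}
    for s in ids:
        others = [r for r in ref if r != s]
        if not others:
            raise ValueError(
                "within-reference distance undefined for a reference group of 1"
            )
        out[s] = float(d.loc[s, others].mean())
    return pd.Series(out, name=f"mean_distance_to_{reference}")


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    k = len(groups)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):
        # perfectly clustered groups give ss_within == 0 and an infinite F
        return float(np.divide(ss_between / (k - 1), ss_within / (n - k)))


def permanova(
    dm: DistanceMatrix,
    meta: CohortMetadata,
    grouping: str = "group",
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """PERMANOVA (Adonis) pseudo-F test of group separation.

    ``n_permutations`` may be ``"exact"`` to enumerate every distinct label
    ordering (small cohorts only); otherwise the p-value uses the standard
    +1 convention ``(count{F_perm >= F_obs} + 1) / (B + 1)`` with random
    label permutations drawn from ``seed``.
    """
    ids = list(dm.ids)
    labels = meta.frame.loc[ids, grouping].to_numpy()
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if (counts < 2).any():
        raise ValueError("PERMANOVA group with fewer than 2 samples")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, labels)
    eps = 1e-12
    if n_permutations == "exact":
        perms = set(itertools.permutations(labels))
        count = sum(_pseudo_f(d2, np.array(p)) >= f_obs - eps for p in perms)
        return f_obs, count / len(perms)
    rng = np.random.default_rng(seed)
    count = 0
    work = labels.copy()
    for _ in range(int(n_permutations)):
        rng.shuffle(work)
        if _pseudo_f(d2, work) >= f_obs - eps:
            count += 1
    return f_obs, (count + 1) / (int(n_permutations) + 1)
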