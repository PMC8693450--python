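"""Readers, writers, and core containers for feature tables, metadata, and trees.

All on-disk formats are plain text: tab-delimited tables (samples as rows,
first column ``sample_id``) and single-tree Newick files.  The in-memory
containers are thin wrappers over :class:`pandas.DataFrame` /
:class:`skbio.TreeNode` that enforce the invariants every downstream stage
relies on (non-negative abundances, unique ids, proportion rows summing
to one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

log = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "CohortMetadata",
    "FeatureTableError",
    "MetadataError",
    "TreeError",
    "read_feature_table",
    "write_table",
    "to_relative_abundance",
    "collapse_taxonomy",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "write_records",
    "read_records",
    "RANKS",
]

#: Greengenes-style rank order; lineage strings are ';'-delimited with
#: single-letter prefixes, e.g. ``k__Bacteria;p__Firmicutes;...;g__Blautia``.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_RANK_PREFIX = dict(zip(RANKS, ("k", "p", "c", "o", "f", "g")))

HUMAN_GROUPS = ("control", "T2D", "AIS", "AIS_T2D")
MOUSE_GROUPS = ("control_FMT", "T2D_FMT")
KNOWN_GROUPS = HUMAN_GROUPS + MOUSE_GROUPS

#: Clinical/behavioural score ranges enforced on metadata.
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "NIHSS": (0, 42),
    "mRS": (0, 6),
    "Essen": (0, 9),
    "mNSS": (0, 14),
    "infarct_ratio": (0.0, 1.0),
}


class FeatureTableError(ValueError):
    pass


class MetadataError(ValueError):
    pass


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample ids on the index and taxon ids on the columns.
    unit:
        ``"counts"`` (non-negative, typically integral) or ``"proportions"``
        (every row sums to 1 within 1e-9).
    taxonomy:
        Optional map taxon_id -> rank-delimited lineage string.
    """

    data: pd.DataFrame
    unit: str
    taxonomy: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "proportions"):
            raise FeatureTableError(f"unknown unit {self.unit!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise FeatureTableError("feature table contains NaN")
        if (values < 0).any():
            raise FeatureTableError("negative abundance")
        if self.data.index.has_duplicates:
            raise FeatureTableError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise FeatureTableError("duplicate taxon ids")
        if self.unit == "proportions":
            # taxon-filtered tables are deliberately NOT renormalised, so a
            # row may sum to less than 1; all-zero rows stay forbidden.
            sums = values.sum(axis=1)
            if (sums <= 0).any() or (sums > 1.0 + 1e-9).any():
                raise FeatureTableError(
                    "proportion rows must sum to at most 1 and not be all zero"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        return self.data.loc[sample_id]


@dataclass(frozen=True)
class CohortMetadata:
    """Per-sample group labels plus optional clinical scores / outcomes.

    ``frame`` is indexed by sample_id and must carry a ``group`` column;
    any other column is a numeric score or outcome.  Missing values are NaN.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.frame.columns:
            raise MetadataError("metadata requires a 'group' column")
        if self.frame.index.has_duplicates:
            raise MetadataError("duplicate sample ids in metadata")
        unknown = set(self.frame["group"]) - set(KNOWN_GROUPS)
        if unknown:
            raise MetadataError(
                f"unknown group label(s): {sorted(map(str, unknown))}"
            )
        for col, (lo, hi) in SCORE_RANGES.items():
            if col in self.frame.columns:
                vals = pd.to_numeric(self.frame[col], errors="coerce")
                bad = vals.dropna()
                bad = bad[(bad < lo) | (bad > hi)]
                if len(bad):
                    raise MetadataError(f"{col} out of range {lo}-{hi}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.frame.index[self.frame["group"] == group])

    def numeric_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "group"]


# ---------------------------------------------------------------------------
# feature tables


def read_feature_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    unit: str | None = None,
    taxonomy: Mapping[str, str] | None = None,
) -> FeatureTable:
    """Read a TSV abundance matrix.

    The unit is inferred unless given explicitly: all-integral values are
    counts; rows summing to 1 within 1e-6 are proportions; anything else is
    an error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise FeatureTableError("duplicate IDs in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise FeatureTableError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FeatureTableError(f"non-numeric cell in {path}") from exc
    if np.isnan(values).any():
        raise FeatureTableError("missing/non-numeric cell in feature table")
    if (values < 0).any():
        raise FeatureTableError("negative abundance")
    if unit is None:
        if np.array_equal(values, np.round(values)):
            unit = "counts"
        elif np.allclose(values.sum(axis=1), 1.0, atol=1e-6, rtol=0.0):
            unit = "proportions"
        else:
            raise FeatureTableError(
                "ambiguous unit: values are neither integral counts nor "
                "rows summing to 1; pass unit= explicitly"
            )
    if unit == "proportions":
        # re-normalise tiny rounding drift from text round-trips
        sums = values.sum(axis=1)
        if (sums <= 0).any():
            raise FeatureTableError("empty sample in proportions table")
        values = values / sums[:, None]
        df = pd.DataFrame(values, index=df.index, columns=df.columns)
    return FeatureTable(df, unit=unit, taxonomy=taxonomy)


def write_table(table: FeatureTable, path: str | Path) -> None:
    """Write samples-as-rows TSV (one canonical orientation everywhere)."""
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Convert counts to per-sample proportions (row-normalise).

    Idempotent on proportion tables.  A sample with zero total count is an
    error: its composition is undefined.
    """
    values = table.data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise FeatureTableError(f"empty sample(s): {bad}")
    data = pd.DataFrame(
        values / sums[:, None], index=table.data.index, columns=table.data.columns
    )
    return FeatureTable(data, unit="proportions", taxonomy=table.taxonomy)


def _lineage_prefix(lineage: str, rank: str) -> str:
    """Lineage prefix up to ``rank``; an absent/empty rank token becomes an
    'unclassified' bucket under its parent prefix."""
    depth = RANKS.index(rank)
    tokens = [t.strip() for t in lineage.split(";")]
    prefix = _RANK_PREFIX[rank] + "__"
    kept = tokens[: depth + 1]
    if len(kept) < depth + 1 or kept[depth] in ("", prefix):
        kept = kept + [""] * (depth + 1 - len(kept))
        kept[depth] = prefix + "unclassified"
    return ";".join(kept)


def collapse_taxonomy(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum taxa sharing the lineage prefix up to ``rank``.

    Taxa whose lineage lacks the rank collapse into a per-parent
    ``<prefix>__unclassified`` bucket; two taxa with distinct parent
    lineages stay in distinct buckets.  Per-sample totals are conserved
    exactly (pure column sums).
    """
    if rank not in RANKS:
        raise FeatureTableError(f"unknown rank {rank!r}")
    if table.taxonomy is None:
        raise FeatureTableError("collapse requires a taxonomy map")
    missing = [t for t in table.taxon_ids if t not in table.taxonomy]
    if missing:
        raise FeatureTableError(f"taxa without taxonomy: {missing[:5]}")
    keys = {t: _lineage_prefix(table.taxonomy[t], rank) for t in table.taxon_ids}
    collapsed = table.data.T.groupby(table.data.columns.map(keys), sort=False).sum().T
    return FeatureTable(collapsed, unit=table.unit, taxonomy=None)


# ---------------------------------------------------------------------------
# trees


def read_tree(path: str | Path) -> TreeNode:
    """Read a single rooted Newick tree.

    Missing branch lengths default to 0 with a logged warning; the root
    edge always carries length 0 and is excluded from UniFrac branch sets.
    Duplicate leaf names are an error.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise TreeError(f"cannot parse Newick file {path}: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: TreeNode) -> TreeNode:
    names = [leaf.name for leaf in tree.tips()]
    if len(names) != len(set(names)):
        raise TreeError("duplicate leaf name in tree")
    if any(n is None for n in names):
        raise TreeError("unnamed leaf in tree")
    defaulted = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            defaulted += 1
        elif not np.isfinite(node.length) or node.length < 0:
            raise TreeError(f"invalid branch length on {node.name!r}")
    if defaulted:
        log.warning("tree: %d missing branch lengths defaulted to 0", defaulted)
    tree.length = 0.0
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path: str | Path) -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    if "group" not in df.columns:
        raise MetadataError("metadata requires a 'group' column")
    for col in df.columns:
        if col != "group":
            df[col] = pd.to_numeric(df[col], errors="raise")
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.12g", na_rep="NA")


# ---------------------------------------------------------------------------
# correlation records (see association.CorrelationRecord)

_RECORD_COLUMNS = ("feature_id", "target_name", "rho", "p_value", "n", "significant")


def write_records(records: Iterable, path: str | Path) -> None:
    """Write correlation records as a TSV with one row per (feature, target)."""
    rows = [
        {
            "feature_id": r.feature_id,
            "target_name": r.target_name,
            "rho": r.rho,
            "p_value": r.p_value,
            "n": r.n,
            "significant": r.significant,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_records(path: str | Path) -> list:
    from .association import CorrelationRecord

    df = pd.read_csv(path, sep="\t")
    return [
        CorrelationRecord(
            feature_id=str(r.feature_id),
            target_name=str(r.target_name),
            rho=float(r.rho),
            p_value=float(r.p_value),
            n=int(r.n),
            significant=bool(r.significant),
        )
        for r in df.itertuples(index=False)
    ]
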