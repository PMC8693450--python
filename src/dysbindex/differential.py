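"""Prevalence filtering, Wilcoxon rank-sum testing, and dysbiosis-index fitting.

The index model is fitted from a two-group differential-abundance screen:
genera present in at least 10% of samples are tested case vs control with
the Wilcoxon rank-sum test, and every significant genus enters the model
with weight ``-log10(p)`` and a direction (case-enriched or
control-enriched) taken from the mean-rank comparison.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import logging

import numpy as np
from scipy import stats

from .io_formats import CohortMetadata, FeatureTable, FeatureTableError

log = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "IndexEntry",
    "IndexModel",
    "prevalence_filter",
    "wilcoxon_rank_sum",
    "differential_genera",
    "fit_index_model",
    "EmptyModelError",
]

#: p-values are floored here before -log10 weighting so underflow can never
#: produce an infinite weight.
P_FLOOR = 1e-300


class EmptyModelError(ValueError):
    """No significant, direction-bearing taxa to build an index from."""


@dataclass(frozen=True)
class DifferentialResult:
    taxon_id: str
    prevalence: float
    p_value: float
    p_adjusted: float
    direction: str  # case_enriched | control_enriched | tied
    mean_rank_case: float
    mean_rank_control: float
    significant: bool


@dataclass(frozen=True)
class IndexEntry:
    taxon_id: str
    weight: float
    direction: str


@dataclass(frozen=True)
class IndexModel:
    """Fitted dysbiosis scorer: per-taxon -log10(p) weights and directions."""

    entries: tuple[IndexEntry, ...]
    case_label: str
    control_label: str
    alpha: float
    adjustment: str

    def __post_init__(self) -> None:
        taxa = [e.taxon_id for e in self.entries]
        if len(taxa) != len(set(taxa)):
            raise ValueError("taxon appears twice in index model")
        if any(e.weight <= 0 for e in self.entries):
            raise ValueError("index weights must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "case_label": self.case_label,
                "control_label": self.control_label,
                "alpha": self.alpha,
                "adjustment": self.adjustment,
                "entries": [
                    {"taxon_id": e.taxon_id, "weight": e.weight, "direction": e.direction}
                    for e in self.entries
                ],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "IndexModel":
        obj = json.loads(text)
        return cls(
            entries=tuple(
                IndexEntry(e["taxon_id"], float(e["weight"]), e["direction"])
                for e in obj["entries"]
            ),
            case_label=obj["case_label"],
            control_label=obj["control_label"],
            alpha=float(obj["alpha"]),
            adjustment=obj["adjustment"],
        )


# ---------------------------------------------------------------------------


def prevalence_filter(table: FeatureTable, min_prevalence: float = 0.10) -> FeatureTable:
    """Keep taxa with nonzero abundance in >= ``min_prevalence`` of samples.

    The threshold is inclusive: a taxon present in exactly 10% of samples
    survives the default filter.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    if table.n_samples == 0 or table.n_taxa == 0:
        raise FeatureTableError("empty feature table")
    prevalence = (table.data.to_numpy() > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    dropped = [t for t, k in zip(table.taxon_ids, keep) if not k]
    if dropped:
        log.info("prevalence filter dropped %d taxa: %s", len(dropped), dropped)
    data = table.data.loc[:, keep]
    return FeatureTable(data, unit=table.unit, taxonomy=table.taxonomy)


def _exact_rank_sum_p(ranks: np.ndarray, n_x: int, w_obs: float) -> float:
    """Two-sided exact p by complete enumeration of rank assignments.

    Enumerates every choice of which ``n_x`` of the pooled (mid-)ranks go to
    x and compares the resulting rank-sums with the observed one.  Two-sided
    p is ``2 * min(P(W <= w), P(W >= w))`` capped at 1, which for tie-free
    ranks equals the symmetric tail probability.
    """
    n_le = 0
    n_ge = 0
    total = 0
    eps = 1e-9
    for combo in itertools.combinations(ranks, n_x):
        w = sum(combo)
        total += 1
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Returns ``(statistic, p)`` where the statistic is the rank-sum of ``x``
    over the pooled sample (mid-ranks for ties).  ``mode='exact'`` computes
    the p-value by complete enumeration of rank assignments (valid with
    ties); ``'asymptotic'`` uses the tie-corrected normal approximation with
    continuity correction; ``'auto'`` is exact when the pooled size is <= 12
    and tie-free, asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input vector")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN in input")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    if mode == "exact":
        if pooled.size > 20:
            raise ValueError("exact enumeration limited to pooled size <= 20")
        return w, _exact_rank_sum_p(ranks, x.size, w)
    if mode != "asymptotic":
        raise ValueError(f"unknown mode {mode!r}")
    if np.unique(pooled).size == 1:
        return w, 1.0  # all observations identical: no evidence either way
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return w, float(res.pvalue)


def differential_genera(
    table: FeatureTable,
    meta: CohortMetadata,
    case: str,
    control: str,
    alpha: float = 0.05,
    adjustment: str = "none",
) -> list[DifferentialResult]:
    """Per-taxon two-group Wilcoxon screen on relative abundances.

    Results are sorted by p ascending (ties broken by taxon id).  With
    ``adjustment='bonferroni'`` the significance flag uses
    ``p_adjusted <= alpha``; with ``'none'`` it uses raw ``p < alpha``.
    """
    if table.unit != "proportions":
        raise FeatureTableError("differential testing expects relative abundances")
    if case == control:
        raise ValueError("case and control groups must differ")
    if adjustment not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    case_ids = [s for s in meta.samples_in_group(case) if s in table.data.index]
    ctrl_ids = [s for s in meta.samples_in_group(control) if s in table.data.index]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("both groups need >= 2 samples present in the table")
    m = table.n_taxa
    results = []
    for taxon in table.taxon_ids:
        x = table.data.loc[case_ids, taxon].to_numpy(dtype=float)
        y = table.data.loc[ctrl_ids, taxon].to_numpy(dtype=float)
        pooled = np.concatenate([x, y])
        prevalence = float((pooled > 0).mean())
        ranks = stats.rankdata(pooled)
        mr_case = float(ranks[: len(x)].mean())
        mr_ctrl = float(ranks[len(x):].mean())
        _, p = wilcoxon_rank_sum(x, y, mode="auto")
        if mr_case > mr_ctrl:
            direction = "case_enriched"
        elif mr_case < mr_ctrl:
            direction = "control_enriched"
        else:
            direction = "tied"
        p_adj = min(1.0, m * p) if adjustment == "bonferroni" else p
        significant = (p_adj <= alpha) if adjustment == "bonferroni" else (p < alpha)
        results.append(
            DifferentialResult(
                taxon_id=taxon,
                prevalence=prevalence,
                p_value=p,
                p_adjusted=p_adj,
                direction=direction,
                mean_rank_case=mr_case,
                mean_rank_control=mr_ctrl,
                significant=significant,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.taxon_id))
    return results


def fit_index_model(
    results: Sequence[DifferentialResult],
    case: str,
    control: str,
    alpha: float = 0.05,
    adjustment: str = "none",
) -> IndexModel:
    """Build the index model from a differential screen.

    Significant, direction-bearing taxa enter with weight ``-log10(p)``.
    The printed enriched-minus-depleted form needs positive weights for
    case-enriched taxa to raise the score, so the negated log is used
    throughout.  Tied-direction taxa are excluded (the score needs a side).
    """
    entries = []
    for r in results:
        significant = (
            r.p_adjusted <= alpha if adjustment == "bonferroni" else r.p_value < alpha
        )
        if not significant:
            continue
        if r.direction == "tied":
            log.warning("tied-direction taxon %s excluded from index", r.taxon_id)
            continue
        weight = -math.log10(max(r.p_value, P_FLOOR))
        entries.append(IndexEntry(r.taxon_id, weight, r.direction))
    if not entries:
        raise EmptyModelError(
            f"no significant taxa at alpha={alpha} (adjustment={adjustment}): "
            "empty model"
        )
    return IndexModel(
        entries=tuple(entries),
        case_label=case,
        control_label=control,
        alpha=alpha,
        adjustment=adjustment,
    )
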