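"""Correlation engines: Spearman (exact small-n p), clinical-score and
mouse-outcome screens, Pearson chi-square, and comparative-Ct fold changes.

The Spearman engine computes rho as the Pearson correlation of mid-ranks.
For small samples (n <= 9) the two-sided p-value is exact: the full
permutation distribution of rho is enumerated, which matches the scale of
the mouse experiment (9 animals) where the t-approximation is unreliable.
"""

from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dysbiosis_index import IndexScoreTable
from .io_formats import CohortMetadata, FeatureTable

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationRecord",
    "SpearmanResult",
    "spearman",
    "score_correlations",
    "taxa_outcome_screen",
    "chi_square_2x2",
    "relative_expression",
]

#: Exact enumeration is capped here (9! ~ 3.6e5 permutations, sub-second).
EXACT_N_MAX = 9

STROKE_GROUPS = ("AIS", "AIS_T2D")
CLINICAL_TARGETS = ("NIHSS", "mRS", "Essen")


@dataclass(frozen=True)
class CorrelationRecord:
    feature_id: str
    target_name: str
    rho: float
    p_value: float
    n: int
    significant: bool

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")
        if self.n < 3:
            raise ValueError("correlation record needs n >= 3")


@dataclass(frozen=True)
class SpearmanResult:
    """rho and p, or a degenerate flag when either input is constant."""

    rho: float | None
    p_value: float | None
    n: int
    method: str
    degenerate: bool = False


@functools.lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    """All n! index permutations, cached (int8; n <= 9 keeps this small)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _exact_two_sided_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Fraction of rank-alignment permutations with |rho| >= |rho_obs|.

    Enumerates permutations of one vector against the other; valid with
    mid-ranks (tied values) because every relative alignment is equally
    likely under the null.
    """
    n = len(x_ranks)
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    norm = np.sqrt((xc**2).sum() * (yc**2).sum())
    perms = _perm_matrix(n)
    dots = xc[perms] @ yc
    rhos = dots / norm
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(
    x: Sequence[float], y: Sequence[float], p_mode: str = "auto"
) -> SpearmanResult:
    """Spearman rank correlation with exact or t-approximate p.

    ``auto`` uses full permutation enumeration when n <= 9 and both vectors
    are tie-free, the t-approximation on mid-ranks otherwise.  A constant
    vector yields a degenerate result (rho undefined) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman needs n >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN in input")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return SpearmanResult(rho=None, p_value=None, n=n, method="degenerate", degenerate=True)
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if p_mode == "auto":
        p_mode = "exact" if (n <= EXACT_N_MAX and tie_free) else "asymptotic"
    if p_mode == "exact":
        if n > EXACT_N_MAX:
            raise ValueError(f"exact enumeration limited to n <= {EXACT_N_MAX}")
        p = _exact_two_sided_p(xr, yr, rho)
        return SpearmanResult(rho=rho, p_value=p, n=n, method="exact")
    if p_mode != "asymptotic":
        raise ValueError(f"unknown p_mode {p_mode!r}")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho=rho, p_value=p, n=n, method="asymptotic")


def _exact_p_many(x_matrix: np.ndarray, y_ranks: np.ndarray) -> np.ndarray:
    """Exact two-sided p for many features against one target.

    Shares the permutation expansion of the target's ranks across features
    (the permutation distributions of ``rho(x_sigma, y)`` and
    ``rho(x, y_sigma)`` coincide), making screens over dozens of taxa cheap.
    """
    n = y_ranks.size
    yc = y_ranks - y_ranks.mean()
    y_perm = yc[_perm_matrix(n)]  # n! x n
    ps = np.empty(x_matrix.shape[0])
    for i, xr in enumerate(x_matrix):
        xc = xr - xr.mean()
        norm = np.sqrt((xc**2).sum() * (yc**2).sum())
        rhos = (y_perm @ xc) / norm
        rho_obs = float(xc @ yc) / norm
        ps[i] = np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)
    return ps


def score_correlations(
    scores: IndexScoreTable,
    meta: CohortMetadata,
    targets: Sequence[str] = CLINICAL_TARGETS,
    alpha: float = 0.05,
) -> list[CorrelationRecord]:
    """Correlate the dysbiosis index with clinical scores over stroke samples.

    Only samples in a stroke group (AIS, AIS_T2D) with the score present are
    used; clinical scores are heavily tied so the mid-rank t-approximation
    applies.
    """
    stroke = meta.frame[meta.frame["group"].isin(STROKE_GROUPS)]
    records = []
    for target in targets:
        if target not in stroke.columns:
            raise ValueError(f"score column {target!r} absent from metadata")
        present = stroke[target].notna()
        ids = [s for s in stroke.index[present] if s in scores.scores.index]
        if len(ids) < 3:
            raise ValueError(f"fewer than 3 usable samples for {target}")
        res = spearman(
            scores.scores.loc[ids].to_numpy(),
            stroke.loc[ids, target].to_numpy(dtype=float),
            p_mode="auto",
        )
        if res.degenerate:
            log.warning("degenerate correlation for %s (constant input)", target)
            continue
        records.append(
            CorrelationRecord(
                feature_id="dysbiosis_index",
                target_name=target,
                rho=res.rho,
                p_value=res.p_value,
                n=res.n,
                significant=res.p_value < alpha,
            )
        )
    return records


def _family_aggregates(table: FeatureTable) -> dict[str, list[str]]:
    """Group taxa by the family token of their lineage."""
    if table.taxonomy is None:
        raise ValueError("family aggregation requires a taxonomy map")
    groups: dict[str, list[str]] = {}
    for taxon in table.taxon_ids:
        family = "f__unclassified"
        for token in table.taxonomy[taxon].split(";"):
            token = token.strip()
            if token.startswith("f__") and token != "f__":
                family = token
        groups.setdefault(family, []).append(taxon)
    return groups


def taxa_outcome_screen(
    table: FeatureTable,
    meta: CohortMetadata,
    alpha: float = 0.05,
    level: str = "otu",
    aggregates: Mapping[str, Sequence[str]] | None = None,
    outcomes: Sequence[str] | None = None,
) -> list[CorrelationRecord]:
    """All feature x outcome Spearman correlations (the heatmap screen).

    ``level='otu'`` correlates each taxon; ``level='family-aggregate'`` sums
    member abundances per family (or per the explicit ``aggregates`` map)
    before correlating.  Missing outcome values are handled
    pairwise-complete, with the per-record n always reported.  Significance
    is raw ``p < alpha``.
    """
    if outcomes is None:
        outcomes = [c for c in meta.numeric_columns() if c not in CLINICAL_TARGETS]
    if not outcomes:
        raise ValueError("no outcome columns in metadata")
    ids = [s for s in table.sample_ids if s in meta.frame.index]
    if len(ids) < 3:
        raise ValueError("screen needs >= 3 samples")
    data = table.data.loc[ids]
    if level == "family-aggregate" or aggregates is not None:
        agg = dict(aggregates) if aggregates is not None else _family_aggregates(table)
        unknown = [t for ts in agg.values() for t in ts if t not in data.columns]
        if unknown:
            raise ValueError(f"aggregate references unknown taxa: {unknown[:5]}")
        data = pd.DataFrame(
            {name: data[list(ts)].sum(axis=1) for name, ts in agg.items()}
        )
    elif level != "otu":
        raise ValueError(f"unknown level {level!r}")

    records = []
    for outcome in outcomes:
        if outcome not in meta.frame.columns:
            raise ValueError(f"unknown outcome column {outcome!r}")
        y_all = meta.frame.loc[ids, outcome]
        usable = y_all.notna().to_numpy()
        if usable.sum() < 3:
            log.warning("outcome %s has <3 complete samples; skipped", outcome)
            continue
        y = y_all.to_numpy(dtype=float)[usable]
        n = int(usable.sum())
        yr = stats.rankdata(y)
        y_tiefree = np.unique(y).size == n
        exact_batch: list[tuple[int, np.ndarray, float]] = []
        partial: dict[str, SpearmanResult] = {}
        features = list(data.columns)
        for feat in features:
            x = data[feat].to_numpy(dtype=float)[usable]
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                log.info("constant feature/outcome %s vs %s excluded", feat, outcome)
                partial[feat] = SpearmanResult(None, None, n, "degenerate", True)
                continue
            xr = stats.rankdata(x)
            rho = float(np.corrcoef(xr, yr)[0, 1])
            tie_free = y_tiefree and np.unique(x).size == n
            if n <= EXACT_N_MAX and tie_free:
                exact_batch.append((len(exact_batch), xr, rho))
                partial[feat] = SpearmanResult(rho, None, n, "exact")
            else:
                res = spearman(x, y, p_mode="asymptotic")
                partial[feat] = res
        if exact_batch:
            xmat = np.array([xr for _, xr, _ in exact_batch])
            ps = _exact_p_many(xmat, yr)
        feat_exact = [f for f in features if partial[f].method == "exact"]
        for i, feat in enumerate(feat_exact):
            r = partial[feat]
            partial[feat] = SpearmanResult(r.rho, float(ps[i]), n, "exact")
        for feat in features:
            res = partial[feat]
            if res.degenerate:
                continue
            records.append(
                CorrelationRecord(
                    feature_id=feat,
                    target_name=outcome,
                    rho=res.rho,
                    p_value=res.p_value,
                    n=res.n,
                    significant=res.p_value < alpha,
                )
            )
    return records


def chi_square_2x2(
    contingency: Sequence[Sequence[float]], yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table (df = 1).

    No continuity correction by default; set ``yates=True`` to apply it.
    All four margins must be positive.
    """
    t = np.asarray(contingency, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative cell count")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), float(p)


def relative_expression(
    ct_target: float, ct_reference: float, calibrator_delta: float
) -> float:
    """Comparative-Ct fold change: ``2 ** -((Ct_t - Ct_ref) - calibrator)``."""
    for v in (ct_target, ct_reference, calibrator_delta):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_reference) - calibrator_delta
    return float(2.0 ** (-ddct))
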