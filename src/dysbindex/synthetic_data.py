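"""Synthetic cohorts with the statistical structure the analysis assumes.

Communities are drawn from a Dirichlet-multinomial model: each group has an
expected composition ``softmax(base_log_abundance + sum of active-disease
log-fold effects)``, per-sample compositions are Dirichlet around it with a
configurable precision, and counts are multinomial at a negative-binomial
library size.  Disease effects are signed log2 fold changes on named
genera; the comorbid group's effect is *definitionally* the sum of the two
single-disease effects, which is the additive structure the human cohort
exhibits.

The default panel mirrors a Bacteroidetes/Firmicutes/Proteobacteria-
dominated gut community: Bacteroides, Prevotella, Faecalibacterium, and
Parabacteroides carry the highest abundance, the 11 planted diabetes-
associated genera include Porphyromonas, Lactobacillus, Blautia, Dorea,
Lachnospira, Roseburia, Megasphaera, Catenibacterium, Cetobacterium and two
unclassified Enterobacteriaceae genus buckets, and a tail of genuinely rare
genera gives presence/absence contrast for unweighted UniFrac.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import CohortMetadata, FeatureTable, HUMAN_GROUPS, MOUSE_GROUPS

__all__ = [
    "ScoreLink",
    "SyntheticConfig",
    "CohortTruth",
    "default_config",
    "generate_cohort",
    "generate_scores",
    "generate_tree",
    "generate_mouse_study",
    "substream",
]

LN2 = float(np.log(2.0))


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream: one global seed, independent per-stage draws."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,))
    )


@dataclass(frozen=True)
class ScoreLink:
    """Linear link from latent dysbiosis to an integer clinical score."""

    intercept: float
    slope: float
    noise_sd: float
    lo: int
    hi: int


# ---------------------------------------------------------------------------
# default human panel

# unnormalised expected relative abundances for the healthy composition;
# softmax of their logs is the control expectation.
_BASE_ABUNDANCE: dict[str, float] = {
    # dominant background genera
    "Bacteroides": 0.18,
    "Prevotella": 0.12,
    "Faecalibacterium": 0.10,
    "Parabacteroides": 0.06,
    "Alistipes": 0.04,
    "Ruminococcus": 0.04,
    "Coprococcus": 0.025,
    "Oscillospira": 0.020,
    "Clostridium": 0.020,
    "Eubacterium": 0.020,
    "Blautia": 0.015,
    "Roseburia": 0.015,
    "Lachnospira": 0.015,
    "Dorea": 0.010,
    "Streptococcus": 0.015,
    "Bifidobacterium": 0.015,
    "Enterobacteriaceae_g1": 0.018,
    "Phascolarctobacterium": 0.012,
    "Veillonella": 0.010,
    "Sutterella": 0.008,
    "Collinsella": 0.008,
    "Fusobacterium": 0.006,
    "Akkermansia": 0.006,
    # low-prevalence genera: detected in only part of the cohort at
    # realistic sequencing depth, so presence/absence carries signal
    "Anaerostipes": 0.0020,
    "Dialister": 0.0020,
    "Odoribacter": 0.0015,
    "Porphyromonas": 0.0020,
    "Catenibacterium": 0.0020,
    "Cetobacterium": 0.0015,
    "Butyricimonas": 0.0010,
    "Paraprevotella": 0.0010,
    "Turicibacter": 0.0010,
    "Lactobacillus": 0.0003,
    "Enterobacteriaceae_g2": 0.0003,
    "Haemophilus": 0.0008,
    "Succinivibrio": 0.0008,
    "Christensenella": 0.0006,
    "Desulfovibrio": 0.0006,
    "Megasphaera": 0.0003,
    "Bilophila": 0.0004,
}

_LINEAGE: dict[str, str] = {
    "Bacteroides": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides",
    "Prevotella": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Prevotellaceae;g__Prevotella",
    "Parabacteroides": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Porphyromonadaceae;g__Parabacteroides",
    "Porphyromonas": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Porphyromonadaceae;g__Porphyromonas",
    "Alistipes": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Rikenellaceae;g__Alistipes",
    "Odoribacter": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Odoribacteraceae;g__Odoribacter",
    "Butyricimonas": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Odoribacteraceae;g__Butyricimonas",
    "Paraprevotella": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Prevotellaceae;g__Paraprevotella",
    "Faecalibacterium": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__Faecalibacterium",
    "Ruminococcus": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__Ruminococcus",
    "Oscillospira": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__Oscillospira",
    "Blautia": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia",
    "Roseburia": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Roseburia",
    "Coprococcus": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Coprococcus",
    "Lachnospira": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Lachnospira",
    "Dorea": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Dorea",
    "Anaerostipes": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Anaerostipes",
    "Clostridium": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Clostridiaceae;g__Clostridium",
    "Eubacterium": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Eubacteriaceae;g__Eubacterium",
    "Christensenella": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Christensenellaceae;g__Christensenella",
    "Streptococcus": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Streptococcaceae;g__Streptococcus",
    "Lactobacillus": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Lactobacillaceae;g__Lactobacillus",
    "Turicibacter": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Turicibacterales;f__Turicibacteraceae;g__Turicibacter",
    "Veillonella": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Veillonellaceae;g__Veillonella",
    "Megasphaera": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Veillonellaceae;g__Megasphaera",
    "Dialister": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Veillonellaceae;g__Dialister",
    "Phascolarctobacterium": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Veillonellaceae;g__Phascolarctobacterium",
    "Catenibacterium": "k__Bacteria;p__Firmicutes;c__Erysipelotrichi;o__Erysipelotrichales;f__Erysipelotrichaceae;g__Catenibacterium",
    "Enterobacteriaceae_g1": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacteriales;f__Enterobacteriaceae;g__",
    "Enterobacteriaceae_g2": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacteriales;f__Enterobacteriaceae;g__unclassified_2",
    "Haemophilus": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pasteurellales;f__Pasteurellaceae;g__Haemophilus",
    "Succinivibrio": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Aeromonadales;f__Succinivibrionaceae;g__Succinivibrio",
    "Sutterella": "k__Bacteria;p__Proteobacteria;c__Betaproteobacteria;o__Burkholderiales;f__Alcaligenaceae;g__Sutterella",
    "Desulfovibrio": "k__Bacteria;p__Proteobacteria;c__Deltaproteobacteria;o__Desulfovibrionales;f__Desulfovibrionaceae;g__Desulfovibrio",
    "Bilophila": "k__Bacteria;p__Proteobacteria;c__Deltaproteobacteria;o__Desulfovibrionales;f__Desulfovibrionaceae;g__Bilophila",
    "Fusobacterium": "k__Bacteria;p__Fusobacteria;c__Fusobacteriia;o__Fusobacteriales;f__Fusobacteriaceae;g__Fusobacterium",
    "Cetobacterium": "k__Bacteria;p__Fusobacteria;c__Fusobacteriia;o__Fusobacteriales;f__Fusobacteriaceae;g__Cetobacterium",
    "Bifidobacterium": "k__Bacteria;p__Actinobacteria;c__Actinobacteria;o__Bifidobacteriales;f__Bifidobacteriaceae;g__Bifidobacterium",
    "Collinsella": "k__Bacteria;p__Actinobacteria;c__Coriobacteriia;o__Coriobacteriales;f__Coriobacteriaceae;g__Collinsella",
    "Akkermansia": "k__Bacteria;p__Verrucomicrobia;c__Verrucomicrobiae;o__Verrucomicrobiales;f__Verrucomicrobiaceae;g__Akkermansia",
}

#: 11 planted diabetes-associated genera, signed log2 fold changes (±1.5).
_T2D_EFFECTS: dict[str, float] = {
    "Lactobacillus": +1.5,
    "Megasphaera": +1.5,
    "Porphyromonas": -1.5,
    "Catenibacterium": -1.5,
    "Cetobacterium": -1.5,
    "Enterobacteriaceae_g1": +1.5,
    "Enterobacteriaceae_g2": +1.5,
    "Blautia": -1.5,
    "Dorea": -1.5,
    "Lachnospira": -1.5,
    "Roseburia": -1.5,
}

#: Stroke-associated shifts: Proteobacteria (Enterobacteriaceae and
#: Desulfovibrionaceae members) up, SCFA producers down.
_AIS_EFFECTS: dict[str, float] = {
    "Enterobacteriaceae_g1": +1.2,
    "Enterobacteriaceae_g2": +1.2,
    "Desulfovibrio": +1.5,
    "Bilophila": +1.5,
    "Haemophilus": +1.2,
    "Prevotella": -1.0,
    "Faecalibacterium": -1.0,
    "Lachnospira": -1.0,
    "Coprococcus": -1.0,
    # low-prevalence SCFA/butyrate producers lost after stroke: their
    # dropout is what makes the presence/absence beta-diversity shift
    "Anaerostipes": -1.5,
    "Dialister": -1.5,
    "Odoribacter": -1.5,
    "Butyricimonas": -1.5,
    "Paraprevotella": -1.5,
    "Turicibacter": -1.5,
}

_DEFAULT_SCORE_LINKS: dict[str, ScoreLink] = {
    "NIHSS": ScoreLink(intercept=6.0, slope=24.0, noise_sd=2.0, lo=0, hi=15),
    "mRS": ScoreLink(intercept=2.5, slope=10.0, noise_sd=1.0, lo=0, hi=6),
    "Essen": ScoreLink(intercept=3.5, slope=14.0, noise_sd=1.2, lo=0, hi=9),
}

#: which diseases are active in each cohort group
_ACTIVE = {
    "control": (),
    "T2D": ("T2D",),
    "AIS": ("AIS",),
    "AIS_T2D": ("T2D", "AIS"),
    "control_FMT": (),
    "T2D_FMT": ("T2D",),
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_per_group: Mapping[str, int]
    base_abundance: Mapping[str, float]
    effects: Mapping[str, Mapping[str, float]]  # disease -> taxon -> log2FC
    taxonomy: Mapping[str, str] | None = None
    concentration: float = 200.0
    library_size_mean: float = 20000.0
    library_size_shape: float = 10.0
    score_links: Mapping[str, ScoreLink] = field(
        default_factory=lambda: dict(_DEFAULT_SCORE_LINKS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        known = set(HUMAN_GROUPS) | set(MOUSE_GROUPS)
        for group, n in self.n_per_group.items():
            if group not in known:
                raise ValueError(f"unknown group {group!r}")
            if n < 2:
                raise ValueError("all group sizes must be >= 2")
        if self.concentration <= 0:
            raise ValueError("Dirichlet concentration must be > 0")
        if self.library_size_mean <= 0 or self.library_size_shape <= 0:
            raise ValueError("library size parameters must be positive")
        if any(v <= 0 for v in self.base_abundance.values()):
            raise ValueError("base abundances must be positive")
        for disease, taxa in self.effects.items():
            if disease not in ("T2D", "AIS"):
                raise ValueError(
                    f"effects keyed by disease in {{T2D, AIS}}; got {disease!r} "
                    "(the comorbid shift is their sum by definition)"
                )
            unknown = set(taxa) - set(self.base_abundance)
            if unknown:
                raise ValueError(f"effect references unknown taxa: {sorted(unknown)}")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.base_abundance)

    def effect_vector(self, disease: str) -> np.ndarray:
        """Signed natural-log shift per taxon for one disease."""
        taxa = self.taxon_ids
        eff = self.effects.get(disease, {})
        return np.array([eff.get(t, 0.0) * LN2 for t in taxa])

    def expected_log_shift(self, group: str) -> np.ndarray:
        """Group's expected log-abundance shift from control, pre-softmax.

        Built as the exact float sum of the active diseases' effect
        vectors, so the comorbid shift equals the sum of the two
        single-disease shifts bit-for-bit.
        """
        shift = np.zeros(len(self.base_abundance))
        for disease in _ACTIVE[group]:
            shift = shift + self.effect_vector(disease)
        return shift

    def expected_composition(self, group: str) -> np.ndarray:
        logits = (
            np.log(np.array(list(self.base_abundance.values())))
            + self.expected_log_shift(group)
        )
        w = np.exp(logits - logits.max())
        return w / w.sum()


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests.

    ``latent`` is the generator's own dysbiosis value per sample: the sum of
    the planted diabetes log2-fold effects weighted by the realised
    (pre-count) composition — the quantity the fitted index tries to
    recover, not the fitted index itself.
    """

    latent: pd.Series
    planted: dict[str, dict[str, float]]
    note: str = (
        "Dirichlet-multinomial cohort model; abundance distributions are a "
        "modelling stand-in, not an empirical fit."
    )

    def to_json_dict(self) -> dict:
        return {
            "note": self.note,
            "planted_log2_effects": {k: dict(v) for k, v in self.planted.items()},
            "latent_dysbiosis": {k: float(v) for k, v in self.latent.items()},
        }


def default_config(
    seed: int = 0,
    n_per_group: Mapping[str, int] | None = None,
    effect_scale: float = 1.0,
) -> SyntheticConfig:
    """Study-sized default: 55 controls, 90 AIS, 35 T2D, 60 comorbid."""
    if n_per_group is None:
        n_per_group = {"control": 55, "AIS": 90, "T2D": 35, "AIS_T2D": 60}
    effects = {
        "T2D": {t: v * effect_scale for t, v in _T2D_EFFECTS.items()},
        "AIS": {t: v * effect_scale for t, v in _AIS_EFFECTS.items()},
    }
    return SyntheticConfig(
        n_per_group=dict(n_per_group),
        base_abundance=dict(_BASE_ABUNDANCE),
        effects=effects,
        taxonomy=dict(_LINEAGE),
        seed=seed,
    )


def _draw_samples(
    rng: np.random.Generator,
    expected: np.ndarray,
    concentration: float,
    lib_mean: float,
    lib_shape: float,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (counts, realised compositions) for ``n`` samples of one group."""
    alpha = concentration * expected
    comps = rng.dirichlet(alpha, size=n)
    p_nb = lib_shape / (lib_shape + lib_mean)
    sizes = np.maximum(rng.negative_binomial(lib_shape, p_nb, size=n), 1)
    counts = np.empty((n, len(expected)), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(sizes[i], comps[i])
    return counts, comps


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[FeatureTable, CohortMetadata, CohortTruth]:
    """Simulate the four-group cohort; deterministic given ``config.seed``."""
    rng = substream(config.seed, "cohort")
    taxa = config.taxon_ids
    t2d_weights = np.array(
        [config.effects.get("T2D", {}).get(t, 0.0) for t in taxa]
    )
    rows, groups, sample_ids, latents = [], [], [], []
    for group in sorted(config.n_per_group):
        n = config.n_per_group[group]
        expected = config.expected_composition(group)
        counts, comps = _draw_samples(
            rng,
            expected,
            config.concentration,
            config.library_size_mean,
            config.library_size_shape,
            n,
        )
        for i in range(n):
            sample_ids.append(f"{group}_{i + 1:03d}")
            groups.append(group)
            rows.append(counts[i])
            latents.append(float(comps[i] @ t2d_weights))
    table = FeatureTable(
        pd.DataFrame(np.array(rows), index=sample_ids, columns=taxa),
        unit="counts",
        taxonomy=config.taxonomy,
    )
    meta = CohortMetadata(pd.DataFrame({"group": groups}, index=sample_ids))
    truth = CohortTruth(
        latent=pd.Series(latents, index=sample_ids, name="latent_dysbiosis"),
        planted={k: dict(v) for k, v in config.effects.items()},
    )
    return table, meta, truth


def generate_scores(
    meta: CohortMetadata,
    latent: pd.Series,
    score_links: Mapping[str, ScoreLink] | None = None,
    seed: int = 0,
) -> CohortMetadata:
    """Attach clinical scores to stroke samples, monotone in latent dysbiosis.

    Each score is ``clip(round(intercept + slope * latent + noise), lo, hi)``;
    the NIHSS ceiling of 15 honours an admission criterion restricted to
    scores below 16.  Non-stroke samples get no scores.
    """
    links = dict(_DEFAULT_SCORE_LINKS) if score_links is None else dict(score_links)
    for name, link in links.items():
        if not (np.isfinite(link.slope) and np.isfinite(link.noise_sd)):
            raise ValueError(f"non-finite score link for {name}")
    rng = substream(seed, "scores")
    frame = meta.frame.copy()
    stroke_ids = [s for s in frame.index if frame.loc[s, "group"] in ("AIS", "AIS_T2D")]
    missing = [s for s in stroke_ids if s not in latent.index]
    if missing:
        raise ValueError(f"latent value missing for stroke samples: {missing[:5]}")
    for name, link in links.items():
        raw = (
            link.intercept
            + link.slope * latent.loc[stroke_ids].to_numpy()
            + rng.normal(0.0, link.noise_sd, size=len(stroke_ids))
        )
        vals = np.clip(np.round(raw), link.lo, link.hi)
        col = pd.Series(np.nan, index=frame.index, dtype=float)
        col.loc[stroke_ids] = vals
        frame[name] = col
    return CohortMetadata(frame)


def generate_tree(taxon_ids: Sequence[str], seed: int = 0) -> TreeNode:
    """Random rooted binary tree over the taxa: sequential random joins with
    exponential(1) branch lengths; the root edge carries length 0."""
    taxon_ids = list(taxon_ids)
    if len(taxon_ids) < 2:
        raise ValueError("tree needs >= 2 taxa")
    rng = substream(seed, "tree")
    nodes = [TreeNode(name=t) for t in taxon_ids]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        a.length = float(rng.exponential(1.0))
        b.length = float(rng.exponential(1.0))
        parent = TreeNode(children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


# ---------------------------------------------------------------------------
# mouse study

_MOUSE_BASE: dict[str, tuple[float, str]] = {
    # OTU id: (base share, lineage)
    "OTU_Bacteroides_1": (0.15, "k__Bacteria;p__Bacteroidetes;f__Bacteroidaceae;g__Bacteroides"),
    "OTU_Bacteroides_2": (0.08, "k__Bacteria;p__Bacteroidetes;f__Bacteroidaceae;g__Bacteroides"),
    "OTU_S24-7": (0.05, "k__Bacteria;p__Bacteroidetes;f__S24-7;g__"),
    "OTU_Rikenellaceae": (0.02, "k__Bacteria;p__Bacteroidetes;f__Rikenellaceae;g__"),
    "OTU_Parabacteroides": (0.04, "k__Bacteria;p__Bacteroidetes;f__Porphyromonadaceae;g__Parabacteroides"),
    "OTU_Pdistasonis": (0.02, "k__Bacteria;p__Bacteroidetes;f__Porphyromonadaceae;g__Parabacteroides;s__distasonis"),
    "OTU_Rumino_1": (0.05, "k__Bacteria;p__Firmicutes;f__Ruminococcaceae;g__Ruminococcus"),
    "OTU_Rumino_2": (0.04, "k__Bacteria;p__Firmicutes;f__Ruminococcaceae;g__"),
    "OTU_Rumino_3": (0.03, "k__Bacteria;p__Firmicutes;f__Ruminococcaceae;g__Oscillospira"),
    "OTU_Rumino_4": (0.03, "k__Bacteria;p__Firmicutes;f__Ruminococcaceae;g__Faecalibacterium"),
    "OTU_Rumino_5": (0.02, "k__Bacteria;p__Firmicutes;f__Ruminococcaceae;g__"),
    "OTU_Rumino_6": (0.02, "k__Bacteria;p__Firmicutes;f__Ruminococcaceae;g__Ruminococcus"),
    "OTU_Lachnospira_1": (0.03, "k__Bacteria;p__Firmicutes;f__Lachnospiraceae;g__Lachnospira"),
    "OTU_Lachnospira_2": (0.02, "k__Bacteria;p__Firmicutes;f__Lachnospiraceae;g__Lachnospira"),
    "OTU_Lachnospiraceae_1": (0.03, "k__Bacteria;p__Firmicutes;f__Lachnospiraceae;g__"),
    "OTU_Lachnospiraceae_2": (0.02, "k__Bacteria;p__Firmicutes;f__Lachnospiraceae;g__"),
    "OTU_Coprococcus_1": (0.02, "k__Bacteria;p__Firmicutes;f__Lachnospiraceae;g__Coprococcus"),
    "OTU_Coprococcus_2": (0.015, "k__Bacteria;p__Firmicutes;f__Lachnospiraceae;g__Coprococcus"),
    "OTU_Clostridiales_1": (0.02, "k__Bacteria;p__Firmicutes;o__Clostridiales;f__;g__"),
    "OTU_Clostridiales_2": (0.015, "k__Bacteria;p__Firmicutes;o__Clostridiales;f__;g__"),
    "OTU_Turicibacter": (0.006, "k__Bacteria;p__Firmicutes;f__Turicibacteraceae;g__Turicibacter"),
    "OTU_Christensenellaceae": (0.004, "k__Bacteria;p__Firmicutes;f__Christensenellaceae;g__"),
    "OTU_Lactobacillus": (0.01, "k__Bacteria;p__Firmicutes;f__Lactobacillaceae;g__Lactobacillus"),
    "OTU_Akkermansia": (0.01, "k__Bacteria;p__Verrucomicrobia;f__Verrucomicrobiaceae;g__Akkermansia"),
    "OTU_Desulfovibrio": (0.006, "k__Bacteria;p__Proteobacteria;f__Desulfovibrionaceae;g__Desulfovibrio"),
}

#: donor-community shift in the diabetic-FMT group: SCFA producers down,
#: the S24-7 (LPS-producing) bucket and Rikenellaceae up.
_MOUSE_EFFECTS: dict[str, float] = {
    "OTU_Rumino_1": -2.0,
    "OTU_Rumino_2": -2.0,
    "OTU_Rumino_3": -2.0,
    "OTU_Rumino_4": -2.0,
    "OTU_Rumino_5": -2.0,
    "OTU_Rumino_6": -2.0,
    "OTU_Lachnospira_1": -2.0,
    "OTU_Lachnospira_2": -2.0,
    "OTU_Lachnospiraceae_1": -1.5,
    "OTU_Lachnospiraceae_2": -1.5,
    "OTU_S24-7": +2.0,
    "OTU_Rikenellaceae": +1.0,
}

SCFA_TAXA = tuple(t for t in _MOUSE_BASE if t.startswith(("OTU_Rumino", "OTU_Lachno")))
S247_TAXON = "OTU_S24-7"

#: outcome name -> (baseline, severity slope, noise sd); positive slope
#: means "worse with severity".  Tight-junction expression fold changes are
#: log2-linked with negative slopes (barrier genes drop as injury worsens).
_MOUSE_OUTCOMES: dict[str, tuple[float, float, float]] = {
    "infarct_ratio": (0.25, 0.10, 0.02),
    "mNSS": (7.0, 2.2, 0.6),
    "LBP": (12.0, 3.0, 0.8),
    "LPS": (0.9, 0.25, 0.06),
}
_MOUSE_EXPRESSION: dict[str, float] = {
    # log2 fold-change slope vs severity (negative: tight junction genes)
    "Ocln_ileum": -0.6,
    "Cldn4_ileum": -0.6,
    "Ocln_colon": -0.5,
    "Cldn4_colon": -0.5,
    "Cxcl1_colon": +0.6,
    "Cxcl2_colon": +0.6,
}


def generate_mouse_study(
    n_control: int = 5,
    n_t2d: int = 4,
    coupling: float = 1.0,
    seed: int = 0,
    library_size_mean: float = 20000.0,
    concentration: float = 150.0,
) -> tuple[FeatureTable, CohortMetadata]:
    """Simulate the germfree FMT experiment (5 control vs 4 diabetic donors).

    Mouse communities come from the same Dirichlet-multinomial machinery,
    with SCFA-producing taxa depleted and an S24-7 bucket enriched in the
    diabetic-donor group.  A per-mouse severity variable — ``coupling``
    times the standardised S24-7-minus-SCFA contrast plus noise — drives
    all injury outcomes (infarct ratio, mNSS, LBP, LPS) upward and
    tight-junction expression fold changes downward.  ``coupling=0``
    decouples outcomes from the microbiota entirely.
    """
    if n_control < 2 or n_t2d < 2:
        raise ValueError("need >= 2 mice per group")
    rng = substream(seed, "mouse")
    taxa = list(_MOUSE_BASE)
    base = np.array([_MOUSE_BASE[t][0] for t in taxa])
    taxonomy = {t: _MOUSE_BASE[t][1] for t in taxa}
    logits = np.log(base)
    shift = np.array([_MOUSE_EFFECTS.get(t, 0.0) * LN2 for t in taxa])

    rows, groups, ids, comps_all = [], [], [], []
    for group, n, sh in (
        ("control_FMT", n_control, 0.0),
        ("T2D_FMT", n_t2d, 1.0),
    ):
        w = np.exp(logits + sh * shift)
        expected = w / w.sum()
        counts, comps = _draw_samples(
            rng, expected, concentration, library_size_mean, 10.0, n
        )
        for i in range(n):
            ids.append(f"{group}_{i + 1}")
            groups.append(group)
            rows.append(counts[i])
            comps_all.append(comps[i])
    comps_all = np.array(comps_all)

    pos = {t: i for i, t in enumerate(taxa)}
    s247 = comps_all[:, pos[S247_TAXON]]
    scfa = comps_all[:, [pos[t] for t in SCFA_TAXA]].sum(axis=1)

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    severity = coupling * (_z(s247) - _z(scfa)) / np.sqrt(2.0) + rng.normal(
        0.0, 0.3, size=len(ids)
    )

    frame = pd.DataFrame({"group": groups}, index=ids)
    for name, (base_v, slope, noise) in _MOUSE_OUTCOMES.items():
        vals = base_v + slope * severity + rng.normal(0.0, noise, size=len(ids))
        if name == "infarct_ratio":
            vals = np.clip(vals, 0.0, 1.0)
        elif name == "mNSS":
            vals = np.clip(np.round(vals), 0, 14)
        else:
            vals = np.maximum(vals, 0.0)
        frame[name] = vals
    for name, slope in _MOUSE_EXPRESSION.items():
        frame[name] = 2.0 ** (
            slope * severity + rng.normal(0.0, 0.15, size=len(ids))
        )

    table = FeatureTable(
        pd.DataFrame(np.array(rows), index=ids, columns=taxa),
        unit="counts",
        taxonomy=taxonomy,
    )
    return table, CohortMetadata(frame)
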