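# Methods

## The dysbiosis index

The index summarises, per sample, the community shift associated with a
reference disease contrast. Fitting is a two-group differential-abundance
screen on relative abundances: genera below 10% prevalence (fraction of
tested samples with nonzero abundance; the threshold is inclusive) are
removed, the rest are tested with the two-sided Wilcoxon rank-sum test,
and each significant genus enters the model with weight −log₁₀ p and a
direction taken from the mean-rank comparison (case- vs
control-enriched; exactly tied mean ranks carry no direction and are
excluded, since the enriched-minus-depleted form needs a side).

Two conventions deserve note:

* **Sign.** Weights are −log₁₀ p ≥ 0, so case-enriched abundance raises
  the score. Writing the weight as log₁₀ p (negative for p < 1) would
  invert every comparison; the negated form is the one under which "cases
  score higher" holds, and is used throughout.
* **No renormalisation.** Scores are computed on whole-community
  proportions. After prevalence filtering (or any taxon subsetting) rows
  are deliberately *not* rescaled to sum to 1; a `FeatureTable` with
  `unit="proportions"` therefore requires row sums in (0, 1] rather than
  exactly 1. Model taxa absent from a scored table contribute 0.
* p-values are floored at 1e-300 before the log so an underflowing p
  cannot produce an infinite weight.

The model is fitted on one contrast (default T2D vs control) and applied
unchanged to every sample; scores are reported raw, without
standardisation. Default significance is raw p < 0.05; Bonferroni
(p·m capped at 1, m = taxa tested) is available via
`adjustment="bonferroni"`.

## Rank tests

`wilcoxon_rank_sum` reports the rank-sum of the first sample over the
pooled mid-ranks. In `auto` mode the p-value is exact when the pooled
size is ≤ 12 and tie-free, asymptotic otherwise. The exact p enumerates
every C(n+m, n) assignment of the pooled (mid-)ranks and uses
2·min(P(W ≤ w), P(W ≥ w)) capped at 1 — identical to the symmetric tail
probability in the tie-free case, and still a valid permutation p with
ties. The asymptotic branch is the tie-corrected normal approximation
with continuity correction (scipy's Mann-Whitney implementation). A
taxon constant across both groups gets p = 1 and direction "tied".

`spearman` computes rho as the Pearson correlation of mid-ranks. For
n ≤ 9 with tie-free inputs (the scale of the mouse study, where the
t-approximation is unreliable) the two-sided p is exact: the full
permutation distribution of rho is enumerated, vectorised over a cached
n! × n permutation matrix. The screen shares the permutation expansion of
each outcome across all taxa (the permutation distributions of
rho(x<sub>σ</sub>, y) and rho(x, y<sub>σ</sub>) coincide), so a full
taxon×outcome screen at n = 9 costs well under a second. Above n = 9, or
with ties, the usual t-approximation on mid-ranks is used. A constant
vector yields an explicit degenerate result (no rho, no p) rather than
NaN; degenerate features are excluded from screens with a log entry.
Missing outcome values are handled pairwise-complete and every record
carries its own n, since small-animal correlation tables are
uninterpretable without it.

## UniFrac, PCoA, PERMANOVA

Both UniFrac kernels work from a branch decomposition: each non-root edge
contributes its length and the set of leaves below it. The root edge is
excluded and carries length 0 — length shared by every community has no
contrast. Presence for the unweighted kernel is strictly positive
abundance (no detection floor). Unweighted distance is unique branch
length over covered branch length; weighted distance is
Σ ℓ<sub>e</sub>·|A<sub>e</sub> − B<sub>e</sub>| with A<sub>e</sub> the
fraction of the sample's mass below edge e, normalised by
Σ ℓ<sub>e</sub>·(A<sub>e</sub> + B<sub>e</sub>) so the result lies in
[0, 1]. The pairwise driver vectorises both metrics over a
branches × samples incidence matrix, making 240-sample matrices
essentially free. Tests pin both kernels to an independent per-leaf
path-set oracle and to scikit-bio's implementations.

PCoA is the classical Gower construction: double-centre −D²/2,
symmetric eigendecomposition, coordinates = eigenvectors scaled by √λ for
λ > 0. Negative eigenvalues (non-Euclidean distances) are reported
untouched and their axes zeroed; no Lingoes/Cailliez correction is
applied, preferring transparency over silent repair.
`proportion_explained` is taken over the positive eigenvalues.

PERMANOVA computes the usual pseudo-F from total vs within-group sums of
squared distances. The p-value uses the +1 convention
(count{F<sub>perm</sub> ≥ F<sub>obs</sub>} + 1)/(B + 1) with label
permutations drawn from the run seed, so p is never 0 and is reproducible.
`n_permutations="exact"` enumerates all distinct label orderings for tiny
designs (used by tests against a 2+2 hand-enumerated case). Perfectly
clustered groups give an infinite F, which orders correctly in the
permutation comparison.

Distance-to-reference summaries are mean pairwise distances: each
non-reference sample averages over all reference samples, each reference
sample over the *other* reference samples. (Distance-to-centroid is a
possible alternative reading of such box plots; mean pairwise is what is
implemented.)

## Synthetic cohorts

The generator's defaults are the study conditions every statistical test
in this package is run under.

**Community model.** Each group's expected composition is
softmax(log base abundance + Σ active-disease effects·ln 2); per-sample
compositions are Dirichlet with precision 200 around it; counts are
multinomial at a negative-binomial library size (mean 20 000, shape 10 —
realistic 16S depth variation without heavy tails). Disease effects are
signed log2 fold changes of ±1.5 on 11 planted diabetes-associated
genera, ±1.0–1.5 on stroke-associated taxa. The comorbid group's shift
is *constructed* as the float sum of the two single-disease shift vectors,
so additivity holds exactly, not just in expectation. The
Dirichlet-multinomial choice is a modelling stand-in — real 16S data have
heavier zero-inflation and taxon-taxon covariance than any DM model — and
`truth.json` records it as such.

**Panel design.** 40 genera with Greengenes-style lineages. Bacteroides,
Prevotella, Faecalibacterium and Parabacteroides dominate, matching the
usual gut profile. A deliberate block of low-abundance genera
(expected shares 3×10⁻⁴–2×10⁻³) sits near the detection boundary at the
default depth, because presence/absence contrast is the entire signal
unweighted UniFrac sees: a genus detected in ~30% of controls and ~70% of
cases moves the distance-to-controls strongly, whereas shifting an
always-detected genus moves it not at all (and enriching a genus whose
control presence already exceeds one half *reduces* expected mismatch).
Consequently the enriched planted genera (Lactobacillus, Megasphaera, two
unclassified Enterobacteriaceae genus buckets — one moderately common
bucket carries the abundance-level signal) are placed rare, and the three
planted genera with no reported direction (Porphyromonas,
Catenibacterium, Cetobacterium) are planted as depleted moderately-rare
taxa. Stroke additionally depletes rare butyrate producers (Anaerostipes,
Odoribacter, Butyricimonas, Dialister, Paraprevotella, Turicibacter) on
top of the abundant SCFA producers (Prevotella, Faecalibacterium,
Lachnospira, Coprococcus) and enriches Proteobacteria
(Enterobacteriaceae, Desulfovibrio, Bilophila, Haemophilus). Planted
depleted mass is balanced against enriched gain so compositional closure
does not systematically inflate unaffected genera and generate false
differential flags.

**Latent dysbiosis and clinical scores.** Each sample's latent dysbiosis
is the sum of the planted diabetes log2 effects weighted by the realised
(pre-count) composition — the generator's own ground truth, independent
of any fitted index, used for parameter-recovery tests. Clinical scores
for stroke samples are clip(round(intercept + slope·latent + Gaussian
noise)) with NIHSS capped at 15 (an admission-restricted population),
mRS at 0–6, Essen at 0–9; slopes/intercepts are set so group means sit
mid-range rather than at the clips. Non-stroke samples carry no scores.

**Mouse study.** 5 control-FMT vs 4 T2D-FMT germfree mice, same
community machinery over 25 OTU-level taxa: SCFA producers
(Ruminococcaceae, Lachnospira, Lachnospiraceae) depleted and an S24-7
bucket enriched in the diabetic-donor group. A per-mouse severity
variable — coupling × standardised(S24-7 − SCFA contrast) + noise —
drives infarct ratio (clipped to [0, 1]), mNSS (integer 0–14), serum LBP
and LPS upward and tight-junction expression fold changes (2^slope·severity)
downward; chemokine expression rises. `coupling=0` severs the
microbiota-outcome link entirely, giving the null used for screen
calibration.

**Seeding.** One global seed feeds named substreams
(cohort/scores/tree/mouse/permanova) via `SeedSequence` spawn keys, so
changing one stage's draws cannot shift another's; all outputs are
bit-identical under a fixed seed.

## What the tests do and do not show

The Monte-Carlo suite (100 cohorts at the default 55/90/35/60 sizes,
100–200 mouse studies, 200 null cohorts; sizes chosen to keep the whole
suite in a few minutes) verifies: exact-test p-values against enumeration
oracles; UniFrac/PCoA against independent brute-force computations and
scikit-bio; null calibration of the differential screen, PERMANOVA, and
the correlation screen (all within [0.03, 0.07] at α = 0.05); recovery of
≥ 9/11 planted genera with ≤ 2 false flags in ≥ 80% of seeds; index AUC
and latent-recovery rho; and the qualitative disease patterns (index
ordering, comorbid group farthest from controls, positive score
correlations, SCFA/S24-7 correlation signs). Note that with ~29
unaffected genera screened at raw α = 0.05 the false-flag count is
binomial with mean ≈ 1.45, so "≤ 2 false flags" holds in at most ~84% of
seeds even for a perfectly calibrated test — the observed ~83% is the
statistical ceiling, not a defect.

Passing these tests shows the pipeline is correct and well calibrated
*under the generator's assumptions*. It does not show that real 16S data
satisfy those assumptions: no zero-inflation beyond the DM model, no
taxon covariance, no batch or compositional-sequencing artifacts, no
rarefaction (none is implemented; whether to rarefy before index
computation is left to the user), and genus-level tables of 40 taxa
rather than OTU tables of thousands.

## Known limitations

* Exact tests are capped (pooled ≤ 20 for the rank-sum, n ≤ 9 for
  Spearman) — beyond that, asymptotics only.
* Unweighted UniFrac group contrasts depend on taxa near the detection
  boundary; deeply sequenced tables with no rare taxa will show little.
* The screen's raw-p significance is per-pair; with hundreds of pairs the
  expected false-positive count is substantial (Bonferroni is available
  but off by default).
* PCoA axes for negative eigenvalues are zeroed, so reconstructed
  distances understate strongly non-Euclidean inputs.
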