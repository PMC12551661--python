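# Methods

This note documents the models, conventions and numerical choices behind
`streamfd`, in the spirit of the methods documentation of the R packages
(`FD`, `mFD`, `adiv`, `picante`) whose metric definitions it follows.

## Data model

The unit of inference is the **WWTP site pair**: one community sampled
upstream and one downstream of a treatment plant's outfall. Communities
are count vectors over a regional taxon pool; taxa carry fuzzy-coded
affinities to the modalities of nine biological trait groups (49
modalities in total by default). Pair covariates describe the plant: size
class (1–5), connected households, human population equivalents, and
effluent concentrations of BOD, NH₄⁺ and total phosphorus, which increase
as size class decreases.

Intermediate sites that serve simultaneously as the downstream member of
one pair and the upstream member of the next are allowed (the generator
can produce them with `share_intermediate=True`); pair statistics treat
pairs as independent units and do not adjust for the shared site — a
documented limitation of the design, not of the implementation.

## Trait preparation

Fuzzy scores within each trait group are normalized to relative
frequencies (group sum = 1 per taxon). Groups with all-zero scores carry
no information: they are flagged missing, never silently imputed.

**Gap-filling.** A taxon counts as coded when every trait group has a
positive score sum. Uncoded taxa are raised to the nearest parent — genus,
then family — that has at least one coded descendant in the pool (the
threshold is configurable; the literature reports coverage shares but no
explicit sufficiency rule, so ≥ 1 coded descendant per group is this
package's declared convention). The raised profile is the **unweighted**
mean of the coded descendants' normalized profiles, renormalized per
group; unweighted (rather than abundance-weighted) aggregation matches the
standard trait-aggregation proxy for expert allocation. Community taxa
raised to the same parent are merged and their abundances summed, which
conserves total abundance and is order-independent. Taxa unresolvable even
at family level are reported as dropped with a warning.

Each taxon carries one trait profile; stage-specific coding (e.g.
Coleoptera adults vs larvae) is a data-preparation convention upstream of
this package.

## Functional space

**Gower distance.** For trait group *g*,
`d_g(i,j) = ½ Σ_k |p_ik − p_jk|` (half the Manhattan distance between
relative-frequency profiles, so each group contributes in [0, 1]); the
overall distance is the unweighted mean over groups — all nine groups are
weighted equally, as no weights are given in the source methodology.

**Embedding.** Classical PCoA (double-centering + eigendecomposition, via
scikit-bio). The block-Manhattan Gower matrix is generally non-Euclidean,
so a correction is applied first: the default is the square-root
transform, which makes this family of distances Euclidean-embeddable (L1
distances are of negative type); the Cailliez additive constant is
available as an option. The choice affects convex-hull volumes and is
therefore a logged configuration key (`correction`). Only axes with
positive eigenvalues are kept; variance explained is relative to the sum
of positive eigenvalues. Full-dimensional Euclidean distances among the
retained axes reproduce the corrected distance matrix to ~1e-15, which the
test suite asserts.

**Dimensionality (mSD).** For each candidate *m*, Euclidean distances in
the first *m* axes and the original Gower distances are each rescaled to
[0, 1] by their maxima and the quality is the mean squared deviation over
taxon pairs. The scaling convention ("standardised distance") is not fully
specified in the source; max-scaling is this package's declared choice and
yields empirically non-increasing mSD in *m*. The retained dimensionality
minimizes mSD subject to a cap: 3 axes for hull-based alpha metrics and
for the beta space on the full dataset, 8 for the EPT-subset alpha space
(matching the study design these defaults mirror).

**Trait-combination density.** A Gaussian KDE (Scott's rule, 128×128
grid, optionally abundance-weighted) on the first two axes is provided as
a diagnostic surface only; nothing downstream consumes it.

## Alpha metrics

With relative abundances `p`, coordinates `x`, and Gower distances `d`:

* `CWM_k = Σ_i p_i t_ik`; group sums are preserved at 1 exactly.
* **FRic**: convex-hull volume (Qhull) in the first *m* axes, divided by
  the pool hull volume when standardization is on (the default, and
  logged: the R tooling this mirrors standardizes by default, though the
  source is silent). Undefined — NaN, never 0 — when S ≤ m or the point
  set is degenerate.
* **FEve**: minimum spanning tree over full-space distances (a dense
  Prim's algorithm; ties broken by lexicographic taxon order), branch
  weights `EW_l = d_ij/(p_i+p_j)`, and the usual min-against-1/(S−1)
  formula. Undefined for S < 3.
* **FDis**: `Σ p_i ‖x_i − c‖` with `c = Σ p_i x_i`, full space.
* **Rao's Q** on the *raw* Gower matrix (not the embedded space),
  Simpson `D = 1 − Σ p_i²`, and redundancy `FR = Q/D`. The cited
  literature mixes conventions (some call `1 − Q/D` redundancy); this
  package implements `FR = Q/D` literally, with
  `redundancy_complement=True` reporting `1 − Q/D` (SES sign flips,
  p-values unchanged). FR is undefined for monocultures.

Undefined metrics propagate as NaN and are excluded pairwise from tests,
with exclusion counts reported.

## Beta diversity

The beta space uses the first 3 axes (configurable). Per pair, the two
communities' convex hulls are intersected exactly: the joint half-space
system of both hulls is handed to Qhull's halfspace-intersection mode
around an interior point (found from hull vertices contained in the other
hull, or by a Chebyshev-center linear program when no vertex qualifies);
the intersection volume is the hull volume of the resulting polytope.
Numerically infeasible cases fall back to Monte-Carlo rejection sampling
and are flagged. With `B = V_a − V_shared`, `C = V_b − V_shared`:

    beta_total = (B + C)/(V_shared + B + C)
    beta_turn  = 2·min(B,C)/(V_shared + 2·min(B,C))
    beta_nest  = beta_total − beta_turn

Jaccard family by default (Sørensen available); the source names the
decomposition but not the family, so the default follows the cited
framework's own default. Pairs where either community cannot span a
3-dimensional hull are reported undefined rather than padded.

## Null models and SES

Observed metrics are compared against trait-shuffling nulls: a permutation
of the *full pool's* taxon labels applied to the trait matrix, leaving
community membership and abundances untouched. Permutations are drawn
independently per randomization (with pool ≫ community sizes, collisions
are negligible); the same R shuffled tables are reused across all metrics
and units within a run, which reduces variance and keeps metrics
comparable. Because a shuffle is a pure relabelling, null metrics are
computed by permuting community indices through precomputed distance and
coordinate matrices — this is what makes R = 999 runs tractable.

`SES = (obs − mean_null)/sd_null`; the two-tailed Monte-Carlo p-value uses
the add-one rank convention `p = 2·min(#{null ≥ obs}+1, #{null ≤ obs}+1)/(R+1)`,
capped at 1, so p is never exactly zero (the exact two-tailed rule is not
printed in the source; the rank convention is this package's declared
choice). Degenerate nulls (sd = 0) leave SES undefined and are excluded
from significance counts, with counts logged.

## Paired statistics

ΔCWM is **upstream − downstream** (the textual definition; a sign flip
for plotting parity is a presentation choice, not a config of the math).
One-sample Wilcoxon signed-rank tests per modality use Pratt zero
handling with the exact distribution for n ≤ 25 and the normal
approximation with continuity correction above; all-zero samples return
p = 1 by convention. The 49 modality tests are reported **uncorrected**
(mirroring per-modality p < 0.05 reporting conventions); a
Benjamini–Hochberg option exists but is off by default and labelled.
Paired Wilcoxon tests compare upstream vs downstream metric values and
SES values side by side (the source is ambiguous about which was used,
so both are computed). Spearman correlations relate beta SES to
covariates; BOD/NH₄⁺/total P are natural-log transformed (zeros offset by
half the minimum positive value) — immaterial to the rank statistic, but
it keeps reported scales conventional.

**EPT subset.** Pairs whose upstream community has ≥ 50 % EPT individuals
(inclusive threshold) are re-analysed from scratch: functional space
reconstruction, dimension re-selection (alpha cap 8), metrics, nulls and
paired tests. The test suite asserts that this genuinely rebuilds the
space (subset FRic differs from merely filtering full-run values).

## Synthetic data

The generator emulates the statistical structure of a state biomonitoring
paired design; defaults are the study-scale conditions: 169 pairs (338
communities), a 444-taxon pool, nine groups / 49 modalities (sizes
8,7,7,4,5,6,3,4,5), and an EPT-dominance gradient. Where the emulated
study reports no value, the defaults are conventions a field ecologist
would call realistic, chosen once:

* **Trait profiles**: symmetric Dirichlet (concentration 0.35) per group,
  discretized to the 0–3 integer scale typical of fuzzy coding, then
  renormalized. The small concentration yields the peaky profiles real
  fuzzy-coded databases show.
* **Richness** 15–50 taxa per community, **abundance profiles** from a
  symmetric Dirichlet (0.3, strongly dominated), **sample sizes**
  log-uniform 200–2000 individuals — typical of WFD multi-habitat kick
  samples.
* **Taxonomy**: ~1–3 species per genus, 1–3 genera per family; 15 % of
  taxa are left uncoded to exercise gap-filling (the first member of each
  family stays coded so everything remains resolvable).
* **EPT**: 35 % of the pool is flagged; a per-pair mixing weight from
  Beta(1.1, 3.0) biases membership sampling, so a minority of pairs ends
  up EPT-dominated (≥ 50 % upstream individuals).
* **Covariates**: size classes drawn with study-scale frequencies;
  households/population equivalents and effluent concentrations are
  log-normal around per-class means that decrease (concentrations) with
  increasing size class.
* **Effect construct**: downstream expected abundances of taxa with
  affinity ≥ 0.5 for a chosen modality are multiplied by
  `effect_strength` (1 = none, 0 = extirpation) before resampling the
  downstream community from the upstream relative abundances — coupling
  pair members as the paired design assumes. The ground-truth record
  includes the penalized taxa and the analytic expected ΔCWM per pair.

What the generator does **not** emulate: real species identities,
hydrology or chemistry, spatial autocorrelation, seasonal effects, or
downstream immigration (downstream membership is a subset of upstream, so
synthetic beta diversity is nestedness-dominated). Passing tests therefore
demonstrate correctness of the computations and calibration of the
inference under the stated sampling model, not ecological realism of any
particular effect size.

## Problem sizes and determinism

The test suite and the acceptance script run the full design (169 pairs)
with R = 99 randomizations and the calibration study (200 communities)
with R = 199 — scaled-down ensembles of the same construction as the
R = 999 default, chosen to keep a complete run in the minutes range on one
CPU. All randomness flows from explicit seeds through
`numpy.random.Generator`; permutations are drawn once per run and chunked
deterministically across workers, so results are byte-identical across
repeats and worker counts.

## Known limitations

* Exact hull intersection relies on Qhull; near-degenerate pairs fall
  back to a flagged Monte-Carlo estimate.
* The mSD scaling convention and the Jaccard default are declared choices
  where the emulated methodology is silent; both are config keys.
* No multiple-testing correction across modalities by default (mirrors
  reporting practice; BH available).
* Dual-role intermediate sites introduce dependence between adjacent
  pairs that the Wilcoxon tests ignore.
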