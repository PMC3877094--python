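# Methods

## Problem setting

Type I interferon drives a coordinated transcriptional programme in blood
cells. In systemic lupus erythematosus (SLE) the programme is chronically
active and pathologically amplified; after a live viral vaccine it is
acute and self-limited. Given probe-level microarray data from sorted
cell populations in three groups — healthy baseline, day-7 vaccinated,
and disease — the pipeline derives cell-type-specific IFN signatures,
splits them by condition specificity, and uses them to classify
independent samples. All stages operate on probe-sets (groups of
perfect-match/mismatch probe pairs measuring one transcript).

## Probe-level model (mas5_lite)

The detection and change calls emulate the GCOS/MAS5 semantics the
downstream filter assumes, not the full MAS5 algorithm:

* **Detection**: discrimination scores `R_i = (PM_i − MM_i)/(PM_i + MM_i)`
  (0 when `PM+MM = 0`) are tested one-sided against τ by Wilcoxon signed
  rank; Present if p < α₁, Marginal if p < α₂, else Absent.
* **Signal**: one-step Tukey-biweight location of
  `log2(max(PM_i − MM_i, floor))`; the biweight uses `c·MAD + ε` scaling,
  so a constant probe-set returns its value exactly and a lone outlier is
  excluded entirely.
* **Change**: per-probe log2 differences between an experiment and a
  baseline array feed the same signed-rank test in both directions; the
  Increase/Marginal/NoChange/Marginal-Decrease/Decrease call uses
  γ₁ < γ₂, and the SLR is the biweight of the differences.

Defaults are the published GCOS values (τ = 0.015, α₁ = 0.04, α₂ = 0.06,
γ₁ = 0.0025, γ₂ = 0.003, floor = 1, c = 5, ε = 1e-4), all configurable;
which parameter set the original analysis used is not recorded, so these
are flagged as assumptions. Note that γ₁ = 0.0025 presupposes about 11
probe pairs: with n pairs the smallest attainable one-sided exact p is
2⁻ⁿ, so probe-sets with fewer than 10 pairs can never produce an I/D
call at the default thresholds.

Numerical conventions: zero differences are dropped and tied absolute
differences receive mid-ranks; the null distribution of the rank sum is
built exactly by convolution for ≤ 15 non-zero differences (cached per
rank multiset) and by a continuity-corrected normal approximation with
tie-corrected variance above. The decrease-side p is computed as its own
tail, `P(W⁺ ≤ W_obs)`, rather than `1 − p_increase`: on a discrete null
the two differ by the point mass at the observed statistic, and only the
former makes swapping experiment and baseline an exact involution
(SLR negates; I↔D, MI↔MD). A vectorised batch path reproduces the
per-call functions bit for bit (asserted in the tests) and carries the
cohort-scale runs.

## Differential filter (diff_filter)

Every array of the experiment group is compared against every array of
the baseline group; with 4 vs 4 arrays each probe-set accumulates 16
change calls and SLRs. Per probe-set the filter records the fraction of
arrays called Present per group, the fraction of pairs called
increased/decreased, the mean log2 FC, and a two-sided one-sample t-test
of the SLRs against zero with df = n_pairs − 1. The pairs share arrays
and are not independent; treating them as exchangeable replicates is
inherited from the source method by design. Degenerate cases: fewer than
two pairs → p = 1 with a warning flag; zero spread → p = 1 if the mean
is 0, else 0.

The **present gate** requires the larger group-mean signal to reach a
log2 threshold (default 3.0 — the original numeric value is unpublished,
so no fidelity is claimed) and at least one Present call in the union of
both groups (configurable to require each group). The Bonferroni factor
m is the number of gate-passing probe-sets — the universe actually
tested.

Selection OR-combines four query families: homogeneous
increase/decrease (call fraction ≥ 0.30 AND Bonferroni-corrected
p ≤ 0.05 AND a strictly matching mean-FC sign) and heterogeneous
increase/decrease (call fraction > 0.50, no p requirement). The strict
sign makes the homogeneous labels mutually exclusive; at the standard
> 0.5 threshold the heterogeneous pair is exclusive because the
fractions sum to ≤ 1. If a permissive custom threshold lets both
heterogeneous queries fire, the larger fraction wins and an exact tie is
reported not significant — the only labelling that is exactly symmetric
under a group swap. The original analysis used sixteen query groups of
which only these four families are documented; additional groups can be
expressed as AND-clauses over the summary fields (`QueryClause`).

Output rows are ordered by |mean log2 FC| descending with ties broken by
probe-set id, so repeated runs are byte-identical.

## Reference list and partition (reference_signature, signature_partition)

The IFN reference is the union of two published gene lists (2220
literature-compiled genes plus 222 genes induced in IFN-α-stimulated
monocytes; treated as disjoint, since their published union is 2442).
Genes are matched by upper-cased symbol with no alias resolution. An
annotation table maps probe-sets to genes per platform; one gene may own
several probe-sets.

For each condition the significant set is intersected with the
reference's probe-sets (the share is printed to one decimal), then a
signed linear fold-change cutoff is applied: FC = 2^x for x ≥ 0 and
−2^(−x) below, boundary inclusive, so |FC| ≥ 2 keeps two-fold changes in
either direction.

The partition takes overlap membership against the *full* significant
list of the other condition — a probe-set is condition-specific only if
the other condition shows no differential expression for it at all —
while the common set is counted under each condition's own FC cutoff
(`common_x`, `common_y`). A gene whose probe-sets fall into more than
one class has its specific-class probe-sets reassigned to common.
Probe-sets without annotation count as singleton genes. Fold-change
dominance within the common set compares absolute FCs (the documented
examples are all up-regulated; the comparison convention is a package
choice). Dominance percentages print to the nearest integer, matching
the format they are reported in.

## Classification (classify)

Samples are clustered by agglomerative average linkage (complete linkage
available) on the correlation distance 1 − Pearson r, and scored by the
k = 2 cut: the branch holding the strict majority of labelled controls
is the control branch; cases are correct outside it, controls inside. A
tied control split, or a matrix whose signature rows are all constant,
is reported indeterminate with zero correct.

Per-gene preprocessing is configurable (`none`, `center`, `zscore`) and
defaults to **none**: the samples are correlated on their log2 signals
as-is. The shared baseline expression pattern then anchors every
pairwise correlation, and group separation comes from the coherent
signature shift in the responding samples. Median-centering was
considered and rejected as the default because it ties the control
group's coherence to the case/control balance: the gene-wise median sits
between the groups only when they are of similar size, and once it falls
inside the control cloud the controls lose all shared structure and the
top split becomes arbitrary. `zscore` additionally makes the distance
invariant to per-gene affine transforms (a property the tests assert)
but flattens effect-size heterogeneity; it is appropriate when arrays
come from different scales.

The agglomeration is implemented in-package so that exact distance ties
break on sample labels (lexicographically smallest member pair), making
the dendrogram invariant under column permutations even with duplicate
samples; scipy's linkage serves as an independent cross-check on
tie-free instances in the tests. Merge heights are non-decreasing
(average and complete linkage are reducible), and the tree serialises to
Newick with branch lengths from height differences.

Cross-platform application intersects the signature with the target
platform's probe-sets before classifying; an empty intersection is an
error.

## Synthetic cohorts (synthetic_data)

The generator emulates the statistical structure of the three-group
sorted-cell design at the probe level. Per gene: a baseline log2 level
~ N(7, 1.5); per probe-set: probe affinities ~ N(0, 0.5) fixed across
arrays (they cancel in pairwise comparisons); per array: measurement
noise drawn independently per probe at sd 0.4 plus a residual per-probe
jitter at sd 0.15; MM = 0.3·PM with log2 jitter of sd 0.2. Gene classes
and effects (log2 scale, injected before the noise so SLR estimates are
unbiased for the configured fold changes):

| class | count | day-7 effect | disease effect |
|---|---|---|---|
| common IFN | 150 | N(3.0, 0.7) | 1.4 × the day-7 effect |
| disease-specific | 100 | 0 | N(2.5, 0.7) |
| immunisation-specific | 10 | N(2.5, 0.7) | 0 |
| non-IFN differential | 100 | 0 | N(2.5, 0.7) |
| null | 600 | 0 | 0 |
| absent | 40 | — | — |

The disease amplification factor 1.4 reproduces the qualitative finding
that virus-induced transcripts recur in disease with larger fold
changes. The immunisation-specific and non-IFN effect sizes are package
choices (no published values exist): they are set equal to the
disease-specific scale so that no class is trivially easier to detect.
Absent genes sit at a log2 level of 2 with MM tracking PM, so they
draw Absent calls. Ten per cent of genes own two probe-sets
(exercising the reassignment rule), and the reference list adds 10%
decoy genes from the null class so the intersection step can fail
meaningfully. One integer seed reproduces a cohort bit for bit;
per-sample RNG streams let `make_nonresponder` regenerate a single
sample with its effects zeroed while every noise draw stays identical.

**What the noise model omits.** All between-array variation is
measurement noise, independent per probe. Real cohorts add between-donor
biological variance that shifts whole probe-sets coherently; under such
noise the per-pair change calls fire on null genes far above the nominal
rate and the heterogeneous (call-fraction-only) query admits them, so
real false-positive counts exceed what the Bonferroni-bounded behaviour
seen here suggests. Passing recovery tests therefore demonstrate the
pipeline's correctness under its stated conditions, not its
false-positive rate on real arrays. Optical noise, saturation and batch
effects are likewise out of scope.

PBMC mixtures combine cell-type profiles linearly on the natural scale
(transcripts add), with per-sample compositions drawn from a Dirichlet
(mean fractions 0.2/0.5/0.15/0.15 for monocytes/T/B/NK, concentration
30 — matching reported inter-individual spread of major PBMC subsets)
and log-normal noise of sd 0.4. Cell-type profiles share the cohort's
gene structure with cell-type offsets of sd 2.0 log2 (marker-scale
differences between cell types), which gives control samples the
composition-driven covariance real PBMC cohorts show; disease effects
are applied to the monocyte and T-cell profiles. A case sample generated
from unstimulated profiles models a vaccine non-responder.

## Problem sizes and determinism

Default verification runs use 1000-gene cohorts (~1100 probe-sets,
4/4/4 arrays), a 20-seed recovery sweep, 20-sample PBMC cohorts and
10⁴-case oracle comparisons; the full suite and the acceptance script
each complete in well under a minute on one CPU. Every random draw
derives from an explicit seed; CLI runs record config, input digests and
seed in a JSON manifest, and repeated runs are byte-identical (golden
files under `tests/golden`).

## Known limitations

* The MAS5 emulation omits background-zone correction, ideal-mismatch
  substitution and target-intensity scaling; absolute signals are not
  comparable to GCOS output, only the call/SLR semantics are.
* Only the four documented query families ship as defaults; the original
  sixteen-query configuration is not recoverable from the published
  description.
* Gene matching is by symbol; aliases and retired symbols are not
  resolved.
* The t-test treats the |A|×|B| pairwise ratios as replicates; its p
  values are anti-conservative in the same way as the source method's.
* Real-data behaviour of the heterogeneous query is not represented by
  the synthetic noise model (see above).
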