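# Methods

This note documents the models, algorithms and design choices behind
`gyrits`, in the spirit of the methods documentation of mature
phylogenetics packages.

## Motif-anchored annotation

Viviparous gyrodactylid ITS submissions are bracketed by four short
conserved motifs: `ATCATTA` ending the 18S gene, `CAACTC` and
`GTCGGCT` opening and closing the 5.8S gene, and `CCTGACC` opening the
28S gene. Genuine variants observed in the group differ from these by
at most one substitution (e.g. the outgroup's `ATCACTA`, a C/T
transition at motif position 5, or the `CAACTT` variant at the 5.8S
start), so motif search tolerates `max_mismatches = 1` by default.

Search windows: the 18S and 28S motifs are sought within the first and
last 120 nt respectively (GenBank flank lengths vary; the window is
configurable), the 5.8S motifs over the whole sequence. Tie-breaking
among equal-mismatch hits prefers the hit nearest the sequence end the
motif bounds — rightmost for the 18S motif (it terminates the upstream
flank), leftmost otherwise — because the motifs bound the flanks.
Among candidate 5′/3′ 5.8S motif pairs, the pair whose implied 5.8S
length is closest to 157 wins, then fewest total mismatches, then the
leftmost: the invariant 157-bp 5.8S is the strongest prior available.

Coordinates are 1-based inclusive in every report; half-open
arithmetic is internal only. A region is *complete* iff both of its
bounding motifs were located; a missing 18S motif leaves ITS1
incomplete starting at position 1, a missing 28S motif leaves ITS2
incomplete ending at the sequence end. Mismatch class (transition vs
transversion) follows the purine/pyrimidine table. IUPAC codes inside
a motif count as a match-with-note when the code covers the canonical
base, as a mismatch otherwise — a deliberately conservative reading.

QC disposition policy: any missing motif ⇒ `review`; any variant or
5.8S-length flag ⇒ `pass_with_warnings`; otherwise `pass`. This
mirrors field practice of retaining flagged-but-usable submissions
with caveats. Longer published 28S variants (`CCTGACCTT`,
`CCTGACTTC`, `CCTGACTCA`, `CCCGACCTC`) resolve as `CCTGACC` matches
with ≤ 1 mismatch; the observed 9-mer is recorded in the
`nonstandard_28S_motif` flag.

The diagnosis string renders each region's completeness, first and
last heptamers and length, with the total as the arithmetic sum of the
parts. Where a published total disagrees with the sum of its published
parts, `verify_reported_total` logs the discrepancy and the sum is
reported — the package never echoes a printed total it cannot
reproduce.

## Substitution models and distances

Models are the reversible GTR family restricted to TVM (+F), SYM, GTR
and JC, with generator `q_ij = s_ij π_j` normalized to unit expected
rate at stationarity, so branch lengths are expected substitutions per
site. Transition probabilities come from the symmetric
eigendecomposition of `D^{1/2} Q D^{-1/2}` (D = diag π), which is
exact for reversible generators and cheaper and better-conditioned
than a general matrix exponential.

Rate heterogeneity is discrete gamma with C equal-probability
categories (default 4). Category rates are the **conditional means**
of the Gamma(α, α) density over its quantile slices, computed from the
regularized incomplete gamma function; means (not medians) are used so
the simulator, the likelihood and the quadrature oracle share one
discretization, and the mean rate is exactly 1.

The pairwise ML distance maximizes the partitioned two-sequence
log-likelihood with a single shared branch length `t` across
partitions (no per-partition rate multipliers — one "likelihood
distance" is reported per pair), using bounded scalar optimization on
[1e−6, 10] with tolerance 1e−8. Pairs whose optimum sits at the upper
bound are flagged as saturated rather than silently truncated. Sites
with a gap or ambiguity in either sequence are excluded per partition
(pairwise deletion), the policy that preserves the most signal in
ragged ITS alignments; complete-set deletion is available.

Model parameters for distance matrices are estimated once per
partition from the whole alignment and then fixed for all pairs, as
distance-matrix practice in tree software does. `estimate_model_params`
maximizes the composite (sum-of-pairs) likelihood, profiling the
branch length per pair: coordinate-wise sweeps on the log scale from
all-exchangeabilities-1, α = 1, followed by a deterministic
Nelder–Mead polish, because coordinate descent alone crawls along the
ridge coupling the exchangeability scale to the gamma shape.
Empirical (+F) frequencies are observed column proportions. Degenerate
partitions (fewer than two distinct rows) fall back to JC defaults
with a warning. **Caveat:** the gamma shape is weakly identified from
pairwise comparisons; its composite estimate has large sampling
variance at realistic alignment lengths (empirically, sd ≈ 0.17 around
a true α = 0.8 with 20 kb on six sequences). The recovery test
therefore uses a long (100 kb) alignment where the check is sharp;
users fitting α from short ITS alignments should treat the estimate as
indicative.

Group distance summaries average all unordered within-group pairs
(intra) and all cross pairs (inter); reports round to 2 decimals while
tests and internal consumers use full precision.

## Monophyly and delimitation

Trees are consumed, never inferred. Monophyly is unrooted bipartition
membership: a group is monophyletic iff some edge splits the tips
exactly into the group versus the rest; with a designated outgroup the
group must lie on the ingroup side. Polytomies require an
exactly-matching bipartition (no "compatible" credit by default).
Support labels accept compound `bp/pp` values (e.g. `99/1.0`) or bare
numbers disambiguated by magnitude; "well supported" means the
defining edge meets every support threshold present (defaults bp ≥ 75,
pp ≥ 0.95, the usual display cutoffs), ignoring absent support types.

Species delimitation is single-linkage clustering of a p-distance
matrix at a threshold, default 0.013 (the 1.3 % species-level
divergence conventional for gyrodactylid ITS). Distances ≤ threshold
keep sequences together; a pair just above it (0.014) splits —
matching the reading of such pairs as distinct, closely related
species. Clusters are connected components of the threshold graph
(union-find), labelled by their lexicographically smallest member for
determinism. A unit guard rejects ML-scale matrices unless explicitly
overridden, since the threshold is calibrated on the proportion scale.

## Synthetic data: what it emulates, and what it does not

`make_reference_its` builds pre-excision records —
`[18S tail|ATCATTA][ITS1][157-bp 5.8S][ITS2][CCTGACC|28S tail]` — with
i.i.d. background from a configurable base-frequency vector (uniform
by default: no empirical composition is established for this group, so
neutrality is the honest default). Background windows within one
substitution of any canonical motif are resampled, and the assembled
record is re-scanned (junction windows included), so a clean record
contains exactly the four intended motif signals; `apply_mutations`
re-scrubs after editing because a destroyed motif can otherwise
re-match one position over by chance. This makes truth recovery exact
rather than merely probable.

`apply_mutations` injects transitions/transversions at stated motif
positions, indels in the region interior adjacent to a motif (so
5.8S-length deviations arise without destroying the anchors), and
5′/3′ truncations that remove a motif plus k interior bases, emulating
submissions clipped before deposit. It returns the exact flag set and
region lengths the annotator must produce, including the
`None`-lengths of regions made undeterminable by a destroyed 5.8S
anchor.

`simulate_pair` and `simulate_alignment_on_tree` evolve i.i.d. sites
under the package's own models: ancestral states from π, per-site
rates drawn from the discrete-gamma categories (fixed across the tree
— rates are site properties), descendants via `exp(Q·t·r)`. The
simulations are substitution-only: no indels, no alignment error, no
rate drift across lineages. Consequently, passing tests demonstrate
the correctness of the estimators under their own model assumptions —
not robustness to the alignment ambiguity real ITS1 data exhibit,
which is why published distance summaries that depend on an external
aligner are treated as loose references rather than reproduction
targets.

All randomness flows through explicit integer seeds; identical seeds
give identical outputs, including across the CLI and pipeline.

## Numerical choices and degenerate inputs

* Optimizer: SciPy bounded scalar minimization, `xatol = 1e-8` for
  distances; identical-sequence pairs report the 1e−6 lower bound.
* Zero comparable sites (all gaps/ambiguity) is an explicit error,
  never a zero distance.
* Empty batches, empty sequences and sequences under 50 nt are
  rejected; per-record annotation failures inside a batch become
  `review` rows without aborting the batch.
* Distance matrices validate symmetry, zero diagonal and
  non-negativity on construction.
* Chapman–Kolmogorov, stationarity and detailed-balance residuals sit
  at machine precision (≤ 1e−15); gamma category means reproduce
  quadrature to 1e−8 and average to 1 within 1e−10.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data at sizes chosen to keep checks sharp yet quick: 40–50 kb pairs
for closed-form equivalence, 50 replicates of 10 kb pairs per true
distance for recovery (mean |bias| < 5 %, observed < 1 %), 200 mutated
records for the QC round trip, 100 random 8-tip trees × 154 subsets
for monophyly, and 100 random matrices for delimitation.

## Known limitations

* Pairwise "likelihood distances" published from tree software may
  include per-partition rate multipliers; the single-`t` convention
  here can differ from such values by a scale factor.
* The MEGA-style deletion policy behind published p-distance tables is
  often unstated; the default here is pairwise deletion.
* Gamma-shape estimates from pairwise composites are imprecise (see
  above).
* No chimera detection, vector screening or secondary-structure
  boundary refinement; alignment is external by design.
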