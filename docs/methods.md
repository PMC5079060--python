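# Methods

This note documents the models, conventions and parameter choices behind
`metahandoff`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Completeness estimation

A genome bin's completeness is the fraction of a universal single-copy gene
(SCG) set detected at least once above the per-model bitscore cutoff.
Defaults ship as editable YAML (`src/metahandoff/data/scg_*.yaml`): 43
bacterial markers (ribosomal proteins plus infC, secY, ffh — a reduced set
of the kind that stays informative for small-genome lineages such as the
Candidate Phyla Radiation, which lack many classical markers) and 38
archaeal markers. The lists are configuration, not code: projects with
their own curated sets substitute them without touching the package.
Markers found in two or more distinct genes go into the `multi` set; the
dereplication score is `|found| − 2·|multi|`, so contamination is penalized
twice as hard as incompleteness rewards.

Under random independent gene loss at retention c, |found| is
Binomial(|S|, c)/|S|, an unbiased estimator of c with standard error
√(c(1−c)/43) ≈ 0.039 at c = 0.93. The suite verifies bias < 0.02 at
n = 500 genomes. The inclusion filter keeps bins with completeness
*strictly* greater than 0.70 (reading "> 70%" literally); it is applied
once, to the profile computed from the supplied hits — re-estimation after
manual curation is out of scope.

Copy counting uses distinct gene identifiers per marker, so two passing
hits of the same gene against one model count once.

## Dereplication

* **Similarity** from alignment blocks: per ordered pair, the sum of
  aligned lengths over blocks with identity ≥ 0.98 (a per-block filter, not
  a genome-wide average), divided by the query genome length, capped at 1.
  Both directions are reported because the field's conventions differ on
  which genome's length is the denominator; the grouping test uses the
  maximum of the two, which lets a fragment join its parent.
* **k-mer proxy**: when no aligner output is available, containment of
  canonical 21-mers substitutes for aligned fraction. For a strain at
  per-base substitution rate d (substitutions uniform over sites and bases,
  no indels) the expected containment is (1−d)^21 — 0.90 at d = 0.005,
  0.81 at d = 0.01 — comfortably above the 0.50 grouping threshold for
  strain-level divergence and ~0 for unrelated sequence. k < 11 is rejected
  (spurious matches), k > 31 too (2-bit packing into 64-bit words).
* **Grouping**: single-linkage connected components over pairs with
  similarity strictly > 0.50. Single linkage matches the notion of
  *grouping* (a chain of strains is one organism), at the known cost that
  one intermediate genome can bridge two groups.
* **Representative**: argmax score, then greatest total length, then
  lexicographically smallest genome id — the last tie-break is arbitrary
  but makes runs deterministic.

## Trait calling

Hits pass when their full-sequence bitscore is ≥ the model's cutoff —
"above the cutoff" read inclusively, the convention for curated noise
cutoffs, and the full-sequence rather than best-domain score because it is
the conventional gathering-threshold analogue. Rules combine markers as
`any_of` (list of alternative marker sets; alternative enzyme systems or
hydrogenase/Rubisco groups, each group a distinct marker), `all_of`
(multi-subunit complexes) and `none_of` (conditional chemistry: the sox
system yields elemental sulfur only when soxCD are lacking). The shipped
rule file covers the C/N/S/H cycle transformations used by the handoff
chains and is explicitly a default approximation — any study's exact
marker/cutoff tables override it via YAML. Without `none_of`, trait calls
are monotone in hits; with it they are deliberately not.

For a trait detectable through m alternative single-marker routes in a
genome at completeness c, the detection probability is 1−(1−c)^m; observed
prevalences on incomplete genomes are accordingly biased low by a factor
≈ c for single-marker traits. Tests verify this dropout law at c = 0.8.

## Abundance

Genome coverage is the length-weighted mean of per-scaffold mean depths
(scaffolds missing from a sample count as zero depth with their full length
weight). Cross-sample normalization multiplies by
reads(reference)/reads(sample); relative abundance divides by the
within-sample sum over binned genomes, with an optional denominator
inflation factor ≥ 1 so a marker-gene-derived estimate of the *total*
community (binned + unbinned) can be supplied by the caller. Rank-abundance
lists exclude genomes above a coverage cap (default 500×) and keep stable
order on ties.

## Handoff analysis

Chains are configuration (YAML): 3-step sulfur oxidation and 4-step
denitrification ship as defaults, each step carrying the trait id, the
marker count m used by the null, and an optional ΔG° covariate. The ΔG°
defaults are textbook-order standard free energies (denitrification steps
written with H₂ as electron donor); they matter only for the rank
correlation and should be replaced by measured values when available.

Organisms at relative abundance strictly > 0.01% are considered. Each
contributes one count to every **maximal contiguous run** of steps it can
perform — an organism able to run steps 1 and 3 but not 2 counts once in
[1,1] and once in [3,3]. This convention is order-preserving and auditable;
alternatives (counting every sub-window, or only the longest run) would
change counts but not the qualitative handoff pattern. The NO₂⁻ → NO step
is flagged `possible_detox` in the chain config since nitrite reduction to
NO can serve detoxification rather than respiration; it still counts toward
windows.

**Incompleteness null.** For each organism apparently lacking a step:
approx p = (1−c)^m; exact p = C(N−m, n)/C(N, n) with n = round(cN) of N
genes recovered (hypergeometric at zero successes, via
`scipy.stats.hypergeom.logpmf`). The joint probability multiplies across
organisms in log10 space (no underflow verified to 10⁵ organisms). The
`conservative` flag floors every c at a configurable value (default 0.70,
the inclusion threshold): assuming every genome is as incomplete as
allowed can only *inflate* the null probability, so a rejection under the
floor is a fortiori valid. c = 1 under the approximation yields
log₁₀p = −∞ with a `degenerate` flag rather than an exception. Exact and
approximate agree within a factor of 2 for N ≥ 1000, m ≤ 3 (verified
numerically); the approximation ignores only the without-replacement
correction of order m²/N.

**Energy-yield correlation.** Spearman rank correlation of per-step
organism counts (or summed abundance) against −ΔG°, with a two-sided
permutation p-value: exhaustive over all step orderings for ≤ 8 steps,
otherwise 10,000 draws from a fixed, recorded seed (default 42). Constant
inputs make ρ undefined; it is reported as 0 with a degenerate flag.

## Novelty

16S pairwise identity over one multiple alignment counts matches over
columns where at least one row has a base: dual-gap columns are ignored,
single-gap columns count as mismatch — penalizing indels without rewarding
missing data; both choices are knobs. A gap-column filter utility drops
columns whose gap fraction exceeds a threshold (0.97 default; 0.95 typical
for 16S). Monophyly is split-based: a taxon set is monophyletic iff some
edge of the tree separates exactly that set from the rest, which makes the
test invariant to leaf order and to rerooting outside the group; topology
only, no bootstrap-support minima. The identity threshold default is 0.75
("~75%" — the tilde means the threshold is approximate; it is configurable).
Verdicts: `novel` iff identity < threshold ∧ monophyletic in both trees ∧
≥ 1 member above the completeness filter; `insufficient_data` when a
required input is missing (no member with a 16S row, or members absent from
a tree) — common in practice because rRNA scaffolds often fail to bin.

## Synthetic communities

The generator emulates the statistical structure the analyses assume:
archetypes with planted chain-step capabilities (per-step Bernoulli, plus a
small per-chain probability of carrying the complete chain) and accessory
traits; strain copies at controlled substitution rates (uniform over sites,
no indels — keeping k-mer analytics closed-form); independent per-gene
dropout at a target completeness, SCGs included; lognormal per-sample
abundances realized as per-scaffold depths with ±5% multiplicative noise;
and hit rows emitted at cutoff + 10 bits for retained markers only.

Deliberate simplifications, hence what passing tests do *not* show about
real data: hits are synthesized rather than produced by an actual profile
search (no borderline scores, no cross-model confusion); non-marker filler
genes are not materialized — `genes_per_genome` is carried as the total
gene count N for the exact null while only marker genes get coordinates and
sequence; gene dropout is independent, whereas real assembly gaps are
spatially correlated; there is no read-level simulation, chimerism or
binning error. The generator validates feasibility (markers must fit on the
scaffolds and not exceed the gene total) and is byte-identical under a
fixed seed.

Preset conditions: `tiny` (5 archetypes, one strain pair — a smoke test);
`rifle-like` (150 archetypes, median completeness 0.93, roughly a third of
organisms with CO/H₂/reduced-sulfur electron-donor traits, <2% sulfate
reducers, 34%/17% oxygen/nitrate respirers, sulfur-chain step frequencies
0.11/0.04/0.08, denitrification 0.17/0.12/0.10/0.08, complete-chain
probabilities 0.008/0.009, 25 strain groups at 0.5% divergence, 4 samples).
The archetype count is scaled to desk size; prevalence checks use binomial
tolerances at n = 150.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data:
n = 500 genomes for completeness recovery, 46 genomes across 12 strain
groups for dereplication recovery, 120/400 genomes for the handoff checks,
1,000 random ≤ 8-leaf trees (8 taxon subsets each) for monophyly, and the
150-archetype community for the survey — sizes chosen so the whole suite
completes in seconds while keeping binomial error well inside the stated
tolerances. All randomness flows from explicit integer seeds; pipeline
runs are reproducible bit-for-bit from (inputs, config, seed), and the
manifest records the config hash.

## Known limitations

* SCG-based completeness saturates at the marker-set resolution (1/43 ≈
  2.3% steps) and is blind to contamination from lineages sharing no
  markers.
* The k-mer containment proxy is not an ANI estimate; it is a grouping
  statistic calibrated only through the (1−d)^k survival law.
* Trait calls are genomic *potential*, not activity; prevalences inherit
  the dropout bias described above.
* The incompleteness null treats marker losses as independent across
  organisms and genes; linked losses (e.g. operonic) would make the true
  null probability larger than the reported one, though the conservative
  floor absorbs much of this.
* Window counting treats steps as equally granular; chains are user
  configuration and the defaults are one reasonable partition of the
  chemistry, not the only one.
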