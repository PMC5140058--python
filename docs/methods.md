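# Methods

This note documents the models implemented by `ibcpipe`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Consensus variant filtering

Call sets from multiple somatic callers are merged on the key
(chromosome, position, ref, alt) after splitting multi-allelic records.
SNVs require support from at least `min_callers` tools (default 2) and a
consensus VAF of at least `min_vaf` (default 0.05, inclusive boundary).
Indels require presence in both of two call sets after left-normalization
(shared-base trimming, then left-shifting against the reference when one
is supplied). Because callers disagree slightly on read depths at the same
site, the consensus VAF and depths are taken from the first supporting
caller in a fixed priority order — alphabetical by caller label unless
overridden — which makes the output independent of input ordering. The
published protocol does not state how per-caller depths are reconciled;
any deterministic rule yields the same retained *set* whenever callers
agree on which side of the 5% boundary a variant falls.

Coordinates are 1-based inclusive (VCF convention); burden masks are
half-open `[start, end)`. Depths are read from `FORMAT/AD`, with a
fallback adapter for tier-count dialects (`AU/CU/GU/TU`); unfiltered
(`.`) records count as PASS.

## Copy-number classes, wGII and whole-genome doubling

Segment classes are defined on the log2 scale relative to sample mean
ploidy ψ: amplification at log₂(CN/ψ) ≥ log₂(4/2) = 1 (inclusive), gain
from log₂(2.5/2) ≈ 0.322 up to the amplification cutoff, loss at or below
log₂(1.5/2) ≈ −0.415, neutral in the open middle band. A zero-copy
segment maps to −∞ (loss). The classification is invariant to jointly
doubling all copy numbers and ψ.

wGII: per autosome, the fraction of covered base-pairs in segments whose
total copy number differs from round(ψ); the score is the unweighted mean
over autosomes with at least one segment, so chromosome size does not
weight the score. "Aberrant" is defined relative to *rounded* ploidy —
the protocol divides by mean ploidy elsewhere, and integer comparison
against rounded ploidy keeps a cleanly doubled genome at wGII 0.
Per-base (not per-segment) weighting within a chromosome was chosen; the
score is then invariant under splitting a segment into identical-copy
sub-segments.

The whole-genome-doubling test reduces a sample to arm-level major/minor
copies (length-weighted modal pair per arm; the packaged hg19-like table
has 39 arms, excluding the acrocentric short arms 13p/14p/15p/21p/22p).
From the profile it derives Nₛ, the number of unit copy steps from
diploid summed over arms and alleles, and Pₛ = (gain steps, loss
steps)/Nₛ, applied uniformly across arms and alleles — per-arm
probabilities would be degenerate with one observation per arm. Each of
`n_simulations` (default 10,000) null draws applies Nₛ sequential steps
to a diploid profile, choosing arm and allele uniformly and direction by
Pₛ; a loss on a zero-copy allele is redrawn. The p-value counts
simulations whose fraction of arms with major copy ≥ 2 *strictly* exceeds
the observed fraction. A sample is called doubled when the observed
fraction is ≥ 0.5 **and** p < α (default 0.05): the bare p-value is
degenerate for near-diploid genomes (a diploid profile has observed
fraction 0 and Nₛ = 0), so the fraction floor is required for a sane
call; Nₛ = 0 short-circuits to p = 1, not doubled.

## Mutational signatures

Spectra are 96-vectors over (pyrimidine-strand substitution × 5′ base ×
3′ base), in fixed substitution-major alphabetical order with `A[C>A]A`
labels. Refitting is greedy forward selection: at each iteration, for
every catalog signature, the scalar weight on [0, 1] minimizing the sum
of squared differences between the (sum-normalized) weighted
reconstruction and the observed fractions is located by golden-section
search (tolerance 1e-4); the best (signature, weight) update is applied,
and iteration stops when the best achievable improvement falls below
`error_tolerance` (default 1e-3). Weights below `weight_floor` (default
0.06) are zeroed and the rest renormalized. Floor and tolerance follow
the established refitting tool's published defaults. No
trinucleotide-abundance renormalization is applied by default; an
abundance vector may be passed to `refit`.

The packaged catalog is **synthetic**: the published 96×27 catalog is not
redistributable here, so `synthetic_catalog()` builds a deterministic
stand-in whose biologically anchored columns carry the canonical
features — 1A sharply and 1B broadly C>T-weighted (1A at NpCpG,
spontaneous-deamination style), 2 and 13 concentrated at TpC as C>T and
C>G respectively (APOBEC style) — plus smooth Dirichlet background
columns from a fixed seed. Results on real data require supplying the
real catalog via `read_catalog`.

## Cancer cell fractions and clonal clustering

With purity ρ, local total copy CNₜ and allele fraction f:
n_mut = f·(ρ·CNₜ + 2(1−ρ))/ρ. Multiplicity m ∈ {1, …, max(1, major)}
maximizes the binomial likelihood of the observed alt count under the
expected VAF implied by (m, CCF clamped to (0, 1]); ties break to the
smallest m; CCF = min(n_mut/m, 1). The (m, CCF) pair is not always
identifiable — (m = 2, CCF = φ) and (m = 1, CCF = 2φ) give identical
expected VAFs when 2φ ≤ 1 — and the tie-break resolves such cases toward
the smaller multiplicity; the round-trip property (exact inversion at
noise-free read counts, tolerance 1e-9) therefore holds whenever
m·CCF > 1 excludes the smaller-m explanation.

Clustering is a Chinese-restaurant-process Gibbs sampler (concentration
α = 1.0) over mutation-to-cluster assignments, with cluster CCFs φ per
sample on a discrete grid of 101 points in [0, 1] — simple, reproducible
and adequate at exome depths — and Binomial(depth, VAF(m, φ)) emissions.
Multiplicities are fixed before clustering rather than resampled, which
decouples the stages. Mutations undetected in one biopsy enter as zero
alt reads at that sample's median depth (absence treated as an observed
zero). Default 5,000 sweeps with 2,500 burn-in; the point clustering is
extracted from the posterior co-assignment matrix by average-linkage
clustering cut at distance 0.5, and cluster CCFs are posterior means on
the grid. Clusters with 3 or fewer SNVs are moved to an excluded list.
With two planted clusters separated by ≥ 0.3 CCF at depth ~400 and ≥ 40
mutations each, recovery is essentially exact (ARI ≥ 0.9); separation
below ~0.15 at that depth merges clusters, and small clusters near a
large one may be absorbed.

Evolution classification per cluster: *new* if pre-CCF <
`presence_threshold` ≤ post-CCF, *lost* for the reverse,
*expanded*/*contracted* at |ΔCCF| ≥ `shift_threshold` (default 0.20),
else *stable*; the patient is *branched* given any new/lost cluster,
*clonal_shift* given only expansions/contractions, else *stable*. The
presence threshold defaults to 0.02: a subclone observed at 2% CCF before
treatment is present, so its later expansion is a shift in clonal
structure, not the birth of a clone. Both thresholds are configurable.

## Synthetic cohort generator

The generator emulates a deep-exome paired-biopsy trial regime: per
patient a rooted clone tree (root CCF 1.0 in both samples, child CCF ≤
parent, sibling CCFs summing ≤ parent) whose subclone dynamics follow the
configured evolution mode — *branched* (≥ 1 subclone lost to 0, ≥ 1 new
subclone appearing at CCF ≥ 0.2), *clonal_shift* (CCFs move ≥ 0.2 with no
appearance/disappearance, emulating expansion of minor subclones such as
2% → 38%), or *stable*. Defaults plant branched evolution in eight of
every nine patients and a clonal shift in the ninth, matching the
qualitative cohort finding that branching dominates. Mutation counts are
Poisson (truncal mean 70, subclone mean 25), positions uniform without
replacement with chromosomes weighted by length, and trinucleotide
contexts sampled from the configured signature mixture (default: age
0.60 split 1A/1B, APOBEC 0.30 split 2/13, 0.10 background), emulating an
age+APOBEC-dominated breast-tumor spectrum. Copy-number profiles are
arm-level: baseline (1,1), or (2,2) when whole-genome doubling is planted
(probability 0.70, the cohort's observed rate), with per-arm unit
aberrations at rate 0.25; truncal SNVs in doubled genomes carry
multiplicity 2 half the time (mutation preceding the doubling). Purity is
uniform on 0.2–0.9 (no per-patient purities are published for the
emulated cohort; the range is an assumption). Read counts are
Binomial(depth, VAF) at Poisson depth (mean 400, the tumor-exome regime).
Four pseudo-callers — two SNV-only, one SNV+indel, one indel-only — apply
independent Bernoulli misses and Poisson-planted false positives per
sample, the simplest error model that makes the ≥ 2-caller consensus rule
non-trivial.

Not emulated: read-level artifacts (mapping error, strand bias,
FFPE/OCT damage), germline variation, sequencing-error substitutions,
correlated caller errors, focal (sub-arm) copy-number events, and
FASTA-consistent variant placement (contexts are sampled, not read from a
reference; the reference-FASTA path is exercised separately with small
test genomes). Passing tests on synthetic cohorts therefore demonstrate
correctness of the algorithms under the generative model, not robustness
to the artifacts real exomes add. The default synthetic genome is 3
chromosomes of 100 Mb with centromeres at 40 Mb, chosen for desk-scale
speed; the packaged hg19-like arm table supports realistic runs.

## Cohort statistics

Fisher's exact test uses the two-sided probability-ordering convention
(sum of hypergeometric probabilities ≤ the observed table's, relative
tolerance 1e-7); conventions differ in the third decimal for some tables,
and the printed cohort values reproduce under this one. Mann-Whitney uses
midrank ties, exact enumeration for tie-free groups of ≤ 20, and the
tie-corrected normal approximation otherwise (delegated to
`scipy.stats.mannwhitneyu`). Case matching is greedy in case order with
nearest-age preference under exact ER/PgR equality and a ±10-year window;
greedy matching is not maximum-cardinality, and the bipartite optimum is
used as an upper-bound oracle in tests. Benjamini-Hochberg q-values are
reported alongside raw p-values on request, never replacing them.

## Pipeline and reproducibility

`run_all` executes simulate → consensus → cna → signatures → clonal →
cohort from one YAML config that surfaces every threshold above; a stage
failure stops the run and names the stage. The manifest records the
config, per-stage timings and SHA-256 digests of all outputs; identical
config and seeds reproduce identical digests. Demo configs use reduced
problem sizes (6 patients, 2,000 doubling simulations, 1,200 sampler
sweeps) as the package's default desk-scale settings; all are
configurable upward.

## Known limitations

- The DP sampler uses a fixed discrete CCF grid; CCF resolution is 0.01
  and posterior uncertainty is summarized only through co-assignment.
- Multiplicity is point-estimated per sample before clustering; phasing
  of mutations to parental alleles is out of scope.
- The genome-doubling call threshold (observed fraction ≥ 0.5, α = 0.05)
  is a package default; the emulated protocol does not publish its own.
- The synthetic signature catalog is a labelled stand-in; per-sample
  exposure percentages are not comparable to published per-sample values
  without the real catalog and variant lists.
- Tree reconstruction beyond the three-way pattern classification, and
  more than two samples per patient, are not supported.
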