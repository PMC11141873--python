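# Methods

## Problem setting

Given a seed gene, a gene × sample read-count matrix, a genome with TSS
annotation and a vocabulary of IUPAC consensus binding sites, the screen
asks: which binding sites are over-represented in the promoters of the
genes whose expression tracks the seed gene? Enrichment of a factor's
site among the seed gene's coexpression partners — together with the
site's presence in the seed gene's own promoter — nominates that factor
as a candidate regulator. The approach assumes that a meaningful
fraction of the correlated set consists of direct targets, that
regulation acts through proximal promoter sequence, and that a consensus
string is an adequate binding model; all three assumptions fail in
well-known ways (indirect correlation, enhancer-driven genes,
degenerate/low-information motifs), which is why the output is a ranked
hypothesis list, not a claim of regulation.

## Expression filtering

A gene counts as detected in a sample when CPM > 0.25 and the lower 95%
confidence bound on its FPKM is positive; genes detected in
⌈0.05 × n_samples⌉ or more samples are kept (with 99 samples: at least
5). The FPKM bound is the exact (Garwood) Poisson interval on the raw
count, chi-square form χ²(α/2, 2k)/2, rescaled by gene length and
library size. This construction makes the bound exactly zero for a zero
count and strictly positive for any positive count, so it operates as a
principled "nonzero evidence" test rather than a plug-in estimate.
Library size is the raw column sum; no between-sample scaling factors
are applied, because the downstream statistic (Spearman) is rank-based
per gene and invariant to monotone per-sample scaling only when that
scaling is shared across genes — raw CPM keeps the pipeline simple and
the filter interpretable.

The correlation screen runs on log2-CPM with the half-count offset,
log2((k + 0.5)/(N + 1) × 10⁶). Precision weights (the full voom
procedure) are deliberately omitted: Spearman correlation ignores
weights, so only the monotone transform matters.

## Correlation screen

Spearman's ρ is computed as Pearson correlation of average ranks
(vectorised over all genes against the seed), with a two-sided
t-approximation p-value (exact permutation is available for n < 10).
The seed gene is excluded from its own BH family. The correlated set is
cut by a conjunctive, always-recorded policy — default sign = positive
(ρ > 0), ρ ≥ 0.5, FDR ≤ 0.05; `top_n` is available when a fixed-size
set is wanted. Ties in ρ order lexicographically by gene id so output
is deterministic.

## Promoter windows and scanning

Coordinates are 1-based inclusive. An (upstream u, downstream d) window
of a plus-strand TSS t is [t − u, t + d]; minus-strand windows are the
mirror image, and extracted sequence is reverse-complemented so
position 1 is always the most-distal upstream base. This convention
reproduces the reference worked example exactly: u = 10000, d = 1000 at
t = 88638571 (+) gives [88628571, 88639571]. Windows are clipped (and
flagged) at contig bounds rather than erroring, so genome-scale runs
survive telomeric genes.

Scanning slides every consensus length over the sequence and tests the
forward window against each consensus string and each string's reverse
complement (a minus-strand site). Occurrences are collapsed per
(start, length) across orientations and variants: the E-box pair
CAGGTG/CACCTG — two spellings of one physical element — therefore counts
once per site. Overlapping occurrences at different starts all count
(no masking); masking was considered and rejected as an extra
nondeterministic-looking knob, and the enrichment model uses
log(1 + count) precisely to bound the influence of repeat-dense
promoters. An N in the sequence never satisfies a non-N consensus code,
so assembly gaps cannot create hits. The scanner is vectorised
(bitmask-encoded bases, sliding windows) and is verified exactly
against a naive enumerator in the test suite.

## Enrichment model

For each motif surviving the seed-window site filter, membership in the
correlated set is modelled over all promoter-bearing genes (the seed
itself excluded) as

    logit P(member) = β₀ + β₁·f(count) + s(GC) + s(log length)

with f = log1p by default (raw count and presence selectable) and
penalized cubic B-spline smooths (basis dimension 5, fixed penalty
α = 1) for the two composition covariates any sequence-level screen
must absorb — GC content and window length. Degenerate covariates
(constant columns, as when every window has one length) are dropped
automatically, in which case the fit reduces to ordinary logistic
regression; with a presence predictor and no covariates it agrees with
the closed-form 2 × 2 log-odds-ratio to machine precision and with the
2 × 2 LR test closely (the spline fit is exactly the GLM in that case).
β₁ is tested by a likelihood-ratio test (full versus β₁-dropped model,
χ² with 1 df); because the penalty applies only to the smooths, which
appear in both models, the df = 1 reference is appropriate. Complete or
quasi-complete separation (unbounded β̂₁ or non-finite likelihoods)
falls back to a ridge-stabilised linear logistic fit and is flagged
`separation`; an all-constant predictor reports effect 0, p = 1,
flagged. BH adjustment is applied within one window-size family, and
results sort by p, then |effect|, then motif id — fully deterministic.

The LR p-value is asymptotic; with very small gene universes (tests
enforce ≥ 20) or very rare motifs it will be approximate, which is one
reason the null-calibration property (label permutation keeps the
family-level false-alarm rate at or below nominal) is part of the
acceptance suite rather than assumed.

## Target ranking

Per motif, each gene's score is √(q_count · q_rho) where q is the
fraction of genes strictly below the gene's value. Strictly-below
quantiles send any gene with the minimum motif count (typically zero
sites) to score 0, and the geometric mean annihilates a gene missing
either signal. The rule is invariant under monotone transforms of
counts or ρ, needs no tuning, and reproduces the qualitative behaviour
wanted of such a ranking: a gene with many sites and high seed
correlation ranks first. It is intentionally pluggable — proximity
weighting or external target priors would slot in as alternative
components.

## Synthetic data

The generator emulates the statistical structure the screen relies on,
at desk scale:

- **Expression.** Per sample a latent regulator activity r ~ N(0, 1);
  target genes' log-mean shifts by β·r (default β = 1.5; negative β
  emulates a repressor), the seed gene follows r with unit effect, and
  other genes are independent of r. Counts are negative-binomial
  (dispersion 0.2) around 2^U(3, 9) baselines with log-normal
  (σ = 0.2) library-size factors — the mean–variance and library-size
  structure of a ~100-sample bulk RNA-Seq cohort, which also exercises
  the CPM/FPKM filter. Defaults: 1,000 genes × 99 samples, 150 targets.
- **Promoters.** Per gene an i.i.d. sequence at class GC (background
  0.45; an optional `gc_confounding` shift on target promoters tests
  covariate adjustment), with planted-motif instances at Poisson rates
  (defaults: 3 expected sites per target promoter versus 1 for
  background, i.e. 3-fold enrichment) at uniform non-overlapping
  positions, each degenerate position realised uniformly and
  orientation random. Genes sit on alternating strands along synthetic
  contigs with 100 bp spacing. The motif library is the planted
  consensus plus 29 random IUPAC decoys of length 5–8 with ≤ 2
  degenerate positions.
- **Truth.** Per-gene target flags and per-promoter planted-site
  positions are retained; `evaluate_recovery` reports
  precision/recall of the selected set and the planted motif's rank
  and FDR.

What the generator does **not** emulate: distance-dependent site
placement, dinucleotide/repeat structure, enhancer regulation, batch
effects, or correlated non-target gene modules. Passing tests therefore
demonstrate that the pipeline recovers the signal it is designed for
when the assumptions hold — not that those assumptions hold in real
tissue.

With 2 kb synthetic promoters and a planting rate of 3, the reference
seed-window filter of ≥ 5 sites would stochastically remove the planted
motif (P(Poisson(3) ≥ 5) ≈ 0.18), so desk-scale screens of generated
data run with `min_sites = 1`; the default elsewhere remains 5, which
is calibrated to a 10 kb window.

## Determinism and provenance

Every random step flows from one integer seed through
`numpy.random.default_rng`; regenerating a dataset and rerunning the
screen reproduces all fixture and result files byte-for-byte. Result
TSVs carry a one-line provenance header with the tool version and a
hash of the analytic configuration (paths excluded — identical inputs
at different locations are identical analyses); the JSON manifest
records config, seed, stage row counts and timings, and is written even
when a stage fails, with the failing stage named.

## Problem sizes used in the checks

The acceptance suite runs the scanner-vs-enumerator comparison on 1,000
random (≤ 2 kb sequence, motif) pairs; null calibration on one 400-gene
dataset with 20 motifs and 200 membership permutations; and signal
recovery on 20 replicates at the generator's default conditions (1,000
genes × 99 samples, β = 1.5, 3× planting, 30-motif library), requiring
the planted motif at rank 1 with FDR < 0.05 and ≥ 90% target recall in
at least 19 of 20 replicates.

## Known limitations

- Consensus-string matching is binary; position-weight-matrix scoring
  would grade near-matches and is out of scope by design.
- The LR test's χ² reference is asymptotic; very small universes or
  ultra-rare motifs deserve permutation p-values.
- One promoter per gene (designated/longest transcript); alternative
  TSSs are not aggregated.
- FDR families are per window size; no correction is applied across
  window sizes, matching the per-window reporting convention.
- The correlation screen measures marginal association; a correlated
  set contaminated by indirect targets dilutes, but does not bias,
  the enrichment test.
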