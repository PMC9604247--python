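# Methods

## Model

`methylseg` segments a CpG methylome with a K-state hidden Markov model.
The observation at site *t* is the pair (m_t, n_t): methylated calls and
total read depth. Each hidden state k has a mean methylation level β_k and
emits m_t ~ Binomial(n_t, β_k); a site with n_t = 0 has emission
probability 1 in every state and is carried through the chain without
influencing it. Transition probabilities depend on the genomic gap d
between consecutive CpGs,

    P(S_t = S_{t-1} | d) = 1/K + (K-1)/K · exp(-d/d0)
    P(S_t = j ≠ S_{t-1} | d) = 1/K · (1 - exp(-d/d0)),

which interpolates between the identity matrix at d = 0 and the uniform
matrix as d → ∞, modelling the decay of methylation correlation with
distance. At K = 4 this equals the familiar 1/4 ± (3/4 or 1/4)·e^(-d/d0)
coefficient form; for other K it is the unique row-stochastic
generalization with a single decay scale. A `transition_form="literal"`
mode instead keeps the K = 4 coefficients for any K and renormalizes rows;
the two coincide at K = 4 to machine precision.

Assumptions worth keeping in mind: binomial (not beta-binomial) counts, a
single global d0 for all chromosomes, and state-independent switch
probabilities (all off-diagonal targets equally likely).

## Training

Parameters β (and the initial distribution π) are estimated by Baum–Welch
with the transition matrix fixed by d0; d0 itself is a hyperparameter
chosen by grid search (`select_model`), not re-estimated inside EM. Two
deliberate deviations from a textbook fit:

- **Depth weighting.** During training each site's emission likelihood is
  raised to the power (n_t + 2), so cytosines with more reads dominate
  learning while uncovered sites stay neutral (1 raised to any power). The
  weight enters the forward–backward pass and the M-step sufficient
  statistics, so the monitored weighted log-likelihood is a proper EM
  objective and is non-decreasing every iteration (a tested invariant).
- **Bidirectionality.** A CpG's state should be informed by both
  neighbours, so the reverse-directed copy of every series (positions
  negated and reversed, preserving the gap multiset) joins the training
  set, and decoding reconciles a forward and a reverse Viterbi pass:
  sites where the two disagree are labelled "un" and excluded from
  segments.

Numerical choices: the forward–backward pass runs in scaled linear space
with a per-site rescaling by the largest weighted emission, which keeps
depth-8 weighted emissions (log-values near -10^3) finite; Viterbi runs in
log space with ties broken toward the lowest state index; betas are
clamped to [1e-6, 1 - 1e-6] so log-emissions are never NaN; betas and π
are permuted into ascending-β order on return (transitions are symmetric,
so the permutation leaves the likelihood unchanged). The sequential scans
are numba-compiled; one EM iteration on 10^5 sites takes milliseconds.

**Initialization.** β_k start at evenly spaced quantiles (10%…90%) of the
per-site methylated fractions of covered sites, clamped into [0.05, 0.95].
The clamp matters: at sparse depth the outer quantiles are exactly 0 and
1, and a state whose β sits at the clamp floor assigns vanishing weighted
likelihood to any site with a single methylated call, making it an
absorbing degenerate fixed point of the weighted EM. π starts uniform.
Convergence is declared when the weighted log-likelihood improves by less
than 1e-4 (relative) between iterations, with a 200-iteration cap.

**Known bias of the depth-weighted objective.** Raising emissions to the
(n_t + 2) power sharpens responsibilities toward a classification of sites
by their observed fraction. Two measurable consequences on data simulated
exactly from the model (regimes 0.05/0.50/0.85, depth ~ Poisson(3)
truncated at 8, 50k sites):

- The outer state means are pushed outward: the fitted hyper-state mean
  lands near 0.90 (≈ +0.05 from truth) at the default tolerance, and the
  fully converged weighted optimum is more extreme still (the same
  optimum is reached when EM is started at the true values, so this is a
  property of the objective, not of initialization). An unweighted fit of
  the same machinery recovers all three means to within ±0.005.
- On truly single-regime data, extra states can "explain" the granular
  binomial spread of observed fractions and gain likelihood faster than
  the BIC penalty (2·ln N per state) grows, so information criteria do
  not shrink K on degenerate inputs. On genuinely multi-regime data the
  criteria behave well: with three regimes present, K = 4 and K = 5 fits
  reach worse optima and BIC reliably selects K = 3.

Decoding is nearly unaffected by the outward bias (state boundaries move
little when the means spread), which is why segment-level results —
regime labels, hypomethylated-locus calls, specific-locus detection —
remain accurate.

Model selection uses p = 2K free parameters (K betas, K−1 initial
probabilities, one distance parameter), N = the number of covered sites,
and the unweighted forward-direction log-likelihood; the depth weight is a
training device only, and including it in BIC would distort the p-vs-N
balance. Whether reverse copies should also enter the selection likelihood
is not determined by the model; forward-only is used.

## Segmentation and locus analyses

Maximal runs of identically-labelled CpGs become segments; "un" sites are
skipped and do not break a run when the flanking labels agree. A segment
spans its first to its last CpG (conservative; no midpoint extension) and
must contain at least `min_cpg` covered CpGs (default 3, a support filter
against single-site noise). Regimes are named by β rank: hypo /
intermediate / hyper at K = 3.

Hypomethylated loci are segments whose count-weighted mean methylation
over covered CpGs is ≤ 0.20 ("does not exceed 20%" read literally as an
inclusive bound). Cross-sample specific loci: a locus is focal-specific
iff it is hypomethylated in the focal sample and in none of the others,
or hypomethylated in every other sample but not the focal one (strict
all-others rule); loci missing a sample's data are never flagged.

Feature enrichment uses a permutation null: every locus keeps its
chromosome and length and is re-placed uniformly at random, overlaps among
placed loci allowed; the statistic is the number of features overlapped by
≥ 1 bp. The null preserves chromosome assignment because locus density
varies across chromosome classes; mean, SD and z-score are reported, with
z undefined when the null is degenerate (SD = 0).

## Coverage QC

In one diplotene nucleus each chromosome is present as four chromatids,
and bisulfite conversion makes the two strands of each chromatid
independent sequencing templates, so at most 8 unique reads can cover one
CpG dinucleotide. Sites deeper than 8 are treated as artifacts or somatic
contamination and removed; the artifact fraction is reported relative to
sites with depth ≥ 1 (uncovered entries are not artifacts). The filter is
idempotent and keeps depth exactly 8.

## Methylome statistics

Global and per-feature methylation default to count-weighted means
(total methylated calls / total calls), the robust choice at sparse
single-cell depth; a per-site-mean mode exists behind a flag. Genomic bins
tile each chromosome from coordinate 1 in fixed windows (default 5 kb);
bins with fewer than 3 covered CpGs report no mean but keep their counts
so totals are conserved. Between-sample comparison uses Spearman rank
correlation over shared non-missing bins (ties by average ranks, ≥ 3 bins
required). Feature distributions are summarized by a 20-bin histogram and
the fractions below/above 20/40/60% cut lines — enough to see the bimodal
promoter and CpG-island pattern without a formal bimodality test.

## Repeat methylation

Tandem repeats cannot be analysed by genomic alignment, so methylation is
estimated against manually constructed reference variants of the monomer:
the methylated variant converts only non-CpG cytosines C→T (CpG cytosines
stay C), the unmethylated variant converts every C; bottom-strand variants
apply the same rules to the reverse complement, covering non-directional
libraries. The monomer is treated as circular so a terminal C keeps its
CpG context across the junction of a tandem array. Reads are scored by
best ungapped identity over every phase of the tandem concatenation
(an exhaustive equivalent of a k-mer-anchored search) and join the pool of
their best-scoring variant; ties and reads below 80% identity stay
unassigned. Error-free reads from a variant are recovered with 100%
accuracy (tested); an external-aligner mode is deliberately out of scope.

## Synthetic data

The generator is the exact sampling counterpart of the model: CpG
positions from cumulative geometric gaps (mean 100 bp — a memoryless
stand-in for CpG spacing), hidden states from the distance-decay chain,
depths from a Poisson (mean 3) truncated at the 8-read single-nucleus
ceiling so simulated data satisfy the QC rule by construction, and counts
from Binomial(depth, β_state). Defaults (β = 0.05/0.50/0.85, d0 = 1250 bp,
one ~5 Mb chromosome ≈ 50,000 CpGs) emulate the scale and sparsity of a
single-oocyte methylome at desk size. The multi-sample generator shares
one state backbone across samples and overrides planted loci to opposite
extreme regimes in (or outside) a focal sample, giving ground truth for
specific-locus detection.

What the generator does not emulate: real CpG clustering (islands),
beta-binomial overdispersion, conversion errors, mapping bias, and
chromosome-class structure. Passing tests therefore demonstrate
correctness of the algorithms under the model's own assumptions, not
performance on real libraries.

## Problem sizes

Tests and the reproduction script run on ~50,000-site simulations (three
seeds for model selection, twenty single-fit replicates for the recovery
property), which the numba kernels complete in seconds; larger genomes
scale linearly in sites and states².
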