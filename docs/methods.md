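# Methods

## Model and assumptions

The pipeline treats transcription-factor regulation as a linear response of
gene expression *changes* to motif binding affinity. For gene *g* and the
interval between consecutive timepoints *t* and *t+1*,

    Δ_{g,t} = log2( (E_{g,t+1} + δ) / (E_{g,t} + δ) )
            = c_t + Σ_m Ñ_{gm} A_{mt} + ε_{g,t},

where `E` is expression (TPM scale), `δ` a pseudocount, `Ñ` the
column-standardized affinity matrix, `A_{mt}` the motif activity, `c_t` an
interval intercept, and `ε` gene-level noise. Zero activity therefore means
"no change in expression between the two consecutive timepoints" — activities
are defined on T−1 intervals (11 for the 12-point design), each labelled by
its flanking timepoints. Modelling changes rather than levels removes stable
gene-specific offsets (GC content, baseline promoter strength) that a
level-model intercept per gene would otherwise have to absorb.

Assumptions worth keeping in mind: additivity of motif contributions, a
shared linear response across genes within an interval, and affinities that
are constant in time (regulation enters only through `A`).

## Affinity model

The affinity of motif *m* (4 × w position probability matrix `P`) for a
region sequence `s` is the occupancy-style sum over all windows on both
strands:

    N = Σ_i Π_j P[s_{i+j}, j]  +  the same sum on revcomp(s).

This is the REDUCE-family convention: non-negative, additive over windows,
and suitable as a regression design without thresholding individual "hits".
Windows containing non-ACGT bases contribute exactly 0; background base
frequencies are kept as scan metadata only. An alternative (log-odds /
energy weights, or single-strand scanning) would change the scale but not
the sign structure of the design; the probability-product, double-strand
form is declared as this package's model. Promoter windows are 400 bp
(−300/+100 of the dominant CAGE peak, mirrored on the minus strand because
upstream/downstream are strand-relative notions); enhancer windows are
midpoint ± 200 bp. Windows that would overrun a chromosome edge are hard
errors rather than being clipped, so that all design rows score equal-length
sequence.

## Regression

Each interval is fitted separately by least squares with an unpenalised
intercept. Centering both sides separates the intercept exactly, leaving
`(X'X + λI) A = X'Y` on the centered matrices. The default is λ = 0
(ordinary least squares) whenever genes outnumber motifs more than
five-fold; otherwise λ = 1.0 on the standardized design is used and
surfaced. Standard errors use the OLS covariance `σ̂²(X'X)⁻¹` at λ = 0 and
the ridge sandwich `(X'X+λI)⁻¹X'X(X'X+λI)⁻¹σ̂²` otherwise, with
`σ̂² = RSS/(G−K−1)`. Rank-deficient designs and K ≥ G at λ = 0 are errors
that instruct the user toward a positive λ. Promoter and enhancer fits are
two independent regressions — never a joint model — with enhancers mapped to
genes through an explicit link table (multiple enhancers per gene sum their
affinities; genes without an enhancer are excluded from the enhancer fit
rather than zero-filled, because zero affinity is a statement about
sequence, not missingness).

## Clustering and choice of k

Activity profiles are clustered by Euclidean k-means (k-means++
initialisation, 50 restarts by default, fixed seed; profiles are already on
a common scale because the design was standardized, so no further scaling is
applied). k is selected as the mean-silhouette argmax among candidate k
whose largest cluster holds at most `floor(0.5 · n)` motifs, ties to the
smaller k. The cap operationalises "no cluster may swallow half the motifs"
and rejects trivially high-silhouette coarse partitions. Singleton clusters
contribute silhouette 0. Clusters are described by the mean pairwise
Spearman ρ of member profiles (pairs with a constant profile are excluded
and logged; clusters of size < 2 report NA).

## Candidate discovery

Seed regulators are supplied as a symbol → motif table. Every non-seed,
non-known motif is correlated against every seed across the T−1 intervals;
the candidate rule is **positive correlation with p < 0.05** (two-sided
t-based p on n−2 df), with **r > 0.80** flagging the "highly correlated"
subset — both thresholds are exposed because the looser rule defines the
candidate set while the stricter one describes its core. No multiple-testing
correction is applied to the screen; a Benjamini–Hochberg q-value column is
reported for transparency but unused for filtering. Candidates are then
intersected (case-insensitively, with an optional alias table) with the
stage-2 expression filter, and each reports its best seed, cluster
membership, expression rank and predicted targets (top affinity quantile,
default 1 %).

For the expression filter itself, the "Mean" column is computed as the grand
mean of the timepoint means (the printed reference table does not define it
unambiguously; the value is labelled and never used as a filter criterion).
Ranking ties break lexicographically by symbol for determinism. Missing
replicate columns are rejected rather than imputed — absent measurements
must be explicit zeros upstream.

## Synthetic data: what it emulates and what it does not

The generator inverts the analysis model. Motifs get pairwise-distinct
random consensi with a per-column consensus mass (`informativeness`, default
0.9). Sites are planted Poisson(2 per region) at uniform offsets on either
strand, sampled from the matrix; every motif is guaranteed at least one site.
True activities follow `n_archetypes` (default 5) smooth archetype curves
(moving-average-smoothed noise, peak-normalised to `amplitude` = 1 log2
unit, pairwise |r| < 0.3), times a per-motif gain U[0.8, 1.2], plus jitter
(SD 0.05·amplitude). Expression accumulates multiplicatively from baselines
drawn log-uniform over 10–1000 TPM in *pseudocounted* space
(`M_t = M_0·2^{Σδ}`, `E = M − δ`), so the analysis-side fold-change
transform inverts the generative one exactly at zero noise; baselines are
raised deterministically where a deep excursion would drive `E` below zero,
and the adjustment count is recorded in the truth bundle. Replicates
multiply by `2^{N(0, τ²)}`. Defaults σ = 0.3 and τ = 0.15 log2 units are
calibration choices for a heavy-tailed CAGE-like time course, set once; the
data themselves publish no replicate noise level. The first `n_motifs` genes
carry the TF symbols so the expression filter and the motif analysis talk
about the same entities; one motif in each of the first two archetypes is
flagged as a known seed regulator, and same-archetype motifs are the planted
novel candidates.

Real CAGE data differ in ways the generator does not model: motif
co-occurrence and correlated affinity columns, expression heteroskedasticity
and count noise at low TPM, enhancer–promoter linkage uncertainty, TF-family
motif redundancy, and non-stationary (condition-dependent) activities within
an interval. Passing the recovery tests therefore demonstrates correctness
of the inference machinery under the stated model, not performance on tissue
data.

## Numerical choices

- Standardization uses the population SD (ddof = 0); constant affinity
  columns are dropped with a warning and recorded for back-transformation.
- Fold changes use δ = 1 TPM by default; δ must be > 0.
- Rank deficiency at λ = 0 is detected via the smallest eigenvalue of `X'X`
  against a machine-precision threshold scaled by the matrix size.
- The affinity scanner is exact (no log-space approximation); products of up
  to 30 probabilities stay well inside double-precision range.
- Dominant-peak ties resolve to the 5′-most position on the promoter's
  strand; ranking ties resolve by symbol; k-selection ties resolve to the
  smaller k. All randomness flows from explicit integer seeds, and repeated
  runs are byte-identical.
- QC ordination operates on log2(TPM + 1) timepoint means; the dendrogram
  uses average linkage on 1 − Pearson distance (the convention for CAGE
  sample QC), and a constant profile is an error because the correlation is
  undefined.

## Problem sizes in the shipped checks

The bundled checks run the generator at moderate sizes chosen to make the
statistics stable: the noiseless round trip at G = 200, K = 10; noisy
parameter recovery at the default study conditions (G = 1000, K = 20, 10
runs); archetype-count recovery at K = 50 over 20 runs; candidate recovery
at G = 600, K = 20 over 20 runs; the scanner oracle on 100 random
sequence–motif pairs; and the permutation check of the correlation p-value
with 10⁵ draws at n = 12. The permutation comparison is reported as an
absolute difference; at n = 12 the discrete permutation null can sit a few
×10⁻³ from the t approximation depending on the realised sample moments.

## Known limitations

- The affinity model ignores nucleotide interdependence within motifs and
  saturation at strong sites.
- Activities are per-interval point estimates; no smoothing or borrowing of
  strength across intervals is attempted.
- The enhancer fit requires an externally supplied enhancer → gene link
  table; no linkage inference is performed.
- TFs whose motif is missing can only be handled through an explicit
  motif → TF mapping supplied by the user; no automatic family substitution.
- The candidate screen's p-values are conditional on the fitted activity
  profiles and do not propagate regression uncertainty.
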