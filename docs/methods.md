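# Methods

`hcdscan` re-implements, as a tested pipeline, the computational analyses
that connect 3D genome organization (Hi-C) to heterochromatin domains in a
wild-type vs mutant comparison: per-arm compartment scoring and strength,
a two-state Gaussian-HMM caller for hypercompartmentalized domains (HCDs),
insulation-score stratification of TAD borders, declining CTCF/SCC1
anchorpoint selection with PE-SCAn pile-ups, circular-permutation overlap
enrichment, domain-scaled signal aggregation, and k = 2 expression
clustering. Everything runs per chromosome arm and is exercised end-to-end
on a synthetic generator with planted, recorded ground truth.

## Coordinate and masking conventions

All coordinates are 0-based half-open (BED convention). A `GenomeLayout`
lists chromosome arms; arms sharing a chromosome are laid out consecutively
so chromosome coordinates resolve unambiguously onto arms. No statistic
ever crosses a centromere. Bins whose contact-matrix marginal is zero are
auto-masked — a stand-in for the unmappable/blacklisted bins a real
pipeline inherits from upstream balancing; masked bins are excluded from
every statistic, and masking is absorbing (removing masked data beforehand
gives identical results, property-tested).

## Compartment score and strength

Per arm, the observed/expected (O/E) matrix divides each count by the mean
unmasked count at its genomic distance; diagonals whose expected value is
zero become undefined (NaN) and the per-diagonal unmasked means of O/E are
1 to 1e-9 by construction. The compartment score is

    CS_i = e1_i * sqrt(|lambda_1|)

where (lambda_1, e1) is the leading eigenpair of O/E − 1 restricted to
unmasked bins: among eigenvalues ≥ 0 the algebraically largest, otherwise
the largest in magnitude (with a warning; the sqrt then uses |lambda|).
NaN entries of O/E − 1 are treated as 0 (neutral) for the decomposition.
Because the eigenvector sign is arbitrary, the score is oriented by its
Pearson correlation with per-bin H3K4me1 signal (active chromatin): a
negative correlation flips the sign; exactly zero leaves the profile
unflipped and flagged unoriented.

Compartment strength takes the unmasked bins in the top/bottom 20% of the
score (ties at the cutoff broken by ascending bin index) as the A and B
classes and reports

    strength = log2( (AA * BB) / AB^2 )

with AA/BB/AB the mean finite O/E over unordered within/between-class bin
pairs, self-pairs excluded. Strength is computed per arm; the genome-wide
result is the per-arm list, never a pooled value.

A caveat the test-bench quantifies: on a compartment-free arm the strength
is biased upward (~0.27 at 1e7 reads/arm on 400 bins) because the same
noisy eigenvector both defines the classes and orders the O/E values being
averaged. The null checks therefore run at sequencing depths where every
distance class averages ≥ 100 reads per bin pair
(`depth_for_min_class_reads`), where the bias is ~0.06.

## HCD calling

Observations at each bin are the 2-vector (mutant compartment score,
|mutant − wild-type score|). A single two-state hidden Markov model with
diagonal-covariance Gaussian emissions is fitted jointly across all arms
(each contiguous unmasked run is an independent sequence) by Baum–Welch
with per-step scaling; the per-iteration log-likelihood is exact and
asserted nondecreasing. Initialization: k-means on the observations for
the emission means (scikit-learn), 0.9/0.1 transitions, uniform start;
5 restarts by default (later restarts jitter the means), best
log-likelihood kept; tol 1e-6, max 500 iterations. The "differential"
state is the one with the larger mean |delta| response — a labeling rule
invariant to state permutation.

Each arm is then decoded separately by Viterbi (posterior decoding is
available behind a flag). Decoding uses the stationary distribution of the
fitted transition matrix as the start-state prior: an arm is an arbitrary
window of the genome, so its first bin must not be penalized because the
training sequences happened to begin in one state. Masked bins break
decoding runs; runs are never bridged across masks.

Two filters produce calls: a maximal run of differential-state bins must
be at least 5 bins long (200 kb at 40 kb), and the run's mean mutant score
must be negative (B compartment). The negative-score filter is region-wise
by default (mean over the run); a strict bin-wise variant is available.

The synthetic recovery benchmark plants a B-compartment-wide strengthening
(`hcd_truth_fraction = 1`): in the mutant, B–B affinity is boosted inside
every truth region, which is the minimal mechanism for an overall
strengthening of B-compartment scores. Under these conditions the caller
recovers the truth at base-pair Jaccard ≈ 1. When only a subset of B
blocks is strengthened (`hcd_truth_fraction < 1`), the two-state model's
maximum-likelihood solution splits A from B rather than stable from
differential — the score response's bimodality dominates the likelihood —
and recall against a partial truth plateaus near the truth/B coverage
ratio. This is a structural property of a two-state model on two responses,
not an optimization failure; the harder partial scenario remains available
through the same knob.

## Insulation and TAD borders

The insulation score of bin i is the mean unmasked count in the w × w
square spanning rows (i−w … i−1) and columns (i+1 … i+w), log2-normalized
to the arm mean (so scaling the matrix by a constant leaves it unchanged).
Default w = 10 bins; bins within w of an arm end are masked. Higher
insulation means more contacts across the bin, i.e. a weaker boundary.

Borders (provided as BED, typically wild-type TAD borders; the generator
emits planted ones) are located by their midpoint bin. Borders inside an
HCD are ordered by delta = mutant − wild-type normalized insulation and
split into three near-equal categories: highest third "weaker", lowest
"stronger", middle "unchanged"; ties break by coordinate. Sizes differ by
at most one: one remainder goes to "unchanged", a second to "weaker".
The relative position of a border inside its HCD is
min(distance to either edge)/length ∈ [0, 0.5].

## Anchorpoints, PE-SCAn and domain aggregation

Peak signals are summed coverage over each peak footprint after total-count
depth normalization; relative decline is (wt − mut)/wt. For each factor
(CTCF, SCC1) the ceil(0.10·n) peaks with the largest decline are selected
(ties by coordinate) and anchors are the union spans of selected CTCF/SCC1
peaks overlapping by ≥ 1 bp.

PE-SCAn averages the (2m+1)² O/E window over every same-arm anchor pair
with separation in [1, 10] Mb (defaults m = 10 at 20 kb, i.e. ±200 kb;
the minimum separation must clear the window off the diagonal). Rows
follow the left anchor; masked cells are ignored per cell. The summary
score is the mean of the central 3×3 over the mean of the four corner
3×3 blocks — declared here because pile-ups are usually reported only as
images. `pescan_pairs` applies the same aggregation to an explicit pair
list (APA on BEDPE loop calls).

Domain aggregation rescales each domain body to 3k positions and flanks of
half the domain length to k positions each (k = 30), using exact
piecewise-constant integrals of the binned track, so the mean over the
rescaled body equals the length-weighted mean over the original bins to
1e-9. Off-arm or fully masked segments are missing; the profile is the
NaN-skipping column mean over domains.

## Circular permutation, overlap statistics, expression clustering

The enrichment test statistic is the fraction of anchor midpoints inside
the (merged) domain set. Each of the n shuffles draws one uniform offset
per arm and rotates all of that arm's anchor midpoints modulo the arm
length, preserving counts and circular spacing (property-tested). The
empirical p uses the add-one rule, p = (1 + #{null ≥ observed})/(n + 1),
so it is never zero; enrichment is observed/mean(null). The test's type-I
error is calibrated by `permutation_type1_study`: 500 independent null
datasets of 100 uniform anchors over two 10-Mb arms against a fixed
periodic domain set, 199 shuffles each. The anchor count matters: a coarse
fraction lattice (few anchors) ties with the rotation null and makes the
add-one p conservative; at 100 anchors the rejection rate at p ≤ 0.05 is
0.038–0.048 across master seeds.

Overlap statistics merge each interval set and report base-pair coverage,
intersection, Jaccard, and the fraction of A intervals touching B —
verified against a per-base oracle.

Expression clustering restricts a gene × sample TPM table to domain-
overlapping genes, transforms log2(TPM + 1) and mean-centers each gene,
then runs k-means (k = 2 default, scikit-learn, k-means++/Lloyd, best of
10 restarts, seeded). Mean-centering rather than z-scoring is deliberate:
z-scoring a near-flat gene inflates its sampling noise to unit variance,
turning the stable cluster into an isotropic cloud and making clean
recovery impossible; centering preserves the ~4.3 log2 silencing step an
~95%-silenced gene shows regardless of its baseline. Row z-scoring remains
available (`scale="zscore"`).

## The synthetic generator

`simulate_contact_matrix` draws symmetric Poisson counts around

    E[o_ij] = depth · Z · (1+|i−j|)^(−alpha) · c_ij · t_ij · l_ij

with alternating A/B blocks (sizes uniform in 1–3 Mb by default) giving
c_ij = 1 + k_eff·sigma_i·sigma_j (sigma = ±1; k_eff = k_comp·boost for
mutant pairs inside truth HCDs, else k_comp), planted TAD borders
attenuating cross-border contacts by `tad_insulation_factor`, and planted
loop-anchor loci boosting contacts by `loop_strength` between every pair
of loci 1–10 Mb apart (within ±1 bin). Z normalizes the expected total to
`depth`. TAD attenuation is capped at one border crossing by default
(`tad_crossing_cap = 1`): insulation in real Hi-C is a local effect, and
compounding the factor per crossing would attenuate a 10-Mb contact by
three orders of magnitude and erase all long-range structure. Setting the
cap to `None` restores the fully compounding model.

Defaults are chosen once as the study conditions: depth 1e7 reads per
~40-Mb arm (deep in-situ Hi-C scale; at 2e6 the |delta-score| noise floor
swamps the HCD effect), alpha = 1, k_comp = 0.2, boost = 2.5, TAD spacing
1 Mb with factor 0.5, 10 loop anchor loci per arm at strength 3, 200
CTCF/SCC1 peaks per arm with decline factor 0.2 inside domains and
Gamma–Poisson track noise 0.1. Tracks: H3K9me3 mean is 5× baseline inside
domain regions (= the B blocks), H3K4me1 5× outside; CTCF and SCC1 share
peak positions and a per-site decline severity (lognormal around the
decline factor), because the same cohesin-loss event hits both factors at
a co-bound site — this shared severity is what makes the top-decile
rankings of the two factors agree, as they do in real data.

Both conditions share one planted truth (geometry drawn from a dedicated
stream of the seed) and differ only in the boosted B–B affinity, declining
peak amplitudes, and independent Poisson noise. Everything is deterministic
given (params, seed).

What the generator does **not** emulate: trans contacts,
restriction-fragment structure, balancing artifacts, copy-number
variation, graded per-bin compartment identity, and biological
replicate-to-replicate variability. Passing tests therefore demonstrate
the correctness and calibration of the computations under a faithful but
idealized contact model — not performance on real libraries.

## Problem sizes in the test-bench

The standard scenario uses two 40-Mb arms at 100 kb (400 bins each); the
compartment-null and sign-agreement checks use single 40–50-Mb arms with
depth set by `depth_for_min_class_reads` (≥ 50–100 reads per distance
class); pile-up checks run one 40-Mb arm at 20 kb (2000 bins); HMM
recovery uses 5000-step simulated sequences over 10 seeds; the
permutation calibration runs 500 datasets × 199 shuffles. These sizes were
chosen so each check is statistically decisive at desk scale.

## Known limitations

- The two-state HMM identifies B-wide strengthening; partial-B scenarios
  need either a third state or an explicitly supervised contrast (see HCD
  section).
- Compartment strength inherits the selection bias discussed above at low
  depth; compare conditions at matched depth only.
- The insulation window and normalization follow common practice (w = 10,
  arm-mean log-ratio); other conventions shift absolute values but not the
  weaker/stronger ordering used downstream.
- Interval arithmetic is exact but designed for domain-scale inputs
  (thousands of intervals), not genome-wide base-pair feature sets.
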