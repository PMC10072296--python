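# Methods

This note documents the models, numerical choices, and open design
decisions behind each pipeline stage, and what the synthetic-data
generator does and does not emulate.

## Stage 1 — topology and the extracellular screen

**Topology caller.** Membrane topology is assigned with a
Kyte–Doolittle hydropathy scan: per-residue hydropathy values are
averaged in a sliding window (default 19 residues, odd, full windows
only), and positions whose windowed mean is at least the threshold
(default 1.6) seed transmembrane (TM) calls.  Because a windowed mean
erodes segment ends (a 21-residue hydrophobic helix produces only
~13 above-threshold window centers), each seeded call is extended
outward while the *per-residue* hydropathy stays positive, then calls
separated by fewer than 3 residues are merged and calls shorter than
the minimum TM length (default 15) are dropped.  The extension rule is
what makes the caller's segment boundaries coincide with the
underlying hydrophobic blocks rather than with the eroded window
response.  Defaults (19 / 1.6 / 15) are the classical operating point
for 7-TM membrane proteins.

The N terminus is taken as extracellular (class-A GPCR convention,
configurable) and sides alternate across TM segments.  The caller is a
deliberate, dependency-free stand-in for server-based secondary
structure/topology predictors; externally computed per-residue E/M/I
annotations can be supplied per record and take precedence.

**Extracellular segments.** The E-labeled stretches are assigned roles
NTERM, ECL1, ECL2, ECL3 in N→C order; stretches beyond the fourth
(possible on non-7-TM topologies) are dropped with a warning.  A
record with zero TM calls cannot be oriented and is rejected with a
pointer to the external-annotation path.

**Similarity score.** Segment pairs of equal role are compared by
*maximal ungapped sliding hamming similarity*: the shorter string is
slid along the longer at every offset and the score is the maximum
count of identically aligned residues.  For equal lengths this is
length minus hamming distance; the sliding maximum is the minimal
extension of hamming similarity to unequal lengths that introduces
neither gaps nor a substitution matrix.  `X` (unknown) never matches
anything, including another `X`.  A candidate's score against a
reference is the sum over roles; roles missing on either side
contribute zero.  The pass rule defaults to requiring score ≥ 30
against *both* references ("each" mode; a "sum" mode is provided since
the original threshold statement is ambiguous between the two).
Ranking is by combined score, ties broken lexicographically by id.
Whether the original screen counted matches, normalized matches, or an
inverse distance is not documented anywhere we know of; raw match
counts are the most literal reading and are what the threshold of 30
is applied to.

## Stage 2 — percent-identity matrix

All pairs are aligned with Needleman–Wunsch global alignment
(Biopython `PairwiseAligner`; BLOSUM62, gap open 10, gap extend 0.5 by
default — note Biopython charges the open penalty for the *first*
gapped position, so a length-k gap costs open + (k−1)·extend).  Among
co-optimal tracebacks the library's first alignment is taken, which is
deterministic.  Percent identity is 100 × identical columns / total
alignment columns; gap columns count in the denominator and never as
identities.  An alternative denominator (length of the shorter
sequence) is exposed because the two conventions diverge noticeably
for length-mismatched receptors.

This is a pairwise substitute for a multiple-alignment-derived
identity matrix: values will differ in detail from any MSA-based
matrix, but symmetry, the 100% diagonal, and the candidate ordering
behave the same.  The reference-normalized score is
raw(c) = ½(PID(c, ref₁) + PID(c, ref₂)) and
normalized(c) = raw(c) / PID(ref₁, ref₂); since the normalization is a
positive constant it can never reorder candidates — it only rescales
the ranking against how related the two references themselves are.

## Stage 3 — dose-response and assay arithmetic

**Model.** The four-parameter logistic on log₁₀ dose:
y = bottom + (top − bottom) / (1 + 10^((logEC50 − log₁₀x)·h)).
Agonist fits constrain the Hill slope h to (0, 10]; antagonist fits
constrain h to [−10, 0) so the curve decreases and the midpoint is an
IC50.  A fixed-|h|=1 option is available.

**Fitting.** Trust-region least squares (`scipy.optimize.least_squares`)
with an analytic Jacobian over all individual replicates (not dose
means).  Initialization is data-driven — bottom/top from the extreme
dose-group means, logEC50 from the dose whose group mean is nearest
the response midpoint, |h| = 1 — plus five seeded jittered restarts;
the lowest-cost converged solution wins.  logEC50 is bounded to the
dose range ± 2 decades.  If no start converges the result carries
`converged=False` and the solver messages; parameters are never
reported silently in that case.  Standard errors come from the
Jacobian covariance σ²(JᵀJ)⁻¹ with σ² = RSS/(n−p); the EC50 SE is
propagated from the logEC50 SE by the delta method (SE = ln10 · EC50 ·
SE_log).  They are asymptotic SEs and are labeled as such.

**Direction check.** Before fitting, the correlation of dose-group
means with dose order is compared with the sign the mode implies; a
contradiction sets `direction_mismatch=True` on the result so that an
agonist fit on inhibition data (or vice versa) is flagged rather than
silently absorbed by the bounds.

**Simple quantities.** RFU ratio = mean(after window)/mean(before
window), rejecting non-positive baselines; binding ratio =
F_anti-HA/F_anti-Flag per cell with group mean ± SEM (SEM 0 for a
single cell); relative expression = 2^−(Ct_target − Ct_ref) and
knockdown = 1 − expr_sh/expr_scramble.  Both ratios are invariant
under a common positive rescaling of their inputs, which is what makes
them comparable across imaging sessions.

## Stage 4 — colocalization

**Pixel metrics.** PCC is the sample Pearson correlation of the two
channels' intensities (mean-subtracted: invariant under independent
positive affine transforms of either channel); MOC is
Σab / √(Σa²·Σb²) (not mean-subtracted: invariant under positive
scaling only, and sensitive to additive offsets — the test suite
demonstrates the difference).  Constant or zero-energy channels raise
errors rather than yielding NaN.  By default both metrics are computed
over the *union-of-signal* mask (pixels above the detection threshold
in either channel); a whole-frame mode exists.  The mask choice
materially changes values — background-dominated frames dilute PCC
toward 0 and inflate MOC toward the background autocorrelation — so
the mask is always reported alongside the metrics.

**Puncta detection.** The detection threshold follows a
background-plus-k·SD rule with the background estimated from pixels
below the image median (k default 3).  Because that background sample
is the lower half of the noise distribution, the resulting threshold
sits only ≈1 noise-SD above the background level; the binary mask is
therefore cleaned with one iteration of morphological opening (3×3
cross), which removes single-pixel speckles and the thin noise bridges
that would otherwise merge nearby spots, before 8-connected components
with at least `min_area` pixels (default 9) are kept.  The default
operating point was fixed by a noise-only calibration: on pure-noise
fields it yields zero false components per 256×256 field, and on
planted-spot fields at peak/noise = 10 it gives recall ≈ 0.99 at
false-discovery ≈ 0.01.  Centroids are intensity-weighted on the
original (uncleaned) pixel values.  An optional Gaussian pre-smoothing
is exposed but off by default: at this threshold it enlarges
correlated-noise clusters and defeats the area filter.

**Triple overlap.** A triple-positive overlay dot is one punctum from
each of three channels with all pairwise centroid distances within the
match radius (default 0.3 µm).  Candidate triples are accepted
greedily in order of increasing summed pairwise distance, each punctum
used at most once; the count divided by the field area gives the
density in counts/mm².  The greedy criterion is symmetric in the three
channels, so permuting channel order leaves the count unchanged.
A pixel-overlap alternative was considered and rejected: centroid
matching is robust to the area differences that thresholding induces
between channels.

## Synthetic data: what it emulates, what it does not

**Receptor families.** A template receptor is built from alternating
blocks — hydrophilic N terminus (30 aa), seven 21-aa TM helices drawn
from {L,I,V,F,A,M}, 12-aa loops and a 20-aa tail drawn from a
hydrophilic set — and candidates are derived by per-site substitution:
loops at the candidate's loop-divergence rate (substitutions stay
hydrophilic), TMs at a lower rate (substitutions stay hydrophobic).
Class-preserving substitution keeps the true topology recoverable by
the hydropathy caller, so topology recovery is an exact invariant on
synthetic families, and the template's 66 extracellular residues serve
as both references — which is what ties a candidate's expected screen
score directly to its divergence (≈ 66·(1−p) per reference).  The
generator does *not* emulate indels, paralog structure, or realistic
evolutionary substitution processes; screen behavior on real families
with length variation rests on the sliding-alignment rule, which the
oracle tests cover separately.

**Plates.** Forward 4PL responses on an 11-point half-log dose grid
from 0.01 to 1000 nM (bottom 1.0, top 3.0 — typical span of a
fluorescence-ratio Ca²⁺ readout), 3 replicates per dose, 5%
multiplicative Gaussian noise by default (additive-SD mode available).
Replicate noise is independent; no plate-position or day effects are
modeled.

**Image fields.** 256×256 px at 0.05 µm/px, 60 puncta per channel with
Gaussian profiles (σ 2 px, peak 10 over a background level of 5,
noise SD 1 — i.e. peak SNR 10), a configurable fraction of channel-2/3
puncta planted coincident with channel-1 positions up to 1 px Gaussian
localization jitter (emulating two-fluorophore registration error).
Planted puncta keep a 10 px minimum within-channel separation so
ground-truth identity stays well defined; resolving genuinely
overlapping puncta is out of scope, as is point-spread-function or
blinking/reconstruction realism.

All generators are pure functions of their spec including its seed;
no global random state is touched.

## Problem sizes and determinism in the test suite

The recovery experiments run at desk scale: 200 seeded plates per
EC50 constant, 20 seeds × 60 candidates for the screening-recovery
check, 20 seeds per colocalization fraction, 10 fields for the
detection benchmark, ~10⁵ sampled string pairs and 10³ sampled
sequence pairs against the brute-force oracles.  All randomness is
seeded; hypothesis-based property tests run derandomized.

## Known limitations

- The hydropathy caller is a heuristic: highly polar TM faces or short
  helices in real receptors can be missed; the external-annotation
  path is the intended remedy.
- Hamming-based screening cannot see homology through indels; the
  percent-identity stage is the complementary, alignment-based view.
- Reference binding domains are a required input; the package ships no
  receptor-specific residue ranges.
- EC50/IC50 standard errors are asymptotic; bootstrap intervals are
  not implemented.
- PCC/MOC are computed per image pair (or per ROI via masks);
  cluster-level aggregation is left to the caller.
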