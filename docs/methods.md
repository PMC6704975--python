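# Methods

This note documents the models and procedures implemented in `microstates`,
the parameters that matter, and the design choices made where the standard
methodology leaves the details open.

## The microstate model

Resting-state EEG topographies do not drift continuously: the scalp
potential map stays quasi-stable for tens of milliseconds (classically
~80–120 ms) and then switches abruptly to a different configuration.  The
microstate model describes the recording as a sequence of such stable
periods, each drawn from a small alphabet of K prototype maps.  Because a
map and its polarity-reversed copy reflect the same generator configuration
at a different oscillatory phase, every comparison between topographies is
polarity-invariant: it uses the absolute spatial (Pearson) correlation
across channels.

Two scalar fields drive the analysis:

- **GFP (global field power)** — the per-sample population standard
  deviation across channels (`ddof = 0`), a reference-free measure of
  field strength.  For average-referenced data GFP equals the spatial RMS.
- **GEV (global explained variance)** — the fraction of squared-GFP-weighted
  variance a labeled model explains:
  `GEV = Σ_t gfp_t² r_t² / Σ_t gfp_t²`, where `r_t` is the spatial
  correlation between the sample map and its assigned prototype.  GEV
  decomposes exactly into per-class contributions.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (default 1–40 Hz) applied
forward–backward per channel (no phase distortion of topographies);
integer-ratio decimation (default target 125 Hz) behind a zero-phase
low-pass at 0.4 × target rate, refusing non-integer ratios rather than
silently resampling; average re-referencing.  All three are linear and
preserve channel identity.  The first and last second of a filtered
recording are excluded from GFP-peak extraction because forward–backward
filtering contaminates the edges.

## Clustering

Only maps at GFP peaks are clustered (highest signal-to-noise instants).
Peaks are strict local maxima with a deterministic plateau rule (a run of
equal values above both neighbours contributes its first index); optional
thinning keeps the larger of two peaks closer than a minimum distance
(default: no thinning).

**Modified k-means.**  The assignment step labels each peak map by maximum
absolute correlation with the K prototypes (ties to the lowest class
index).  The update step re-estimates each prototype as the dominant
spatial mode of its assigned maps, computed as one power-iteration step on
the cluster scatter, `a ← X^T (X a)` renormalised — the amplitude-weighted,
sign-aligned mean of the assigned maps.  Both steps are provably
non-decreasing in GEV (the power step cannot decrease the Rayleigh
quotient of a positive semidefinite scatter), so the within-restart GEV
trace is monotone, and the fixed points coincide with the exact
eigenvector update at a fraction of its cost.  An empty cluster is
re-seeded from the currently worst-explained map.  The best of
`n_restarts` random initialisations by GEV wins; every stochastic step
takes an explicit seed.  Prototypes are returned unit-norm,
average-referenced, ordered by explained variance, with a canonical sign
(largest-magnitude channel positive) for reproducible output files.

**Choosing K.**  Seven cluster-validity criteria are computed for every
candidate K, all in the polarity-invariant dissimilarity
`d = sqrt(2 − 2|r|)` (the chordal distance between the lines spanned by
two unit maps): Baker–Hubert Gamma, mean Silhouette, Davies–Bouldin
(negated), Point-Biserial, Dunn, Krzanowski–Lai (from within-dispersions
at K−1, K, K+1), and a predictive-residual cross-validation criterion
`σ̂²((C−1)/(C−1−K))²` (negated).  Each criterion is oriented so larger is
better, min–max normalised across the K range, and converted to ranks; the
K with the best median rank is selected, ties resolved toward smaller K.
The composition of the criterion set is a documented choice — the
criteria are standard, independent in construction, and the median vote is
robust to any single criterion misbehaving; the full score table is always
returned and written to disk.

**Two-level clustering.**  Each subject's peak maps are first clustered at
a fixed per-subject K (default 6); the pooled subject prototypes are then
clustered at the group level with K chosen by the meta-criterion.  Fixing
the individual-level K (rather than running the meta-criterion per
subject) stabilises the pooled second level; it is configurable.
Per-subject seeds derive from the subject identifier (CRC-32 mixed into a
seed sequence) and pooled prototypes are sorted by subject id, so the
global model is invariant to subject order.

## Backfitting and temporal smoothing

Every sample of the recording (not only GFP peaks) is assigned to the
class of highest absolute correlation; there is no minimum-correlation
rejection, so every sample is labeled.  The label sequence is then
smoothed by windowed iterated conditional modes: sample `t` is reassigned
to the class minimising

    d²(k, t) / (2 e)  −  λ · N_bkt / W²

where `d²(k, t) = ‖x_t‖² (1 − r²_kt)` is the variance of the sample left
unexplained by map k, `e` is the residual variance of the current labeling
(re-estimated every sweep, so the data/continuity balance adapts to the
noise level and the noiseless limit degenerates to plain backfitting),
`N_bkt` counts the other samples within ±b samples currently labeled k,
and `W = 2b + 1` is the window length.  Defaults: window half-size `b = 3`,
strength (Besag factor) `λ = 10`.

The count normalisation is the one genuinely open design point.  Entering
the count as `λ · (N/W) / W` — a support fraction, expressed per window
sample — makes the strength parameter invariant to the window choice and
places the conventional strength 10 in the balanced regime: at low GFP the
data term vanishes with `‖x_t‖²` and continuity wins (noise there cannot
fragment segments), while at GFP peaks the data term retains authority so
genuinely short microstates survive.  An unnormalised count at the same
nominal strength degenerates into data-blind majority voting, which
systematically absorbs every dwell shorter than the window (≈ +20% mean
duration, −19% occurrence on planted synthetic truth); the package's
normalisation keeps all three temporal parameters within a few percent of
planted truth at the default simulation conditions (see
`tests/test_acceptance.py`).  Synchronous ICM sweeps can enter a
two-state cycle; the iteration detects this and keeps the lower-energy
state (data term minus λ/2 per same-label pair in the window).

## Temporal metrics

Per class: **occurrence** = segments per second of labeled time;
**coverage** = fraction of samples carrying the class (sums to 1);
**duration** = mean segment length in ms.  Segments truncated by the
recording boundary bias dwell estimates downward, so they are excluded
from the duration mean (but retained in occurrence and coverage) unless a
class occurs only at the edges; a class that never occurs reports NaN
duration and zero occurrence/coverage.  Internally everything is counted
in samples with half-open `[start, start+length)` segments; milliseconds
and seconds appear only at the reporting boundary.  The identity
`coverage = occurrence × duration / 1000` holds exactly when edge segments
are included in the duration mean, and within edge tolerance otherwise.

## Statistics

Group comparisons use the classical pooled-variance independent t-test
(Welch optional) per (parameter, class), two-sided, with
Benjamini–Hochberg FDR correction applied within each parameter family —
the K class-wise tests of one temporal parameter form one family.  Cells
where both groups are constant are reported as NaN while the rest of the
family proceeds.

Clinical correlations use Spearman's rank coefficient (Pearson correlation
of mid-ranks; two-sided p from the t-approximation with n − 2 degrees of
freedom, standard at the target sample sizes of ~19 patients), computed
patients-only for every (parameter × class × clinical covariate) cell with
pairwise deletion of missing values, flagged at α = 0.01.  The full table
is always returned, not only significant rows.  The expected clinical
covariates are a depression severity score (MADRS), a global severity
score (CGI), lifetime episode count, illness duration in years, a
benzodiazepine-equivalent dose, and an ordinal 1–4 medication scale
(number of psychotropic medicaments and whether doses are therapeutic).

## The synthetic-EEG generator

The generator emulates a high-density resting-state acquisition: 110
average-referenced channels at 125 Hz for 300 s (the post-decimation
geometry of a 128-channel, 1 kHz system), six planted template maps, mean
dwell 100 ms, and signal-to-noise RMS ratio 2.  Components:

- **Templates** — random combinations of smooth low-order spatial modes
  (cosine profiles over a randomly permuted virtual channel ordering),
  centered and orthonormalised, so all pairwise correlations are exactly
  zero and any separation bound holds by construction.
- **State sequence** — semi-Markov: each segment's class is uniform over
  the alphabet excluding the previous class; dwell times are gamma with
  shape 2 (positive, right-skewed, few near-zero dwells) scaled to the
  target mean, rounded to ≥ 1 sample.
- **Amplitude envelope** — a rectified 10 Hz sinusoid scaled to unit mean
  (alpha-band surrogate), giving GFP peaks roughly every 50 ms so peak
  extraction has structure to find.
- **Noise** — spatially correlated Gaussian noise from a random orthogonal
  rotation of an exponentially decaying eigenvalue spectrum
  (`λ_j = exp(−j/10)`), average-referenced; white sensor noise would be
  unrealistically easy to cluster away.  SNR is defined as the ratio of
  noiseless-signal RMS to noise RMS pooled over channels and time;
  `snr=None` is noiseless, `snr=0` pure noise.

Identical configuration and seed give bit-identical output.  The planted
labels yield exact per-class ground-truth metrics, so every downstream
stage is validated by parameter recovery.

What the generator does **not** emulate: no head model or dipole sources
(templates are abstract smooth fields, not forward-modeled potentials), no
ocular/cardiac artifacts (artifact removal is out of scope), no non-
stationarity, no 1/f spectral background beyond the envelope structure.
Passing recovery tests therefore demonstrate the correctness of the
algorithms under the stated generative model, not clinical performance on
real recordings.

## Numerical choices and problem sizes

k-means convergence: relative GEV change < 1e-6 or 1000 iterations;
default restarts 100 for single fits, 25 inside the pipeline (the
two-level design averages over subjects, so fewer restarts per subject
suffice); ties in assignment and in argmin/argmax always resolve to the
lowest index; ICM smoothing caps at 1000 sweeps (typical convergence < 15).
Validity criteria build an O(N²) distance matrix — intended for peak-map
sets up to a few thousand maps and for pooled prototype sets (tens).
The test suite and the acceptance script run cohorts of 10 × 300 s
recordings at full channel count (criteria checks) and scaled-down
variants (48–64 channels, 30–60 s) for per-module properties; scaled sizes
are chosen so each property is measured with comfortable statistical
margin.

## Known limitations

- EDF output is plain 16-bit EDF with one-second records; recordings must
  be a whole number of seconds long at an integer sampling rate.
- The meta-criterion's candidate range must start at K ≥ 2; K = 1 models
  are fitted only internally (for the Krzanowski–Lai dispersion at the
  range edge).
- Spearman p-values use the t-approximation; exact permutation p-values
  for very small n are not implemented.
- The medication scale is treated as a plain ordinal covariate; no attempt
  is made to model dose equivalence beyond the 1–4 levels.
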