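# Methods

This note documents the models, the parameter choices that matter, the
numerical conventions, and what the synthetic data do and do not
establish.

## The coupling analysis

For one participant with n white-matter contacts, each modality yields
a symmetric n × n matrix: SEEG FC per band (Pearson r of the
band-filtered, conditioned traces, or band-averaged magnitude-squared
coherence), BOLD FC (Pearson r of the preprocessed sphere-ROI series),
SC (streamline counts between contact spheres), and Euclidean distance
D (mm).

Every comparison operates on the half-vectorized upper triangle
(n(n−1)/2 edges, lexicographic pair order):

1. **Distance residualization.** Nearby contacts are more connected in
   every modality, so distance is a confound, not a finding.  Each edge
   vector is replaced by its OLS residual on [1, d].  Residuals have
   exactly zero mean and zero sample covariance with distance.  The
   regression uses raw (not rank-transformed) distance with an
   intercept; this is a design choice, since "regressed out" admits
   several readings — raw-scale OLS is the least aggressive one and
   keeps the residualizer linear.
2. **Spearman rank correlation** of the two residual vectors: Pearson
   correlation of mid-rank transforms (ties get average ranks), with a
   two-sided p from t = ρ√((n−2)/(1−ρ²)) on n−2 df.  FC distributions
   are skewed, so a rank statistic is the appropriate similarity
   measure; the t-approximation is accurate for the edge counts in play
   (dozens to thousands).
3. **SC masking.** Structure–function comparisons keep only edges with
   SC > 0, because the hypothesis concerns direct anatomical support;
   the mask is applied *before* residualization, so the distance fit
   uses exactly the edges being compared (the alternative — residualize
   first, mask second — mixes information from unconnected pairs into
   the fit; the choice is documented because either is defensible).
4. **FDR.** Benjamini–Hochberg step-up jointly across all participants
   × bands within one comparison family (BOLD-vs-SEEG, SC-vs-SEEG,
   SC-vs-BOLD).  Families are not pooled with each other: they answer
   different questions and are reported separately.
5. **Summaries.** Median ρ across participants per band, plus counts of
   FDR-significant participants.

Edges whose FC is undefined (a zero-variance channel) are dropped
pairwise from all vectors before residualization, with the drop count
reported.  An exact permutation p-value for Spearman is unnecessary at
these edge counts and is not implemented.

## SEEG conditioning

Third-order Butterworth filters throughout, applied zero-phase
(forward–backward on second-order sections).  Zero-phase application is
a deliberate choice: a causal one-pass filter imposes a
frequency-dependent lag that would distort instantaneous correlation
between channels, which is the quantity under study.  The broadband
pass is 0.5–300 Hz; power-line energy is removed by cascaded band-stops
at 49–61, 99–101, 149–151, 199–201, 249–251 and 299–300 Hz.  Note that
a tone exactly at 50 Hz sits at the *edge* of the first stop band,
where a third-order response attenuates only ~13 dB (zero-phase); the
stop-band interior exceeds 70 dB.  Recordings at 2048 Hz are polyphase
resampled to 2000 Hz.

Bad channels are those with variance below `flat_tol` (flat line) or
with robust z-score of log-variance above `noise_z` = 5 (excessive
noise or drift), standing in for the visual inspection used on clinical
data; both thresholds are configuration values.

The common average reference subtracts the instantaneous mean over the
white-matter channels from every channel.  Segment averaging takes the
first window_s × n_segments seconds (defaults 6 s × 10 = 60 s), splits
them into consecutive non-overlapping windows and averages them
pointwise, boosting SNR at the cost of suppressing activity not
phase-locked across segments.  FC is computed on the averaged trace, as
the analysis prescribes; averaging per-segment FC instead is possible
with the same primitives but is not the default.

Coherence FC uses Welch cross-spectra (1 s Hann windows, 50% overlap)
and averages the magnitude-squared coherence over the frequency bins
inside the band.

## BOLD preprocessing

Deliberately reduced to the temporal steps: the package consumes
already-gridded volumes (2 mm isotropic, diagonal RAS affine) or
pre-extracted panels; registration, distortion correction and
normalization are upstream concerns and out of scope.  ROI extraction
averages the sphere voxels at each time point.  Sphere definitions are
by voxel count, not geometric radius: 7 = center + face neighbors,
19 = center + face + edge neighbors (the "3 mm radius" sphere at 2 mm
voxels), 27 = the full 3×3×3 cube.  The center voxel is the nearest
grid voxel with round-half-away-from-zero per axis — the convention is
fixed and tested because no standard exists.  Edge-of-grid spheres keep
their in-grid voxels with a warning; a contact with under half its ROI
in-grid is flagged.

Temporal chain: drop the first 5 volumes, demean and detrend per
channel, optional OLS confound regression (e.g. 24 motion parameters;
rank-deficient designs are repaired by dropping dependent columns with
a warning), then a zero-phase Butterworth bandpass, 0.01–0.2 Hz by
default with 0.01–0.08 Hz as the sensitivity variant.  Global/CSF
regressors are optional columns, off by default.

## Structural counting

A streamline connects pair (i, j) when at least one of its points lies
within `roi_radius_mm` (default one voxel = 2 mm) of contact i and at
least one within the radius of j — the pass-through convention, chosen
because endpoint-only counting is a stricter reading that tracking
software does not consistently apply.  Polylines are densified at
0.5 mm before the test so coarse vertices cannot tunnel through a
sphere.  Each streamline increments every pair it connects by exactly
one.

## The synthetic study generator

The generator's defaults are the study conditions the package is
validated under, mirroring the clinical acquisitions it stands in for:
47 contacts (hence 1081 pairs), 2000 Hz LFP for 60 s, TR 2 s with 240
volumes at 2 mm isotropic, coupling strength 0.5.

**Contacts** are placed by rejection sampling, uniform in a box
(default 120 mm), with Euclidean separation ≥ 2 voxels *and*
center-voxel Chebyshev distance ≥ 3 voxels.  The second condition is
what actually guarantees disjoint 19/27-voxel sphere ROIs (Euclidean
separation alone does not: two center voxels 2 apart share a face
neighbor), and volume rendering re-checks and raises on overlap.

**Structural network.**  Edge (i, j) is present with probability
sc_density · exp(−distance_decay · d_ij) (defaults 0.6 and 0.03/mm),
giving the sparse, distance-dependent networks seen in tractography;
present edges carry an integer weight 1 + Poisson(mean 2).  Each
counted streamline is emitted as a quadratic Bézier polyline with
jittered endpoints inside the two contact spheres and a random bow,
re-drawn until its densified path stays ≥ 2.5 mm from every other
contact — so streamline counting recovers the weight matrix exactly,
by construction, and the round trip is an end-to-end test of the
counting geometry.

**Neural dynamics.**  A stable linear stochastic network model,
x[t] = A x[t−1] + e[t] with A = φI + κC, where
C = coupling_strength · SC/λ_max(SC), φ (`ar_retention`) = 0.5 and
κ (`coupling_gain`) = 0.9.  This is the simplest generative model in
which pairwise synchronization provably increases with structural
weight, at every frequency.  The constants were fixed so that the
canonical "on" condition (coupling_strength = 0.5) sits near
criticality (spectral radius 0.95), where the strongest edges reach
pairwise correlations of ~0.4–0.6 — the magnitude intracranial
recordings show for well-connected white-matter contact pairs.  The
model is stable for coupling_strength < (1−φ)/κ ≈ 0.556; beyond that
the simulator raises rather than renormalizing, so a requested coupling
is never silently reduced.  Innovations are 1/f-shaped: one white
stream per node, shaped by a white floor plus three unit-variance
first-order components with cutoffs at 0.3, 3 and 30 Hz (the cascade
approximation to a 1/f spectrum; weights are the slope knob).  The
0.3 Hz component matters doubly: it gives the LFP realistic infra-slow
power, which is what the hemodynamic model ultimately samples.  Because
A is symmetric, the system is simulated exactly by eigendecomposition
into scalar AR(1) modes.  A 10 s burn-in is discarded; channels are
standardized and white measurement noise (SD 0.1) added.

**BOLD.**  Each node's activity envelope is the moving RMS over 1 s
windows, carried at 10 Hz, convolved with a canonical double-gamma HRF
(gamma peak 5 s minus 1/6 × gamma peak 15 s, unit peak), sampled at the
TR, standardized, plus white noise of SD 0.3.  The envelope-then-HRF
construction means BOLD FC tracks the *square* of the neural
correlation (envelope correlations of jointly Gaussian signals scale as
ρ²) — a monotone, sign-losing transform, which is all the rank-based
coupling statistics require.  When the recorded LFP is shorter than the
scan, the envelope is extended by continuing the same generative model
with a dedicated substream rather than by tiling or stretching: the two
modalities are acquired in separate sessions in the motivating setting,
so sharing the coupling structure but not the noise realization is the
faithful model, and tiling would make the BOLD signal periodic and
collapse the effective degrees of freedom of its FC estimates.  The
envelope+HRF link is a stand-in for an unknown forward model, not a
mechanistic claim.

**Volumes.**  Each contact's BOLD series is painted into its 19-voxel
sphere on a grid covering the box; background voxels carry independent
noise of the same SD.

**Determinism.**  Every generator is a pure function of
(config, seed): the study seed spawns fixed named substreams
(contacts/structure/lfp/bold/render), and study orchestration derives a
fixed per-participant seed, so results are independent of execution
order and reproducible byte-for-byte.

## Reference desk-scale studies

Validation uses two fixed study conditions, chosen once:

* **Null calibration** — 100 participants, 20 contacts, 15 s LFP
  (ten 1.5 s segments), 120 volumes, coupling 0.  The fraction of
  FDR-significant BOLD-vs-SEEG results must stay ≤ 1.5 × α (α = 0.05).
* **Recovery** — 20 participants, 30 contacts, 30 s LFP (ten 3 s
  segments), 240 volumes, coupling 0.5.  At least 80% of participants
  must show significant positive BOLD-vs-SEEG coupling in ≥ 6 of 7
  bands, and likewise for the SC comparisons.

These sizes keep a full study in the minutes range on one CPU while
preserving the pipeline end to end (volume rendering and ROI extraction
included).

## What passing tests do and do not show

The generator produces stationary, linear, Gaussian dynamics with a
known monotone structure–function link, no artifacts, no epileptiform
activity, no vasculature, no head motion, no registration error, and
contacts that are all cleanly in white matter.  Passing null and
recovery checks therefore demonstrates that the *pipeline* is unbiased
and sensitive under its own assumptions — that the statistics are
correctly implemented and calibrated — not that real white-matter BOLD
FC has an electrophysiological basis; that question needs the clinical
data the synthetic study stands in for.  Known limitations: the linear
model cannot express frequency-specific coupling differences between
bands (all bands inherit the same structural pattern); envelope-based
BOLD loses the sign of neural correlations; and the common average
reference couples channels weakly under the null, which the calibration
test bounds empirically rather than eliminating.
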