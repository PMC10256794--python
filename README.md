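# wmcoupling

Structure–function coupling of white-matter BOLD and SEEG functional
connectivity.

## The scientific problem

Resting-state fMRI detects blood-oxygenation-level-dependent (BOLD)
signals not only in gray matter but also in white matter, where their
correlations organize into networks.  Whether white-matter BOLD
functional connectivity (FC) reflects genuine electrophysiological
synchronization — rather than vascular or motion artifact — can be
tested in patients implanted with stereotactic-EEG (SEEG) depth
electrodes, whose contacts record local field potentials (LFPs) inside
white matter at the same locations where BOLD is sampled, and whose
diffusion tractography yields the streamline counts connecting those
locations.

`wmcoupling` implements that three-way comparison as a reusable
pipeline for researchers working on structure–function coupling:

* **SEEG FC** — condition the LFP (0.5–300 Hz third-order Butterworth
  bandpass, power-line band-stops, bad-channel exclusion, white-matter
  common average reference, averaging of ten 6 s segments), filter into
  seven bands (1–4, 4–8, 8–13, 13–30, 30–40, 40–70, 70–170 Hz), and
  correlate channel pairs (Pearson r, or band-averaged magnitude-squared
  coherence).
* **BOLD FC** — extract sphere-ROI time series (19 voxels ≈ 3 mm radius
  at 2 mm isotropic; 7 and 27 as variants) at each contact, drop initial
  volumes, detrend, regress confounds, bandpass 0.01–0.2 Hz, and
  correlate ROI pairs.
* **SC** — count the tractography streamlines interconnecting each pair
  of contact sphere ROIs (radius one voxel).
* **Coupling statistics** — for edge vectors x, y over the n(n−1)/2
  contact pairs, regress the Euclidean distance d out of each by OLS
  (FC and SC both decay with distance) and evaluate Spearman's rank
  correlation ρ of the residuals, with a two-sided p from the
  t-approximation on n−2 df; structure–function comparisons are
  restricted to pairs with nonzero SC.  Benjamini–Hochberg FDR is
  applied jointly across all participants and bands within each
  comparison family, and per-band medians of ρ summarize the group.

Because clinical multimodal recordings cannot be shipped with a
package, `wmcoupling` includes a **synthetic study generator** with
known ground truth: contacts scattered in a box, a sparse
distance-dependent structural network realized as explicit streamline
polylines, LFP-like signals from a stable linear stochastic network
model x[t] = A x[t−1] + e[t] whose pairwise synchronization is a
monotone function of streamline count, and BOLD-like signals obtained
by convolving a slow activity envelope with a canonical double-gamma
hemodynamic response.  Every stage of the pipeline is therefore
testable at desk scale, including null calibration (no coupling ⇒ FDR
discoveries at the nominal rate) and parameter recovery (coupling 0.5 ⇒
positive, significant coupling in essentially all bands).

## Worked example

`examples/05_coupling_study.py` runs five synthetic participants
(20 contacts, 15 s LFP, 120 BOLD volumes, coupling strength 0.5)
through the full pipeline:

```
  comparison     band  median_r  n_participants  n_significant
bold_vs_seeg    1-4Hz  0.300286               5              5
  sc_vs_seeg    1-4Hz  0.324597               5              2
bold_vs_seeg    4-8Hz  0.241362               5              4
  sc_vs_seeg    4-8Hz  0.415271               5              4
bold_vs_seeg   8-13Hz  0.453580               5              5
  sc_vs_seeg   8-13Hz  0.509677               5              3
bold_vs_seeg  13-30Hz  0.444034               5              5
  sc_vs_seeg  13-30Hz  0.682897               5              5
bold_vs_seeg  30-40Hz  0.321945               5              5
  sc_vs_seeg  30-40Hz  0.629557               5              5
bold_vs_seeg  40-70Hz  0.417715               5              5
  sc_vs_seeg  40-70Hz  0.718719               5              5
bold_vs_seeg 70-170Hz  0.453667               5              5
  sc_vs_seeg 70-170Hz  0.855311               5              5
  sc_vs_bold     bold  0.479310               5              4

completed 5/5 participants
```

`median_r` is the across-participant median of the
distance-residualized Spearman coupling for that comparison and band;
`n_significant` counts participants whose coupling survives FDR at
α = 0.05.  With ground-truth coupling switched on, BOLD FC tracks SEEG
FC in every band and both track the structural network — the pattern
the pipeline is designed to detect.

The other examples demonstrate individual capabilities: generating a
participant (01), SEEG conditioning and band FC (02), sphere-ROI BOLD
extraction (03), and streamline counting (04).

A thin CLI mirrors the library:

```bash
wmcoupling synth --out part/ --seed 1
wmcoupling seeg-fc --in part/seeg_panel.tsv --out fc/ --window 1.5
wmcoupling sc --streamlines part/streamlines.txt --contacts part/contacts.tsv --out sc.tsv
wmcoupling run --participants 5 --coupling 0.5 --seed 1 --out study/
```

## What this is not

No tractography, registration, spatial normalization, artifact
templating or seizure analysis — the package consumes localized
contacts, streamlines and gridded volumes, and focuses on the
connectivity and coupling statistics.  See `docs/methods.md` for the
model details, parameter choices and known limitations.
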