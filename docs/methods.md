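# Methods

This package analyzes the modulation of brain oscillations by repeated
continuous theta-burst stimulation (cTBS) in a within-subject
active/sham crossover: resting-state wake EEG at six timepoints (before
and after each of three stimulation sessions, T1–T6), followed by an
overnight polysomnogram. Because no patient data are distributable, a
synthetic-study generator reproduces the design with known injected
effects, and every analysis stage is validated against that ground
truth or against closed-form/brute-force oracles.

## Preprocessing

Wake recordings (1000 Hz, the 21-channel 10–20 subset Fp1…P8) and sleep
EEG (512 Hz, 6- or 19-channel montage) pass through the same chain:
common-average reference over the analysis channels, 1–60 Hz band-pass
(4th-order Butterworth), 50 Hz notch (IIR, Q = 30), all applied
forward–backward so the net phase shift is zero — a hard requirement
ahead of phase-locking estimation. The signal is then cut into
consecutive non-overlapping epochs (5 s wake, 30 s sleep); an epoch is
rejected iff any retained channel strictly exceeds ±100 μV. The
trailing partial epoch is discarded. Channel-wise crossings are
retained so sleep analyses can drop channels artifactual on strictly
more than 50 % of epochs and recompute epoch rejection on the
survivors. Conventions pinned here, where the underlying protocol is
silent: the reference is computed over the analysis subset (selection
precedes referencing, and the two do not commute); the amplitude rule
is applied to the filtered, re-referenced signal; both the 100 μV and
the 50 % rule are strict inequalities.

Note the zero-phase band-pass leaves a designed stop-band residue: for
white noise, out-of-band power is ~3 % of in-band power (the |H|⁴
response of the 4th-order design). Tests pin the measured residue to
this computed response rather than to an arbitrary attenuation figure.

## Spectral analysis

PSD is estimated by Welch's averaged modified periodogram: one
Hamming-windowed periodogram per kept epoch — the segment is the whole
epoch, no sub-windowing, no overlap — averaged across epochs, density
normalization (unit-variance white noise integrates to 1 over
[0, Nyquist]), frequency resolution 1/epoch length (0.2 Hz wake,
1/30 Hz sleep). Band power is the mean PSD in μV²/Hz over half-open
bands: delta [1, 4), theta [5, 8), alpha [8, 13), beta [13, 30), gamma
[30, 60) Hz. The half-open convention resolves the shared 8 Hz edge in
favor of alpha; the conventional 4–5 Hz gap is kept as printed in the
clinical literature (bins in [4, 5) belong to no band). Mean-vs-
integral is inert for within-band comparisons but pinned. Statistics
run on raw band power by default; a log10 flag exists.

ΔPSD is the post-minus-baseline change (T6 − T1) per subject at one
electrode (F4, the stimulation target, by default), z-scored across
subjects within each band using the population (n-denominator) SD.
Zero across-subject SD is reported as an explicit degenerate condition
(NaN z-scores, band listed), never silently imputed.

## Connectivity

Phase-locking value (PLV): each epoch is zero-phase band-pass filtered
to the band, the instantaneous phase taken from the Hilbert analytic
signal, and 10 % of samples at each epoch edge excluded from averaging
(filter/transform edge distortion). Per epoch and channel pair the PLV
is |mean_t exp(i Δφ)|; the matrix entry is the mean of per-epoch moduli
(not the modulus of the grand mean), respecting the epoched structure
of resting-state data. The estimator is amplitude- and lag-invariant,
symmetric, unit-diagonal, bounded in [0, 1].

The estimator's null is biased above zero: T iid phase samples give an
expected modulus of (1/2)√(π/T), and band-limited signals hold far
fewer independent phase samples than time samples (for 5-s theta epochs
the per-epoch null is ≈ 0.23, not 0.03). Coupling detection therefore
uses null quantiles from matched simulation — independent band-limited
noise pairs with the same band, sampling rate, epoch length and count —
never the iid formula.

## Network properties

PLV matrices (21 × 21 wake; sleep montages of ≥ 6 channels) are treated
as weighted graphs with no thresholding; the unit diagonal is removed.
Implemented in the brain-connectivity-toolbox weighted formulations:
Onnela clustering coefficient on weights normalized by the off-diagonal
maximum; characteristic path length and global efficiency from Dijkstra
shortest paths over connection lengths 1/w (disconnected pairs are
excluded from CPL with a logged count and contribute 0 to efficiency —
a safeguard only, since PLV graphs are complete); local efficiency as
the weighted neighbor-subgraph variant (Rubinov & Sporns 2010 lineage),
with nodes of degree < 2 assigned 0. The Onnela variant and the 1/w
length transform are the toolbox defaults; Barrat/Zhang–Horvath
clustering and log-length transforms were rejected for fidelity to the
named toolbox. All metrics are verified to 1e-12 against exhaustive
triple-summation / Floyd–Warshall oracles on 5–6-node graphs.

## Statistics

* Paired two-tailed t-tests per unit (electrode or edge), with
  Benjamini–Hochberg FDR applied within one family = one band × one
  comparison (21 electrodes or 210 edges), matching per-panel
  reporting. Units with zero within-pair variance are reported
  degenerate and excluded from the family (never assigned p = 1). The
  stricter p_FDR < 0.005 network-figure threshold is carried as a
  display threshold distinct from the 0.05 analysis threshold.
* Two-way repeated-measures ANOVA (intervention × timepoint, both
  within-subject) via the classical sums-of-squares decomposition, each
  effect tested against its own subject-interaction error term; no
  sphericity correction by default. Exactly constant or perfectly
  additive data are 0/0 cases and reported as F = 0, p = 1 under a
  numerical-noise guard (general-purpose ANOVA routines return
  meaningless ratios there).
* Wake→sleep coupling: Pearson correlation (Spearman by flag) between
  ΔPSD z-scores and first-cycle NREM band power, two-tailed p from the
  t transform of r.
* A priori sample size: smallest n with paired-t power ≥ the target,
  computed by iterating the noncentral t distribution (noncentrality
  d√n, df n−1). The design anchor dz = 0.5, α = 0.05, 1−β = 0.9 gives
  n = 44.

## Sleep analysis

Hypnograms are 30-s AASM stage sequences (W, N1, N2, N3, R).
Architecture: TIB is the lights interval; TST the staged sleep minutes;
SL lights-off to first non-W epoch; WASO counts W from sleep onset to
lights-on (no final-awakening trimming — disclosed convention);
SE = TST/TIB. NREM–REM cycles follow the Feinberg–Floyd criteria with
parameters pinned at NREM period ≥ 15 min and REM period ≥ 5 min, the
first REM period exempt from its minimum; non-NREM interruptions
shorter than 5 min do not split a NREM period (a practical tolerance
required by real hypnograms, exposed as a parameter and not attributed
to the published criteria). A REM run below its minimum is treated as
an interruption; a trailing NREM period without terminal REM forms an
incomplete final cycle only behind a flag (off by default).

First-cycle NREM spectra: the N1/N2/N3-staged epochs inside cycle 1's
NREM span (interleaved R or W epochs excluded) are screened with the
sleep artifact rules and passed to the spectral and connectivity
modules. PLV is computed only on montages of ≥ 6 channels; the montage
size is recorded in the output metadata.

## Synthetic-data generator

Each channel is a sum of five band-limited Gaussian noise components
produced by filtering white noise with the same band edges the spectral
module uses, closing the loop between generator and analyzer. The
white-noise variance is pre-compensated by the filter's mean in-band
|H|⁴ response, so a configured level *is* the expected Welch band PSD
(recovered within 10 % at 300 s in the calibration test). Components
are padded (4 cycles of the band's lower edge per end) and trimmed
after filtering so filtfilt edge transients of the pre-filter white
noise never reach the output.

Injected study effects:

* **Power ramp.** In the active arm, delta and theta components are
  scaled by a non-decreasing six-point gain ramp, default
  (1.0, 1.1, 1.1, 1.2, 1.2, 1.3) — +30 % at T6; T1 is pinned at gain 1.
  Each subject carries a responsiveness factor u ~ N(1, 0.2²)
  multiplying the ramp increment, and a lognormal (σ = 0.2) baseline
  power scale shared across arms and timepoints. The published study
  reports no effect sizes, so these are free parameters chosen once as
  plausible for band-power modulation studies; they are study
  conditions, not estimates.
* **Coupling.** A configured channel pair (default F4–O1, delta and
  theta, strength 0.6) shares a narrowband source mixed as
  √(1−c)·own + √c·shared, preserving band power exactly while mapping c
  monotonically (not identically) to PLV; c = 1 drives PLV → 1. The
  active arm ramps the strength by (0, 0.2, …, 1.0) × c across T1–T6;
  the sham arm is uncoupled.
* **Artifacts.** 200-ms raised-cosine pulses of ±300 μV on one random
  channel at 2 events/min (Poisson), with the affected epoch indices
  recorded. The amplitude is sized so the pulse still clears the
  ±100 μV rule after referencing and filtering strip its sub-1 Hz
  content (filtered peak ≈ 228 μV).
* **Line noise.** A 50 Hz sinusoid, default 5 μV.
* **Sleep.** A semi-Markov hypnogram (W latency, then NREM/REM cycles
  with random run lengths; the first NREM period is guaranteed
  ≥ 15 min) drives stage-dependent synthesis with multipliers enforcing
  delta N3 > N2 > N1 > R, W (N3 delta = 10× wake). After the active
  arm, the subject's responsiveness also scales sleep delta/theta by
  the T6 wake gain, which is the ground truth behind the wake→sleep
  correlation.

Reproducibility: one global seed expands into per-(subject, arm,
timepoint) substreams through `numpy.random.SeedSequence` spawn keys, a
counter scheme that makes every recording independently and
deterministically regenerable; identical configurations are
byte-identical after serialization.

What the generator does **not** emulate: 1/f aperiodic background,
ocular/muscle artifact morphology, TMS pulse artifacts, non-stationary
drowsiness drift within recordings, volume-conduction mixing beyond the
configured coupling, or biophysical (neural-mass) dynamics. Passing
parameter-recovery tests therefore demonstrates that the pipeline
recovers effects of the modeled kind at the configured sizes — not that
the published clinical findings reproduce.

## Problem sizes and numerics

The defaults mirror the study design: 20 subjects (the published power
analysis asked ~44; 41 enrolled), 300-s wake recordings, 480-min
nights. Tests and drivers run scaled-down sizes chosen for their
purpose and stated locally: 60–120 s recordings in unit tests, 90-min
nights (enough for the first cycle plus REM), a 50-study × 6-subject
type-I-error calibration, and the full 20-subject / 300-s conditions in
the parameter-recovery test and acceptance script. Monte-Carlo
tolerances are set for these sizes (e.g. band-power calibration ±10 %
at 300 s; iid-null PLV within 5 % over 1000 repetitions). EDF export
quantizes to 16 bits over a symmetric physical range (step
2·max|x|/65535); round-trips are asserted to that precision.

## Known limitations

* The Welch detrend is scipy's per-segment constant detrend; with the
  1 Hz high-pass upstream this is inert, but raw unfiltered input with
  drift will differ slightly from a no-detrend implementation.
* Whether the original analysis averaged PLV across epochs or
  concatenated them is not stated; mean-of-moduli is pinned here and
  its upward null bias handled by matched-simulation nulls.
* Sleep synthesis switches band powers at stage-run boundaries, which
  introduces (physiologically plausible) spectral discontinuities
  between runs.
* Only Feinberg–Floyd cycle scoring is implemented; alternative cycle
  definitions (e.g. skipped-first-REM variants beyond the exemption)
  are out of scope.
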