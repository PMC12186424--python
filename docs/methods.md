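# Methods

## Problem and pipeline

`locomode` implements event-driven locomotion-mode decoding for lower-limb
prosthesis control. A session records 8 surface-EMG channels, 3 six-axis
IMUs (18 axes) and one uniaxial ground-reaction-force (GRF) channel at a
common 2000 Hz clock, together with the conductor's raw mode-transition
markers and the participant's body weight. The pipeline is:

1. **EMG conditioning** — a 50 Hz notch of total order 6 (three cascaded
   second-order notch sections, Q = 30) followed by a Butterworth bandpass
   with 20 and 500 Hz edges (design order 4). Causal filtering is the
   default everywhere so that the batch path and the sample-by-sample
   replay path execute identical arithmetic; a zero-phase option exists for
   purely offline exploration but is never used by the replay. IMU and GRF
   channels are not filtered; the GRF channel is thresholded raw.
2. **Gait events** — heel contact (HC) at each upward crossing of
   10 % of body weight on the GRF channel, toe-off (TO) at each downward
   crossing, debounced by requiring the new phase to persist for
   `min_phase_s` (default 0.10 s). Debouncing is not strictly needed on a
   clean insole signal but guards against chatter near the threshold; it
   also bounds the emission latency of the streaming detector by
   `min_phase_s`. Event kinds alternate by construction.
3. **Marker realignment** — each raw marker is projected forward to the
   first event, at or after it, of the kind its transition requires:
   toe-off for stair-ascent transitions, heel contact for stair- and
   ramp-descent transitions. The rule for ramp-ascent transitions is not
   dictated by the biomechanics literature we follow; we realign them to
   the next toe-off for symmetry with the other ascent mode, and the rule
   table is overridable per transition. The realigned instants are the
   *critical timings*; the mode timeline switches inclusively at each
   critical event and is the ground truth for labels and scoring.
4. **Windows** — at every eligible event, a 300 ms segment (200 ms before
   to 100 ms after) is cut into four 200 ms windows stepped by 30 ms
   (offsets −200, −170, −140, −110 ms; 400 samples each at 2000 Hz).
   Events closer than 200 ms to the start or 100 ms to the end of the
   recording are skipped rather than zero-padded.
5. **Features** — per EMG channel: mean absolute value, waveform length,
   zero crossings and slope-sign changes (ZC/SSC accept an amplitude
   deadband, default 0 for exactness; classical usage sometimes uses small
   positive thresholds). Per IMU axis and for GRF: mean, max, min and
   sample (N−1) standard deviation. Channel-major, feature-minor ordering;
   8·4 + 18·4 + 1·4 = 108 features on the full montage.
6. **Classifier bank** — one LDA model per (current mode, event kind):
   5 × 2 = 10 models. Walking is the hub of the transition graph:
   `allowed(W) = {W, RA, RD, SA, SD}` and `allowed(M) = {M, W}` otherwise,
   so two non-walking modes can never hand over directly. At each event the
   model matching the decoder's current mode and the event kind classifies
   the four windows; the majority wins and a 2–2 tie retains the current
   mode (the safety-conservative choice for a prosthesis).

## LDA details

Classes are modeled as Gaussians with a shared covariance. The pooled
within-class covariance S (unbiased, N−K denominator) is regularized as
S + λ·(trace(S)/d)·I with λ = 1e-3 by default — with 108 features a
per-cell sample count in the hundreds makes the raw pooled estimate
ill-conditioned. The discriminant of class k is

    g_k(x) = xᵀ S⁻¹ μ_k − ½ μ_kᵀ S⁻¹ μ_k + ln π_k

with priors π taken from class frequencies (a uniform-priors flag exists
because steady-state windows vastly outnumber transition windows).
Training a cell requires at least two samples per class. The realignment
rules make four of the ten cells single-class *by construction*: a mode
entered and left at toe-offs (both ascent modes) never exhibits a
non-self target at heel contacts, and symmetrically for the descent modes
at toe-offs. Those cells hold a degenerate constant model that predicts
their only observed class — which is also the only legal steady behavior
there; `strict_cells=True` turns this into an error instead. An 80/20
random split (stratified by cell and label) mirrors the deployment
training regime; cross-validated reporting uses stratified k-fold (k = 10)
within each cell, reducing the fold count with a warning when the rarest
class is smaller than k.

## Evaluation metrics

*Transition period*: the span from 2 gait events before to 3 events after
a critical timing (the widened variant uses 4 and 5). *Online window
error*: the percentage of wrongly-voted windows at the events inside the
period. *Detection*: the first event at or after the period start whose
majority output equals the target mode; a transition counts as correct
only if that event lies inside the period, and one never detected within
the period plus a 3-event grace horizon is scored as 100 % error for that
occurrence. *Prediction time*: detection time minus critical timing, in
ms; negative values are anticipatory. Truncated periods at recording edges
are flagged and excluded from aggregates. Per-transition offline errors
attribute each cross-validated window to the transition period containing
its event; the overall offline error also counts steady-state windows.

Widening the period can never lose a detection (the narrow period is a
subset of the wide one). The window-error *ratio*, however, is only
guaranteed to fall when errors concentrate around the transition; with
scattered vote noise the extra outer events can raise it slightly. The
test suite therefore asserts the detection superset on every trace, the
ratio ordering where separability is high, and a seed-averaged ordering at
moderate separability.

## Synthetic sessions

The simulator emulates a closed walking circuit (one lap =
W → RA → W → SD → W → SA → W → RD) with `strides_per_surface` strides per
surface (default 5), stride duration 1.2 s and stance fraction 0.6. Per
stride the GRF is a trapezoidal stance pulse peaking at 1.1 × body weight
with 30 ms edge ramps; the conventional 10 %-body-weight crossings — which
sit ramp/11 ≈ 2.7 ms inside the edges — are the recorded true event
times, so the detector recovers them to within a sample. EMG is
amplitude-modulated band-limited (20–450 Hz) Gaussian noise: a per-channel
raised-cosine gait-phase envelope scaled by a mode gain
max(1 + δ·P[mode, ch], 0), plus broadband sensor noise and a 50 Hz line
component that exercises the notch. IMU axes are stride-locked sinusoids
with distinct harmonics and phases per axis and placement, amplitude-scaled
by an analogous mode gain. The signature matrices P are fixed constants
with a zero walking row, so the separability parameter δ scales the
difference from level walking; δ = 0 (with `imu_informative=False`) is an
exact null in which window features are mode-independent. A
`complementary_modalities` variant zeroes the descent rows of the EMG
signatures and the ascent rows of the IMU signatures, producing a dataset
in which neither sensor alone separates all five modes but their fusion
does — the designed condition for sensor-fusion experiments.

Two timing choices matter. Raw markers are placed `reaction_delay_s`
(0.15 s, plus up to 50 ms of seeded jitter) *before* each surface
boundary, emulating the conductor tagging just ahead of the participant,
so forward realignment is genuinely exercised. Mode-dependent signal
character switches `anticipation_s` (0.30 s) before each nominal critical
timing: muscle activation and segment kinematics change in preparation
for a transition, not at the instant the prosthetic heel meets the new
surface. The value 0.30 s covers the full 200 ms look-back of the windows
anchored at the critical event (with margin inside the 0.48 s swing), so
the labeling convention is learnable — without anticipation the critical
event's windows would contain almost no new-mode signal. This
consistency depends on the default stride geometry; markedly shorter
strides would shrink the margin.

What the simulator does **not** model: multi-step biomechanical
transitions, electrode shift and sweat artifacts, inter-stride timing
variability, cross-talk between muscles, or any physics-based gait
dynamics. Passing the recovery tests therefore demonstrates that the
pipeline's machinery — filtering, event detection, realignment, labeling,
the phase-dependent bank and the scoring — is internally consistent and
recovers planted structure; it does not certify performance on real
recordings.

## Problem sizes and numerics

The end-to-end recovery experiments use the two-session protocol at its
stated scale (30 training rounds, 15 evaluation rounds, five seeds); the
ordering and ablation experiments use shorter sessions (3–6 rounds) with
the same structure, which keeps the whole suite within a normal CI run
while leaving hundreds of transitions per experiment. Streaming filtering
carries `scipy.signal.sosfilt` state across chunks and is bit-for-bit
equal to whole-signal causal filtering; the streaming event detector is
the batch detector (one chunk) by construction. Model files are a single
JSON with row-major matrices and feature names; floats serialize via
`repr` and round-trip exactly. Ties in the argmax of the discriminant
resolve to the earliest class in the fixed mode order (W, RA, RD, SA,
SD), making predictions deterministic.
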