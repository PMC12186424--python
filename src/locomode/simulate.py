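"""Seeded synthetic multimodal gait sessions with ground truth.

The generator emulates a walking circuit that alternates level walking with
ramp ascent, stair descent, stair ascent and ramp descent (one lap =
W, RA, W, SD, W, SA, W, RD), with a fixed number of strides per surface.

Signal model, per stride of duration ``stride_s`` (stance fraction
``stance_fraction``, heel contact at the stride start, toe-off at the end
of stance):

* **GRF** — trapezoidal stance pulses peaking at 1.1 x body weight, zero in
  swing (short linear ramps at both edges keep the 10 %-body-weight
  crossings within ~3 ms of the nominal event times).
* **EMG** (8 channels) — amplitude-modulated band-limited Gaussian noise,
  the standard surrogate for interference-pattern surface EMG: a gait-phase
  envelope per channel, scaled by a mode-dependent gain ``max(1 + delta *
  P[mode, ch], 0)``, multiplying a 20-450 Hz noise carrier; plus broadband
  sensor noise and a 50 Hz line component (which the preprocessing notch
  must remove).
* **IMU** (3 units x 6 axes) — stride-locked sinusoids with per-axis
  harmonic and phase, amplitude scaled by a mode-dependent gain when
  ``imu_informative``; plus broadband noise.

``separability_delta`` (delta) scales how strongly the modes differ; at
delta = 0 (and ``imu_informative=False``) the per-window feature
distributions are mode-independent by construction.

Mode-dependent signal character switches ``anticipation_s`` before each
nominal critical timing — the gait event the conductor's marker realigns to
— emulating the anticipatory muscle and kinematic changes that precede the
biomechanical transition. Raw markers are placed ``reaction_delay_s``
(plus a small random extra) *before* each surface boundary, emulating the
conductor tagging just before the participant enters the new surface, so
marker realignment is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .events import EventKind, GaitEvent
from .labeling import realign_kind_for
from .session import (
    ChannelSpec,
    LocomotionMode,
    Modality,
    ModeMarker,
    SessionRecording,
)

__all__ = ["SimConfig", "GroundTruth", "build_montage", "generate_session", "make_dataset"]

_DEFAULT_PATH = (
    LocomotionMode.W,
    LocomotionMode.RA,
    LocomotionMode.W,
    LocomotionMode.SD,
    LocomotionMode.W,
    LocomotionMode.SA,
    LocomotionMode.W,
    LocomotionMode.RD,
)

_EMG_MUSCLES = [
    "semitendinosus",
    "biceps_femoris_long",
    "biceps_femoris_short",
    "tensor_fasciae_latae",
    "rectus_femoris",
    "vastus_lateralis",
    "vastus_medialis",
    "gracilis",
]
_IMU_PLACEMENTS = ["thigh", "shank", "foot"]

# Fixed mode-signature matrices (modes x channels/axes), drawn once from a
# frozen internal stream; the walking row is zero so delta scales the
# *difference* from level walking. Entries lie in [-0.5, 1] so gains stay
# non-negative for delta <= 2.
_sig_rng = np.random.default_rng(19_730_214)
_EMG_SIG = _sig_rng.uniform(-0.5, 1.0, size=(5, 8))
_EMG_SIG[0] = 0.0
_IMU_SIG = _sig_rng.uniform(-0.5, 1.0, size=(5, 18))
_IMU_SIG[0] = 0.0
_MODE_ROW = {m: i for i, m in enumerate(
    [LocomotionMode.W, LocomotionMode.RA, LocomotionMode.RD,
     LocomotionMode.SA, LocomotionMode.SD])}

# Complementary variants for fusion experiments: EMG distinguishes only the
# ascent modes, the IMU only the descent modes, so neither sensor alone can
# separate all five modes but the combination can.
_EMG_SIG_COMPL = _EMG_SIG.copy()
_EMG_SIG_COMPL[[_MODE_ROW[LocomotionMode.RD], _MODE_ROW[LocomotionMode.SD]]] = 0.0
_IMU_SIG_COMPL = _IMU_SIG.copy()
_IMU_SIG_COMPL[[_MODE_ROW[LocomotionMode.RA], _MODE_ROW[LocomotionMode.SA]]] = 0.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    fs_hz: float = 2000.0
    body_weight_n: float = 700.0
    n_rounds: int = 30
    path: tuple[LocomotionMode, ...] = _DEFAULT_PATH
    strides_per_surface: int = 5
    stride_s: float = 1.2
    stance_fraction: float = 0.6
    separability_delta: float = 1.0
    noise_sigma: float = 0.05
    emg_informative: bool = True
    imu_informative: bool = True
    reaction_delay_s: float = 0.15
    anticipation_s: float = 0.30
    grf_ramp_s: float = 0.03
    complementary_modalities: bool = False

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ConfigurationError("n_rounds must be >= 1")
        if self.strides_per_surface < 4:
            raise ConfigurationError(
                "strides_per_surface must be >= 4 (transition periods need surrounding events)"
            )
        if self.separability_delta < 0:
            raise ConfigurationError("separability_delta must be >= 0")
        if not (0 < self.stance_fraction < 1):
            raise ConfigurationError("stance_fraction must lie in (0, 1)")
        if len(self.path) < 2:
            raise ConfigurationError("path needs at least two surfaces")
        n = len(self.path)
        for i, m in enumerate(self.path):
            nxt = self.path[(i + 1) % n]
            if m == nxt:
                raise ConfigurationError("path must not repeat a surface consecutively")
            if m != LocomotionMode.W:
                prev = self.path[i - 1]
                if prev != LocomotionMode.W or nxt != LocomotionMode.W:
                    raise ConfigurationError(
                        "path must alternate through walking (every non-W surface "
                        "preceded and followed by W)"
                    )


@dataclass
class GroundTruth:
    """Simulator oracle: true events, markers and the labeled mode timeline."""

    true_events: list[GaitEvent]
    true_markers: list[ModeMarker]           # at the stride boundary entering each surface
    mode_schedule: list[tuple[float, LocomotionMode]]  # switch times (critical timings)
    initial_mode: LocomotionMode = LocomotionMode.W
    stance_intervals: list[tuple[float, float]] = field(default_factory=list)

    def mode_at(self, t: float) -> LocomotionMode:
        mode = self.initial_mode
        for ts, m in self.mode_schedule:
            if ts <= t:
                mode = m
            else:
                break
        return mode

    def to_dict(self) -> dict:
        return {
            "initial_mode": self.initial_mode.value,
            "true_events": [
                {"sample_index": e.sample_index, "time_s": e.time_s, "kind": e.kind.value}
                for e in self.true_events
            ],
            "true_markers": [m.to_dict() for m in self.true_markers],
            "mode_schedule": [{"time_s": t, "mode": m.value} for t, m in self.mode_schedule],
        }


def build_montage() -> list[ChannelSpec]:
    """The study montage: 8 EMG + 3 six-axis IMUs + 1 GRF channel."""
    channels = [
        ChannelSpec(f"emg_{m}", Modality.EMG, placement=m.replace("_", " "), units="mV")
        for m in _EMG_MUSCLES
    ]
    for place in _IMU_PLACEMENTS:
        for axis in "xyz":
            channels.append(ChannelSpec(f"acc_{place}_{axis}", Modality.ACC, axis, place, "g"))
        for axis in "xyz":
            channels.append(
                ChannelSpec(f"gyr_{place}_{axis}", Modality.GYR, axis, place, "deg/s")
            )
    channels.append(ChannelSpec("grf_heel", Modality.GRF, placement="prosthetic heel", units="N"))
    return channels


def _emg_gain(
    mode_rows: np.ndarray, delta: float, informative: bool, complementary: bool = False
) -> np.ndarray:
    if not informative or delta == 0:
        return np.ones((mode_rows.size, 8))
    sig = _EMG_SIG_COMPL if complementary else _EMG_SIG
    return np.maximum(1.0 + delta * sig[mode_rows], 0.0)


def _imu_gain(
    mode_rows: np.ndarray, delta: float, informative: bool, complementary: bool = False
) -> np.ndarray:
    if not informative or delta == 0:
        return np.ones((mode_rows.size, 18))
    sig = _IMU_SIG_COMPL if complementary else _IMU_SIG
    return np.maximum(1.0 + delta * sig[mode_rows], 0.0)


def generate_session(config: SimConfig) -> tuple[SessionRecording, GroundTruth]:
    """Generate one seeded session plus its ground truth."""
    fs = config.fs_hz
    stance = config.stride_s * config.stance_fraction
    sps_count = config.strides_per_surface
    surfaces = list(config.path) * config.n_rounds
    lead_in = 0.4  # recording opens mid-swing so the first event is a heel contact
    tail = 0.5

    # Stride grid and per-surface boundaries. The GRF pulse ramps from 0 to
    # 1.1 x body weight, so the conventional 10 %-body-weight load/unload
    # instants sit ramp/11 inside each edge; those crossings are the
    # observable (and therefore "true") heel-contact / toe-off times.
    n_strides = len(surfaces) * sps_count
    hc_nominal = lead_in + config.stride_s * np.arange(n_strides)
    to_nominal = hc_nominal + stance
    cross = config.grf_ramp_s / 11.0
    hc_times = hc_nominal + cross
    to_times = to_nominal - cross
    boundaries = [hc_nominal[j * sps_count] for j in range(len(surfaces))]

    duration = float(hc_nominal[-1] + config.stride_s + tail)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # True events at the threshold crossings.
    events: list[GaitEvent] = []
    for hc, to in zip(hc_times, to_times):
        events.append(GaitEvent(int(round(hc * fs)), hc, EventKind.HC))
        events.append(GaitEvent(int(round(to * fs)), to, EventKind.TO))
    events.sort(key=lambda e: e.sample_index)

    # Markers, critical timings (mode schedule) and the signal-switch times.
    rng = np.random.default_rng(config.seed)
    markers: list[ModeMarker] = []
    true_markers: list[ModeMarker] = []
    schedule: list[tuple[float, LocomotionMode]] = []
    switch_times: list[tuple[float, LocomotionMode]] = []
    current = surfaces[0]
    for j in range(1, len(surfaces)):
        b = boundaries[j]
        to_mode = surfaces[j]
        kind = realign_kind_for(current, to_mode)
        stride0 = j * sps_count  # first stride on the new surface
        critical = (
            hc_times[stride0] if kind == EventKind.HC else to_times[stride0]
        )
        markers.append(
            ModeMarker(b - config.reaction_delay_s - rng.uniform(0.0, 0.05), to_mode)
        )
        true_markers.append(ModeMarker(float(b), to_mode))
        schedule.append((float(critical), to_mode))
        switch_times.append((float(critical - config.anticipation_s), to_mode))
        current = to_mode

    # Per-sample mode row index for the *signal* (anticipatory) timeline.
    sw_t = np.array([s for s, _ in switch_times])
    sw_modes = [surfaces[0]] + [m for _, m in switch_times]
    sample_mode_idx = np.searchsorted(sw_t, t, side="right")
    mode_rows = np.array([_MODE_ROW[m] for m in sw_modes])[sample_mode_idx]

    # Stride phase in [0, 1).
    phase = np.mod((t - lead_in) / config.stride_s, 1.0)

    channels = build_montage()
    signals = np.zeros((len(channels), n))

    # EMG: envelope x mode gain x band-limited carrier + sensor noise + 50 Hz line.
    emg_gain = _emg_gain(mode_rows, config.separability_delta, config.emg_informative,
                         config.complementary_modalities)
    carrier_sos = sps.butter(4, [20.0, min(450.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    for c in range(8):
        center = c / 8.0
        bump = 0.5 * (1.0 + np.cos(2.0 * np.pi * (phase - center)))
        envelope = 0.2 + 0.8 * bump**2
        carrier = sps.sosfilt(carrier_sos, rng.standard_normal(n))
        carrier /= max(carrier.std(), 1e-12)
        line = 0.15 * np.sin(2.0 * np.pi * 50.0 * t + 0.7 * c)
        signals[c] = (
            emg_gain[:, c] * envelope * carrier
            + config.noise_sigma * rng.standard_normal(n)
            + line
        )

    # IMU: stride-locked sinusoids, distinct harmonic/phase per axis and placement.
    imu_gain = _imu_gain(mode_rows, config.separability_delta, config.imu_informative,
                         config.complementary_modalities)
    for a in range(18):
        ch = 8 + a
        base_amp = 1.0 if channels[ch].modality == Modality.ACC else 2.0
        harmonic = 1 + (a % 3)
        ph = 2.0 * np.pi * a / 18.0 + 0.9 * (a // 6)
        signals[ch] = (
            base_amp
            * imu_gain[:, a]
            * np.sin(2.0 * np.pi * harmonic * phase + ph)
            + config.noise_sigma * rng.standard_normal(n)
        )

    # GRF: trapezoidal stance pulses, zero in swing, no noise.
    peak = 1.1 * config.body_weight_n
    ramp = config.grf_ramp_s
    knots_t, knots_v = [], []
    for hc, to in zip(hc_nominal, to_nominal):
        knots_t += [hc, hc + ramp, to - ramp, to]
        knots_v += [0.0, peak, peak, 0.0]
    signals[-1] = np.interp(t, knots_t, knots_v, left=0.0, right=0.0)

    session = SessionRecording(
        fs_hz=fs,
        signals=signals,
        channels=channels,
        markers=markers,
        body_weight_n=config.body_weight_n,
        initial_mode=surfaces[0],
        meta={"simulated": True, "seed": config.seed, "n_rounds": config.n_rounds},
    )
    truth = GroundTruth(
        true_events=events,
        true_markers=true_markers,
        mode_schedule=schedule,
        initial_mode=surfaces[0],
        stance_intervals=[(float(hc), float(to)) for hc, to in zip(hc_times, to_times)],
    )
    return session, truth


def make_dataset(
    config: SimConfig,
    n_train_rounds: int = 30,
    n_test_rounds: int = 15,
) -> tuple[list[tuple[SessionRecording, GroundTruth]], list[tuple[SessionRecording, GroundTruth]]]:
    """Disjoint seeded train/test sessions emulating the two-session protocol
    (a training-data collection session, then a real-time evaluation one)."""
    if n_train_rounds < 1 or n_test_rounds < 1:
        raise ConfigurationError("round counts must be >= 1")
    train_cfg = replace(config, n_rounds=n_train_rounds, seed=(2 * config.seed) % 2**31)
    test_cfg = replace(config, n_rounds=n_test_rounds, seed=(2 * config.seed + 1) % 2**31)
    return [generate_session(train_cfg)], [generate_session(test_cfg)]
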