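"""EMG conditioning filters.

EMG channels are conditioned with a 50 Hz notch (power-line interference)
followed by a 20-500 Hz Butterworth bandpass. IMU and GRF channels are left
untouched; the GRF channel in particular is thresholded raw.

Causal filtering is the default everywhere so that the offline path and the
sample-by-sample replay path run *identical* arithmetic: the streaming filter
carries scipy's ``sosfilt`` state between chunks and is bit-for-bit equal to
filtering the whole signal in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, StreamingError
from .session import Modality, SessionRecording

__all__ = [
    "FilterSpec",
    "design_sos",
    "filter_emg",
    "StreamingEmgFilter",
    "filter_emg_streaming",
    "preprocess_session",
]


@dataclass(frozen=True)
class FilterSpec:
    """EMG filter chain parameters.

    ``notch_order`` is the total transfer-function order of the notch,
    realized as ``notch_order / 2`` cascaded second-order notch sections at
    ``notch_hz`` with quality factor ``notch_q`` (the narrow default Q=30
    keeps the surrounding EMG band intact). ``bp_order`` is the Butterworth
    design order of the bandpass.
    """

    notch_hz: float = 50.0
    notch_order: int = 6
    notch_q: float = 30.0
    bp_low_hz: float = 20.0
    bp_high_hz: float = 500.0
    bp_order: int = 4
    causal: bool = True

    def __post_init__(self) -> None:
        for name in ("notch_order", "bp_order"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0 and v % 2 == 0):
                raise ConfigurationError(f"{name} must be a positive even integer, got {v!r}")
        if not (0 < self.bp_low_hz < self.bp_high_hz):
            raise ConfigurationError("need 0 < bp_low_hz < bp_high_hz")
        if self.notch_q <= 0:
            raise ConfigurationError("notch_q must be positive")

    def validate_for_fs(self, fs: float) -> None:
        if self.bp_high_hz >= fs / 2:
            raise ConfigurationError(
                f"bandpass edge {self.bp_high_hz} Hz is at or above Nyquist "
                f"({fs / 2} Hz) for fs={fs} Hz"
            )
        if self.notch_hz >= fs / 2:
            raise ConfigurationError("notch frequency at or above Nyquist")

    def to_dict(self) -> dict:
        return {
            "notch_hz": self.notch_hz,
            "notch_order": self.notch_order,
            "notch_q": self.notch_q,
            "bp_low_hz": self.bp_low_hz,
            "bp_high_hz": self.bp_high_hz,
            "bp_order": self.bp_order,
            "causal": self.causal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        return cls(**d)


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order sections for the full notch+bandpass cascade."""
    spec.validate_for_fs(fs)
    b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    biquad = sps.tf2sos(b, a)
    notch = np.vstack([biquad] * (spec.notch_order // 2))
    band = sps.butter(
        spec.bp_order, [spec.bp_low_hz, spec.bp_high_hz], btype="bandpass", fs=fs, output="sos"
    )
    return np.vstack([notch, band])


def filter_emg(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Condition one EMG channel. Output length equals input length.

    Causal by default; with ``spec.causal=False`` a zero-phase (forward-
    backward) pass is used instead — offline use only, since it cannot be
    replayed in real time.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    sos = design_sos(spec, fs)
    if spec.causal:
        return sps.sosfilt(sos, x)
    return sps.sosfiltfilt(sos, x)


class StreamingEmgFilter:
    """Chunk-wise causal EMG filter with persistent state.

    Feeding any partition of a signal through :meth:`process` yields exactly
    the concatenation that :func:`filter_emg` (causal) produces on the whole
    signal.
    """

    def __init__(self, spec: FilterSpec, fs: float):
        if not spec.causal:
            raise ConfigurationError("streaming filtering is necessarily causal")
        self.spec = spec
        self.fs = fs
        self.sos = design_sos(spec, fs)
        self.zi = np.zeros((self.sos.shape[0], 2))

    def process(self, chunk: np.ndarray) -> np.ndarray:
        chunk = np.asarray(chunk, dtype=float)
        if chunk.size == 0:
            return chunk.copy()
        if not np.all(np.isfinite(chunk)):
            raise StreamingError("chunk contains NaN/inf samples")
        out, self.zi = sps.sosfilt(self.sos, chunk, zi=self.zi)
        return out


def filter_emg_streaming(state: StreamingEmgFilter, chunk: np.ndarray):
    """Functional wrapper: ``(state, chunk) -> (filtered chunk, state)``."""
    return state.process(chunk), state


def preprocess_session(session: SessionRecording, spec: FilterSpec | None = None) -> SessionRecording:
    """Return a copy of ``session`` with every EMG channel filtered.

    IMU and GRF channels are passed through unchanged.
    """
    spec = spec or FilterSpec()
    signals = session.signals.copy()
    for i in session.indices_of(Modality.EMG):
        signals[i] = filter_emg(signals[i], session.fs_hz, spec)
    return replace_signals(session, signals)


def replace_signals(session: SessionRecording, signals: np.ndarray) -> SessionRecording:
    return SessionRecording(
        fs_hz=session.fs_hz,
        signals=signals,
        channels=list(session.channels),
        markers=list(session.markers),
        body_weight_n=session.body_weight_n,
        initial_mode=session.initial_mode,
        meta=dict(session.meta),
    )
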