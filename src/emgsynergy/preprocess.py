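"""Surface-EMG conditioning: from raw multichannel recordings to
analysis-ready activation envelopes.

The chain implemented here is the standard one for synergy analysis:

1. ``clean_raw``      -- harmonic notch removal of power-line interference
                         (PLI), 20-400 Hz band-pass, baseline (mean) removal.
2. ``make_envelope``  -- full-wave rectification, zero-phase low-pass
                         (default 40 Hz), per-channel minimum subtraction,
                         short moving-average integration (default 20 ms).
3. ``condition_envelope`` -- robust despiking (median + z*MAD) and
                         per-channel variance normalization.
4. ``segment_and_concatenate`` -- excision of dropout/flatline runs longer
                         than a gap threshold and concatenation of repeated
                         trials of the same (subject, side, task, style).

All filters are 4th-order Butterworth (or IIR notch, Q=30) applied
forward-backward, so the chain is zero-phase and envelope timing is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import median_filter, uniform_filter1d

__all__ = [
    "RawEMG",
    "EMGEnvelope",
    "clean_raw",
    "make_envelope",
    "condition_envelope",
    "segment_and_concatenate",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RawEMG:
    """A channels x samples recording at full sampling rate.

    ``meta`` carries acquisition labels (subject, side, task, style, ...).
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"channel count {self.data.shape[0]} does not match "
                f"{len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EMGEnvelope:
    """A nonnegative channels x samples activation envelope.

    ``processing_log`` is an ordered record of the applied steps with their
    parameters, serialized into the JSON sidecar on write.
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    meta: dict = field(default_factory=dict)
    processing_log: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"channel count {self.data.shape[0]} does not match "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# raw cleaning
# ---------------------------------------------------------------------------

def clean_raw(
    raw: RawEMG,
    pli_freq: float = 50.0,
    n_harmonics: int = 3,
    band: tuple[float, float] = (20.0, 400.0),
    notch_q: float = 30.0,
) -> RawEMG:
    """Remove PLI and its harmonics, band-pass, and remove the baseline.

    Notch filters are placed at ``pli_freq`` and its first ``n_harmonics``
    integer multiples (those below Nyquist); the band-pass is a zero-phase
    4th-order Butterworth; finally the per-channel mean is subtracted.
    """
    nyq = raw.fs / 2.0
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError(f"invalid band {band}")
    if hi >= nyq:
        raise ValueError(
            f"band upper edge {hi} Hz violates Nyquist: fs={raw.fs} Hz "
            f"allows at most {nyq} Hz"
        )
    x = raw.data.astype(float, copy=True)
    applied = []
    for k in range(1, n_harmonics + 2):
        f0 = k * pli_freq
        if f0 >= nyq:
            break
        b, a = signal.iirnotch(f0, Q=notch_q, fs=raw.fs)
        x = signal.filtfilt(b, a, x, axis=1)
        applied.append(f0)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=raw.fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    meta = dict(raw.meta)
    log = list(meta.get("processing_log", []))
    log.append(
        {
            "step": "clean_raw",
            "notch_hz": applied,
            "notch_q": notch_q,
            "band_hz": [lo, hi],
        }
    )
    meta["processing_log"] = log
    return RawEMG(x, raw.fs, list(raw.channel_names), meta)


# ---------------------------------------------------------------------------
# envelope extraction
# ---------------------------------------------------------------------------

def make_envelope(
    raw: RawEMG,
    lp_cutoff: float = 40.0,
    smooth_window_ms: float = 20.0,
    smoothing: str = "moving_average",
    subtract_min: bool = True,
) -> EMGEnvelope:
    """Rectify, low-pass, subtract the per-channel minimum, and smooth.

    ``smoothing='moving_average'`` integrates with a centered window of
    ``round(smooth_window_ms*fs/1000)`` samples, preserving the sampling
    rate; ``smoothing='decimate'`` instead averages non-overlapping windows,
    reducing the rate by the window length.  ``subtract_min=False`` skips
    the static-noise removal (useful when inspecting the raw envelope).
    """
    if lp_cutoff >= raw.fs / 2.0:
        raise ValueError(
            f"low-pass cutoff {lp_cutoff} Hz violates Nyquist at fs={raw.fs}"
        )
    x = np.abs(raw.data)
    sos = signal.butter(4, lp_cutoff, btype="lowpass", fs=raw.fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    if subtract_min:
        x = x - x.min(axis=1, keepdims=True)  # per-channel min -> exactly 0
    w = int(round(smooth_window_ms * raw.fs / 1000.0))
    fs_out = raw.fs
    if w > 1:
        if smoothing == "moving_average":
            x = uniform_filter1d(x, size=w, axis=1, mode="nearest")
        elif smoothing == "decimate":
            n = (x.shape[1] // w) * w
            x = x[:, :n].reshape(x.shape[0], -1, w).mean(axis=2)
            fs_out = raw.fs / w
        else:
            raise ValueError(f"unknown smoothing mode {smoothing!r}")
    log = list(raw.meta.get("processing_log", []))
    log.append(
        {
            "step": "make_envelope",
            "lp_cutoff_hz": lp_cutoff,
            "smooth_window_ms": smooth_window_ms,
            "smooth_window_samples": w,
            "smoothing": smoothing,
        }
    )
    meta = {k: v for k, v in raw.meta.items() if k != "processing_log"}
    return EMGEnvelope(x, fs_out, list(raw.channel_names), meta, log)


def subtract_minimum(env: EMGEnvelope) -> EMGEnvelope:
    """Subtract the per-channel minimum (afterwards each channel's min is 0)."""
    x = env.data - env.data.min(axis=1, keepdims=True)
    log = env.processing_log + [{"step": "subtract_minimum"}]
    return EMGEnvelope(x, env.fs, list(env.channel_names), dict(env.meta), log)


# ---------------------------------------------------------------------------
# despike + variance normalization
# ---------------------------------------------------------------------------

def condition_envelope(env: EMGEnvelope, spike_z: float = 5.0) -> EMGEnvelope:
    """Despike (median + spike_z*MAD rule) then normalize each channel to
    unit variance.

    Samples above ``median + spike_z*MAD`` of their channel are replaced by
    the median of their 5-sample neighbourhood.  A zero-variance channel is
    reported as a dead electrode.
    """
    x = env.data.astype(float, copy=True)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    thresh = med + spike_z * mad
    spikes = x > thresh
    n_spikes = int(spikes.sum())
    if n_spikes:
        neighborhood = median_filter(x, size=(1, 5), mode="nearest")
        x[spikes] = neighborhood[spikes]
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [env.channel_names[i] for i in dead]
        raise ValueError(
            f"zero-variance channel(s) {names}: dead electrode, cannot "
            "normalize by variance"
        )
    x /= sd[:, None]
    log = env.processing_log + [
        {"step": "condition_envelope", "spike_z": spike_z, "n_spikes": n_spikes}
    ]
    return EMGEnvelope(x, env.fs, list(env.channel_names), dict(env.meta), log)


# ---------------------------------------------------------------------------
# dropout excision + trial concatenation
# ---------------------------------------------------------------------------

_CONCAT_KEYS = ("subject", "side", "task", "style")


def _dropout_mask(x: np.ndarray, max_gap: int) -> np.ndarray:
    """True for samples inside a constant (all channels unchanged) or
    all-zero run strictly longer than ``max_gap`` samples."""
    n = x.shape[1]
    if n == 0:
        return np.zeros(0, dtype=bool)
    change = np.any(np.diff(x, axis=1) != 0, axis=0)
    # boundaries of maximal runs of identical consecutive samples
    boundaries = np.concatenate(([0], np.flatnonzero(change) + 1, [n]))
    mask = np.zeros(n, dtype=bool)
    for start, stop in zip(boundaries[:-1], boundaries[1:]):
        if stop - start > max_gap:
            mask[start:stop] = True
    return mask


def segment_and_concatenate(
    trials: Sequence[EMGEnvelope], max_gap_s: float = 0.5
) -> EMGEnvelope:
    """Excise dropout runs longer than ``max_gap_s`` and concatenate trials.

    All trials must share the channel set, sampling rate and the
    (subject, side, task, style) labels.
    """
    if not trials:
        raise ValueError("no trials to concatenate")
    ref = trials[0]
    for t in trials[1:]:
        if list(t.channel_names) != list(ref.channel_names) or t.fs != ref.fs:
            raise ValueError("trials have mismatched channels or sampling rate")
        for k in _CONCAT_KEYS:
            if t.meta.get(k) != ref.meta.get(k):
                raise ValueError(
                    f"trials have mismatched metadata field {k!r}: "
                    f"{t.meta.get(k)!r} vs {ref.meta.get(k)!r}"
                )
    max_gap = int(round(max_gap_s * ref.fs))
    pieces, cuts = [], []
    for i, t in enumerate(trials):
        mask = _dropout_mask(t.data, max_gap)
        if mask.any():
            idx = np.flatnonzero(mask)
            cuts.append({"trial": i, "n_samples_cut": int(idx.size)})
        pieces.append(t.data[:, ~mask])
    data = np.concatenate(pieces, axis=1)
    log = list(ref.processing_log) + [
        {
            "step": "segment_and_concatenate",
            "n_trials": len(trials),
            "max_gap_s": max_gap_s,
            "cuts": cuts,
        }
    ]
    return EMGEnvelope(data, ref.fs, list(ref.channel_names), dict(ref.meta), log)
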