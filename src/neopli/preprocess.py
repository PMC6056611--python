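"""Preprocessing chain: average reference, downsampling, epoching, filtering.

The analysis convention is fixed: re-reference to the common average of all
21 electrodes, decimate 500 -> 250 Hz, cut the first 50 consecutive
non-overlapping epochs of 4096 samples (16.384 s each), then band-pass each
epoch into one of seven frequency bands.  Referencing and decimation are
linear and commute; segmentation precedes filtering so that every epoch is
an independent analysis unit.

Filtering is zero-phase by construction: each 4096-sample epoch is
transformed with a real FFT, out-of-band coefficients are zeroed through a
raised-cosine transition centred on the band edge (width 0.2 Hz or 5 % of
the edge frequency, whichever is larger), and the epoch is transformed
back.  A purely real spectral mask cannot distort phase, which is mandatory
upstream of a phase-based connectivity statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .montage import Recording

__all__ = [
    "Band",
    "BANDS",
    "EpochSet",
    "average_reference",
    "downsample",
    "segment_epochs",
    "bandpass",
    "band_mask",
    "highpass_cutoff",
    "EPOCH_LENGTH",
    "N_EPOCHS",
    "TARGET_RATE",
]

#: analysis defaults
EPOCH_LENGTH = 4096   # samples per epoch after decimation
N_EPOCHS = 50         # epochs per recording
TARGET_RATE = 250.0   # Hz after decimation


@dataclass(frozen=True)
class Band:
    """A frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"invalid band {self.name}: [{self.low}, {self.high})")


#: The canonical seven-band table.
BANDS: dict[str, Band] = {
    b.name: b
    for b in (
        Band("broad", 0.1, 45.0),
        Band("delta", 0.5, 4.0),
        Band("theta", 4.0, 8.0),
        Band("lower_alpha", 8.0, 10.0),
        Band("upper_alpha", 10.0, 13.0),
        Band("beta", 13.0, 30.0),
        Band("gamma", 30.0, 45.0),
    )
}

#: Narrow bands tiling [0.5, 45) Hz (i.e. all bands except broad).
NARROW_BANDS: tuple[str, ...] = (
    "delta", "theta", "lower_alpha", "upper_alpha", "beta", "gamma",
)


def highpass_cutoff(time_constant_s: float) -> float:
    """First-order high-pass cutoff 1/(2*pi*tau) in Hz.

    Utility for relating an amplifier time constant to its -3 dB lower
    cutoff (tau = 0.6 s gives 0.265 Hz).  The pipeline never re-applies this
    acquisition filter; it is a property of the input data.
    """
    if not time_constant_s > 0:
        raise ValueError("time constant must be positive")
    return 1.0 / (2.0 * math.pi * time_constant_s)


@dataclass
class EpochSet:
    """Consecutive non-overlapping epochs cut from the start of a recording.

    epochs: array (n_epochs, channels, epoch_length); band is the Band the
    epochs were filtered into, or None for unfiltered epochs.
    """

    epochs: np.ndarray
    sampling_rate: float
    band: Band | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, channels, samples)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_length(self) -> int:
        return self.epochs.shape[2]


def average_reference(recording: Recording) -> Recording:
    """Re-reference to the common average of all channels.

    Subtracts the instantaneous cross-channel mean from every channel, so
    the channel mean is zero at every sample.  Idempotent.
    """
    if recording.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return replace(recording, data=data)


def downsample(recording: Recording, target_rate: float = TARGET_RATE,
               antialias: bool = False) -> Recording:
    """Decimate to ``target_rate`` by keeping every factor-th sample.

    The sampling rate must be an integer multiple of the target.  Plain
    decimation assumes the acquisition chain already low-passed the signal
    below the target Nyquist (clinical recordings are low-pass filtered at
    100 Hz before 500 Hz sampling, well under the 125 Hz target Nyquist).
    Set ``antialias=True`` for inputs of unknown provenance: a zero-phase
    spectral low-pass at the target Nyquist is applied first.
    """
    ratio = recording.sampling_rate / target_rate
    factor = round(ratio)
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"sampling rate {recording.sampling_rate} Hz is not an integer "
            f"multiple of target {target_rate} Hz"
        )
    if factor == 1:
        return replace(recording, data=recording.data.copy())
    data = recording.data
    if antialias:
        n = data.shape[1]
        spec = np.fft.rfft(data, axis=1)
        freqs = np.fft.rfftfreq(n, d=1.0 / recording.sampling_rate)
        spec[:, freqs >= target_rate / 2.0] = 0.0
        data = np.fft.irfft(spec, n=n, axis=1)
    n_out = data.shape[1] // factor
    out = data[:, : n_out * factor : factor].copy()
    return replace(recording, data=out, sampling_rate=target_rate)


def segment_epochs(recording: Recording, epoch_length: int = EPOCH_LENGTH,
                   n_epochs: int = N_EPOCHS,
                   allow_short: bool = False) -> EpochSet:
    """Cut the first ``n_epochs`` consecutive epochs of ``epoch_length``.

    Epoch k spans samples [k*epoch_length, (k+1)*epoch_length), 0-based
    half-open, from the start of the recording.  A recording shorter than
    n_epochs * epoch_length is fatal unless ``allow_short`` is set, in
    which case as many full epochs as available are returned (at least 1).
    """
    needed = epoch_length * n_epochs
    avail = recording.n_samples
    if avail < needed:
        if not allow_short:
            raise ValueError(
                f"recording too short: need {needed} samples "
                f"({n_epochs} epochs x {epoch_length}), have {avail}"
            )
        n_epochs = avail // epoch_length
        if n_epochs == 0:
            raise ValueError(
                f"recording too short for even one epoch of {epoch_length} samples"
            )
    data = recording.data[:, : n_epochs * epoch_length]
    epochs = (
        data.reshape(recording.n_channels, n_epochs, epoch_length)
        .transpose(1, 0, 2)
        .copy()
    )
    return EpochSet(
        epochs=epochs,
        sampling_rate=recording.sampling_rate,
        band=None,
        subject_id=recording.subject_id,
    )


def _transition_width(edge_hz: float) -> float:
    return max(0.2, 0.05 * edge_hz)


def band_mask(n_samples: int, sampling_rate: float, band: Band) -> np.ndarray:
    """Real-valued rFFT mask for ``band`` with raised-cosine transitions.

    The transition of width max(0.2 Hz, 5 % of the edge) is centred on each
    band edge, so masks of adjacent canonical bands cross at amplitude 0.5
    exactly on the shared edge frequency.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    mask = np.ones_like(freqs)

    w_lo = _transition_width(band.low)
    lo0, lo1 = band.low - w_lo / 2.0, band.low + w_lo / 2.0
    lo0 = max(lo0, 0.0)
    below = freqs <= lo0
    rise = (freqs > lo0) & (freqs < lo1)
    mask[below] = 0.0
    if np.any(rise):
        mask[rise] = 0.5 * (1.0 - np.cos(np.pi * (freqs[rise] - lo0) / (lo1 - lo0)))

    w_hi = _transition_width(band.high)
    hi0, hi1 = band.high - w_hi / 2.0, band.high + w_hi / 2.0
    above = freqs >= hi1
    fall = (freqs > hi0) & (freqs < hi1)
    mask[above] = 0.0
    if np.any(fall):
        mask[fall] *= 0.5 * (1.0 + np.cos(np.pi * (freqs[fall] - hi0) / (hi1 - hi0)))
    return mask


def bandpass(epoch_set: EpochSet, band: Band) -> EpochSet:
    """Zero-phase band-pass of every epoch via a real spectral mask."""
    nyq = epoch_set.sampling_rate / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name} upper edge {band.high} Hz >= Nyquist {nyq} Hz"
        )
    n = epoch_set.epoch_length
    mask = band_mask(n, epoch_set.sampling_rate, band)
    spec = np.fft.rfft(epoch_set.epochs, axis=2)
    filtered = np.fft.irfft(spec * mask, n=n, axis=2)
    return EpochSet(
        epochs=filtered,
        sampling_rate=epoch_set.sampling_rate,
        band=band,
        subject_id=epoch_set.subject_id,
    )
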