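"""Power spectra and relative band power.

Plain FFT periodogram per epoch (rectangular window), scaled so that the
one-sided spectrum satisfies Parseval's identity: the bin powers of a
channel sum to its time-domain mean square.  Relative band power pools
power across all channels before forming the ratio, and assigns a bin to a
band by low <= f < high so that adjacent canonical bands never double-count
their shared edge frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Band, BANDS, EpochSet

__all__ = [
    "PowerSpectrum",
    "epoch_power_spectrum",
    "relative_band_power",
    "subject_relative_band_power",
]


@dataclass
class PowerSpectrum:
    """One-sided periodogram: power per channel per frequency bin."""

    frequencies: np.ndarray
    power: np.ndarray  # channels x n_bins

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2 or self.power.shape[1] != self.frequencies.size:
            raise ValueError("power must be channels x n_bins")
        if np.any(self.power < 0) or not np.all(np.isfinite(self.power)):
            raise ValueError("power must be nonnegative and finite")

    def band_power(self, band: Band) -> np.ndarray:
        """Per-channel power summed over bins with band.low <= f < band.high."""
        sel = (self.frequencies >= band.low) & (self.frequencies < band.high)
        return self.power[:, sel].sum(axis=1)


def epoch_power_spectrum(epoch: np.ndarray, sampling_rate: float) -> PowerSpectrum:
    """Rectangular-window periodogram of one epoch.

    Scaling: P_k = |X_k|^2 / N^2, doubled for interior bins, so that
    sum_k P_k equals mean(x^2) exactly (Parseval).
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2:
        raise ValueError("epoch must be 2-D (channels x samples)")
    n = epoch.shape[1]
    spec = np.fft.rfft(epoch, axis=1)
    power = np.abs(spec) ** 2 / n**2
    # one-sided doubling: all bins except DC (and Nyquist when n is even)
    interior = np.ones(power.shape[1])
    interior[1:] = 2.0
    if n % 2 == 0:
        interior[-1] = 1.0
    power *= interior
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return PowerSpectrum(frequencies=freqs, power=power)


def relative_band_power(spectrum: PowerSpectrum, band: Band,
                        total_band: Band | None = None) -> float:
    """Fraction of total-band power (pooled over channels) that lies in ``band``.

    ``total_band`` defaults to the broad band (0.1-45 Hz).  Zero total
    power is fatal (degenerate recording).
    """
    total_band = total_band or BANDS["broad"]
    total = float(spectrum.band_power(total_band).sum())
    if total <= 0:
        raise ValueError("zero total power in the reference band")
    part = float(spectrum.band_power(band).sum())
    return part / total


def subject_relative_band_power(epoch_set: EpochSet, band: Band,
                                total_band: Band | None = None) -> float:
    """Mean relative band power over the (unfiltered) epochs of a subject."""
    if epoch_set.band is not None:
        raise ValueError("relative band power is computed on unfiltered epochs")
    shares = [
        relative_band_power(
            epoch_power_spectrum(ep, epoch_set.sampling_rate), band, total_band
        )
        for ep in epoch_set.epochs
    ]
    return float(np.mean(shares))
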