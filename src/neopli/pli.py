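"""Phase lag index (PLI) and its subject-level aggregations.

The PLI between two signals is

    PLI = | < sign(sin(dphi(t_k))) > |,

the absolute time average of the sign of the sine of their instantaneous
phase difference.  Phase differences at exactly 0 mod pi contribute 0
(signum of zero), so consistent zero-lag coupling — the signature of volume
conduction, where one source projects instantaneously to several
electrodes — yields PLI 0, while a consistent nonzero lead/lag yields PLI
1.  Phases come from the analytic signal of each band-filtered epoch.

Aggregation follows the two cohort conventions: mPLI (mean over the 210
channel pairs per epoch, then over epochs) and pwPLI (per-pair mean over
epochs, a 21 x 21 symmetric matrix per subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.signal

from .montage import Montage
from .preprocess import Band, EpochSet

__all__ = [
    "PhaseSeries",
    "PLIMatrix",
    "instantaneous_phase",
    "pli_pair",
    "epoch_pli_matrix",
    "mean_pli_of_epoch",
    "subject_mpli",
    "subject_pwpli",
    "epoch_set_pli",
    "null_pli_level",
]


@dataclass
class PhaseSeries:
    """Instantaneous phases (radians in (-pi, pi]) of one epoch.

    ``zero_channels`` flags channels that were identically zero, whose
    phase is defined as 0 throughout.
    """

    phases: np.ndarray
    zero_channels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if self.zero_channels is None:
            self.zero_channels = np.zeros(self.phases.shape[0], dtype=bool)
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("non-finite phases")


@dataclass
class PLIMatrix:
    """Symmetric channels x channels PLI matrix with zero diagonal."""

    values: np.ndarray
    n_epochs_averaged: int = 1
    band: Band | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("PLI matrix must be square")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("PLI values must lie in [0, 1]")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("PLI diagonal must be exactly 0")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("PLI matrix must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """The 210 pair values in canonical pair-index order."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]


def instantaneous_phase(epoch: np.ndarray) -> PhaseSeries:
    """Analytic-signal phase of each channel of a band-filtered epoch.

    Uses the Hilbert-transform construction over the whole epoch, no
    padding and no edge trimming.  An identically zero channel gets phase 0
    throughout and is flagged.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2:
        raise ValueError("epoch must be 2-D (channels x samples)")
    zero = ~np.any(epoch != 0.0, axis=1)
    analytic = scipy.signal.hilbert(epoch, axis=1)
    phases = np.angle(analytic)
    phases[zero] = 0.0
    return PhaseSeries(phases=phases, zero_channels=zero)


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI between two phase series: |mean sign(sin(phi_a - phi_b))|.

    sign(0) = 0 exactly, so samples with phase difference 0 mod pi dilute
    the average instead of counting for either direction.  Symmetric in its
    arguments.
    """
    a = np.asarray(phase_a, dtype=np.float64).ravel()
    b = np.asarray(phase_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty phase series")
    return float(np.abs(np.mean(np.sign(np.sin(a - b)))))


def epoch_pli_matrix(phase_series: PhaseSeries,
                     montage: Montage | None = None,
                     band: Band | None = None) -> PLIMatrix:
    """All-pairs PLI matrix of one epoch.

    Entry (i, j) equals ``pli_pair`` on channels i and j.  Vectorised over
    the upper triangle via sin(a-b) = sin a cos b - cos a sin b, which is
    algebraically identical to the pairwise path.
    """
    phases = phase_series.phases
    n = phases.shape[0]
    if montage is not None and n != montage.n_channels:
        raise ValueError(
            f"expected {montage.n_channels} channels, got {n}"
        )
    s = np.sin(phases)
    c = np.cos(phases)
    iu, ju = np.triu_indices(n, k=1)
    cross = s[iu] * c[ju] - c[iu] * s[ju]          # sin(phi_i - phi_j)
    pli = np.abs(np.sign(cross).mean(axis=1))
    values = np.zeros((n, n))
    values[iu, ju] = pli
    values[ju, iu] = pli
    return PLIMatrix(values=values, n_epochs_averaged=1, band=band)


def mean_pli_of_epoch(matrix: PLIMatrix) -> float:
    """Arithmetic mean of the off-diagonal pair values (upper triangle)."""
    return float(matrix.upper_triangle().mean())


def subject_mpli(epoch_means: Sequence[float]) -> float:
    """Mean over per-epoch pair means: the subject-level mPLI."""
    means = np.asarray(epoch_means, dtype=np.float64)
    if means.size == 0:
        raise ValueError("no epoch means to average")
    return float(means.mean())


def subject_pwpli(epoch_matrices: Sequence[PLIMatrix]) -> PLIMatrix:
    """Entrywise mean over epochs: the subject-level pairwise PLI matrix."""
    if len(epoch_matrices) == 0:
        raise ValueError("no epoch matrices to average")
    stack = np.stack([m.values for m in epoch_matrices])
    return PLIMatrix(
        values=stack.mean(axis=0),
        n_epochs_averaged=int(sum(m.n_epochs_averaged for m in epoch_matrices)),
        band=epoch_matrices[0].band,
    )


def epoch_set_pli(epoch_set: EpochSet,
                  montage: Montage | None = None) -> tuple[float, PLIMatrix]:
    """Full PLI aggregation of a band-filtered EpochSet.

    Returns (mPLI, pwPLI): per-epoch phases -> per-epoch PLI matrices ->
    the epoch-mean scalar averaged over epochs, and the entrywise
    epoch-mean matrix.
    """
    matrices = [
        epoch_pli_matrix(instantaneous_phase(ep), montage, band=epoch_set.band)
        for ep in epoch_set.epochs
    ]
    mpli = subject_mpli([mean_pli_of_epoch(m) for m in matrices])
    return mpli, subject_pwpli(matrices)


def null_pli_level(n_samples: int) -> float:
    """Expected PLI of two channels with i.i.d. random phase differences.

    The per-sample signs are i.i.d. +/-1, so the mean of |their average| is
    sqrt(2/(pi*N)) by the half-normal limit — the chance level an observed
    PLI must clear before it means anything.
    """
    return float(np.sqrt(2.0 / (np.pi * n_samples)))
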