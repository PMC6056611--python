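"""Synthetic neonatal-EEG cohorts with known ground truth.

The generator builds 21-channel, 500 Hz recordings whose delta-band
phase-lag consistency follows a configured linear trend in postmenstrual
age (PMA), so the full pipeline — preprocessing, PLI, cohort statistics —
can be exercised and its parameter recovery checked without clinical data.

Signal model, per subject:

* background noise: per channel, independent Gaussian noise shaped to a
  1/f^2.5 spectrum with a two-pole low-frequency rolloff at 0.7 Hz and a
  100 Hz acquisition-style low-pass, i.e. a delta-dominant neonatal-like
  spectrum (roughly 70 % of broad-band power in 0.5-4 Hz);
* coupling: one shared narrow-band oscillator in the coupling band, mixed
  into every channel with per-channel phase offsets (cumulative increments
  drawn once per subject, each in (pi/8, 3pi/8), so every lag is nonzero
  and visible to a phase-lag statistic) and a mixing amplitude kappa;
  alternatively, designated channel pairs with independent oscillators;
* maturation: kappa is chosen through a Monte-Carlo calibration map so the
  pipeline's expected delta mPLI tracks
  target_intercept + target_slope * PMA, plus an individual dispersion.

PMA enters only through the mixing amplitude; the lag structure itself is
age-independent.  All randomness flows from a single seed with per-subject
substreams, so a cohort is bit-identical under the same seed and config.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .montage import Montage, Recording, SubjectRecord
from .pli import epoch_set_pli
from .preprocess import (
    BANDS, Band, average_reference, bandpass, downsample, segment_epochs,
)

__all__ = [
    "GeneratorConfig",
    "CouplingMap",
    "calibrate_coupling",
    "simulate_subject",
    "synthesize_recording",
    "simulate_cohort",
    "simulate_longitudinal_subject",
    "inject_artifacts",
    "SyntheticCohort",
]

log = logging.getLogger(__name__)

#: metadata proportions for cosmetic realism (diagnosis mix, sex ratio,
#: label prevalences of a mixed clinical neonatal cohort)
_DIAGNOSIS_P = {
    "asphyxia": 42, "hemorrhage/infarction": 19, "infection": 8,
    "prematurity complication": 10, "malformation": 8,
    "epileptic encephalopathy": 4, "other": 11, "none": 29,
}
_P_MALE = 0.55
_P_HIGH_QUALITY = 63 / 131
_P_CLINICAL_NORMAL = 30 / 131


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Defaults are the cohort conditions the analysis targets: 131 subjects,
    PMA uniform on 27.6-45.3 weeks, delta-band mPLI following
    0.344 - 0.005 * PMA with individual dispersion 0.033, recorded at
    500 Hz long enough for 50 epochs of 4096 samples after 2x decimation.
    """

    n_subjects: int = 131
    pma_range: tuple[float, float] = (27.6, 45.3)
    target_intercept: float = 0.344
    target_slope: float = -0.005
    subject_noise_sd: float = 0.033
    coupling_band_name: str = "delta"
    n_channels: int = 21
    sampling_rate: float = 500.0
    target_rate: float = 250.0
    n_epochs: int = 50
    epoch_length: int = 4096
    noise_model: str = "one_over_f"      # "one_over_f" | "white"
    noise_exponent: float = 2.5
    noise_corner_hz: float = 0.7
    lowpass_hz: float = 100.0
    amplitude_uv: float = 50.0
    coupled_pairs: Optional[tuple[tuple[int, int], ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pma_range[0] >= self.pma_range[1]:
            raise ValueError("pma_range must be increasing")
        if self.noise_model not in ("one_over_f", "white"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.sampling_rate % self.target_rate:
            raise ValueError("sampling_rate must be a multiple of target_rate")

    @property
    def coupling_band(self) -> Band:
        return BANDS[self.coupling_band_name]

    @property
    def decimation(self) -> int:
        return int(self.sampling_rate / self.target_rate)

    @property
    def n_samples_raw(self) -> int:
        """Samples at the acquisition rate covering all epochs after decimation."""
        return self.n_epochs * self.epoch_length * self.decimation

    @property
    def duration_s(self) -> float:
        return self.n_samples_raw / self.sampling_rate

    def coupled_channels(self) -> np.ndarray:
        """Channels receiving the shared oscillator (all, unless pairs planted)."""
        if self.coupled_pairs is None:
            return np.arange(self.n_channels)
        chans = sorted({c for pair in self.coupled_pairs for c in pair})
        return np.asarray(chans, dtype=int)


def _subject_rng(config_seed: int, index: int) -> np.random.Generator:
    """Deterministic per-subject substream: root seed + subject index."""
    return np.random.default_rng(np.random.SeedSequence((config_seed, index)))


def _shaped_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                  fs: float, config: GeneratorConfig) -> np.ndarray:
    """Independent background noise per channel, built in the frequency domain."""
    n_bins = n_samples // 2 + 1
    spec = rng.standard_normal((n_channels, n_bins)) + 1j * rng.standard_normal(
        (n_channels, n_bins)
    )
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    if config.noise_model == "one_over_f":
        amp = np.zeros_like(freqs)
        f = freqs[1:]
        amp[1:] = (
            f ** (-config.noise_exponent / 2.0)
            * (f**2 / (f**2 + config.noise_corner_hz**2))
            * 1.0 / np.sqrt(1.0 + (f / config.lowpass_hz) ** 16)
        )
    else:
        amp = np.ones_like(freqs)
        amp[0] = 0.0
        amp *= 1.0 / np.sqrt(1.0 + (freqs / config.lowpass_hz) ** 16)
    x = np.fft.irfft(spec * amp, n=n_samples, axis=1)
    rms = np.sqrt((x**2).mean(axis=1, keepdims=True))
    return x / rms


def _oscillator(rng: np.random.Generator, n_samples: int, fs: float,
                band: Band) -> np.ndarray:
    """Shared narrow-band analytic oscillator (complex, Re part unit RMS)."""
    freqs = np.fft.fftfreq(n_samples, d=1.0 / fs)
    sel = (freqs >= band.low) & (freqs < band.high)
    spec = np.zeros(n_samples, dtype=complex)
    k = int(sel.sum())
    spec[sel] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    z = np.fft.ifft(spec)
    rms = np.sqrt((z.real**2).mean())
    return z / rms


def synthesize_recording(rng: np.random.Generator, kappa: float,
                         config: GeneratorConfig,
                         subject_id: str = "probe") -> Recording:
    """One raw 500 Hz recording: shaped noise + kappa x lagged oscillator(s).

    Without ``coupled_pairs``, one shared oscillator feeds every channel
    with per-channel phase offsets built as cumulative increments, each in
    (pi/8, 3pi/8): every adjacent pair keeps a guaranteed nonzero lag,
    while the offsets spread around the circle so the lag structure
    survives common-average referencing (iid offsets confined to one narrow
    arc would collapse to 0/pi pairwise lags after the reference mean is
    subtracted, which a phase-lag statistic discards by design).

    With ``coupled_pairs``, each planted pair receives its own independent
    oscillator with a nonzero within-pair lag, so only the designated pairs
    — not the whole clique of coupled channels — carry coupling.
    """
    n = config.n_samples_raw
    noise = _shaped_noise(rng, config.n_channels, n, config.sampling_rate, config)
    data = noise
    if kappa > 0 and config.coupled_pairs is None:
        z = _oscillator(rng, n, config.sampling_rate, config.coupling_band)
        offsets = np.cumsum(
            rng.uniform(math.pi / 8, 3 * math.pi / 8, size=config.n_channels)
        )
        mix = np.exp(-1j * offsets)[:, None]
        data = noise + kappa * (mix * z[None, :]).real
    elif kappa > 0:
        data = noise.copy()
        for (i, j) in config.coupled_pairs:
            z = _oscillator(rng, n, config.sampling_rate, config.coupling_band)
            theta = rng.uniform(0, 2 * math.pi)
            lag = rng.uniform(math.pi / 8, 3 * math.pi / 8)
            data[i] += kappa * (np.exp(-1j * theta) * z).real
            data[j] += kappa * (np.exp(-1j * (theta + lag)) * z).real
    data *= config.amplitude_uv
    return Recording(
        data=data, sampling_rate=config.sampling_rate,
        montage=Montage(), subject_id=subject_id,
    )


_synthesize = synthesize_recording  # internal alias


def _pipeline_mpli(recording: Recording, config: GeneratorConfig) -> float:
    """Delta (coupling-band) mPLI of a recording through the analysis chain."""
    rec = downsample(average_reference(recording), config.target_rate)
    epochs = segment_epochs(rec, config.epoch_length, config.n_epochs)
    filtered = bandpass(epochs, config.coupling_band)
    mpli, _ = epoch_set_pli(filtered)
    return mpli


@dataclass
class CouplingMap:
    """Monotone map between target mPLI and mixing amplitude kappa."""

    kappa_grid: np.ndarray
    achieved_mpli: np.ndarray
    tolerance: float = 0.02

    @property
    def floor(self) -> float:
        return float(self.achieved_mpli[0])

    @property
    def ceiling(self) -> float:
        return float(self.achieved_mpli[-1])

    def kappa_for(self, target_mpli: float, clip: bool = True) -> float:
        """Mixing amplitude achieving ``target_mpli`` (0 at/below the floor)."""
        if not clip and not (self.floor - self.tolerance
                             <= target_mpli <= self.ceiling + self.tolerance):
            raise ValueError(
                f"requested mPLI {target_mpli:.3f} outside achievable "
                f"range [{self.floor:.3f}, {self.ceiling:.3f}]"
            )
        t = min(max(target_mpli, self.floor), self.ceiling)
        return float(np.interp(t, self.achieved_mpli, self.kappa_grid))


_DEFAULT_KAPPA_GRID = (0.0, 0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 1.0, 1.25, 1.5,
                       2.0, 2.5, 3.5, 5.0, 7.0)
_calibration_cache: dict[tuple, CouplingMap] = {}


def calibrate_coupling(config: GeneratorConfig,
                       kappa_grid: Sequence[float] = _DEFAULT_KAPPA_GRID,
                       n_probe_epochs: int | None = None,
                       n_reps: int = 2) -> CouplingMap:
    """Monte-Carlo sweep: achieved pipeline mPLI for each mixing amplitude.

    For each kappa on the grid, probe recordings (with a reduced epoch
    count: the epoch mean is unbiased in the number of epochs) are pushed
    through the actual analysis chain and the achieved mPLI is averaged.
    The sweep must come out monotone within its Monte-Carlo noise; small
    inversions are flattened, larger ones are fatal with diagnostics.
    The sweep uses a fixed substream of the config seed, so the map is
    deterministic per config.
    """
    key = (config, tuple(kappa_grid), n_probe_epochs, n_reps)
    if key in _calibration_cache:
        return _calibration_cache[key]
    if n_probe_epochs is None:
        n_probe_epochs = min(config.n_epochs, 12)
    probe_config = replace(config, n_epochs=n_probe_epochs)
    # keep the Monte-Carlo error of each sweep point roughly constant:
    # smaller probes (short epochs / few of them) get more repetitions
    probe_samples = n_probe_epochs * config.epoch_length
    n_reps = max(n_reps, math.ceil(2 * 12 * 4096 / max(probe_samples, 1) / 2))
    kappas = np.asarray(sorted(kappa_grid), dtype=np.float64)
    achieved = np.empty_like(kappas)
    for i, kappa in enumerate(kappas):
        vals = []
        for rep in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, 0xCA1, i, rep))
            )
            rec = _synthesize(rng, float(kappa), probe_config)
            vals.append(_pipeline_mpli(rec, probe_config))
        achieved[i] = np.mean(vals)
    diffs = np.diff(achieved)
    if np.any(diffs < -0.02):
        raise RuntimeError(
            "coupling calibration sweep is not monotone: "
            f"kappa={kappas.tolist()} mpli={achieved.tolist()}"
        )
    achieved = np.maximum.accumulate(achieved)  # flatten MC jitter
    cmap = CouplingMap(kappa_grid=kappas, achieved_mpli=achieved)
    log.info(
        "coupling calibration: floor=%.3f ceiling=%.3f over kappa %s",
        cmap.floor, cmap.ceiling, kappas.tolist(),
    )
    _calibration_cache[key] = cmap
    return cmap


def _draw_metadata(rng: np.random.Generator, subject_id: str,
                   pma: float) -> SubjectRecord:
    """Clinical-style metadata with realistic marginals (cosmetic only)."""
    postnatal_days = float(np.clip(rng.lognormal(math.log(5.0), 1.0), 1, 127))
    ga = float(np.clip(pma - postnatal_days / 7.0, 24.0, 42.43))
    if rng.random() < 0.05:
        weight = None
    else:
        weight = float(np.clip(rng.normal(3130 + 150 * (ga - 39.0), 550), 585, 5500))
    names = list(_DIAGNOSIS_P)
    probs = np.array([_DIAGNOSIS_P[nm] for nm in names], dtype=float)
    diagnosis = str(rng.choice(names, p=probs / probs.sum()))
    return SubjectRecord(
        subject_id=subject_id,
        pma_weeks=float(pma),
        ga_weeks=ga,
        birth_weight_g=weight,
        sex="male" if rng.random() < _P_MALE else "female",
        diagnosis=diagnosis,
        quality="high" if rng.random() < _P_HIGH_QUALITY else "low",
        clinical_normal=bool(rng.random() < _P_CLINICAL_NORMAL),
    )


def simulate_subject(pma: float, config: GeneratorConfig, index: int,
                     coupling_map: CouplingMap | None = None,
                     ) -> tuple[Recording, SubjectRecord, float]:
    """Simulate one subject at the given PMA.

    Returns (recording, metadata, intended_mpli): the recording is the raw
    500 Hz signal; ``intended_mpli`` is the subject's target on the
    maturation line after individual dispersion, clipped to the achievable
    range of the coupling map.
    """
    if coupling_map is None:
        coupling_map = calibrate_coupling(config)
    line = config.target_intercept + config.target_slope * pma
    if not (coupling_map.floor - 0.05 <= line <= coupling_map.ceiling + 0.05):
        raise ValueError(
            f"target line value {line:.3f} at PMA {pma:.1f} outside achievable "
            f"mPLI range [{coupling_map.floor:.3f}, {coupling_map.ceiling:.3f}]"
        )
    rng = _subject_rng(config.seed, index)
    target = line + rng.normal(0.0, config.subject_noise_sd)
    target = min(max(target, coupling_map.floor), coupling_map.ceiling)
    kappa = coupling_map.kappa_for(target)
    sid = f"S{index:04d}"
    # metadata drawn before the signal so the cohort table (which skips
    # signal synthesis) consumes the identical substream prefix
    record = _draw_metadata(rng, sid, pma)
    recording = _synthesize(rng, kappa, config, subject_id=sid)
    return recording, record, target


@dataclass
class SyntheticCohort:
    """A simulated cohort: metadata plus on-demand recordings.

    Recordings are regenerated deterministically per subject instead of
    being held in memory (a full-size cohort would be ~9 GB of signal).
    ``intended_mpli`` is the ground-truth table of per-subject targets.
    """

    config: GeneratorConfig
    records: list[SubjectRecord]
    pma: np.ndarray
    intended_mpli: np.ndarray
    coupling_map: CouplingMap

    @property
    def n_subjects(self) -> int:
        return len(self.records)

    def recording(self, index: int) -> Recording:
        rec, _, _ = simulate_subject(
            float(self.pma[index]), self.config, index, self.coupling_map
        )
        return rec

    def iter_subjects(self):
        """Yield (recording, metadata) pairs, generating signals lazily."""
        for i in range(self.n_subjects):
            yield self.recording(i), self.records[i]


def simulate_cohort(config: GeneratorConfig,
                    coupling_map: CouplingMap | None = None) -> SyntheticCohort:
    """Simulate the metadata and ground truth of a whole cohort.

    PMA is uniform over ``config.pma_range``.  Signals are not generated
    here; :meth:`SyntheticCohort.recording` rebuilds any subject's raw
    recording bit-identically from the seed.
    """
    if coupling_map is None:
        coupling_map = calibrate_coupling(config)
    pma_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xB0A)))
    pma = pma_rng.uniform(*config.pma_range, size=config.n_subjects)
    records: list[SubjectRecord] = []
    targets = np.empty(config.n_subjects)
    for i in range(config.n_subjects):
        # metadata + target only; the signal path is deferred
        rng = _subject_rng(config.seed, i)
        line = config.target_intercept + config.target_slope * pma[i]
        target = line + rng.normal(0.0, config.subject_noise_sd)
        target = min(max(target, coupling_map.floor), coupling_map.ceiling)
        targets[i] = target
        records.append(_draw_metadata(rng, f"S{i:04d}", float(pma[i])))
    return SyntheticCohort(
        config=config, records=records, pma=pma,
        intended_mpli=targets, coupling_map=coupling_map,
    )


def simulate_longitudinal_subject(
    pma_points: Sequence[float], config: GeneratorConfig,
    subject_index: int = 0, coupling_map: CouplingMap | None = None,
) -> tuple[list[Recording], list[float]]:
    """Repeated recordings of one subject along the maturation line.

    The subject keeps a single individual offset across visits; each
    visit's target mPLI is the configured line at that PMA plus the offset.
    Returns (recordings, intended mPLI per visit).
    """
    if len(pma_points) < 2:
        raise ValueError("need at least 2 time points")
    if coupling_map is None:
        coupling_map = calibrate_coupling(config)
    rng = _subject_rng(config.seed, subject_index)
    offset = rng.normal(0.0, config.subject_noise_sd)
    recordings, targets = [], []
    for v, pma in enumerate(pma_points):
        target = config.target_intercept + config.target_slope * pma + offset
        target = min(max(target, coupling_map.floor), coupling_map.ceiling)
        kappa = coupling_map.kappa_for(target)
        visit_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, subject_index, 0x10F6, v))
        )
        recordings.append(
            _synthesize(visit_rng, kappa, config,
                        subject_id=f"L{subject_index:03d}v{v}")
        )
        targets.append(target)
    return recordings, targets


#: epochs a reviewer inspects when labelling recording quality (1-based)
PROBE_EPOCHS = (1, 10, 20, 30, 40, 50)
ARTIFACT_EPOCH_FRACTION_LIMIT = 0.30


def inject_artifacts(
    recording: Recording,
    affected_fraction: float,
    seed: int,
    epoch_indices: Sequence[int] | None = None,
    epoch_length: int | None = None,
    amplitude_uv: float = 500.0,
) -> tuple[Recording, str]:
    """Plant broadband high-amplitude transients and derive a quality label.

    ``affected_fraction`` of each targeted epoch's samples (a contiguous
    stretch at a random position) is overlaid with large broadband noise on
    all channels.  ``epoch_indices`` are 1-based epoch numbers at the
    recording's own rate (default: every epoch).  The label mirrors the
    visual scoring rule mechanically: among the probe epochs 1, 10, 20, 30,
    40, 50, an epoch counts as artifacted when more than 30 % of its
    samples are affected; two or more such probe epochs give "low" quality,
    otherwise "high".
    """
    if not 0.0 <= affected_fraction <= 1.0:
        raise ValueError("affected_fraction must be in [0, 1]")
    if epoch_length is None:
        epoch_length = int(4096 * recording.sampling_rate / 250.0)
    n_epochs = recording.n_samples // epoch_length
    if epoch_indices is None:
        epoch_indices = range(1, n_epochs + 1)
    data = recording.data.copy()
    rng = np.random.default_rng(seed)
    affected = {}
    if affected_fraction > 0:
        for e in epoch_indices:
            if not 1 <= e <= n_epochs:
                continue
            span = int(round(affected_fraction * epoch_length))
            if span == 0:
                continue
            start = (e - 1) * epoch_length + rng.integers(0, epoch_length - span + 1)
            data[:, start : start + span] += amplitude_uv * rng.standard_normal(
                (recording.n_channels, span)
            )
            affected[e] = span / epoch_length
    n_bad_probes = sum(
        1 for e in PROBE_EPOCHS
        if affected.get(e, 0.0) > ARTIFACT_EPOCH_FRACTION_LIMIT
    )
    quality = "low" if n_bad_probes >= 2 else "high"
    return replace(recording, data=data), quality
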