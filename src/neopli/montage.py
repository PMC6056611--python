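"""Electrode montage, recording containers, and file I/O.

The package works in sensor space on the fixed 21-electrode International
10-20 montage used for neonatal clinical EEG (including the A1/A2 ear
electrodes, which are full members of the montage, of the average reference
and of every channel pair).  Channel order is the package's canonical
convention and every matrix in the pipeline follows it.

Supported on-disk formats: EDF/EDF+ for recordings, plain numeric text
matrices (samples x channels, tab/comma/whitespace delimited) and CSV for
subject metadata tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CHANNELS_1020",
    "Montage",
    "Recording",
    "SubjectRecord",
    "MontageError",
    "read_edf",
    "write_edf",
    "read_text_matrix",
    "write_text_matrix",
    "read_metadata",
    "write_metadata",
]

#: Canonical channel order. The ten-twenty montage as listed in routine
#: neonatal recordings; this exact ordering defines pair indices 0..209.
CHANNELS_1020: tuple[str, ...] = (
    "Fp2", "Fp1", "F8", "F7", "F4", "F3", "A2", "A1", "T4", "T3",
    "C4", "C3", "T6", "T5", "P4", "P3", "O2", "O1", "Fz", "Cz", "Pz",
)

DIAGNOSES: tuple[str, ...] = (
    "asphyxia", "hemorrhage/infarction", "infection",
    "prematurity complication", "malformation",
    "epileptic encephalopathy", "other", "none",
)


class MontageError(ValueError):
    """Raised when channels cannot be mapped onto the canonical montage."""


@dataclass(frozen=True)
class Montage:
    """The fixed 21-channel montage with canonical pair indexing.

    Unordered channel pairs (i, j), i < j, are numbered 0..209 in row-major
    order of the upper triangle of the canonical channel order, i.e.
    (0,1), (0,2), ..., (0,20), (1,2), ..., (19,20).
    """

    electrode_names: tuple[str, ...] = CHANNELS_1020

    def __post_init__(self) -> None:
        if len(self.electrode_names) != len(set(self.electrode_names)):
            raise MontageError("duplicate electrode names in montage")
        if set(self.electrode_names) != set(CHANNELS_1020):
            missing = set(CHANNELS_1020) - set(self.electrode_names)
            extra = set(self.electrode_names) - set(CHANNELS_1020)
            raise MontageError(
                f"montage must be exactly the 21-channel 10-20 set; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.electrode_names)

    @property
    def n_pairs(self) -> int:
        n = self.n_channels
        return n * (n - 1) // 2

    def channel_index(self, name: str) -> int:
        try:
            return self.electrode_names.index(name)
        except ValueError:
            raise MontageError(f"channel {name!r} not in montage") from None

    def pair_index(self, i: int | str, j: int | str) -> int:
        """Index of the unordered pair in 0..209; symmetric in (i, j)."""
        if isinstance(i, str):
            i = self.channel_index(i)
        if isinstance(j, str):
            j = self.channel_index(j)
        if i == j:
            raise MontageError("self-pairs have no pair index")
        if i > j:
            i, j = j, i
        n = self.n_channels
        # row-major upper triangle offset
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    def pairs(self) -> list[tuple[int, int]]:
        """All 210 unordered pairs (i < j) in canonical pair-index order."""
        n = self.n_channels
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    def pair_labels(self) -> list[tuple[str, str]]:
        return [
            (self.electrode_names[i], self.electrode_names[j])
            for i, j in self.pairs()
        ]


DEFAULT_MONTAGE = Montage()


@dataclass
class Recording:
    """A multichannel EEG recording in canonical montage order.

    data
        channels x samples array of amplitudes in microvolts.
    sampling_rate
        sampling frequency in Hz.
    """

    data: np.ndarray
    sampling_rate: float
    montage: Montage = field(default_factory=Montage)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"expected {self.montage.n_channels} channels, "
                f"got {self.data.shape[0]}"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class SubjectRecord:
    """Clinical metadata for one subject.

    Ages are decimal weeks (40 weeks + 1 day = 40.142857...).  ``quality``
    (high/low) and ``clinical_normal`` are externally supplied labels — the
    visual scoring that produces them is outside this package and they are
    never computed from the signal.
    """

    subject_id: str
    pma_weeks: float
    ga_weeks: Optional[float] = None
    birth_weight_g: Optional[float] = None
    sex: Optional[str] = None
    diagnosis: Optional[str] = None
    quality: Optional[str] = None
    clinical_normal: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.pma_weeks > 0:
            raise ValueError(
                f"subject {self.subject_id!r}: pma_weeks must be positive"
            )
        if self.ga_weeks is not None:
            if not self.ga_weeks > 0:
                raise ValueError(
                    f"subject {self.subject_id!r}: ga_weeks must be positive"
                )
            if self.pma_weeks < self.ga_weeks:
                raise ValueError(
                    f"subject {self.subject_id!r}: pma_weeks < ga_weeks"
                )
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.quality is not None and self.quality not in ("high", "low"):
            raise ValueError(f"quality must be 'high' or 'low', got {self.quality!r}")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, montage: Montage | None = None,
             subject_id: str | None = None) -> Recording:
    """Read an EDF recording and reorder its channels to canonical order.

    Channels not in the montage are dropped; a montage channel missing from
    the file is a fatal error naming the channel.  Amplitudes are returned
    in microvolts.
    """
    montage = montage or DEFAULT_MONTAGE
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import mne  # local import: heavy module, only needed for EDF

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = {_norm_label(n): i for i, n in enumerate(raw.ch_names)}
    rows = []
    for ch in montage.electrode_names:
        key = _norm_label(ch)
        if key not in names:
            raise MontageError(f"EDF file {path.name} is missing montage channel {ch!r}")
        rows.append(names[key])
    data_uv = raw.get_data()[rows] * 1e6  # mne returns volts
    return Recording(
        data=data_uv,
        sampling_rate=float(raw.info["sfreq"]),
        montage=montage,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def _norm_label(label: str) -> str:
    """Normalise a channel label: strip 'EEG ' prefix, reference suffix, case."""
    lab = label.strip()
    if lab.upper().startswith("EEG "):
        lab = lab[4:]
    lab = lab.split("-")[0].strip()
    return lab.upper()


def write_edf(path: str | Path, recording: Recording) -> None:
    """Write a Recording as a 16-bit EDF file.

    A minimal writer for the plain EDF variant: one signal per channel,
    physical dimension microvolts, per-channel physical scaling to the full
    16-bit digital range.  Record duration is 1 s when the sample count is
    an integer number of seconds, otherwise a single record holding the
    whole signal is used.
    """
    _write_edf_raw(
        Path(path), recording.data, recording.sampling_rate,
        list(recording.montage.electrode_names),
        patient_id=recording.subject_id or "X",
    )


def _write_edf_raw(path: Path, data: np.ndarray, fs: float,
                   labels: Sequence[str], patient_id: str = "X") -> None:
    """Low-level EDF writer for arbitrary channel label sets."""
    data = np.asarray(data, dtype=np.float64)
    n_ch, n_samp = data.shape
    if len(labels) != n_ch:
        raise ValueError("one label per channel required")
    if n_samp % int(fs) == 0 and fs == int(fs):
        n_records = n_samp // int(fs)
        samples_per_record = int(fs)
        record_duration = 1.0
    else:
        n_records = 1
        samples_per_record = n_samp
        record_duration = n_samp / fs

    # physical range per channel; degenerate flat channels get a unit range
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    def f(x: object, width: int) -> bytes:
        s = str(x)
        if len(s) > width:
            s = s[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8),
        f(patient_id, 80),
        f("neopli", 80),
        f("01.01.00", 8),
        f("00.00.00", 8),
        f(256 + 256 * n_ch, 8),
        f("", 44),
        f(n_records, 8),
        f(f"{record_duration:g}", 8),
        f(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(f(ch, 16) for ch in labels),
        b"".join(f("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(f("uV", 8) for _ in range(n_ch)),
        b"".join(f(f"{v:.8g}"[:8], 8) for v in pmin),
        b"".join(f(f"{v:.8g}"[:8], 8) for v in pmax),
        b"".join(f(dmin, 8) for _ in range(n_ch)),
        b"".join(f(dmax, 8) for _ in range(n_ch)),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f(samples_per_record, 8) for _ in range(n_ch)),
        b"".join(f("", 32) for _ in range(n_ch)),
    ])
    # re-read the physical min/max exactly as written so scaling matches
    pmin_w = np.array([float(f"{v:.8g}"[:8]) for v in pmin])
    pmax_w = np.array([float(f"{v:.8g}"[:8]) for v in pmax])
    scale = (dmax - dmin) / (pmax_w - pmin_w)
    digital = np.rint(
        (data - pmin_w[:, None]) * scale[:, None] + dmin
    ).clip(dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for rec in range(n_records):
            sl = slice(rec * samples_per_record, (rec + 1) * samples_per_record)
            fh.write(digital[:, sl].tobytes())


# ---------------------------------------------------------------------------
# Plain text matrices
# ---------------------------------------------------------------------------

def read_text_matrix(path: str | Path, sampling_rate: float,
                     montage: Montage | None = None,
                     subject_id: str | None = None) -> Recording:
    """Read a samples-x-channels numeric text matrix (ASCII export format).

    The delimiter is auto-detected among tab, comma and whitespace.  Columns
    are interpreted in canonical montage order.
    """
    montage = montage or DEFAULT_MONTAGE
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if "\t" in line:
                parts = line.split("\t")
            elif "," in line:
                parts = line.split(",")
            else:
                parts = line.split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}: non-numeric value at row {lineno}: {exc}"
                ) from None
            if len(rows[-1]) != montage.n_channels:
                raise ValueError(
                    f"{path.name}: expected {montage.n_channels} columns, "
                    f"found {len(rows[-1])} at row {lineno}"
                )
    if not rows:
        raise ValueError(f"{path.name}: empty matrix")
    data = np.asarray(rows, dtype=np.float64).T  # -> channels x samples
    return Recording(
        data=data, sampling_rate=sampling_rate, montage=montage,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_text_matrix(path: str | Path, recording: Recording,
                      fmt: str = "%.8e", delimiter: str = "\t") -> None:
    """Write a Recording as a samples-x-channels text matrix."""
    np.savetxt(path, recording.data.T, fmt=fmt, delimiter=delimiter)


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

_OPTIONAL_FLOAT = ("ga_weeks", "birth_weight_g")
_TRUE = {"1", "true", "yes", "normal"}
_FALSE = {"0", "false", "no", "abnormal"}


def read_metadata(path: str | Path) -> list[SubjectRecord]:
    """Read a subject metadata CSV into SubjectRecords.

    Required columns: ``subject_id``, ``pma_weeks``.  Optional columns
    (``ga_weeks``, ``birth_weight_g``, ``sex``, ``diagnosis``, ``quality``,
    ``clinical_normal``) may be absent or empty; empty cells are recorded
    as missing.  Duplicate subject ids and non-positive PMA are fatal.
    """
    path = Path(path)
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "subject_id", "pma_weeks"
        }.issubset(reader.fieldnames):
            raise ValueError(
                f"{path.name}: metadata table needs columns subject_id, pma_weeks"
            )
        for rownum, row in enumerate(reader, start=2):
            sid = (row.get("subject_id") or "").strip()
            if not sid:
                raise ValueError(f"{path.name}: empty subject_id at row {rownum}")
            if sid in seen:
                raise ValueError(f"{path.name}: duplicate subject_id {sid!r}")
            seen.add(sid)
            try:
                pma = float(row["pma_weeks"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path.name}: bad pma_weeks at row {rownum}"
                ) from None
            if not pma > 0:
                raise ValueError(
                    f"{path.name}: non-positive pma_weeks at row {rownum}"
                )
            kwargs: dict = {}
            for col in _OPTIONAL_FLOAT:
                val = (row.get(col) or "").strip()
                kwargs[col] = float(val) if val else None
            for col in ("sex", "diagnosis", "quality"):
                val = (row.get(col) or "").strip()
                kwargs[col] = val if val else None
            val = (row.get("clinical_normal") or "").strip().lower()
            if val in _TRUE:
                kwargs["clinical_normal"] = True
            elif val in _FALSE:
                kwargs["clinical_normal"] = False
            else:
                kwargs["clinical_normal"] = None
            records.append(SubjectRecord(subject_id=sid, pma_weeks=pma, **kwargs))
    return records


def write_metadata(path: str | Path, records: Sequence[SubjectRecord]) -> None:
    """Write SubjectRecords to CSV (inverse of :func:`read_metadata`)."""
    cols = ["subject_id", "pma_weeks", "ga_weeks", "birth_weight_g",
            "sex", "diagnosis", "quality", "clinical_normal"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            writer.writerow([
                r.subject_id,
                f"{r.pma_weeks:.6f}",
                "" if r.ga_weeks is None else f"{r.ga_weeks:.6f}",
                "" if r.birth_weight_g is None else f"{r.birth_weight_g:.1f}",
                r.sex or "",
                r.diagnosis or "",
                r.quality or "",
                "" if r.clinical_normal is None else str(r.clinical_normal).lower(),
            ])
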