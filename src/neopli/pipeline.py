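"""Cohort orchestration: preprocessing -> PLI -> statistics -> report.

``run_subject`` turns one raw recording into per-band mPLI/pwPLI and
relative band power; ``run_cohort`` assembles the per-subject results into
the cohort statistical battery: the per-band correlation table, the
regression and hierarchical steps in the band with the strongest global
association, sex and asphyxia contrasts, subgroup reruns (high-quality
EEGs, clinically normal EEGs), the per-pair topography map, and the
delta-power summary.  ``write_report`` serialises everything to CSV with a
config-hash provenance header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .montage import Recording, SubjectRecord
from .pli import PLIMatrix, epoch_set_pli
from .preprocess import (
    BANDS, EPOCH_LENGTH, N_EPOCHS, TARGET_RATE,
    average_reference, bandpass, downsample, segment_epochs,
)
from .spectral import subject_relative_band_power
from .stats import (
    ALPHA_GLOBAL, ALPHA_LOCAL, CorrelationResult, GroupContrast,
    HierarchicalStep, RegressionResult, TopographyResult, correlate_band,
    fit_linear_model, hierarchical_regression, mann_whitney,
    topography_correlations,
)

__all__ = ["RunConfig", "SubjectResult", "CohortReport",
           "run_subject", "run_cohort", "write_report"]

log = logging.getLogger(__name__)

DELTA_POWER_THRESHOLD = 0.60


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; defaults are the standard study conditions."""

    bands: tuple[str, ...] = tuple(BANDS)
    epoch_length: int = EPOCH_LENGTH
    n_epochs: int = N_EPOCHS
    target_rate: float = TARGET_RATE
    allow_short: bool = False
    antialias: bool = False
    power_band: str = "delta"
    topography_band: Optional[str] = None   # None = strongest global band
    covariates: tuple[str, ...] = ("ga_weeks", "birth_weight_g")
    run_topography: bool = True
    run_contrasts: bool = True
    run_subgroups: bool = True
    alpha_global: float = ALPHA_GLOBAL
    alpha_local: float = ALPHA_LOCAL
    min_longitudinal_points: int = 6

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        for key in ("bands", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class SubjectResult:
    """Per-subject analysis bundle."""

    subject_id: str
    mpli: dict[str, float]                 # band -> mPLI
    pwpli: dict[str, PLIMatrix]            # band -> 21x21 epoch-mean matrix
    relative_power: dict[str, float]       # band -> relative power share
    n_epochs: int
    flags: list[str] = field(default_factory=list)


def run_subject(recording: Recording, config: RunConfig | None = None
                ) -> SubjectResult:
    """Full per-subject chain: reference, decimate, epoch, filter, PLI.

    Returns the per-band mPLI and pwPLI plus the relative power of the
    configured band, computed on the unfiltered epochs.
    """
    config = config or RunConfig()
    flags: list[str] = []
    rec = average_reference(recording)
    rec = downsample(rec, config.target_rate, antialias=config.antialias)
    epochs = segment_epochs(rec, config.epoch_length, config.n_epochs,
                            allow_short=config.allow_short)
    if epochs.n_epochs < config.n_epochs:
        flags.append(f"short_recording:{epochs.n_epochs}_epochs")
    zero = ~np.any(epochs.epochs != 0.0, axis=(0, 2))
    if np.any(zero):
        flags.append(f"zero_channels:{int(zero.sum())}")
    mpli: dict[str, float] = {}
    pwpli: dict[str, PLIMatrix] = {}
    for name in config.bands:
        filtered = bandpass(epochs, BANDS[name])
        mpli[name], pwpli[name] = epoch_set_pli(filtered, recording.montage)
    rel = {
        config.power_band: subject_relative_band_power(
            epochs, BANDS[config.power_band]
        )
    }
    log.debug("subject %s: %d epochs, flags=%s",
              recording.subject_id, epochs.n_epochs, flags)
    return SubjectResult(
        subject_id=recording.subject_id, mpli=mpli, pwpli=pwpli,
        relative_power=rel, n_epochs=epochs.n_epochs, flags=flags,
    )


@dataclass
class CohortReport:
    """All cohort-level outputs for one analysis run."""

    config: RunConfig
    subject_table: pd.DataFrame
    band_correlations: dict[str, CorrelationResult]
    strongest_band: str
    regression: RegressionResult
    hierarchical: list[HierarchicalStep]
    contrasts: dict[str, GroupContrast]
    subgroup_correlations: dict[str, CorrelationResult]
    topography: Optional[TopographyResult]
    power_band: str
    high_power_fraction: float
    n_subjects: int


def run_cohort(
    subjects: Iterable[tuple[Recording, SubjectRecord]],
    config: RunConfig | None = None,
) -> CohortReport:
    """Run the whole battery over (recording, metadata) pairs.

    Recordings are consumed one at a time, so the iterable may generate
    them lazily.  Requires at least 3 subjects.  Analyses whose metadata
    columns are entirely missing are skipped with a logged warning.
    """
    config = config or RunConfig()
    rows = []
    pw_store: dict[str, list[PLIMatrix]] = {b: [] for b in config.bands}
    records: list[SubjectRecord] = []
    for recording, record in subjects:
        res = run_subject(recording, config)
        row = {
            "subject_id": record.subject_id,
            "pma_weeks": record.pma_weeks,
            "ga_weeks": record.ga_weeks,
            "birth_weight_g": record.birth_weight_g,
            "sex": record.sex,
            "diagnosis": record.diagnosis,
            "quality": record.quality,
            "clinical_normal": record.clinical_normal,
            "n_epochs": res.n_epochs,
            f"rel_power_{config.power_band}": res.relative_power[config.power_band],
        }
        for b in config.bands:
            row[f"mpli_{b}"] = res.mpli[b]
            pw_store[b].append(res.pwpli[b])
        rows.append(row)
        records.append(record)
    table = pd.DataFrame(rows)
    n = len(table)
    if n < 3:
        raise ValueError(f"cohort analysis needs >= 3 subjects, got {n}")

    pma = table["pma_weeks"].to_numpy(dtype=float)

    band_corr = {
        b: correlate_band(pma, table[f"mpli_{b}"].to_numpy(dtype=float))
        for b in config.bands
    }
    strongest = max(band_corr, key=lambda b: abs(band_corr[b].coefficient))
    log.info("strongest global association: %s band (r=%.3f)",
             strongest, band_corr[strongest].coefficient)
    y = table[f"mpli_{strongest}"].to_numpy(dtype=float)
    regression = fit_linear_model(pma, y)

    covs = {}
    for name in config.covariates:
        col = table[name].to_numpy(dtype=float) if name in table else None
        if col is None or np.all(~np.isfinite(col)):
            log.warning("covariate %r entirely missing; step skipped", name)
            continue
        covs[name] = col
    hierarchical = hierarchical_regression(pma, y, covs) if covs else []

    contrasts: dict[str, GroupContrast] = {}
    if config.run_contrasts:
        sex = table["sex"]
        if sex.notna().all() and sex.nunique() == 2:
            contrasts["sex"] = mann_whitney(
                y[(sex == "male").to_numpy()], y[(sex == "female").to_numpy()]
            )
        else:
            log.warning("sex contrast skipped (missing or one-level)")
        diag = table["diagnosis"]
        if diag.notna().any():
            is_asp = (diag == "asphyxia").to_numpy()
            if is_asp.any() and (~is_asp).any():
                contrasts["asphyxia"] = mann_whitney(y[is_asp], y[~is_asp])
            else:
                log.warning("asphyxia contrast skipped (one-sided grouping)")

    subgroups: dict[str, CorrelationResult] = {}
    if config.run_subgroups:
        hq = (table["quality"] == "high").to_numpy()
        if hq.sum() >= 3:
            subgroups["quality_high"] = correlate_band(pma[hq], y[hq])
        else:
            log.warning("high-quality subgroup too small; skipped")
        cn = (table["clinical_normal"] == True).to_numpy()  # noqa: E712
        if cn.sum() >= 3:
            subgroups["clinical_normal"] = correlate_band(pma[cn], y[cn])
        else:
            log.warning("clinically-normal subgroup too small; skipped")

    topography = None
    if config.run_topography:
        topo_band = config.topography_band or strongest
        topography = topography_correlations(
            pw_store[topo_band], pma, alpha=config.alpha_local
        )

    rel = table[f"rel_power_{config.power_band}"].to_numpy(dtype=float)
    high_frac = float((rel > DELTA_POWER_THRESHOLD).mean())

    return CohortReport(
        config=config,
        subject_table=table,
        band_correlations=band_corr,
        strongest_band=strongest,
        regression=regression,
        hierarchical=hierarchical,
        contrasts=contrasts,
        subgroup_correlations=subgroups,
        topography=topography,
        power_band=config.power_band,
        high_power_fraction=high_frac,
        n_subjects=n,
    )


def _header(config: RunConfig) -> str:
    return f"# neopli {__version__} config_hash={config.config_hash()}\n"


def write_report(report: CohortReport, outdir: str | Path) -> None:
    """Serialise a CohortReport to CSV files in ``outdir``.

    Every file starts with a provenance comment carrying the package
    version and the config hash; the config itself is copied verbatim to
    ``config.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = _header(report.config)
    (outdir / "config.json").write_text(report.config.to_json() + "\n")

    def dump(name: str, df: pd.DataFrame) -> None:
        with open(outdir / name, "w") as fh:
            fh.write(head)
            df.to_csv(fh, index=False)

    dump("subjects.csv", report.subject_table)
    dump("band_correlations.csv", pd.DataFrame([
        {"band": b, "coefficient": c.coefficient, "p_value": c.p_value,
         "method": c.method, "n": c.n,
         "significant": c.significant(report.config.alpha_global)}
        for b, c in report.band_correlations.items()
    ]))
    r = report.regression
    dump("regression.csv", pd.DataFrame([{
        "band": report.strongest_band, "b0": r.intercept_b0, "b1": r.slope_b1,
        "t_b0": r.t_b0, "t_b1": r.t_b1, "p_b0": r.p_b0, "p_b1": r.p_b1,
        "f": r.f_stat, "df1": r.df_model, "df2": r.df_resid,
        "p_model": r.p_model, "r": r.r, "r_squared": r.r_squared, "n": r.n,
    }]))
    if report.hierarchical:
        dump("hierarchical.csv", pd.DataFrame([
            {"added_covariate": s.added_covariate,
             "r_squared_change": s.r_squared_change, "f_change": s.f_change,
             "df1": s.df1, "df2": s.df2, "p_change": s.p_change,
             "r_squared_full": s.r_squared_full, "n": s.n}
            for s in report.hierarchical
        ]))
    if report.contrasts:
        dump("contrasts.csv", pd.DataFrame([
            {"contrast": k, "u": c.u, "z": c.z, "p": c.p,
             "n1": c.n1, "n2": c.n2}
            for k, c in report.contrasts.items()
        ]))
    if report.subgroup_correlations:
        dump("subgroups.csv", pd.DataFrame([
            {"subgroup": k, "coefficient": c.coefficient, "p_value": c.p_value,
             "method": c.method, "n": c.n}
            for k, c in report.subgroup_correlations.items()
        ]))
    if report.topography is not None:
        topo = report.topography
        rank_of = {int(idx): r for r, idx in enumerate(topo.ranking)}
        dump("topography.csv", pd.DataFrame([
            {"pair_index": i, "electrode_i": a, "electrode_j": b,
             "coefficient": topo.coefficients[i], "p_value": topo.p_values[i],
             "significant": bool(topo.significant[i]),
             "rank": rank_of.get(i, "")}
            for i, (a, b) in enumerate(topo.pair_labels)
        ]))
    dump("power_summary.csv", pd.DataFrame([{
        "band": report.power_band,
        "threshold": DELTA_POWER_THRESHOLD,
        "fraction_above": report.high_power_fraction,
        "n": report.n_subjects,
    }]))
    log.info("report written to %s", outdir)
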