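"""Synthetic cohort generator.

Forward-simulates, per patient, the three dynamic acquisitions the
analysis consumes — a dynamic amino-acid PET lesion/reference curve pair,
a DSC first-pass bolus signal pair, and a DCE tissue-concentration curve —
from label-conditional ground-truth kinetic parameters, then extracts the
per-patient metric table with the package's own measurement code. Every
downstream statistic is therefore testable end-to-end without any image
download, and noiseless curves round-trip their generating parameters.

Generative model
----------------
* PET: the frame-wise tumor-to-brain ratio follows a wash-in ramp from
  zero that joins, at ``ttp_center``, a late linear phase
  ``L(t) = tbr_plateau + washout_slope * (t - 1800 s)`` (slope in TBR/h,
  anchored at the late-window center). Progressive lesions have a
  negative late slope, so the join is the global peak; treatment-change
  lesions keep rising and peak at scan end. Lesion SUV is the TBR curve
  times the (constant) reference uptake; noise is additive Gaussian on
  SUV (no Poisson count simulation).
* DSC: a shared gamma-variate bolus shape whose lesion amplitude is
  ``rcbv_true`` times the reference amplitude, converted to signal via
  ``S = S0 exp(-TE * dR2*)``.
* DCE: the two-parameter Tofts forward model driven by a population
  biexponential arterial input function, plus proportional Gaussian noise.

MRI lesion-volume change is carried as a plain per-patient scalar
(volumetry from images is out of scope).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .diagnostics import POD, TRC
from .kinetics import (
    FrameSchedule,
    TimeActivityCurve,
    PetMetrics,
    pet_metrics,
)
from .perfusion import (
    AifModel,
    BiexponentialAif,
    PerfusionMetrics,
    dsc_delta_r2star,
    rcbv_ratio,
    tofts_forward,
    tofts_fit,
)

__all__ = [
    "ATDG",
    "BM",
    "COHORT_COLUMNS",
    "AcquisitionConfig",
    "KineticProfile",
    "LabelEffects",
    "CohortEffects",
    "PatientRecord",
    "Cohort",
    "DscSignals",
    "Phantom",
    "default_acquisition",
    "simulate_pet_tac",
    "simulate_dsc_signal",
    "simulate_dce_concentration",
    "simulate_phantom_image",
    "generate_cohort",
    "write_cohort",
]

ATDG = "ATDG"  # adult-type diffuse glioma (WHO CNS grade 3-4)
BM = "BM"  # brain metastasis

#: Canonical cohort CSV schema (one row per patient).
COHORT_COLUMNS = (
    "patient_id",
    "truth_label",
    "origin",
    "suv_mean",
    "suv_max",
    "suv_slope",
    "suv_intercept",
    "tbr_mean",
    "tbr_max",
    "tbr_slope",
    "tbr_intercept",
    "ttp_s",
    "rcbv",
    "ktrans",
    "ve",
    "volume_change_pct",
)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scanner/protocol constants shared by the whole cohort.

    PET is acquired 0-40 min post-injection; DSC at 2.02 s temporal
    resolution with a 30 ms echo time; DCE at 2.70 s resolution.
    """

    pet_scan_start_s: float = 0.0
    pet_scan_end_s: float = 2400.0
    pet_frame_schedule: FrameSchedule = field(
        default_factory=FrameSchedule.default_dynamic
    )
    injected_dose_mbq: float = 650.0
    dose_range_mbq: tuple[float, float] = (503.0, 810.0)
    body_weight_kg: float = 75.0
    dsc_echo_time_s: float = 0.030
    dsc_temporal_resolution_s: float = 2.020
    dsc_duration_s: float = 120.0
    dce_temporal_resolution_s: float = 2.70
    dce_duration_s: float = 300.0

    def __post_init__(self) -> None:
        sched = self.pet_frame_schedule
        if not np.isclose(sched.starts[0], self.pet_scan_start_s) or not np.isclose(
            sched.ends[-1], self.pet_scan_end_s
        ):
            raise ValueError("frame schedule must span the full PET scan window")
        if not np.allclose(sched.starts[1:], sched.ends[:-1]):
            raise ValueError("frames must be contiguous")
        lo, hi = self.dose_range_mbq
        if not (lo <= self.injected_dose_mbq <= hi):
            raise ValueError(
                f"injected dose {self.injected_dose_mbq} MBq outside [{lo}, {hi}]"
            )
        for name in (
            "body_weight_kg",
            "dsc_echo_time_s",
            "dsc_temporal_resolution_s",
            "dsc_duration_s",
            "dce_temporal_resolution_s",
            "dce_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def default_acquisition() -> AcquisitionConfig:
    return AcquisitionConfig()


@dataclass(frozen=True)
class KineticProfile:
    """Ground-truth generative parameters for one simulated patient."""

    truth_label: str  # POD or TRC
    origin: str = ATDG  # ATDG or BM
    tbr_plateau: float = 3.0  # late-window TBR level (dimensionless)
    washout_slope: float = -1.0  # TBR/h, signed
    ttp_center_s: float = 900.0  # wash-in completion time
    reference_suv: float = 1.0
    noise_sd: float = 0.0  # additive SUV noise per frame
    rcbv_true: float = 4.5
    ktrans_true: float = 0.8  # 1/min
    ve_true: float = 0.4
    volume_change_true: float = 25.0  # percent
    dsc_noise_sd: float = 0.0  # additive signal noise, same units as S0
    dce_noise_frac: float = 0.0  # Gaussian sd as a fraction of peak Ct

    def __post_init__(self) -> None:
        if self.truth_label not in (POD, TRC):
            raise ValueError("truth_label must be POD or TRC")
        if self.origin not in (ATDG, BM):
            raise ValueError("origin must be ATDG or BM")
        if self.tbr_plateau < 0:
            raise ValueError("tbr_plateau must be non-negative")
        if self.reference_suv <= 0:
            raise ValueError("reference_suv must be positive")
        if not (0 < self.ve_true <= 1):
            raise ValueError("ve_true must lie in (0, 1]")
        if self.ktrans_true < 0 or self.rcbv_true <= 0 or self.noise_sd < 0:
            raise ValueError("invalid kinetic profile parameter")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _tbr_truth_curve(profile: KineticProfile, times_s: np.ndarray) -> np.ndarray:
    """Noiseless frame-wise TBR: min(wash-in ramp, late line), clipped at 0."""
    slope_per_s = profile.washout_slope / 3600.0
    late = profile.tbr_plateau + slope_per_s * (times_s - 1800.0)
    peak = profile.tbr_plateau + slope_per_s * (profile.ttp_center_s - 1800.0)
    if profile.tbr_plateau == 0:
        return np.zeros_like(times_s)
    if peak <= 0 or profile.ttp_center_s <= 0:
        raise ValueError("profile implies a non-positive uptake peak")
    ramp = times_s * (peak / profile.ttp_center_s)
    return np.clip(np.minimum(ramp, late), 0.0, None)


def simulate_pet_tac(
    profile: KineticProfile,
    acq: AcquisitionConfig | None = None,
    seed=0,
) -> tuple[TimeActivityCurve, TimeActivityCurve]:
    """Simulate one lesion/reference SUV curve pair.

    Returns ``(lesion, reference)`` time-activity curves in SUV units;
    with ``noise_sd = 0`` the frame-wise lesion/reference ratio equals the
    profile's truth TBR curve exactly.
    """
    acq = acq or default_acquisition()
    rng = _rng(seed)
    sched = acq.pet_frame_schedule
    t = sched.midpoints
    tbr = _tbr_truth_curve(profile, t)
    lesion = tbr * profile.reference_suv
    reference = np.full_like(t, profile.reference_suv)
    if profile.noise_sd > 0:
        lesion = lesion + rng.normal(0.0, profile.noise_sd, size=t.size)
        reference = reference + rng.normal(0.0, profile.noise_sd, size=t.size)
        reference = np.clip(reference, 0.05 * profile.reference_suv, None)
    return (
        TimeActivityCurve(sched, lesion, unit="SUV"),
        TimeActivityCurve(sched, reference, unit="SUV"),
    )


@dataclass
class DscSignals:
    """One simulated DSC acquisition: lesion and reference signal curves."""

    times_s: np.ndarray
    lesion: np.ndarray
    reference: np.ndarray
    s0: float
    baseline_frames: int
    echo_time_s: float


def simulate_dsc_signal(
    profile: KineticProfile,
    acq: AcquisitionConfig | None = None,
    seed=0,
    s0: float = 100.0,
    bolus_arrival_s: float = 12.0,
    bolus_alpha: float = 3.0,
    bolus_beta_s: float = 4.5,
    reference_peak_dr2: float = 20.0,
) -> DscSignals:
    """Simulate lesion and reference DSC signal curves.

    Both tissues see the same gamma-variate bolus
    ``g(t) ~ (t - t0)^alpha exp(-(t - t0)/beta)``; the lesion relaxation
    amplitude is ``rcbv_true`` times the reference amplitude, so the
    noiseless integrated-area ratio recovers ``rcbv_true`` exactly.
    """
    acq = acq or default_acquisition()
    rng = _rng(seed)
    t = np.arange(0.0, acq.dsc_duration_s, acq.dsc_temporal_resolution_s)
    tau = np.clip(t - bolus_arrival_s, 0.0, None)
    g = tau**bolus_alpha * np.exp(-tau / bolus_beta_s)
    peak = g.max()
    if peak > 0:
        g = g / peak
    ref_dr2 = reference_peak_dr2 * g
    lesion_dr2 = profile.rcbv_true * ref_dr2
    te = acq.dsc_echo_time_s
    lesion_sig = s0 * np.exp(-te * lesion_dr2)
    ref_sig = s0 * np.exp(-te * ref_dr2)
    if profile.dsc_noise_sd > 0:
        lesion_sig = lesion_sig + rng.normal(0, profile.dsc_noise_sd, t.size)
        ref_sig = ref_sig + rng.normal(0, profile.dsc_noise_sd, t.size)
        floor = 1e-3 * s0
        lesion_sig = np.clip(lesion_sig, floor, None)
        ref_sig = np.clip(ref_sig, floor, None)
    n_baseline = max(1, int(bolus_arrival_s // acq.dsc_temporal_resolution_s))
    return DscSignals(
        times_s=t,
        lesion=lesion_sig,
        reference=ref_sig,
        s0=s0,
        baseline_frames=n_baseline,
        echo_time_s=te,
    )


def simulate_dce_concentration(
    profile: KineticProfile,
    acq: AcquisitionConfig | None = None,
    aif: AifModel | None = None,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one DCE tissue-concentration curve.

    Returns ``(times_s, ct)`` with ``ct`` the Tofts forward solution for
    the profile's true ``Ktrans``/``ve`` plus proportional Gaussian noise.
    """
    acq = acq or default_acquisition()
    aif = aif or BiexponentialAif()
    rng = _rng(seed)
    t = np.arange(0.0, acq.dce_duration_s, acq.dce_temporal_resolution_s)
    ct = tofts_forward(profile.ktrans_true, profile.ve_true, aif, t)
    if profile.dce_noise_frac > 0 and ct.max() > 0:
        ct = ct + rng.normal(0.0, profile.dce_noise_frac * ct.max(), t.size)
    return t, ct


@dataclass
class Phantom:
    """A small 4-D dynamic phantom with lesion and reference masks."""

    data: np.ndarray  # (x, y, z, frame)
    lesion_mask: np.ndarray
    reference_mask: np.ndarray
    schedule: FrameSchedule


def simulate_phantom_image(
    profile: KineticProfile,
    acq: AcquisitionConfig | None = None,
    grid: tuple[int, int, int] = (12, 12, 6),
    seed=0,
    background: float = 0.0,
) -> Phantom:
    """Paint lesion and reference curves into a small 4-D dynamic volume.

    Lesion voxels follow the lesion curve, reference voxels the reference
    curve, all other voxels a constant background; the two masks are
    disjoint boxes. Intended for exercising image-based curve extraction.
    """
    acq = acq or default_acquisition()
    grid = tuple(int(g) for g in grid)
    if len(grid) != 3 or min(grid) < 2:
        raise ValueError("grid must be 3-D with at least 2 voxels per axis")
    if max(grid) > 32:
        raise ValueError("phantom grids are capped at 32 voxels per axis")
    lesion_tac, ref_tac = simulate_pet_tac(profile, acq, seed)
    nx, ny, nz = grid
    nt = lesion_tac.values.size
    data = np.full((nx, ny, nz, nt), background, dtype=float)
    lesion_mask = np.zeros(grid, dtype=bool)
    reference_mask = np.zeros(grid, dtype=bool)
    lesion_mask[: nx // 2 - 1, : ny // 2, :] = True
    reference_mask[nx // 2 :, ny // 2 :, :] = True
    if (lesion_mask & reference_mask).any():
        raise ValueError("lesion and reference masks overlap")
    data[lesion_mask, :] = lesion_tac.values
    data[reference_mask, :] = ref_tac.values
    return Phantom(
        data=data,
        lesion_mask=lesion_mask,
        reference_mask=reference_mask,
        schedule=lesion_tac.schedule,
    )


# ---------------------------------------------------------------------------
# Label-conditional effect configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelEffects:
    """Generative distributions for one diagnostic class.

    Ratio-scale parameters (TBR plateau, rCBV, Ktrans, reference SUV) are
    log-normal, given by median and log-scale sigma; the others are
    (truncated) normal.
    """

    tbr_plateau_median: float
    tbr_plateau_sigma: float
    washout_slope_mean: float  # TBR/h
    washout_slope_sd: float
    ttp_center_mean_s: float
    ttp_center_sd_s: float
    rcbv_median: float
    rcbv_sigma: float
    ktrans_median: float  # 1/min
    ktrans_sigma: float
    ve_mean: float
    ve_sd: float
    volume_change_mean: float  # percent
    volume_change_sd: float


@dataclass(frozen=True)
class CohortEffects:
    """Full effect configuration: one distribution set per class plus the
    shared nuisance settings (reference uptake, noise levels)."""

    pod: LabelEffects
    trc: LabelEffects
    reference_suv_median: float = 1.0
    reference_suv_sigma: float = 0.2
    noise_sd: float = 0.05
    dsc_noise_sd: float = 1.0
    dce_noise_frac: float = 0.05

    def draw_profile(
        self, label: str, origin: str, rng: np.random.Generator
    ) -> KineticProfile:
        eff = self.pod if label == POD else self.trc
        tbr = float(rng.lognormal(np.log(eff.tbr_plateau_median), eff.tbr_plateau_sigma))
        slope = float(rng.normal(eff.washout_slope_mean, eff.washout_slope_sd))
        ttp = float(
            np.clip(rng.normal(eff.ttp_center_mean_s, eff.ttp_center_sd_s), 120.0, 2340.0)
        )
        rcbv = float(rng.lognormal(np.log(eff.rcbv_median), eff.rcbv_sigma))
        ktrans = float(rng.lognormal(np.log(eff.ktrans_median), eff.ktrans_sigma))
        ve = float(np.clip(rng.normal(eff.ve_mean, eff.ve_sd), 0.05, 0.95))
        vol = float(rng.normal(eff.volume_change_mean, eff.volume_change_sd))
        ref = float(rng.lognormal(np.log(self.reference_suv_median), self.reference_suv_sigma))
        # Guard: the late line must stay positive across the scan for a
        # physically meaningful uptake curve.
        min_late = tbr - abs(slope) * (1800.0 / 3600.0)
        if min_late <= 0.05:
            slope = float(np.sign(slope) * (tbr - 0.05) * 2.0) if tbr > 0.05 else 0.0
        return KineticProfile(
            truth_label=label,
            origin=origin,
            tbr_plateau=tbr,
            washout_slope=slope,
            ttp_center_s=ttp,
            reference_suv=ref,
            noise_sd=self.noise_sd,
            rcbv_true=rcbv,
            ktrans_true=ktrans,
            ve_true=ve,
            volume_change_true=vol,
            dsc_noise_sd=self.dsc_noise_sd,
            dce_noise_frac=self.dce_noise_frac,
        )


#: Default study conditions: progressive lesions show high plateau uptake
#: with early peak and washout, high blood volume and permeability;
#: treatment-related change shows lower, slowly rising uptake.
DEFAULT_EFFECTS = CohortEffects(
    pod=LabelEffects(
        tbr_plateau_median=3.0,
        tbr_plateau_sigma=0.25,
        washout_slope_mean=-1.0,
        washout_slope_sd=0.9,
        ttp_center_mean_s=900.0,
        ttp_center_sd_s=600.0,
        rcbv_median=4.5,
        rcbv_sigma=0.45,
        ktrans_median=0.8,
        ktrans_sigma=0.55,
        ve_mean=0.45,
        ve_sd=0.15,
        volume_change_mean=25.0,
        volume_change_sd=20.0,
    ),
    trc=LabelEffects(
        tbr_plateau_median=1.8,
        tbr_plateau_sigma=0.25,
        washout_slope_mean=0.4,
        washout_slope_sd=0.9,
        ttp_center_mean_s=2100.0,
        ttp_center_sd_s=600.0,
        rcbv_median=2.5,
        rcbv_sigma=0.45,
        ktrans_median=0.4,
        ktrans_sigma=0.55,
        ve_mean=0.30,
        ve_sd=0.10,
        volume_change_mean=5.0,
        volume_change_sd=15.0,
    ),
)


@dataclass
class PatientRecord:
    """Synthetic twin of one per-patient table row."""

    patient_id: str
    truth_label: str
    origin: str
    pet: PetMetrics | None = None
    perfusion: PerfusionMetrics | None = None
    volume_change_pct: float = float("nan")
    pet_call: str | None = None
    mri_call: str | None = None
    hybrid_call: str | None = None
    profile: KineticProfile | None = None
    lesion_tac: TimeActivityCurve | None = None
    reference_tac: TimeActivityCurve | None = None
    dsc: DscSignals | None = None
    dce_times_s: np.ndarray | None = None
    dce_ct: np.ndarray | None = None
    extra_scores: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "patient_id": self.patient_id,
            "truth_label": self.truth_label,
            "origin": self.origin,
            "volume_change_pct": self.volume_change_pct,
        }
        pet = self.pet.to_dict() if self.pet else {}
        perf = self.perfusion.to_dict() if self.perfusion else {}
        for col in COHORT_COLUMNS:
            if col in row:
                continue
            row[col] = pet.get(col, perf.get(col, float("nan")))
        row.update(self.extra_scores)
        return row


@dataclass
class Cohort:
    """A generated or loaded cohort: records plus generation metadata."""

    records: list[PatientRecord]
    seed: int | None = None
    acquisition: AcquisitionConfig | None = None

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self):
        import pandas as pd

        rows = [r.to_row() for r in self.records]
        extra = sorted({k for r in rows for k in r} - set(COHORT_COLUMNS))
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS) + extra)


def generate_cohort(
    n: int,
    prevalence: float = 42.0 / 80.0,
    origin_mix: float = 42.0 / 80.0,
    seed: int | None = 0,
    effects: CohortEffects = DEFAULT_EFFECTS,
    acq: AcquisitionConfig | None = None,
    aif: AifModel | None = None,
    modalities: Sequence[str] = ("pet", "dsc", "dce"),
    keep_curves: bool = False,
) -> Cohort:
    """Generate ``n`` patients and measure them with the analysis pipeline.

    Labels are Bernoulli(``prevalence``) draws (POD positive), origins
    Bernoulli(``origin_mix``) (ATDG vs BM). For each requested modality
    the corresponding curves are simulated and *measured*: PET metrics via
    late-window kinetics, rCBV via bolus-area integration, Ktrans/ve via
    the Tofts fit. Identical ``(parameters, seed)`` reproduce the cohort
    bit for bit.
    """
    if n < 0:
        raise ValueError("cohort size must be non-negative")
    if not (0 <= prevalence <= 1):
        raise ValueError("prevalence must lie in [0, 1]")
    if not (0 <= origin_mix <= 1):
        raise ValueError("origin_mix must lie in [0, 1]")
    acq = acq or default_acquisition()
    aif = aif or BiexponentialAif()
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    for i in range(n):
        label = POD if rng.random() < prevalence else TRC
        origin = ATDG if rng.random() < origin_mix else BM
        profile = effects.draw_profile(label, origin, rng)
        rec = PatientRecord(
            patient_id=f"P{i + 1:04d}",
            truth_label=label,
            origin=origin,
            volume_change_pct=profile.volume_change_true,
            profile=profile,
        )
        if "pet" in modalities:
            lesion, reference = simulate_pet_tac(profile, acq, rng)
            rec.pet = pet_metrics(lesion, reference)
            if keep_curves:
                rec.lesion_tac, rec.reference_tac = lesion, reference
        if "dsc" in modalities or "dce" in modalities:
            rcbv = float("nan")
            ktrans = float("nan")
            ve = float("nan")
            if "dsc" in modalities:
                dsc = simulate_dsc_signal(profile, acq, rng)
                lesion_dr2 = dsc_delta_r2star(dsc.lesion, dsc.baseline_frames, dsc.echo_time_s)
                ref_dr2 = dsc_delta_r2star(dsc.reference, dsc.baseline_frames, dsc.echo_time_s)
                rcbv = rcbv_ratio(lesion_dr2, ref_dr2, dsc.times_s)
                if keep_curves:
                    rec.dsc = dsc
            if "dce" in modalities:
                t, ct = simulate_dce_concentration(profile, acq, aif, rng)
                ktrans, ve, _ = tofts_fit(ct, aif, t)
                if keep_curves:
                    rec.dce_times_s, rec.dce_ct = t, ct
            rec.perfusion = PerfusionMetrics(rcbv=rcbv, ktrans=ktrans, ve=ve)
        records.append(rec)
    return Cohort(records=records, seed=seed, acquisition=acq)


def write_cohort(cohort: Cohort, path: str | Path, metadata_path: str | Path | None = None) -> None:
    """Write the cohort table as CSV (canonical schema plus any extra
    score columns) and, optionally, a JSON metadata sidecar recording the
    generation seed."""
    frame = cohort.to_frame()
    path = Path(path)
    frame.to_csv(path, index=False)
    if metadata_path is not None:
        meta = {"seed": cohort.seed, "n": len(cohort), "columns": list(frame.columns)}
        Path(metadata_path).write_text(json.dumps(meta, indent=2))
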