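"""Synthetic-data generators for every analysis stage.

The study's raw data (pig MRI, PCD waveforms, plasma ELISA) are not public,
so each analysis arm is driven by a seeded generator with known ground truth:

* :func:`simulate_pcd` — pulsed PCD waveforms: harmonic tones in every pulse,
  white broadband noise in every pulse, and a subharmonic tone added after
  microbubble injection.  Defaults follow the sonication protocol:
  f0 = 0.65 MHz, PRF 1 Hz, 10 ms pulses, 3 min treatment, 15 baseline pulses
  before microbubble injection.
* :func:`simulate_tissue_curve` — extended-Tofts forward curves sampled at
  7.5 s over 10 min with a 60 s bolus delay, plus optional Gaussian noise.
* :func:`generate_t1_pair` — pre/post T1-weighted phantom volumes with an
  ellipsoidal enhancing opening at 0.68 x 0.68 x 1.5 mm voxels.
* :func:`simulate_biomarker_panel` — paired pre/post GFAP and MBP plasma
  concentrations per animal (correlated bivariate normal, clipped at zero),
  calibrated by default to the printed group means/SDs.
* :func:`simulate_elisa_plate` — 4PL optical densities with a standards block
  for curve refitting.

Every generator is a pure function of its config (including the seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerPanel, FourPLCurve
from .cavitation import PCDRecording
from .errors import ConfigurationError, InputError
from .opening import ImageVolume
from .pharmacokinetics import AIF, POPULATION_AIF, TissueCurve, ToftsParams, tofts_forward

__all__ = [
    "PCDSimConfig",
    "DCESimConfig",
    "PhantomSpec",
    "AnalyteLevels",
    "BiomarkerSimConfig",
    "DEFAULT_ANALYTES",
    "DEFAULT_4PL_CURVE",
    "simulate_pcd",
    "simulate_tissue_curve",
    "generate_t1_pair",
    "simulate_biomarker_panel",
    "simulate_elisa_plate",
    "ellipsoid_semiaxes_for_volume",
    "ellipsoid_mask",
    "write_pcd_recording",
]


# ---------------------------------------------------------------------------
# PCD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCDSimConfig:
    """PCD waveform generator configuration.

    f0 and fs in MHz, pulse_duration in ms, prf in Hz.  ``harmonic_amps`` are
    the amplitudes of the n*f0 tones (n = 1..3) present in every pulse;
    ``subharmonic_amp`` is the f0/2 tone added post-microbubble;
    ``broadband_sd`` is the white-noise SD present in every pulse (the noise
    floor against which IC is normalized).  ``post_broadband_sd``, when set,
    replaces the noise SD for post-MB pulses so an inertial-cavitation
    elevation can be simulated.  Tone amplitudes are arbitrary pressure units
    (no quantitative emission levels are available to calibrate against).
    """

    f0: float = 0.65
    fs: float = 10.0
    pulse_duration: float = 10.0
    prf: float = 1.0
    n_baseline_pulses: int = 15
    n_post_pulses: int = 165
    harmonic_amps: tuple[float, ...] = (1.0, 0.3, 0.1)
    subharmonic_amp: float = 0.5
    broadband_sd: float = 0.02
    post_broadband_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ConfigurationError("f0 must be positive")
        if self.fs <= 2.0 * (3.0 * self.f0 + 0.15):
            raise ConfigurationError("fs must exceed twice the highest band edge (3 f0 + 0.15)")
        if self.prf <= 0:
            raise ConfigurationError("prf must be positive")
        if any(a < 0 for a in self.harmonic_amps):
            raise ConfigurationError("harmonic_amps must be >= 0")
        if self.subharmonic_amp < 0:
            raise ConfigurationError("subharmonic_amp must be >= 0")
        if self.broadband_sd < 0:
            raise ConfigurationError("broadband_sd must be >= 0")
        if self.post_broadband_sd is not None and self.post_broadband_sd < 0:
            raise ConfigurationError("post_broadband_sd must be >= 0")
        if self.n_baseline_pulses < 0 or self.n_post_pulses < 0:
            raise ConfigurationError("pulse counts must be >= 0")
        n = self.pulse_duration * self.fs * 1000.0
        if abs(n - round(n)) > 1e-6 or round(n) < 64:
            raise ConfigurationError(
                "pulse_duration * fs must yield an integer >= 64 samples (pulse_duration)"
            )

    @property
    def pulse_samples(self) -> int:
        return int(round(self.pulse_duration * self.fs * 1000.0))


def simulate_pcd(config: PCDSimConfig) -> PCDRecording:
    """Generate a seeded PCD recording per the config.

    Baseline pulses: harmonic tones + white noise.  Post-MB pulses add the
    subharmonic tone (and optionally a different broadband noise SD).
    ``mb_injection_time`` is placed midway between the last baseline and the
    first post-MB pulse.
    """
    n_total = config.n_baseline_pulses + config.n_post_pulses
    if config.n_baseline_pulses == 0 or config.n_post_pulses == 0:
        raise ConfigurationError("need baseline and post pulses (n_baseline_pulses/n_post_pulses)")
    rng = np.random.default_rng(config.seed)
    ns = config.pulse_samples
    t_us = np.arange(ns) / config.fs  # sample times within a pulse, microseconds

    base = np.zeros(ns)
    for i, amp in enumerate(config.harmonic_amps, start=1):
        if amp > 0:
            base += amp * np.sin(2.0 * np.pi * (i * config.f0) * t_us)
    sub_tone = (
        config.subharmonic_amp * np.sin(2.0 * np.pi * (config.f0 / 2.0) * t_us)
        if config.subharmonic_amp > 0
        else 0.0
    )

    pulses = np.empty((n_total, ns))
    post_sd = config.post_broadband_sd if config.post_broadband_sd is not None else config.broadband_sd
    for i in range(n_total):
        post = i >= config.n_baseline_pulses
        w = base.copy()
        if post:
            w = w + sub_tone
        sd = post_sd if post else config.broadband_sd
        if sd > 0:
            w = w + rng.normal(0.0, sd, size=ns)
        pulses[i] = w

    pulse_times = np.arange(n_total) / config.prf
    mb_time = 0.5 * (
        pulse_times[config.n_baseline_pulses - 1] + pulse_times[config.n_baseline_pulses]
    )
    return PCDRecording(
        fs=config.fs,
        f0=config.f0,
        pulses=pulses,
        pulse_times=pulse_times,
        mb_injection_time=mb_time,
    )


def write_pcd_recording(rec: PCDRecording, bin_path, sidecar_path=None) -> None:
    """Write raw little-endian float32 (pulse-major) plus a JSON sidecar."""
    bin_path = Path(bin_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else bin_path.with_suffix(".json")
    rec.pulses.astype("<f4").tofile(bin_path)
    meta = {
        "fs_MHz": rec.fs,
        "f0_MHz": rec.f0,
        "n_pulses": int(rec.n_pulses),
        "pulse_samples": int(rec.pulses.shape[1]),
        "pulse_times_s": rec.pulse_times.tolist(),
        "mb_injection_time_s": rec.mb_injection_time,
    }
    sidecar_path.write_text(json.dumps(meta, sort_keys=True))


# ---------------------------------------------------------------------------
# DCE curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DCESimConfig:
    """DCE tissue-curve generator configuration.

    ``t_end`` in minutes, ``dt`` and ``bolus_time`` in seconds, ``noise_sd``
    in concentration units (mM).  The effective AIF has its bolus arrival set
    to ``bolus_time``.
    """

    truth: ToftsParams
    aif: AIF | None = None
    t_end: float = 10.0
    dt: float = 7.5
    bolus_time: float = 60.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.t_end <= self.bolus_time / 60.0:
            raise ConfigurationError("t_end must exceed the bolus arrival time")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def effective_aif(self) -> AIF:
        base = self.aif if self.aif is not None else POPULATION_AIF
        return dataclasses.replace(base, t0=self.bolus_time / 60.0)

    @property
    def times_min(self) -> np.ndarray:
        n = int(round(self.t_end * 60.0 / self.dt)) + 1
        return np.arange(n) * self.dt / 60.0


def simulate_tissue_curve(config: DCESimConfig) -> TissueCurve:
    """Forward extended-Tofts curve plus optional Gaussian noise (seeded)."""
    curve = tofts_forward(config.truth, config.effective_aif, config.times_min)
    conc = curve.concentrations
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        conc = conc + rng.normal(0.0, config.noise_sd, size=conc.shape)
    return TissueCurve(curve.times, conc, label="simulated")


# ---------------------------------------------------------------------------
# T1 phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Pre/post T1 phantom specification.

    The post volume adds ``enhancement`` inside an ellipsoid (voxel included
    when its center lies inside); geometry in world mm with the default T1
    voxel sizes 0.68 x 0.68 x 1.5 mm.
    """

    opening_center_mm: tuple[float, float, float]
    opening_semiaxes_mm: tuple[float, float, float]
    matrix: tuple[int, int, int] = (128, 128, 32)
    voxel_mm: tuple[float, float, float] = (0.68, 0.68, 1.5)
    background_mean: float = 100.0
    background_sd: float = 5.0
    enhancement: float = 50.0
    planned_focus_mm: tuple[float, float, float] | None = None
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_mm):
            raise ConfigurationError("voxel_mm spacings must be > 0")
        if any(m < 2 for m in self.matrix):
            raise ConfigurationError("matrix must have >= 2 voxels per axis")
        if self.enhancement < 0:
            raise ConfigurationError("enhancement must be >= 0")
        if self.background_sd < 0:
            raise ConfigurationError("background_sd must be >= 0")
        if any(a <= 0 for a in self.opening_semiaxes_mm):
            raise ConfigurationError("opening_semiaxes_mm must be > 0")
        for ax in range(3):
            lo = self.origin_mm[ax]
            hi = self.origin_mm[ax] + (self.matrix[ax] - 1) * self.voxel_mm[ax]
            c, a = self.opening_center_mm[ax], self.opening_semiaxes_mm[ax]
            if c - a < lo or c + a > hi:
                raise ConfigurationError(
                    f"opening ellipsoid extends outside the grid along axis {ax} "
                    "(opening_center_mm/opening_semiaxes_mm)"
                )

    @property
    def focus_mm(self) -> tuple[float, float, float]:
        return self.planned_focus_mm if self.planned_focus_mm is not None else self.opening_center_mm


def ellipsoid_mask(
    shape, voxel_mm, origin_mm, center_mm, semiaxes_mm
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside the ellipsoid."""
    coords = [
        origin_mm[ax] + np.arange(shape[ax]) * voxel_mm[ax] - center_mm[ax] for ax in range(3)
    ]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    a, b, c = semiaxes_mm
    return (gx / a) ** 2 + (gy / b) ** 2 + (gz / c) ** 2 <= 1.0


def ellipsoid_semiaxes_for_volume(
    volume_cm3: float, ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> tuple[float, float, float]:
    """Semi-axes (mm) with shape ``ratios`` whose analytic ellipsoid volume
    (4/3 pi a b c) equals ``volume_cm3``."""
    if volume_cm3 <= 0:
        raise InputError("volume must be positive")
    r = np.asarray(ratios, dtype=float)
    if np.any(r <= 0):
        raise InputError("ratios must be positive")
    scale = (volume_cm3 * 1000.0 * 3.0 / (4.0 * np.pi * np.prod(r))) ** (1.0 / 3.0)
    return tuple(float(v) for v in scale * r)


def generate_t1_pair(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume]:
    """Pre volume: Gaussian background; post volume: pre + enhancement inside
    the opening ellipsoid.  Same seed implies identical backgrounds."""
    rng = np.random.default_rng(spec.seed)
    background = rng.normal(spec.background_mean, spec.background_sd, size=spec.matrix)
    mask = ellipsoid_mask(
        spec.matrix, spec.voxel_mm, spec.origin_mm, spec.opening_center_mm, spec.opening_semiaxes_mm
    )
    pre = ImageVolume(background, spec.voxel_mm, spec.origin_mm)
    post = ImageVolume(
        background + spec.enhancement * mask, spec.voxel_mm, spec.origin_mm
    )
    return pre, post


# ---------------------------------------------------------------------------
# Biomarker panels and ELISA plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyteLevels:
    """Pre/post group mean and SD (ng/mL) for one analyte."""

    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float

    def __post_init__(self) -> None:
        if min(self.pre_mean, self.pre_sd, self.post_mean, self.post_sd) < 0:
            raise ConfigurationError("analyte means/SDs must be >= 0")


#: Default calibration: the study's printed plasma group values (ng/mL).
DEFAULT_ANALYTES: dict[str, AnalyteLevels] = {
    "GFAP": AnalyteLevels(pre_mean=0.156, pre_sd=0.068, post_mean=0.353, post_sd=0.149),
    "MBP": AnalyteLevels(pre_mean=0.091, pre_sd=0.034, post_mean=0.364, post_sd=0.159),
}

#: Default ELISA standard curve spanning the ng/mL working range of the panels.
DEFAULT_4PL_CURVE = FourPLCurve(A=0.05, D=2.5, C=0.5, B=1.2)


@dataclass(frozen=True)
class BiomarkerSimConfig:
    """Paired-panel generator configuration.

    Per animal and analyte, (pre, post) is a correlated bivariate normal with
    the configured margins, clipped at zero (concentrations are nonnegative
    and the printed SDs are large relative to the means).
    """

    analytes: tuple[tuple[str, AnalyteLevels], ...] = tuple(sorted(DEFAULT_ANALYTES.items()))
    within_animal_corr: float = 0.5
    n_animals: int = 7
    curve: FourPLCurve = DEFAULT_4PL_CURVE
    od_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_animal_corr < 1.0):
            raise ConfigurationError("within_animal_corr must lie in [0, 1)")
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be >= 1")
        if self.od_noise_sd < 0:
            raise ConfigurationError("od_noise_sd must be >= 0")

    def analyte_dict(self) -> dict[str, AnalyteLevels]:
        return dict(self.analytes)


def simulate_biomarker_panel(config: BiomarkerSimConfig) -> BiomarkerPanel:
    """Seeded paired pre/post panel with per-analyte calibrated margins."""
    rng = np.random.default_rng(config.seed)
    rho = config.within_animal_corr
    rows = []
    for name, lv in sorted(config.analytes):
        z1 = rng.standard_normal(config.n_animals)
        z2 = rng.standard_normal(config.n_animals)
        pre = lv.pre_mean + lv.pre_sd * z1
        post = lv.post_mean + lv.post_sd * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
        pre = np.clip(pre, 0.0, None)
        post = np.clip(post, 0.0, None)
        for i in range(config.n_animals):
            rows.append({"animal": i + 1, "analyte": name, "pre_ng_ml": pre[i], "post_ng_ml": post[i]})
    return BiomarkerPanel(pd.DataFrame(rows))


#: Default standards block (ng/mL): two log-decades around the curve midpoint.
def _default_standards(curve: FourPLCurve) -> np.ndarray:
    return curve.C * np.logspace(-2, 2, 9)


def simulate_elisa_plate(
    concentrations,
    curve: FourPLCurve = DEFAULT_4PL_CURVE,
    od_noise_sd: float = 0.0,
    seed: int = 0,
    standards=None,
) -> pd.DataFrame:
    """Optical densities for unknown samples plus a standards block.

    Returns a table with columns well, role ('standard'/'unknown'),
    concentration_ng_ml (NaN for unknowns in the OD-only sense — the true
    simulated value is retained for standards only), od.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise InputError("concentrations must be >= 0")
    std = np.asarray(_default_standards(curve) if standards is None else standards, dtype=float)
    if np.any(std < 0):
        raise InputError("standard concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i, c in enumerate(std):
        od = float(curve.od(c))
        if od_noise_sd > 0:
            od += rng.normal(0.0, od_noise_sd)
        rows.append({"well": f"S{i + 1}", "role": "standard", "concentration_ng_ml": c, "od": od})
    for i, c in enumerate(conc):
        od = float(curve.od(c))
        if od_noise_sd > 0:
            od += rng.normal(0.0, od_noise_sd)
        rows.append({"well": f"U{i + 1}", "role": "unknown", "concentration_ng_ml": np.nan, "od": od})
    return pd.DataFrame(rows)
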