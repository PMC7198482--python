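"""End-to-end orchestration: simulate -> analyze -> report.

:func:`run_pipeline` generates per-animal synthetic datasets for the four
analysis arms (cavitation monitoring, BBB-opening volumetry, Ktrans
pharmacokinetics, biomarker panels), runs each analyzer, and assembles a
:class:`ReportBundle` mirroring the study's quantitative results panels:
SC/IC pre-vs-post paired t-tests, FUS+ vs FUS- opening volumes with the
exact Wilcoxon signed-rank p and mean targeting offsets, FUS+ vs FUS- Ktrans
with a paired t-test, and the per-analyte biomarker table.

Group sizes default to the study's (7 animals for the volume/cavitation/
biomarker arms, 4 for Ktrans).  A fixed seed makes the whole bundle
byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import cavitation as cav
from . import opening as op
from . import pharmacokinetics as pk
from . import synthetic as syn
from .errors import AnalysisError, ConfigurationError, InputError

__all__ = [
    "PhantomArmConfig",
    "KtransArmConfig",
    "RunConfig",
    "ReportBundle",
    "run_pipeline",
    "run_cavitation_arm",
    "run_opening_arm",
    "run_ktrans_arm",
    "run_biomarker_arm",
    "write_report",
    "read_report",
]

logger = logging.getLogger("fuslbx.pipeline")

_SEED_MOD = 2**31


def _child_seeds(seed: int, n: int, tag: int) -> list[int]:
    """Deterministic per-stage child seeds below 2^31."""
    state = np.random.SeedSequence([int(seed), int(tag)]).generate_state(n)
    return [int(s % _SEED_MOD) for s in state]


@dataclass(frozen=True)
class PhantomArmConfig:
    """Geometry and calibration of the opening-volumetry arm.

    Per animal the FUS+ opening is an enhancing sphere whose analytic volume
    is drawn from N(volume_mean_cm3, volume_sd_cm3) clipped to
    ``volume_range_cm3`` (the opening must exist and fit inside the ROI), and
    whose center is the planned focus shifted by the fixed per-axis
    ``targeting_offset_mm``.  FUS- volumes apply the same mean + 3 SD rule
    with the ROI roles swapped.
    """

    matrix: tuple[int, int, int] = (112, 64, 24)
    voxel_mm: tuple[float, float, float] = (0.68, 0.68, 1.5)
    background_mean: float = 100.0
    background_sd: float = 5.0
    enhancement: float = 50.0
    fus_center_mm: tuple[float, float] = (19.0, 21.8)
    contra_center_mm: tuple[float, float] = (57.0, 21.8)
    roi_radius_mm: float = 12.0
    z_center_mm: float = 15.0
    volume_mean_cm3: float = 1.21
    volume_sd_cm3: float = 1.84
    volume_range_cm3: tuple[float, float] = (0.05, 2.8)
    targeting_offset_mm: tuple[float, float, float] = (-1.9, -0.4, 5.3)


@dataclass(frozen=True)
class KtransArmConfig:
    """Ground-truth Ktrans distributions (min^-1) for the DCE arm; defaults
    are the printed FUS+ and FUS- group values."""

    fus_mean: float = 9.9e-3
    fus_sd: float = 3.9e-3
    contra_mean: float = 1.4e-3
    contra_sd: float = 0.8e-3
    ve: float = 0.1
    vp: float = 0.01
    noise_sd: float = 0.0
    min_ktrans: float = 1e-4


@dataclass(frozen=True)
class RunConfig:
    """Whole-pipeline configuration.

    ``effect=False`` simulates the no-FUS null: no subharmonic emission, no
    enhancement, FUS- Ktrans on both sides, post biomarker levels equal to
    pre levels.
    """

    seed: int = 0
    effect: bool = True
    n_animals: int = 7
    n_animals_ktrans: int = 4
    pcd: syn.PCDSimConfig = field(default_factory=syn.PCDSimConfig)
    phantom: PhantomArmConfig = field(default_factory=PhantomArmConfig)
    ktrans: KtransArmConfig = field(default_factory=KtransArmConfig)
    biomarkers: syn.BiomarkerSimConfig = field(default_factory=syn.BiomarkerSimConfig)

    def __post_init__(self) -> None:
        if self.n_animals < 2 or self.n_animals_ktrans < 2:
            raise ConfigurationError("group sizes must be >= 2")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        kwargs = {}
        for key in ("seed", "effect", "n_animals", "n_animals_ktrans"):
            if key in d:
                kwargs[key] = d[key]
        if "pcd" in d:
            kwargs["pcd"] = syn.PCDSimConfig(**d["pcd"])
        if "phantom" in d:
            ph = dict(d["phantom"])
            for k in ("matrix", "voxel_mm", "fus_center_mm", "contra_center_mm",
                      "volume_range_cm3", "targeting_offset_mm"):
                if k in ph:
                    ph[k] = tuple(ph[k])
            kwargs["phantom"] = PhantomArmConfig(**ph)
        if "ktrans" in d:
            kwargs["ktrans"] = KtransArmConfig(**d["ktrans"])
        if "biomarkers" in d:
            b = dict(d["biomarkers"])
            if "analytes" in b:
                b["analytes"] = tuple(
                    (name, syn.AnalyteLevels(**lv)) for name, lv in sorted(b["analytes"].items())
                )
            kwargs["biomarkers"] = syn.BiomarkerSimConfig(**b)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Arms
# ---------------------------------------------------------------------------


def run_cavitation_arm(
    pcd_config: syn.PCDSimConfig, n_animals: int, seed: int, effect: bool = True
) -> dict:
    """Simulate one PCD recording per animal and compare pre/post-MB doses."""
    seeds = _child_seeds(seed, n_animals, tag=1)
    bands = cav.build_band_set(pcd_config.f0)
    doses = []
    for s in seeds:
        cfg = dataclasses.replace(
            pcd_config, seed=s, subharmonic_amp=pcd_config.subharmonic_amp if effect else 0.0
        )
        rec = syn.simulate_pcd(cfg)
        doses.append(cav.compute_cavitation_doses(rec, bands))
    tests = cav.compare_pre_post(doses)
    per_animal = {
        "sc_pre": [d.mean_level("SC", post=False) for d in doses],
        "sc_post": [d.mean_level("SC", post=True) for d in doses],
        "ic_pre": [d.mean_level("IC", post=False) for d in doses],
        "ic_post": [d.mean_level("IC", post=True) for d in doses],
    }
    return {"tests": {k: v.to_dict() for k, v in tests.items()}, "per_animal": per_animal}


def _clipped_normal(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def run_opening_arm(
    cfg: PhantomArmConfig, n_animals: int, seed: int, effect: bool = True
) -> dict:
    """Per-animal phantom volumetry: FUS+ vs FUS- volumes, Wilcoxon p,
    per-axis targeting offsets."""
    seeds = _child_seeds(seed, n_animals, tag=2)
    nz = cfg.matrix[2]
    roi_fus = op.EllipticalROI(
        slice_range=(0, nz - 1),
        center_mm=cfg.fus_center_mm,
        major_mm=2 * cfg.roi_radius_mm,
        minor_mm=2 * cfg.roi_radius_mm,
    )
    roi_contra = op.EllipticalROI(
        slice_range=(0, nz - 1),
        center_mm=cfg.contra_center_mm,
        major_mm=2 * cfg.roi_radius_mm,
        minor_mm=2 * cfg.roi_radius_mm,
    )
    vol_plus, vol_minus, offsets = [], [], []
    for s in seeds:
        rng = np.random.default_rng(s)
        planned = (cfg.fus_center_mm[0], cfg.fus_center_mm[1], cfg.z_center_mm)
        if effect:
            v = _clipped_normal(rng, cfg.volume_mean_cm3, cfg.volume_sd_cm3, *cfg.volume_range_cm3)
            semi = syn.ellipsoid_semiaxes_for_volume(v)
            center = tuple(np.asarray(planned) + np.asarray(cfg.targeting_offset_mm))
            enhancement = cfg.enhancement
        else:
            semi = syn.ellipsoid_semiaxes_for_volume(cfg.volume_range_cm3[0])
            center = planned
            enhancement = 0.0
        spec = syn.PhantomSpec(
            opening_center_mm=center,
            opening_semiaxes_mm=semi,
            matrix=cfg.matrix,
            voxel_mm=cfg.voxel_mm,
            background_mean=cfg.background_mean,
            background_sd=cfg.background_sd,
            enhancement=enhancement,
            planned_focus_mm=planned,
            seed=int(rng.integers(_SEED_MOD)),
        )
        _, post = syn.generate_t1_pair(spec)
        res_plus = op.classify_open_voxels(post, roi_fus, roi_contra, planned)
        res_minus = op.classify_open_voxels(post, roi_contra, roi_fus)
        vol_plus.append(res_plus.total_volume_cm3)
        vol_minus.append(res_minus.total_volume_cm3)
        if res_plus.centroid_mm is not None:
            offsets.append(op.targeting_offset(res_plus, planned))
        else:
            offsets.append((np.nan, np.nan, np.nan))
    wil = bm.wilcoxon_signed_rank_exact(vol_minus, vol_plus)
    off = np.asarray(offsets, dtype=float)
    return {
        "volumes_fus_plus_cm3": vol_plus,
        "volumes_fus_minus_cm3": vol_minus,
        "wilcoxon": wil.to_dict(),
        "offsets_mm": off.tolist(),
        "mean_offset_mm": np.nanmean(off, axis=0).tolist(),
    }


def run_ktrans_arm(
    cfg: KtransArmConfig, n_animals: int, seed: int, effect: bool = True
) -> dict:
    """Per-animal Ktrans recovery on both hemispheres plus a paired t-test."""
    seeds = _child_seeds(seed, n_animals, tag=3)
    fus_vals, contra_vals = [], []
    for s in seeds:
        rng = np.random.default_rng(s)
        truth_contra = max(cfg.min_ktrans, float(rng.normal(cfg.contra_mean, cfg.contra_sd)))
        if effect:
            truth_fus = max(cfg.min_ktrans, float(rng.normal(cfg.fus_mean, cfg.fus_sd)))
        else:
            truth_fus = max(cfg.min_ktrans, float(rng.normal(cfg.contra_mean, cfg.contra_sd)))
        for truth, bucket in ((truth_fus, fus_vals), (truth_contra, contra_vals)):
            dce = syn.DCESimConfig(
                truth=pk.ToftsParams(ktrans=truth, ve=cfg.ve, vp=cfg.vp),
                noise_sd=cfg.noise_sd,
                seed=int(rng.integers(_SEED_MOD)),
            )
            curve = syn.simulate_tissue_curve(dce)
            res = pk.fit_tofts(curve, dce.effective_aif)
            bucket.append(res.params.ktrans)
    test = bm.paired_t_test(contra_vals, fus_vals)
    return {
        "ktrans_fus_per_min": fus_vals,
        "ktrans_contra_per_min": contra_vals,
        "paired_t": test.to_dict(),
    }


def run_biomarker_arm(cfg: syn.BiomarkerSimConfig, seed: int, effect: bool = True) -> dict:
    """Generate one paired panel and summarize it per analyte."""
    analytes = cfg.analytes
    if not effect:
        analytes = tuple(
            (name, syn.AnalyteLevels(lv.pre_mean, lv.pre_sd, lv.pre_mean, lv.pre_sd))
            for name, lv in cfg.analytes
        )
    cfg = dataclasses.replace(cfg, analytes=analytes, seed=_child_seeds(seed, 1, tag=4)[0])
    panel = syn.simulate_biomarker_panel(cfg)
    summary = bm.summarize_panel(panel)
    return {"summary": summary.to_dict(orient="records")}


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """Machine-readable results bundle for one pipeline run."""

    config_seed: int
    effect: bool
    cavitation: dict
    opening: dict
    ktrans: dict
    biomarkers: dict

    def to_dict(self) -> dict:
        return {
            "config_seed": self.config_seed,
            "effect": self.effect,
            "cavitation": self.cavitation,
            "opening": self.opening,
            "ktrans": self.ktrans,
            "biomarkers": self.biomarkers,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReportBundle":
        return cls(
            config_seed=d["config_seed"],
            effect=d["effect"],
            cavitation=d["cavitation"],
            opening=d["opening"],
            ktrans=d["ktrans"],
            biomarkers=d["biomarkers"],
        )

    def p_values(self) -> dict[str, float]:
        """Every p-value in the bundle, keyed by arm/test."""
        out = {
            "cavitation/SC": self.cavitation["tests"]["SC"]["p_two_sided"],
            "cavitation/IC": self.cavitation["tests"]["IC"]["p_two_sided"],
            "opening/wilcoxon": self.opening["wilcoxon"]["p_two_sided"],
            "ktrans/paired_t": self.ktrans["paired_t"]["p_two_sided"],
        }
        for row in self.biomarkers["summary"]:
            out[f"biomarkers/{row['analyte']}"] = row["p_two_sided"]
        return out


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run all four arms from one seeded configuration."""
    stages = (
        ("cavitation", lambda: run_cavitation_arm(config.pcd, config.n_animals, config.seed, config.effect)),
        ("opening", lambda: run_opening_arm(config.phantom, config.n_animals, config.seed, config.effect)),
        ("ktrans", lambda: run_ktrans_arm(config.ktrans, config.n_animals_ktrans, config.seed, config.effect)),
        ("biomarkers", lambda: run_biomarker_arm(config.biomarkers, config.seed, config.effect)),
    )
    results = {}
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            results[name] = fn()
        except Exception as exc:  # noqa: BLE001 - surface the failing stage name
            logger.error("stage %s failed: %s", name, exc)
            raise AnalysisError(f"pipeline stage '{name}' failed: {exc}") from exc
        logger.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
    return ReportBundle(
        config_seed=config.seed,
        effect=config.effect,
        cavitation=results["cavitation"],
        opening=results["opening"],
        ktrans=results["ktrans"],
        biomarkers=results["biomarkers"],
    )


def _validate_bundle(bundle: ReportBundle) -> None:
    d = bundle.to_dict()
    for key in ("cavitation", "opening", "ktrans", "biomarkers"):
        if not d.get(key):
            raise InputError(f"bundle schema error: missing or empty '{key}'")
    for name, p in bundle.p_values().items():
        if not (0.0 <= p <= 1.0):
            raise InputError(f"bundle schema error: p-value out of range for {name}")
    for v in bundle.opening["volumes_fus_plus_cm3"] + bundle.opening["volumes_fus_minus_cm3"]:
        if v < 0:
            raise InputError("bundle schema error: negative volume")


def write_report(bundle: ReportBundle, out_dir) -> list[Path]:
    """Write report.json plus per-arm CSVs; returns the written paths.

    JSON floats keep full repr precision (>= 4 significant digits for every
    p-value) and keys are sorted, so identical bundles serialize to identical
    bytes.
    """
    _validate_bundle(bundle)
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create report directory {out_dir}: {exc}") from exc
    paths = []

    report = out_dir / "report.json"
    report.write_text(json.dumps(bundle.to_dict(), sort_keys=True, indent=2))
    paths.append(report)

    ca = bundle.cavitation["per_animal"]
    cav_df = pd.DataFrame(
        {
            "animal": np.arange(1, len(ca["sc_pre"]) + 1),
            "sc_pre": ca["sc_pre"],
            "sc_post": ca["sc_post"],
            "ic_pre": ca["ic_pre"],
            "ic_post": ca["ic_post"],
        }
    )
    off = np.asarray(bundle.opening["offsets_mm"], dtype=float)
    open_df = pd.DataFrame(
        {
            "animal": np.arange(1, len(bundle.opening["volumes_fus_plus_cm3"]) + 1),
            "volume_fus_plus_cm3": bundle.opening["volumes_fus_plus_cm3"],
            "volume_fus_minus_cm3": bundle.opening["volumes_fus_minus_cm3"],
            "offset_x_mm": off[:, 0],
            "offset_y_mm": off[:, 1],
            "offset_z_mm": off[:, 2],
        }
    )
    kt_df = pd.DataFrame(
        {
            "animal": np.arange(1, len(bundle.ktrans["ktrans_fus_per_min"]) + 1),
            "ktrans_fus_per_min": bundle.ktrans["ktrans_fus_per_min"],
            "ktrans_contra_per_min": bundle.ktrans["ktrans_contra_per_min"],
        }
    )
    bio_df = pd.DataFrame(bundle.biomarkers["summary"])
    for name, df in (
        ("cavitation.csv", cav_df),
        ("opening.csv", open_df),
        ("ktrans.csv", kt_df),
        ("biomarkers.csv", bio_df),
    ):
        p = out_dir / name
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


def read_report(out_dir) -> ReportBundle:
    """Parse report.json back into an equal ReportBundle."""
    d = json.loads((Path(out_dir) / "report.json").read_text())
    return ReportBundle.from_dict(d)
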