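"""Cavitation dose metrics from passive cavitation detection (PCD) data.

During microbubble-mediated sonication, sustained bubble oscillation (stable
cavitation, SC) radiates energy at the subharmonic ``f0/2``, while violent
bubble collapse (inertial cavitation, IC) radiates broadband noise.  Per
sonication pulse we compute:

* ``SC_linear`` — RMS of the magnitude-spectrum bins inside the subharmonic
  band ``f0/2 +/- hw``;
* ``IC_linear`` — RMS of the bins inside the broadband window (default
  0.3-2.0 MHz) after notching out the subharmonic band and the harmonic bands
  ``n*f0 +/- hw`` for n = 1..3.

Both metrics are also expressed in dB relative to the mean over the baseline
pulses recorded before microbubble injection
(``SC_dB = 20 log10(SC_linear / baseline_SC)``), and pre-vs-post microbubble
comparisons across animals use the paired t-test.

"RMS amplitude" here means RMS over magnitude-spectrum bins within the band,
computed from one rectangular-window spectrum per pulse; 10 ms pulses sampled
at MHz rates give ~100 Hz bin spacing, ample for the notch geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarkers import PairedTestResult, paired_t_test
from .errors import AnalysisError, ConfigurationError, InputError

__all__ = [
    "PCDRecording",
    "FrequencyBandSet",
    "CavitationDose",
    "Spectrum",
    "build_band_set",
    "pulse_spectrum",
    "band_rms",
    "compute_cavitation_doses",
    "compare_pre_post",
    "read_pcd_recording",
]


@dataclass
class PCDRecording:
    """Per-pulse PCD waveforms with sampling metadata.

    fs, f0 in MHz; ``pulses`` is an (n_pulses, n_samples) matrix in arbitrary
    pressure units; ``pulse_times`` in seconds; ``mb_injection_time`` is the
    microbubble injection time in seconds (baseline pulses precede it).
    """

    fs: float
    f0: float
    pulses: np.ndarray
    pulse_times: np.ndarray
    mb_injection_time: float

    def __post_init__(self) -> None:
        self.pulses = np.asarray(self.pulses, dtype=float)
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.pulses.ndim != 2:
            raise InputError("pulses must be a 2D (n_pulses, n_samples) matrix")
        if not np.all(np.isfinite(self.pulses)):
            raise InputError("pulse samples must be finite")
        if len(self.pulse_times) != self.pulses.shape[0]:
            raise InputError("pulse_times length must match pulse count")
        if len(self.pulse_times) > 1 and not np.all(np.diff(self.pulse_times) > 0):
            raise InputError("pulse_times must be strictly increasing")
        # default analysis bands (up to 3 f0 + 0.15) must sit below Nyquist
        if self.fs <= 2.0 * (3.0 * self.f0 + 0.15):
            raise InputError("fs too low: harmonic bands would exceed Nyquist")

    @property
    def n_pulses(self) -> int:
        return self.pulses.shape[0]

    @property
    def is_post_mb(self) -> np.ndarray:
        return self.pulse_times >= self.mb_injection_time


@dataclass(frozen=True)
class FrequencyBandSet:
    """Subharmonic band, harmonic notch bands, and the kept broadband bins.

    All intervals in MHz, closed on both ends at the bin level; a bin falling
    in both a kept and an excluded interval counts as excluded.
    """

    subharmonic: tuple[float, float]
    harmonic_exclusions: tuple[tuple[float, float], ...]
    broadband_kept: tuple[tuple[float, float], ...]


def _subtract_intervals(base: tuple[float, float], removals) -> list[tuple[float, float]]:
    """Subtract a list of intervals from ``base``, dropping empty pieces."""
    pieces = [base]
    for lo, hi in sorted(removals):
        nxt = []
        for a, b in pieces:
            if hi <= a or lo >= b:
                nxt.append((a, b))
                continue
            if lo > a:
                nxt.append((a, lo))
            if hi < b:
                nxt.append((hi, b))
        pieces = nxt
    return [(a, b) for a, b in pieces if b - a > 1e-12]


def build_band_set(
    f0: float,
    half_width: float = 0.15,
    broad_lo: float = 0.3,
    broad_hi: float = 2.0,
    n_harmonics: int = 3,
) -> FrequencyBandSet:
    """Band algebra for SC/IC dose metrics.

    Subharmonic band ``[f0/2 - hw, f0/2 + hw]``; harmonic exclusion bands
    ``[n f0 - hw, n f0 + hw]`` for n = 1..n_harmonics; broadband kept =
    ``[broad_lo, broad_hi]`` minus subharmonic minus exclusions.
    """
    if f0 <= 0:
        raise ConfigurationError("f0 must be positive")
    if not (0 < half_width < f0 / 2):
        raise ConfigurationError("half_width must lie in (0, f0/2)")
    if not (0 < broad_lo < broad_hi):
        raise ConfigurationError("broadband window must satisfy 0 < lo < hi")
    sub = (f0 / 2 - half_width, f0 / 2 + half_width)
    excl = tuple((n * f0 - half_width, n * f0 + half_width) for n in range(1, n_harmonics + 1))
    kept = tuple(_subtract_intervals((broad_lo, broad_hi), [sub, *excl]))
    if not kept:
        raise ConfigurationError(
            "band configuration leaves no broadband bins (broadband_kept empty)"
        )
    return FrequencyBandSet(subharmonic=sub, harmonic_exclusions=excl, broadband_kept=kept)


@dataclass(frozen=True)
class Spectrum:
    """One-sided amplitude spectrum: frequencies in MHz, magnitudes such that
    a pure tone of amplitude A spanning integer cycles yields bin magnitude A."""

    freqs: np.ndarray
    mags: np.ndarray


def pulse_spectrum(pulse, fs: float) -> Spectrum:
    """One-sided DFT magnitude spectrum of one pulse (rectangular window).

    Amplitude normalization: interior bins are scaled by 2/N, the DC and (for
    even N) Nyquist bins by 1/N, so an integer-cycle tone of amplitude A maps
    to a single bin of magnitude A.  Frequency resolution is fs/N MHz.
    """
    x = np.asarray(pulse, dtype=float)
    if x.ndim != 1 or len(x) < 64:
        raise InputError("pulse must be a 1D waveform with >= 64 samples")
    if not np.all(np.isfinite(x)):
        raise InputError("pulse samples must be finite")
    n = len(x)
    spec = np.fft.rfft(x)
    mags = np.abs(spec) / n
    mags[1:] *= 2.0
    if n % 2 == 0:
        mags[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return Spectrum(freqs=freqs, mags=mags)


def _in_any(freqs: np.ndarray, intervals) -> np.ndarray:
    mask = np.zeros(len(freqs), dtype=bool)
    for lo, hi in intervals:
        mask |= (freqs >= lo) & (freqs <= hi)
    return mask


def band_rms(spectrum: Spectrum, intervals) -> float:
    """RMS of spectral magnitudes over all bins with lo <= f <= hi in any
    interval; 0.0 if no bin falls inside."""
    intervals = list(intervals)
    if not intervals:
        raise InputError("interval list must be nonempty")
    fmax = spectrum.freqs[-1]
    for lo, hi in intervals:
        if lo < 0 or hi > fmax + 1e-12 or hi < lo:
            raise InputError(f"interval [{lo}, {hi}] outside spectrum range")
    mask = _in_any(spectrum.freqs, intervals)
    if not mask.any():
        return 0.0
    return float(np.sqrt(np.mean(spectrum.mags[mask] ** 2)))


@dataclass
class CavitationDose:
    """Per-pulse SC/IC levels, linear and baseline-normalized (dB)."""

    sc_linear: np.ndarray
    ic_linear: np.ndarray
    sc_db: np.ndarray
    ic_db: np.ndarray
    baseline_sc: float
    baseline_ic: float
    is_post_mb: np.ndarray
    pulse_times: np.ndarray
    sc_db_defined: bool = True
    ic_db_defined: bool = True
    bands: FrequencyBandSet | None = field(default=None, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pulse_index": np.arange(len(self.sc_linear)),
                "time_s": self.pulse_times,
                "is_post_mb": self.is_post_mb.astype(int),
                "sc_linear": self.sc_linear,
                "ic_linear": self.ic_linear,
                "sc_db": self.sc_db,
                "ic_db": self.ic_db,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def mean_level(self, metric: str, post: bool) -> float:
        """Mean linear level over baseline (post=False) or post-MB pulses."""
        values = {"SC": self.sc_linear, "IC": self.ic_linear}[metric]
        mask = self.is_post_mb if post else ~self.is_post_mb
        return float(values[mask].mean())


def compute_cavitation_doses(rec: PCDRecording, bands: FrequencyBandSet) -> CavitationDose:
    """Per-pulse SC/IC dose metrics with baseline (pre-microbubble) dB
    normalization.

    Requires at least 2 baseline and 2 post-MB pulses.  A zero baseline mean
    leaves the corresponding dB track flagged undefined (NaN) while the
    linear levels are still returned.
    """
    baseline = rec.pulse_times < rec.mb_injection_time
    if not baseline.any():
        raise AnalysisError("baseline undefined: no pulses precede mb_injection_time")
    if baseline.sum() < 2 or (~baseline).sum() < 2:
        raise AnalysisError("need >= 2 baseline and >= 2 post-MB pulses")

    n = rec.n_pulses
    sc = np.empty(n)
    ic = np.empty(n)
    # frequency grid is common to all pulses; build band masks once
    probe = pulse_spectrum(rec.pulses[0], rec.fs)
    sub_mask = _in_any(probe.freqs, [bands.subharmonic])
    excluded = _in_any(probe.freqs, [bands.subharmonic, *bands.harmonic_exclusions])
    ic_mask = _in_any(probe.freqs, bands.broadband_kept) & ~excluded
    if not ic_mask.any():
        raise AnalysisError("no spectral bins fall in the broadband kept intervals")
    for i in range(n):
        spec = pulse_spectrum(rec.pulses[i], rec.fs)
        sc[i] = np.sqrt(np.mean(spec.mags[sub_mask] ** 2)) if sub_mask.any() else 0.0
        ic[i] = np.sqrt(np.mean(spec.mags[ic_mask] ** 2))

    base_sc = float(sc[baseline].mean())
    base_ic = float(ic[baseline].mean())

    def db(linear, base):
        if base > 0:
            with np.errstate(divide="ignore"):
                return 20.0 * np.log10(np.where(linear > 0, linear / base, np.nan)), True
        return np.full_like(linear, np.nan), False

    sc_db, sc_ok = db(sc, base_sc)
    ic_db, ic_ok = db(ic, base_ic)
    return CavitationDose(
        sc_linear=sc,
        ic_linear=ic,
        sc_db=sc_db,
        ic_db=ic_db,
        baseline_sc=base_sc,
        baseline_ic=base_ic,
        is_post_mb=~baseline,
        pulse_times=rec.pulse_times.copy(),
        sc_db_defined=sc_ok,
        ic_db_defined=ic_ok,
        bands=bands,
    )


def compare_pre_post(doses: list[CavitationDose]) -> dict[str, PairedTestResult]:
    """Paired pre- vs post-microbubble comparison across animals.

    Per animal, the pre value is the mean baseline linear level and the post
    value the mean post-MB linear level; SC and IC are tested separately with
    the paired t-test.
    """
    if len(doses) < 2:
        raise AnalysisError("need doses from at least 2 animals")
    out = {}
    for metric in ("SC", "IC"):
        pre = [d.mean_level(metric, post=False) for d in doses]
        post = [d.mean_level(metric, post=True) for d in doses]
        out[metric] = paired_t_test(pre, post)
    return out


def read_pcd_recording(bin_path, sidecar_path=None) -> PCDRecording:
    """Read a PCD recording from raw little-endian float32 + JSON sidecar.

    The binary holds pulse-major samples; the sidecar carries
    {fs_MHz, f0_MHz, n_pulses, pulse_samples, pulse_times_s,
    mb_injection_time_s}.
    """
    bin_path = Path(bin_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else bin_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    raw = np.fromfile(bin_path, dtype="<f4")
    n_pulses = int(meta["n_pulses"])
    n_samples = int(meta["pulse_samples"])
    if raw.size != n_pulses * n_samples:
        raise InputError("binary size does not match sidecar pulse geometry")
    return PCDRecording(
        fs=float(meta["fs_MHz"]),
        f0=float(meta["f0_MHz"]),
        pulses=raw.reshape(n_pulses, n_samples).astype(float),
        pulse_times=np.asarray(meta["pulse_times_s"], dtype=float),
        mb_injection_time=float(meta["mb_injection_time_s"]),
    )
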