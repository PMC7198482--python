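"""Extended Tofts pharmacokinetic modelling of DCE-MRI concentration curves.

The extended Tofts model describes the tissue contrast-agent concentration
``Ct(t)`` as leakage from the plasma compartment plus an intravascular term::

    Ct(t) = Ktrans * int_0^t Cp(tau) exp(-kep (t - tau)) dtau + vp * Cp(t)

where ``Ktrans`` (min^-1) is the influx rate constant from blood plasma to the
extravascular extracellular space (EES), ``ve`` the EES volume fraction,
``vp`` the plasma volume fraction, ``kep = Ktrans / ve`` the efflux rate, and
``Cp(t)`` the arterial input function (AIF).  ``Ktrans`` is the standard index
of blood-brain-barrier permeability.

The AIF is a biexponential population function with bolus arrival at ``t0``::

    Cp(t) = A1 exp(-m1 (t - t0)) + A2 exp(-m2 (t - t0)),   t >= t0

Because the AIF is piecewise exponential, the convolution above has a closed
form, so forward curves carry no discretization error and parameter-recovery
tests are limited only by the optimizer.

The fitting surface follows the Model/Results idiom: build an
:class:`ExtendedToftsModel` from a curve and AIF, call :meth:`fit`, inspect
the returned :class:`ToftsResults` (parameters, RSS, convergence,
``summary()``).  :func:`fit_tofts` is the one-call functional wrapper.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import AnalysisError, InputError, ParameterError

__all__ = [
    "AIF",
    "POPULATION_AIF",
    "ToftsParams",
    "TissueCurve",
    "aif_eval",
    "tofts_forward",
    "ExtendedToftsModel",
    "ToftsResults",
    "fit_tofts",
    "roi_average_ktrans",
    "signal_to_concentration",
]


@dataclass(frozen=True)
class AIF:
    """Biexponential arterial input function.

    ``Cp(t) = 0`` for ``t < t0``, else
    ``A1 exp(-m1 (t - t0)) + A2 exp(-m2 (t - t0))``.

    Amplitudes are in concentration units (mM), rates in min^-1, ``t0`` in
    minutes.  Defaults are classic population values for a Gd bolus.
    """

    A1: float = 3.99
    A2: float = 4.78
    m1: float = 0.144
    m2: float = 0.0111
    t0: float = 1.0

    def __post_init__(self) -> None:
        if self.A1 < 0 or self.A2 < 0:
            raise ParameterError("AIF amplitudes must be >= 0")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ParameterError("AIF decay rates must be > 0")

    def __call__(self, times) -> np.ndarray:
        return aif_eval(self, times)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AIF":
        return cls(**d)


#: Default population AIF shared by generator and fitter.
POPULATION_AIF = AIF()


@dataclass(frozen=True)
class ToftsParams:
    """Extended Tofts parameters.

    ktrans : influx rate constant, min^-1 (>= 0)
    ve     : EES volume fraction, (0, 1]
    vp     : plasma volume fraction, [0, 1)
    """

    ktrans: float
    ve: float = 0.2
    vp: float = 0.0

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ParameterError("ktrans must be >= 0")
        if not (0.0 < self.ve <= 1.0):
            raise ParameterError("ve must lie in (0, 1]")
        if not (0.0 <= self.vp < 1.0):
            raise ParameterError("vp must lie in [0, 1)")

    @property
    def kep(self) -> float:
        """Efflux rate constant Ktrans/ve (min^-1)."""
        return self.ktrans / self.ve


@dataclass
class TissueCurve:
    """Tissue concentration time series.

    times in minutes (strictly increasing), concentrations in mM.
    """

    times: np.ndarray
    concentrations: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise InputError("times and concentrations must have equal length")
        if self.times.ndim != 1:
            raise InputError("curve must be one-dimensional")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise InputError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "concentration": self.concentrations}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "TissueCurve":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df["concentration"].to_numpy(), label)


def aif_eval(aif: AIF, times) -> np.ndarray:
    """Evaluate the AIF; exactly 0 before bolus arrival ``t0``."""
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputError("times must be finite")
    tau = t - aif.t0
    with np.errstate(over="ignore"):
        cp = aif.A1 * np.exp(-aif.m1 * np.clip(tau, 0, None)) + aif.A2 * np.exp(
            -aif.m2 * np.clip(tau, 0, None)
        )
    return np.where(tau < 0, 0.0, cp)


def _exp_diff(m: float, kep: float, tau: np.ndarray) -> np.ndarray:
    """(exp(-m tau) - exp(-kep tau)) / (kep - m), with the kep -> m limit.

    This is the convolution of exp(-m t) with exp(-kep t); the limit as
    kep -> m is tau * exp(-m tau).
    """
    d = kep - m
    scale = max(abs(kep), abs(m), 1.0)
    if abs(d) < 1e-10 * scale:
        return tau * np.exp(-m * tau)
    return (np.exp(-m * tau) - np.exp(-kep * tau)) / d


def _tofts_conc(ktrans: float, ve: float, vp: float, aif: AIF, t: np.ndarray) -> np.ndarray:
    """Closed-form extended Tofts concentration on arbitrary time points."""
    cp = aif_eval(aif, t)
    ct = vp * cp
    if ktrans > 0:
        kep = ktrans / ve
        tau = np.clip(t - aif.t0, 0.0, None)
        conv = aif.A1 * _exp_diff(aif.m1, kep, tau) + aif.A2 * _exp_diff(
            aif.m2, kep, tau
        )
        ct = ct + ktrans * np.where(t < aif.t0, 0.0, conv)
    return ct


def tofts_forward(params: ToftsParams, aif: AIF, times) -> TissueCurve:
    """Evaluate the extended Tofts model analytically on ``times`` (min).

    The convolution with the biexponential AIF is integrated in closed form,
    so the returned curve is exact to machine precision at any sampling.
    """
    t = np.asarray(times, dtype=float)
    if params.ve == 0 and params.ktrans > 0:  # unreachable via ToftsParams, kept for raw use
        raise ParameterError("kep undefined: ve = 0 with ktrans > 0")
    conc = _tofts_conc(params.ktrans, params.ve, params.vp, aif, t)
    return TissueCurve(t, conc, label="tofts_forward")


_DEFAULT_INIT = ToftsParams(ktrans=0.01, ve=0.2, vp=0.02)
_DEFAULT_BOUNDS = (np.array([0.0, 1e-4, 0.0]), np.array([1.0, 1.0, 0.5]))
#: Ktrans decades tried when ``multistart=True``.
_MULTISTART_KTRANS = (1e-4, 1e-3, 1e-2, 1e-1, 0.5)


class ExtendedToftsModel:
    """Extended Tofts model bound to one tissue curve and one AIF.

    Parameters
    ----------
    curve : TissueCurve
        Measured (or simulated) tissue concentration curve.
    aif : AIF, optional
        Arterial input function; defaults to the population AIF.
    """

    def __init__(self, curve: TissueCurve, aif: AIF = POPULATION_AIF):
        self.curve = curve
        self.aif = aif

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        aif: AIF = POPULATION_AIF,
        time_col: str = "time_min",
        conc_col: str = "concentration",
    ) -> "ExtendedToftsModel":
        return cls(TissueCurve(df[time_col].to_numpy(), df[conc_col].to_numpy()), aif)

    def predict(self, params: ToftsParams) -> np.ndarray:
        return _tofts_conc(params.ktrans, params.ve, params.vp, self.aif, self.curve.times)

    def fit(
        self,
        init: ToftsParams | None = None,
        bounds: tuple | None = None,
        multistart: bool = False,
    ) -> "ToftsResults":
        """Bounded nonlinear least squares for (Ktrans, ve, vp).

        Defaults: init (0.01 min^-1, 0.2, 0.02); bounds Ktrans in [0, 1],
        ve in (1e-4, 1], vp in [0, 0.5].  Convergence when the relative cost
        change or gradient norm drops below 1e-10.  With ``multistart=True``
        the fit is restarted on five Ktrans decades and the lowest-RSS
        solution kept (useful for noisy curves).
        """
        t = self.curve.times
        y = self.curve.concentrations
        if len(t) < 8:
            raise AnalysisError("need at least 8 time points to fit")
        if t[-1] <= self.aif.t0:
            raise AnalysisError("curve must span the bolus arrival")
        lo, hi = bounds if bounds is not None else _DEFAULT_BOUNDS
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        if init is None:
            init = _DEFAULT_INIT

        if np.max(np.abs(y)) == 0.0:
            params = ToftsParams(ktrans=0.0, ve=init.ve, vp=0.0)
            return ToftsResults(self, params, rss=0.0, converged=True, nfev=0)

        def residuals(x):
            return _tofts_conc(x[0], x[1], x[2], self.aif, t) - y

        def run(x0):
            x0 = np.clip(x0, lo, hi)
            return least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                ftol=1e-10,
                xtol=1e-12,
                gtol=1e-10,
                max_nfev=2000,
            )

        starts = [np.array([init.ktrans, init.ve, init.vp])]
        if multistart:
            starts += [np.array([k, init.ve, init.vp]) for k in _MULTISTART_KTRANS]
        best = None
        for x0 in starts:
            sol = run(x0)
            if best is None or sol.cost < best.cost:
                best = sol
        params = ToftsParams(
            ktrans=float(best.x[0]),
            ve=float(min(max(best.x[1], 1e-12), 1.0)),
            vp=float(best.x[2]),
        )
        return ToftsResults(
            self,
            params,
            rss=float(2.0 * best.cost),
            converged=bool(best.success),
            nfev=int(best.nfev),
        )


@dataclass
class ToftsResults:
    """Fit results: parameter estimates plus diagnostics."""

    model: ExtendedToftsModel
    params: ToftsParams
    rss: float
    converged: bool
    nfev: int = 0
    _fitted: np.ndarray | None = field(default=None, repr=False)

    @property
    def fittedvalues(self) -> np.ndarray:
        if self._fitted is None:
            self._fitted = self.model.predict(self.params)
        return self._fitted

    @property
    def resid(self) -> np.ndarray:
        return self.model.curve.concentrations - self.fittedvalues

    def to_dict(self) -> dict:
        return {
            "ktrans_per_min": self.params.ktrans,
            "ve": self.params.ve,
            "vp": self.params.vp,
            "kep_per_min": self.params.kep if self.params.ktrans > 0 else 0.0,
            "rss": self.rss,
            "converged": self.converged,
        }

    def summary(self) -> str:
        p = self.params
        kep = p.kep if p.ktrans > 0 else 0.0
        lines = [
            "Extended Tofts model fit",
            "=" * 40,
            f"n observations : {len(self.model.curve)}",
            f"Ktrans (min^-1): {p.ktrans:.6g}",
            f"ve             : {p.ve:.6g}",
            f"vp             : {p.vp:.6g}",
            f"kep (min^-1)   : {kep:.6g}",
            f"RSS            : {self.rss:.6g}",
            f"converged      : {self.converged}",
        ]
        return "\n".join(lines)


def fit_tofts(
    curve: TissueCurve,
    aif: AIF = POPULATION_AIF,
    init: ToftsParams | None = None,
    bounds: tuple | None = None,
    multistart: bool = False,
) -> ToftsResults:
    """Fit the extended Tofts model to a tissue curve (functional wrapper)."""
    return ExtendedToftsModel(curve, aif).fit(init=init, bounds=bounds, multistart=multistart)


def roi_average_ktrans(ktrans_map: np.ndarray, roi_center: tuple[int, int], size: int = 5) -> float:
    """Arithmetic mean of Ktrans over a ``size x size`` in-plane window.

    ``ktrans_map`` is a 2D voxelwise Ktrans grid (one slice); ``roi_center``
    is the (row, col) index of the window center.  The window must lie fully
    inside the grid.
    """
    km = np.asarray(ktrans_map, dtype=float)
    if km.ndim != 2:
        raise InputError("ktrans_map must be 2D (one slice)")
    if size < 1 or size % 2 == 0:
        raise InputError("size must be a positive odd integer")
    r, c = roi_center
    h = size // 2
    if r - h < 0 or c - h < 0 or r + h >= km.shape[0] or c + h >= km.shape[1]:
        raise InputError("ROI window extends outside the Ktrans map")
    return float(km[r - h : r + h + 1, c - h : c + h + 1].mean())


def signal_to_concentration(
    signal: TissueCurve, baseline_window: tuple[int, int], k: float = 1.0
) -> TissueCurve:
    """Linear relative-enhancement conversion of a raw signal curve.

    ``C(t) = (S(t) - S0) / (k * S0)`` with ``S0`` the mean over the baseline
    window (inclusive start, exclusive stop, indices into the curve).  This is
    a linear front-end, not the full spoiled-gradient-echo signal equation.
    """
    lo, hi = baseline_window
    if not (0 <= lo < hi <= len(signal)):
        raise InputError("baseline_window out of range")
    s0 = float(np.mean(signal.concentrations[lo:hi]))
    if s0 <= 0:
        raise AnalysisError("baseline signal mean must be positive")
    if k <= 0:
        raise InputError("scale k must be positive")
    conc = (signal.concentrations - s0) / (k * s0)
    return TissueCurve(signal.times, conc, label=signal.label or "converted")
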