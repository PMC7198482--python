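"""Biomarker quantitation and paired statistics.

Two pieces live here:

* ELISA quantitation through a four-parameter logistic (4PL) standard curve
  ``OD(x) = D + (A - D) / (1 + (x/C)^B)`` — fitting (:class:`FourPLModel` /
  :func:`fit_4pl`) and analytic inversion (:func:`invert_4pl`).
* Paired pre/post statistics on small animal panels: the paired t-test and
  the *exact* Wilcoxon matched-pairs signed-rank test.  At n = 7 animals the
  exact two-sided signed-rank p for uniformly signed differences is
  2 / 2^7 = 0.015625, which is why the exact (not normal-approximation)
  convention matters at these sample sizes.

Panels are paired per animal; :func:`summarize_panel` produces the per-analyte
"mean ± SD pre/post plus paired t" table used by the report generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .errors import (
    AnalysisError,
    DegenerateVarianceError,
    FittingError,
    InputError,
    QuantitationRangeError,
)

__all__ = [
    "FourPLCurve",
    "FourPLModel",
    "FourPLResults",
    "fit_4pl",
    "invert_4pl",
    "BiomarkerPanel",
    "PairedTestResult",
    "paired_t_test",
    "wilcoxon_signed_rank_exact",
    "summarize_panel",
]


@dataclass(frozen=True)
class FourPLCurve:
    """Four-parameter logistic response curve.

    A: response at zero concentration; D: response at infinite concentration;
    C: inflection concentration (ng/mL, > 0); B: slope factor (!= 0).
    """

    A: float
    D: float
    C: float
    B: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise InputError("C (inflection concentration) must be > 0")
        if self.B == 0:
            raise InputError("B (slope factor) must be nonzero")
        if self.A == self.D:
            raise InputError("A and D must differ")

    def od(self, x) -> np.ndarray | float:
        """Evaluate the curve; OD(0) = A for B > 0 (limit convention)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise InputError("concentrations must be >= 0")
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(x > 0, (x / self.C) ** self.B, 0.0 if self.B > 0 else np.inf)
        out = self.D + (self.A - self.D) / (1.0 + ratio)
        return float(out) if out.ndim == 0 else out

    def inverse(self, od: float) -> float:
        return invert_4pl(self, od)


def invert_4pl(curve: FourPLCurve, od: float) -> float:
    """Analytic 4PL inversion: ``x = C ((A - D)/(od - D) - 1)^(1/B)``.

    ``od`` must lie strictly between the asymptotes; values at or beyond them
    are below/above the quantitation limit.
    """
    lo, hi = sorted((curve.A, curve.D))
    if not (lo < od < hi):
        raise QuantitationRangeError(
            f"OD {od} outside open quantitation interval ({lo}, {hi})"
        )
    return float(curve.C * ((curve.A - curve.D) / (od - curve.D) - 1.0) ** (1.0 / curve.B))


class FourPLModel:
    """4PL standard-curve model over (concentration, OD) calibration points."""

    def __init__(self, concentrations, ods):
        self.concentrations = np.asarray(concentrations, dtype=float)
        self.ods = np.asarray(ods, dtype=float)
        if self.concentrations.shape != self.ods.shape or self.concentrations.ndim != 1:
            raise InputError("standards must be parallel 1D arrays")
        if len(np.unique(self.concentrations)) < 5:
            raise InputError("need >= 5 standards with distinct concentrations")
        if np.any(self.concentrations < 0):
            raise InputError("standard concentrations must be >= 0")

    def fit(self) -> "FourPLResults":
        """Least-squares 4PL fit.

        Initialization: A = OD at the lowest concentration side, D at the
        highest, C = geometric mid concentration, B = 1 (sign flipped when the
        response decreases with concentration).
        """
        x, y = self.concentrations, self.ods
        order = np.argsort(x)
        a0, d0 = float(y[order[0]]), float(y[order[-1]])
        pos = x[x > 0]
        c0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
        b0 = 1.0
        if a0 == d0:
            d0 = a0 + (np.ptp(y) or 1.0)

        def model(p, xv):
            A, D, C, B = p
            with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
                ratio = np.where(xv > 0, (xv / C) ** B, 0.0)
            return D + (A - D) / (1.0 + ratio)

        def resid(p):
            return model(p, x) - y

        sol = least_squares(
            resid,
            x0=[a0, d0, c0, b0],
            bounds=([-np.inf, -np.inf, 1e-12, -50.0], [np.inf, np.inf, np.inf, 50.0]),
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=5000,
        )
        if not sol.success or not np.all(np.isfinite(sol.x)):
            raise FittingError("4PL fit did not converge")
        A, D, C, B = (float(v) for v in sol.x)
        if A == D or B == 0:
            raise FittingError("degenerate 4PL fit")
        curve = FourPLCurve(A=A, D=D, C=C, B=B)
        return FourPLResults(curve=curve, rss=float(2 * sol.cost), n_standards=len(x))


@dataclass
class FourPLResults:
    curve: FourPLCurve
    rss: float
    n_standards: int

    def summary(self) -> str:
        c = self.curve
        return "\n".join(
            [
                "4PL standard curve fit",
                "=" * 40,
                f"n standards : {self.n_standards}",
                f"A (OD at 0) : {c.A:.6g}",
                f"D (OD at inf): {c.D:.6g}",
                f"C (ng/mL)   : {c.C:.6g}",
                f"B (slope)   : {c.B:.6g}",
                f"RSS         : {self.rss:.6g}",
            ]
        )


def fit_4pl(standards) -> FourPLCurve:
    """Fit a 4PL curve to ``standards`` ((concentration, OD) pairs or a
    DataFrame with ``concentration_ng_ml``/``od`` columns)."""
    if isinstance(standards, pd.DataFrame):
        conc = standards["concentration_ng_ml"].to_numpy(dtype=float)
        od = standards["od"].to_numpy(dtype=float)
    else:
        arr = np.asarray(standards, dtype=float)
        conc, od = arr[:, 0], arr[:, 1]
    return FourPLModel(conc, od).fit().curve


# ---------------------------------------------------------------------------
# Paired statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedTestResult:
    """Summary of a paired two-sample comparison."""

    n: int
    mean_pre: float
    mean_post: float
    sd_pre: float
    sd_post: float
    statistic: float
    p_two_sided: float
    method: str

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_pre": self.mean_pre,
            "mean_post": self.mean_post,
            "sd_pre": self.sd_pre,
            "sd_post": self.sd_post,
            "statistic": self.statistic,
            "p_two_sided": self.p_two_sided,
            "method": self.method,
        }


def _as_pairs(pre, post):
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise InputError("pre and post must be parallel 1D arrays")
    if len(pre) < 2:
        raise InputError("need at least 2 pairs")
    return pre, post


def paired_t_test(pre, post) -> PairedTestResult:
    """Two-sided paired t-test on differences ``post - pre``.

    ``t = dbar / (s_d / sqrt(n))`` with the sample (n-1) standard deviation;
    p from Student's t with n-1 degrees of freedom.
    """
    pre, post = _as_pairs(pre, post)
    d = post - pre
    n = len(d)
    sd = float(np.std(d, ddof=1))
    if sd == 0.0 or np.all(d == d[0]):
        if np.all(d == 0.0):
            # no change anywhere: the null outcome, not a pathology
            t, p = 0.0, 1.0
            return PairedTestResult(
                n=n,
                mean_pre=float(np.mean(pre)),
                mean_post=float(np.mean(post)),
                sd_pre=float(np.std(pre, ddof=1)),
                sd_post=float(np.std(post, ddof=1)),
                statistic=t,
                p_two_sided=p,
                method="paired t-test",
            )
        raise DegenerateVarianceError(
            "paired differences have zero variance (constant nonzero shift)"
        )
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(
        n=n,
        mean_pre=float(np.mean(pre)),
        mean_post=float(np.mean(post)),
        sd_pre=float(np.std(pre, ddof=1)),
        sd_post=float(np.std(post, ddof=1)),
        statistic=t,
        p_two_sided=min(p, 1.0),
        method="paired t-test",
    )


def _signed_rank_null_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of the null distribution of W+ on the doubled-rank lattice.

    Equivalent to enumerating all 2^m sign assignments: the generating
    polynomial prod_i (1 + z^{2 r_i}) is expanded by dynamic programming.
    Mid-ranks are multiples of 1/2, so doubled ranks are integers.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.uint64)
    counts[0] = 1
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(pre, post) -> PairedTestResult:
    """Exact two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (Wilcoxon's convention); ties in |d| get
    mid-ranks; ``W = min(W+, W-)``; the exact p doubles the lower tail of the
    null distribution of W+ over all 2^m sign assignments, capped at 1.
    Restricted to n <= 20 pairs (the exact-enumeration regime).
    """
    pre, post = _as_pairs(pre, post)
    n = len(pre)
    if n > 20:
        raise AnalysisError(
            "n > 20: exact enumeration not supported; use a large-sample method"
        )
    d = post - pre
    d = d[d != 0.0]
    m = len(d)
    if m == 0:
        raise AnalysisError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks.sum()) - w_plus
    w_obs = min(w_plus, w_minus)

    doubled = np.rint(2.0 * ranks).astype(int)
    counts = _signed_rank_null_counts(doubled)
    w2 = int(np.rint(2.0 * w_obs))
    lower_tail = float(counts[: w2 + 1].sum()) / float(2**m)
    p = min(1.0, 2.0 * lower_tail)
    return PairedTestResult(
        n=n,
        mean_pre=float(np.mean(pre)),
        mean_post=float(np.mean(post)),
        sd_pre=float(np.std(pre, ddof=1)),
        sd_post=float(np.std(post, ddof=1)),
        statistic=w_obs,
        p_two_sided=p,
        method="exact Wilcoxon signed-rank",
    )


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------


@dataclass
class BiomarkerPanel:
    """Paired pre/post analyte concentrations, one row per (animal, analyte).

    ``data`` columns: animal, analyte, pre_ng_ml, post_ng_ml.
    """

    data: pd.DataFrame

    _COLS = ("animal", "analyte", "pre_ng_ml", "post_ng_ml")

    def __post_init__(self) -> None:
        missing = [c for c in self._COLS if c not in self.data.columns]
        if missing:
            raise InputError(f"panel missing columns: {missing}")
        conc = self.data[["pre_ng_ml", "post_ng_ml"]].to_numpy(dtype=float)
        if np.any(conc[np.isfinite(conc)] < 0):
            raise InputError("concentrations must be >= 0")

    @property
    def analytes(self) -> list[str]:
        return sorted(self.data["analyte"].unique())

    def pairs(self, analyte: str) -> tuple[np.ndarray, np.ndarray]:
        """Complete (pre, post) pairs for one analyte, sorted by animal id.

        Animals with a missing value are excluded with a warning.
        """
        sub = self.data[self.data["analyte"] == analyte].sort_values("animal")
        ok = sub[["pre_ng_ml", "post_ng_ml"]].notna().all(axis=1)
        if (~ok).any():
            dropped = sub.loc[~ok, "animal"].tolist()
            warnings.warn(f"{analyte}: excluding animals with missing pair: {dropped}")
        sub = sub[ok]
        return sub["pre_ng_ml"].to_numpy(dtype=float), sub["post_ng_ml"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        """Write in long format: animal, analyte, timepoint, concentration_ng_ml."""
        rows = []
        for _, r in self.data.iterrows():
            rows.append((r["animal"], r["analyte"], "pre", r["pre_ng_ml"]))
            rows.append((r["animal"], r["analyte"], "post", r["post_ng_ml"]))
        pd.DataFrame(
            rows, columns=["animal", "analyte", "timepoint", "concentration_ng_ml"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BiomarkerPanel":
        df = pd.read_csv(path)
        if "timepoint" in df.columns:
            wide = df.pivot_table(
                index=["animal", "analyte"],
                columns="timepoint",
                values="concentration_ng_ml",
                aggfunc="first",
            ).reset_index()
            wide = wide.rename(columns={"pre": "pre_ng_ml", "post": "post_ng_ml"})
            wide.columns.name = None
            return cls(wide[["animal", "analyte", "pre_ng_ml", "post_ng_ml"]])
        return cls(df)


def summarize_panel(panel: BiomarkerPanel) -> pd.DataFrame:
    """Per-analyte summary: n, mean ± sample SD pre/post, paired t result.

    Rows are ordered by analyte name for deterministic output.
    """
    rows = []
    for analyte in panel.analytes:
        pre, post = panel.pairs(analyte)
        if len(pre) < 2:
            raise AnalysisError(f"{analyte}: need >= 2 complete pairs")
        res = paired_t_test(pre, post)
        t_stat, p = res.statistic, res.p_two_sided
        rows.append(
            {
                "analyte": analyte,
                "n": len(pre),
                "pre_mean": float(np.mean(pre)),
                "pre_sd": float(np.std(pre, ddof=1)),
                "post_mean": float(np.mean(post)),
                "post_sd": float(np.std(post, ddof=1)),
                "t_statistic": t_stat,
                "p_two_sided": p,
            }
        )
    return pd.DataFrame(rows)
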