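"""First-order pesticide dissipation kinetics.

The dissipation model is a single-compartment exponential decay,

    C(t) = C0 * exp(-k * t),

with rate constant ``k`` (per hour) and half-life ``t_1/2 = ln 2 / k``.
Two estimators are provided: a log-linear fit (OLS of ln C on t, the
classical linearization) and a nonlinear least-squares fit on the
concentration scale initialized from the log-linear estimate.  Goodness
of fit is reported as R² on the concentration scale for both.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize as sciopt
from scipy import stats

from .errors import InvalidInputError, NoFitError

__all__ = [
    "DecayCurve",
    "KineticsFit",
    "TreatmentComparison",
    "fit_first_order",
    "half_life",
    "percent_dissipated",
    "compare_treatments",
    "read_timeseries",
    "write_timeseries",
]


@dataclass
class DecayCurve:
    """A concentration-time series for one treatment.

    times in hours (strictly increasing, non-negative), concentrations in
    mg/L (non-negative).  ``c0_nominal`` is the spiked initial
    concentration; ``label`` distinguishes e.g. control vs treatment.
    """

    times: np.ndarray
    concentrations: np.ndarray
    c0_nominal: float | None = None
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise InvalidInputError("times and concentrations must have equal length")
        if len(self.times) < 2:
            raise InvalidInputError("a decay curve needs at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.times < 0) or not np.all(np.isfinite(self.times)):
            raise InvalidInputError("times must be finite and non-negative")
        if np.any(self.concentrations < 0) or not np.all(
            np.isfinite(self.concentrations)
        ):
            raise InvalidInputError("concentrations must be finite and non-negative")


@dataclass
class KineticsFit:
    """First-order fit results: rate constant, C0, half-life and R²."""

    k: float  # per hour
    c0: float  # mg/L
    t_half: float  # hours; inf when k == 0
    r2: float
    method: str
    n_points: int
    n_excluded_zeros: int = 0
    label: str = ""

    @classmethod
    def from_rate_constant(cls, k: float, c0: float = float("nan"), label: str = ""):
        """Construct a fit record from a known rate constant (half-life by Eq.
        t_1/2 = ln2/k); used when comparing externally reported constants."""
        return cls(
            k=float(k), c0=c0, t_half=half_life(k), r2=float("nan"),
            method="given", n_points=0, label=label,
        )


def half_life(k: float) -> float:
    """Half-life of first-order decay, ``ln 2 / k`` hours.

    ``k == 0`` yields ``inf`` (no decay); negative ``k`` is rejected.
    """
    if not math.isfinite(k):
        raise InvalidInputError(f"rate constant must be finite, got {k}")
    if k < 0:
        raise InvalidInputError(f"rate constant must be >= 0, got {k}")
    if k == 0:
        return math.inf
    return math.log(2.0) / k


def _loglinear(t: np.ndarray, c: np.ndarray):
    pos = c > 0
    n_excl = int(np.sum(~pos))
    if n_excl:
        warnings.warn(
            f"log-linear fit: excluding {n_excl} zero concentration(s) "
            "(left-censored under the log transform)",
            RuntimeWarning,
            stacklevel=3,
        )
    t, c = t[pos], c[pos]
    if len(t) < 3 or len(np.unique(t)) < 2:
        raise NoFitError("log-linear fit needs >= 3 positive-concentration points")
    res = stats.linregress(t, np.log(c))
    k = max(0.0, -float(res.slope))
    c0 = float(np.exp(res.intercept))
    return k, c0, n_excl


def fit_first_order(curve: DecayCurve, method: str = "nonlinear") -> KineticsFit:
    """Fit ``C(t) = C0 exp(-k t)`` to a decay curve.

    method="log_linear": OLS of ln C on t (zero concentrations excluded with
    a warning).  method="nonlinear": bounded least squares on the
    concentration scale, initialized from the log-linear estimate; zeros
    participate as observed.  R² is computed on the concentration scale in
    both cases.
    """
    t, c = curve.times, curve.concentrations
    if np.all(c == 0):
        raise NoFitError("all concentrations are zero; nothing to fit")
    if len(t) < 3:
        raise NoFitError("first-order fit needs at least 3 time points")

    if method == "log_linear":
        k, c0, n_excl = _loglinear(t, c)
    elif method == "nonlinear":
        try:
            k0, c00, _ = _loglinear(t, c)
        except NoFitError:
            k0, c00 = 0.01, float(np.max(c))
        if k0 == 0.0:
            k0 = 1e-6
        popt, _ = sciopt.curve_fit(
            lambda tt, c0_, k_: c0_ * np.exp(-k_ * tt),
            t,
            c,
            p0=[max(c00, 1e-6), k0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        c0, k = float(popt[0]), float(popt[1])
        n_excl = 0
    else:
        raise InvalidInputError(f"unknown method {method!r}")

    fitted = c0 * np.exp(-k * t)
    sse = float(np.sum((c - fitted) ** 2))
    sst = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    return KineticsFit(
        k=k,
        c0=c0,
        t_half=half_life(k),
        r2=r2,
        method=method,
        n_points=len(t),
        n_excluded_zeros=n_excl,
        label=curve.label,
    )


def percent_dissipated(curve: DecayCurve, at_time: float) -> float:
    """Observed percentage dissipated by ``at_time`` hours.

    Linear interpolation of the observed series; the baseline is the
    concentration at the first observed time, which must be positive.
    """
    if not (curve.times[0] <= at_time <= curve.times[-1]):
        raise InvalidInputError(
            f"at_time {at_time} outside observed range "
            f"[{curve.times[0]}, {curve.times[-1]}]"
        )
    baseline = curve.concentrations[0]
    if baseline <= 0:
        raise InvalidInputError("baseline concentration must be positive")
    c_t = float(np.interp(at_time, curve.times, curve.concentrations))
    return 100.0 * (1.0 - c_t / baseline)


@dataclass
class TreatmentComparison:
    """Half-life reduction and rate-constant ratio, treatment vs control."""

    delta_t_half: float  # control t1/2 minus treatment t1/2, hours
    k_ratio: float  # treatment k over control k


def compare_treatments(
    control: KineticsFit, treatment: KineticsFit
) -> TreatmentComparison:
    """Half-life difference (control − treatment) and k ratio (treatment / control)."""
    ratio = treatment.k / control.k if control.k > 0 else math.inf
    return TreatmentComparison(
        delta_t_half=control.t_half - treatment.t_half,
        k_ratio=ratio,
    )


# -- delimited-text I/O ------------------------------------------------------


def write_timeseries(curves: list[DecayCurve], path) -> None:
    """Write curves as comma-separated text: time_h, conc_mg_L, replicate, label."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "time_h": c.times,
                    "conc_mg_L": c.concentrations,
                    "replicate": 1,
                    "label": c.label or "series",
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_timeseries(path) -> dict[str, DecayCurve]:
    """Read a time-series file; replicates are averaged per (label, time).

    Returns one DecayCurve per label, keyed by label.
    """
    df = pd.read_csv(path)
    needed = {"time_h", "conc_mg_L"}
    if df.empty or not needed <= set(df.columns):
        raise InvalidInputError(
            f"{path}: expected non-empty table with columns {sorted(needed)}"
        )
    if "label" not in df.columns:
        df["label"] = "series"
    out = {}
    for label, grp in df.groupby("label"):
        means = grp.groupby("time_h")["conc_mg_L"].mean().sort_index()
        out[str(label)] = DecayCurve(
            times=means.index.to_numpy(float),
            concentrations=means.to_numpy(float),
            label=str(label),
        )
    return out
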