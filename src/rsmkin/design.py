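"""Central composite designs and factor coding.

A central composite design (CCD) for ``k`` factors combines a full
two-level factorial block (2^k vertex runs at coded ±1), an axial block
(2k star runs at coded ±alpha on one axis each) and replicated center
runs (all-zero coded coordinates).  With the rotatable choice
``alpha = (2^k)**0.25`` the prediction variance of the fitted quadratic
depends only on the distance from the design center.

Factors are handled on two scales: the *actual* scale (pH units, °C,
days, ...) and the dimensionless *coded* scale

    x = (X - center) / step

where ``center`` is the actual value at coded zero and ``step`` is the
actual increment corresponding to one coded unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UnsupportedDesignError

__all__ = [
    "Factor",
    "DesignTable",
    "code_value",
    "decode_value",
    "generate_ccd",
    "randomize_runs",
    "rotatable_alpha",
    "default_factors",
    "read_design",
    "write_design",
    "read_factor_config",
    "write_factor_config",
]

#: Column names a serialized design always starts with.
_FIXED_COLUMNS = ("run", "class")
_RESPONSE_COLUMNS = ("y_mean", "y_se", "n_rep")

POINT_CLASSES = ("factorial", "axial", "center")


@dataclass(frozen=True)
class Factor:
    """One experimental factor with its actual-to-coded mapping.

    Parameters
    ----------
    name:
        Text label, used for column naming (``x_<name>``, ``X_<name>``).
    center:
        Actual value at coded zero.
    step:
        Actual increment per coded unit; must be strictly positive.
    units:
        Free-text units, carried through for reporting only.
    """

    name: str
    center: float
    step: float
    units: str = ""

    def __post_init__(self):
        if not (math.isfinite(self.center) and math.isfinite(self.step)):
            raise InvalidInputError(
                f"factor {self.name!r}: center and step must be finite"
            )
        if self.step <= 0:
            raise InvalidInputError(
                f"factor {self.name!r}: step must be strictly positive, got {self.step}"
            )

    def code(self, X):
        """Actual value -> coded value, ``(X - center) / step``."""
        return code_value(X, self)

    def decode(self, x):
        """Coded value -> actual value, ``center + x * step``."""
        return decode_value(x, self)


def code_value(X, factor: Factor):
    """Convert an actual factor value to the dimensionless coded scale."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("actual value must be finite")
    out = (X - factor.center) / factor.step
    return float(out) if out.ndim == 0 else out


def decode_value(x, factor: Factor):
    """Convert a coded value back to the actual factor scale."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("coded value must be finite")
    out = factor.center + x * factor.step
    return float(out) if out.ndim == 0 else out


def rotatable_alpha(k: int) -> float:
    """Axial distance making a k-factor CCD rotatable: ``(2**k) ** 0.25``."""
    return float((2.0**k) ** 0.25)


def default_factors() -> list[Factor]:
    """The pH / temperature / incubation-time factor set of the reference study.

    The coded-to-actual steps (pH 1.0 around 6.0, temperature 4 °C around
    26 °C, time 1 day around 5 days) are package defaults consistent with
    the study's single-factor screening ranges and stated optimum; they can
    be overridden by constructing :class:`Factor` objects directly.
    """
    return [
        Factor("pH", center=6.0, step=1.0, units="pH"),
        Factor("temperature", center=26.0, step=4.0, units="degC"),
        Factor("time", center=5.0, step=1.0, units="day"),
    ]


@dataclass
class DesignTable:
    """A CCD run matrix on coded and actual scales, optionally with responses.

    ``runs`` is a DataFrame with columns ``run`` (1-based index),
    ``class`` (factorial | axial | center), one ``x_<name>`` column per
    factor (coded) and one ``X_<name>`` column per factor (actual), plus
    optional ``y_mean``, ``y_se``, ``n_rep`` response columns.
    """

    factors: list[Factor]
    runs: pd.DataFrame
    alpha: float | None = None

    def __post_init__(self):
        missing = [c for c in _FIXED_COLUMNS if c not in self.runs.columns]
        missing += [c for f in self.factors for c in (f"x_{f.name}",) if c not in self.runs.columns]
        if missing:
            raise InvalidInputError(f"design table missing columns: {missing}")
        # Fill actual columns from coded ones when absent.
        for f in self.factors:
            if f"X_{f.name}" not in self.runs.columns:
                self.runs[f"X_{f.name}"] = decode_value(
                    self.runs[f"x_{f.name}"].to_numpy(), f
                )

    # -- accessors ---------------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def coded(self) -> np.ndarray:
        """(n_runs, k) matrix of coded coordinates."""
        return self.runs[[f"x_{n}" for n in self.factor_names]].to_numpy(float)

    @property
    def actual(self) -> np.ndarray:
        """(n_runs, k) matrix of actual coordinates."""
        return self.runs[[f"X_{n}" for n in self.factor_names]].to_numpy(float)

    @property
    def has_responses(self) -> bool:
        return "y_mean" in self.runs.columns and self.runs["y_mean"].notna().all()

    def class_counts(self) -> dict[str, int]:
        return self.runs["class"].value_counts().to_dict()

    def with_responses(self, y_mean, y_se=None, n_rep=None) -> "DesignTable":
        """Return a copy carrying the given per-run responses."""
        out = self.runs.copy()
        out["y_mean"] = np.asarray(y_mean, dtype=float)
        out["y_se"] = 0.0 if y_se is None else np.asarray(y_se, dtype=float)
        out["n_rep"] = 1 if n_rep is None else n_rep
        return DesignTable(list(self.factors), out, self.alpha)

    # -- validation --------------------------------------------------------

    def validate(self, atol: float = 1e-9) -> None:
        """Check CCD structural invariants; raise InvalidInputError on failure.

        Verifies the run-count partition, first-order orthogonality of the
        coded columns (zero column sums and zero pairwise cross-products),
        and that axial points sit on exactly one axis.
        """
        counts = self.class_counts()
        n_fact = counts.get("factorial", 0)
        n_ax = counts.get("axial", 0)
        n_ctr = counts.get("center", 0)
        if n_fact != 2**self.k or n_ax != 2 * self.k:
            raise InvalidInputError(
                f"run partition {n_fact}/{n_ax}/{n_ctr} does not match a "
                f"{self.k}-factor CCD (expected {2**self.k}/{2*self.k}/n_center)"
            )
        Xc = self.coded
        sums = Xc.sum(axis=0)
        if np.abs(sums).max() > atol * max(1, self.n_runs):
            raise InvalidInputError(f"coded column sums not zero: {sums}")
        for i in range(self.k):
            for j in range(i + 1, self.k):
                cross = float(Xc[:, i] @ Xc[:, j])
                if abs(cross) > atol * self.n_runs:
                    raise InvalidInputError(
                        f"coded columns {i},{j} not orthogonal (sum xi*xj = {cross})"
                    )
        ax = Xc[(self.runs["class"] == "axial").to_numpy()]
        if ax.size and np.any((np.abs(ax) > atol).sum(axis=1) != 1):
            raise InvalidInputError("an axial run has more than one nonzero coordinate")


def generate_ccd(
    factors: Sequence[Factor] | int,
    n_center: int = 10,
    alpha: str | float = "rotatable",
) -> DesignTable:
    """Build a five-level central composite design in standard block order.

    Parameters
    ----------
    factors:
        Sequence of :class:`Factor` definitions, or an integer ``k`` to use
        generic unit factors (center 0, step 1) named ``x1..xk``.
    n_center:
        Number of replicated center runs (>= 1).
    alpha:
        ``"rotatable"`` for ``(2**k)**0.25``, ``"face_centered"`` for 1.0,
        or an explicit positive axial distance.

    Returns
    -------
    DesignTable
        ``2**k + 2k + n_center`` runs ordered factorial, axial, center.
    """
    if isinstance(factors, int):
        factors = [Factor(f"x{i+1}", 0.0, 1.0) for i in range(factors)]
    factors = list(factors)
    k = len(factors)
    if k < 2:
        raise UnsupportedDesignError(f"CCD requires at least 2 factors, got {k}")
    if n_center < 1:
        raise InvalidInputError(f"n_center must be >= 1, got {n_center}")
    if isinstance(alpha, str):
        if alpha == "rotatable":
            a = rotatable_alpha(k)
        elif alpha == "face_centered":
            a = 1.0
        else:
            raise InvalidInputError(f"unknown alpha mode {alpha!r}")
    else:
        a = float(alpha)
        if not math.isfinite(a) or a <= 0:
            raise InvalidInputError(f"explicit alpha must be positive, got {alpha}")

    blocks = []
    # factorial vertices: all +/-1 combinations, last factor fastest
    grid = np.array(np.meshgrid(*([[-1.0, 1.0]] * k), indexing="ij"))
    blocks.append((grid.reshape(k, -1).T, "factorial"))
    ax = np.zeros((2 * k, k))
    for i in range(k):
        ax[2 * i, i] = -a
        ax[2 * i + 1, i] = a
    blocks.append((ax, "axial"))
    blocks.append((np.zeros((n_center, k)), "center"))

    rows = np.vstack([b for b, _ in blocks])
    classes = sum(([c] * len(b) for b, c in blocks), [])
    data = {"run": np.arange(1, len(rows) + 1), "class": classes}
    for j, f in enumerate(factors):
        data[f"x_{f.name}"] = rows[:, j]
    table = DesignTable(factors, pd.DataFrame(data), alpha=a)
    table.validate()
    return table


def randomize_runs(table: DesignTable, seed: int) -> DesignTable:
    """Return the same design points in a seeded pseudo-random run order.

    Run indices are reassigned 1..n in the new order; the permutation is
    ``numpy.random.default_rng(seed).permutation(n)``.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n_runs)
    runs = table.runs.iloc[perm].reset_index(drop=True)
    runs["run"] = np.arange(1, len(runs) + 1)
    return DesignTable(list(table.factors), runs, table.alpha)


# -- delimited-text serialization -----------------------------------------


def write_design(table: DesignTable, path) -> None:
    """Write a design table as comma-separated text with a header row."""
    cols = list(_FIXED_COLUMNS)
    cols += [f"x_{n}" for n in table.factor_names]
    cols += [f"X_{n}" for n in table.factor_names]
    cols += [c for c in _RESPONSE_COLUMNS if c in table.runs.columns]
    table.runs[cols].to_csv(path, index=False)


def read_design(path, factors: Sequence[Factor] | None = None) -> DesignTable:
    """Read a design table written by :func:`write_design`.

    When ``factors`` is omitted, each factor's center/step is recovered from
    the paired coded (``x_``) and actual (``X_``) columns: the center is the
    actual value at coded zero and the step the actual-per-coded slope.
    """
    runs = pd.read_csv(path)
    names = [c[2:] for c in runs.columns if c.startswith("x_")]
    if not names:
        raise InvalidInputError(f"{path}: no coded factor columns (x_<name>) found")
    if factors is None:
        factors = []
        for n in names:
            x = runs[f"x_{n}"].to_numpy(float)
            if f"X_{n}" in runs.columns:
                X = runs[f"X_{n}"].to_numpy(float)
                nz = np.abs(x) > 1e-12
                step = float(np.mean((X[nz] - X[~nz].mean()) / x[nz])) if nz.any() else 1.0
                center = float(X[~nz].mean()) if (~nz).any() else float(np.mean(X - step * x))
            else:
                center, step = 0.0, 1.0
            factors.append(Factor(n, center, step))
    return DesignTable(list(factors), runs)


def write_factor_config(factors: Sequence[Factor], path) -> None:
    """Write factor definitions as a plain key:value file, one block per factor."""
    lines = []
    for f in factors:
        lines += [f"name: {f.name}", f"center: {f.center}", f"step: {f.step}",
                  f"units: {f.units}", ""]
    Path(path).write_text("\n".join(lines))


def read_factor_config(path) -> list[Factor]:
    """Parse the plain key:value factor file written by write_factor_config."""
    factors, block = [], {}
    text = Path(path).read_text()
    for raw in text.splitlines() + [""]:
        line = raw.strip()
        if not line:
            if block:
                try:
                    factors.append(
                        Factor(
                            block["name"],
                            float(block["center"]),
                            float(block["step"]),
                            block.get("units", ""),
                        )
                    )
                except KeyError as e:
                    raise InvalidInputError(f"factor block missing key {e}") from e
                block = {}
            continue
        if ":" not in line:
            raise InvalidInputError(f"malformed factor config line: {raw!r}")
        key, _, val = line.partition(":")
        block[key.strip()] = val.strip()
    if not factors:
        raise InvalidInputError(f"{path}: no factor definitions found")
    return factors
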