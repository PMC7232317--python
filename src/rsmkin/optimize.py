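"""Stationary-point analysis, constrained optimization, Box-Cox scans
and prediction grids for a fitted quadratic response surface.

Writing the fitted surface as ``y = b0 + b'x + x'Bx`` with ``B`` the
symmetric curvature matrix (squared-term coefficients on the diagonal,
half the interaction coefficients off it), the stationary point solves
the vanishing-gradient system ``x_s = -B^{-1} b / 2`` and the
eigenvalues of ``B`` classify it: all negative -> maximum, all positive
-> minimum, mixed signs -> saddle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as sciopt
from scipy import stats

from .design import Factor, decode_value
from .errors import InvalidInputError
from .rsm import QuadraticFit, ResponseDataset, predict, quadratic_model_matrix

__all__ = [
    "StationaryPoint",
    "BoxCoxResult",
    "SurfaceGrid",
    "stationary_point",
    "constrained_optimum",
    "boxcox_scan",
    "surface_grid",
    "grid_search_optimum",
]

_EIG_ZERO_TOL = 1e-10  # eigenvalue magnitude treated as zero curvature


@dataclass
class StationaryPoint:
    """Stationary point of the fitted quadratic on coded units."""

    coded: np.ndarray
    predicted: float
    eigenvalues: np.ndarray
    classification: str  # maximum | minimum | saddle | ridge
    inside_region: bool
    actual: np.ndarray | None = None
    ridge_fallback: bool = False  # pseudo-inverse used for singular curvature


def stationary_point(
    fit: QuadraticFit,
    factors: list[Factor] | None = None,
    region_radius: float | None = None,
) -> StationaryPoint:
    """Locate and classify the stationary point of a fitted quadratic.

    Solves ``x_s = -0.5 * B^{-1} b``; if the curvature matrix is singular the
    Moore-Penrose pseudo-inverse is used and the result flagged as a ridge
    system.  ``inside_region`` is True when every coded coordinate lies
    within ``region_radius`` (default: the rotatable axial distance for
    ``fit.k`` factors).

    Passing ``factors`` additionally reports the stationary point on the
    actual factor scales.
    """
    B = fit.curvature_matrix()
    b = fit.linear.astype(float)
    eig = np.linalg.eigvalsh(B)
    singular = np.any(np.abs(eig) < _EIG_ZERO_TOL)
    if singular:
        warnings.warn(
            "curvature matrix is (near-)singular: ridge system; "
            "stationary point from pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        xs = -0.5 * np.linalg.pinv(B) @ b
    else:
        xs = -0.5 * np.linalg.solve(B, b)

    if singular:
        cls = "ridge"
    elif np.all(eig < 0):
        cls = "maximum"
    elif np.all(eig > 0):
        cls = "minimum"
    else:
        cls = "saddle"

    if region_radius is None:
        region_radius = float((2.0**fit.k) ** 0.25)
    actual = None
    if factors is not None:
        actual = np.array([decode_value(x, f) for x, f in zip(xs, factors)])
    return StationaryPoint(
        coded=xs,
        predicted=float(predict(fit, xs)),
        eigenvalues=eig,
        classification=cls,
        inside_region=bool(np.all(np.abs(xs) <= region_radius)),
        actual=actual,
        ridge_fallback=bool(singular),
    )


def constrained_optimum(
    fit: QuadraticFit,
    bounds: tuple[str, float] = ("cube", 1.0),
    n_starts: int = 16,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Maximize the fitted polynomial within a cube or sphere of the coded space.

    ``bounds`` is ``("cube", half_width)`` or ``("sphere", radius)``.  Uses
    multi-start gradient-based maximization (seeded start points plus the
    center and the clipped stationary point) and returns
    ``(best coded point, predicted response)``.
    """
    kind, size = bounds
    if size < 0:
        raise InvalidInputError(f"bound size must be >= 0, got {size}")
    k = fit.k
    if size == 0.0:
        return np.zeros(k), fit.intercept

    def neg(x):
        return -float(predict(fit, x))

    B = fit.curvature_matrix()
    bvec = fit.linear.astype(float)

    def neg_grad(x):
        return -(bvec + 2.0 * B @ x)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)]
    try:
        sp = stationary_point(fit).coded
        starts.append(np.clip(sp, -size, size))
    except Exception:
        pass
    starts += list(rng.uniform(-size, size, size=(n_starts, k)))

    best_x, best_y = None, -np.inf
    for x0 in starts:
        if kind == "cube":
            res = sciopt.minimize(
                neg, x0, jac=neg_grad, method="L-BFGS-B",
                bounds=[(-size, size)] * k,
            )
        elif kind == "sphere":
            if np.linalg.norm(x0) > size:
                x0 = x0 * (size / np.linalg.norm(x0)) * 0.99
            con = sciopt.NonlinearConstraint(
                lambda x: float(x @ x), -np.inf, size**2
            )
            res = sciopt.minimize(
                neg, x0, jac=neg_grad, method="SLSQP", constraints=[con]
            )
        else:
            raise InvalidInputError(f"unknown bound kind {kind!r}")
        if res.success or np.isfinite(res.fun):
            if -res.fun > best_y:
                best_x, best_y = np.asarray(res.x), -float(res.fun)
    return best_x, best_y


def grid_search_optimum(
    fit: QuadraticFit,
    half_width: float = 1.68,
    step: float = 0.005,
    coarse_step: float = 0.05,
):
    """Grid-search maximizer of the fitted surface over a coded cube.

    Two-stage search: a full coarse grid over ``[-half_width, half_width]^k``
    followed by a fine grid at resolution ``step`` in a neighbourhood of the
    coarse argmax.  Returns ``(argmax point, max predicted value)``.
    """
    k = fit.k

    def scan(lo, hi, s):
        axes = [np.arange(lo[i], hi[i] + s / 2, s) for i in range(k)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        vals = predict(fit, pts)
        i = int(np.argmax(vals))
        return pts[i], float(vals[i])

    lo = np.full(k, -half_width)
    hi = np.full(k, half_width)
    x0, _ = scan(lo, hi, coarse_step)
    pad = 2 * coarse_step
    lo2 = np.maximum(x0 - pad, -half_width)
    hi2 = np.minimum(x0 + pad, half_width)
    return scan(lo2, hi2, step)


@dataclass
class BoxCoxResult:
    """Profile log-likelihood scan of the Box-Cox response transformation."""

    lambdas: np.ndarray
    loglik: np.ndarray
    best_lambda: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    ci_rule: str = "f"
    inconclusive: bool = False


def boxcox_scan(
    dataset: ResponseDataset,
    lambdas: np.ndarray | None = None,
    conf_level: float = 0.95,
    ci_rule: str = "f",
) -> BoxCoxResult:
    """Scan Box-Cox power transformations of the response against the quadratic model.

    For each lambda the response is transformed by ``(y**lam - 1)/lam``
    (``log y`` at lambda 0), the full quadratic is refitted, and the profile
    log-likelihood ``-n/2*log(SSE/n) + (lam-1)*sum(log y)`` recorded (the
    second term is the log-Jacobian of the transformation; up to a constant
    this equals the likelihood of the geometric-mean-scaled transform).

    The confidence interval is the set of lambdas whose profile stays above
    a cutoff below the maximum.  ``ci_rule="f"`` (default) uses the
    residual-sum-of-squares threshold ``SSE_min * (1 + F(conf; 1, df)/df)``
    common in response-surface software Box-Cox plots, i.e. a cutoff of
    ``n/2 * log1p(F/df)``; ``ci_rule="chi2"`` uses the asymptotic profile-
    likelihood cutoff ``chi2(1, conf)/2``.

    Responses must be strictly positive.  A flat profile (identical
    responses) is reported as inconclusive.
    """
    y = dataset.y_mean
    if np.any(y <= 0):
        raise InvalidInputError("Box-Cox requires strictly positive responses")
    if lambdas is None:
        lambdas = np.arange(-3.0, 5.0 + 1e-9, 0.01)
    lambdas = np.asarray(lambdas, dtype=float)

    X = quadratic_model_matrix(dataset.design.coded)
    n = len(y)
    logsum = float(np.log(y).sum())
    ll = np.empty_like(lambdas)
    for i, lam in enumerate(lambdas):
        z = np.log(y) if abs(lam) < 1e-12 else (np.power(y, lam) - 1.0) / lam
        beta, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
        r = z - X @ beta
        sse = float(r @ r)
        if sse <= 0:
            ll[i] = np.inf
        else:
            ll[i] = -n / 2.0 * np.log(sse / n) + (lam - 1.0) * logsum

    if not np.all(np.isfinite(ll)) or np.ptp(ll) < 1e-12:
        best = float(lambdas[len(lambdas) // 2])
        return BoxCoxResult(
            lambdas, ll, best, float(lambdas[0]), float(lambdas[-1]),
            conf_level, ci_rule, inconclusive=True,
        )
    ibest = int(np.argmax(ll))
    if ci_rule == "f":
        df = n - X.shape[1]
        if df < 1:
            raise InvalidInputError("F-based interval needs residual df >= 1")
        drop = n / 2.0 * np.log1p(stats.f.ppf(conf_level, 1, df) / df)
    elif ci_rule == "chi2":
        drop = stats.chi2.ppf(conf_level, 1) / 2.0
    else:
        raise InvalidInputError(f"unknown ci_rule {ci_rule!r}")
    inside = lambdas[ll >= ll[ibest] - drop]
    return BoxCoxResult(
        lambdas=lambdas,
        loglik=ll,
        best_lambda=float(lambdas[ibest]),
        ci_low=float(inside[0]),
        ci_high=float(inside[-1]),
        conf_level=conf_level,
        ci_rule=ci_rule,
    )


@dataclass
class SurfaceGrid:
    """Predicted-response grid over two coded factors, others held fixed."""

    factor_x: str
    factor_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    fixed: dict[str, float]
    z: np.ndarray  # shape (len(x_values), len(y_values))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: x, y, fixed..., y_pred."""
        xv, yv = np.meshgrid(self.x_values, self.y_values, indexing="ij")
        out = pd.DataFrame(
            {self.factor_x: xv.ravel(), self.factor_y: yv.ravel()}
        )
        for name, val in self.fixed.items():
            out[name] = val
        out["y_pred"] = self.z.ravel()
        return out

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def surface_grid(
    fit: QuadraticFit,
    pair: tuple[str, str],
    fixed: dict[str, float] | None = None,
    resolution: int = 41,
    span: float = 1.68,
) -> SurfaceGrid:
    """Predicted responses on a 2-D coded grid for contour / 3-D plotting.

    ``pair`` names the two varied factors; remaining factors are held at the
    coded values in ``fixed`` (default 0).  The grid spans
    ``[-span, span]`` in each varied factor at ``resolution`` points.
    """
    fx, fy = pair
    names = fit.factor_names
    if fx == fy or fx not in names or fy not in names:
        raise InvalidInputError(f"pair {pair} must name two distinct model factors")
    if resolution < 2:
        raise InvalidInputError("resolution must be >= 2")
    fixed = dict(fixed or {})
    others = [n for n in names if n not in (fx, fy)]
    for n in others:
        fixed.setdefault(n, 0.0)
    unknown = set(fixed) - set(others)
    if unknown:
        raise InvalidInputError(f"fixed values given for non-held factors: {unknown}")

    xv = np.linspace(-span, span, resolution)
    yv = np.linspace(-span, span, resolution)
    gx, gy = np.meshgrid(xv, yv, indexing="ij")
    pts = np.zeros((gx.size, fit.k))
    pts[:, names.index(fx)] = gx.ravel()
    pts[:, names.index(fy)] = gy.ravel()
    for n in others:
        pts[:, names.index(n)] = fixed[n]
    z = predict(fit, pts).reshape(gx.shape)
    return SurfaceGrid(fx, fy, xv, yv, {n: fixed[n] for n in others}, z)
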