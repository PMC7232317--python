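"""Quadratic response-surface fitting, ANOVA and regression diagnostics.

The model is the full second-order polynomial in coded factors,

    Y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2,

fitted by ordinary least squares.  For k = 3 factors the model has
10 parameters (intercept, 3 linear, 3 two-way interaction, 3 squared
terms).  The default fit basis is the per-run mean responses; a
balanced replicate basis is available and yields identical coefficient
estimates (it changes only the dispersion statistics).

ANOVA reports the overall F test, R², adjusted R², the PRESS-based
predicted R² (leave-one-out, computed in closed form from residuals and
leverages), and the coefficient of variation CV = 100·RMSE/mean(Y).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DesignTable
from .errors import (
    InvalidInputError,
    SingularDesignError,
    UndefinedStatisticError,
)

__all__ = [
    "ResponseDataset",
    "QuadraticFit",
    "AnovaReport",
    "DiagnosticsTable",
    "quadratic_terms",
    "quadratic_model_matrix",
    "fit_quadratic",
    "anova",
    "predict",
    "diagnostics",
    "group_letters",
]

_PERFECT_FIT_TOL = 1e-10  # relative SSE/SST below which the fit counts as exact


@dataclass
class ResponseDataset:
    """A design with observed responses attached.

    ``design.runs`` must carry ``y_mean`` for every run; ``y_se`` and
    ``n_rep`` are used by the replicate basis and by letter grouping.
    """

    design: DesignTable
    response_name: str = "degradation"
    response_units: str = "%"

    def __post_init__(self):
        if "y_mean" not in self.design.runs.columns:
            raise InvalidInputError("design carries no y_mean response column")
        y = self.design.runs["y_mean"].to_numpy(float)
        if not np.all(np.isfinite(y)):
            raise InvalidInputError("every run needs a finite mean response")
        if "y_se" in self.design.runs.columns:
            se = self.design.runs["y_se"].to_numpy(float)
            if np.any(se < 0):
                raise InvalidInputError("replicate standard errors must be >= 0")

    @property
    def y_mean(self) -> np.ndarray:
        return self.design.runs["y_mean"].to_numpy(float)

    @property
    def y_se(self) -> np.ndarray:
        if "y_se" in self.design.runs.columns:
            return self.design.runs["y_se"].to_numpy(float)
        return np.zeros(self.design.n_runs)

    @property
    def n_rep(self) -> np.ndarray:
        if "n_rep" in self.design.runs.columns:
            return self.design.runs["n_rep"].to_numpy(int)
        return np.ones(self.design.n_runs, dtype=int)


def quadratic_terms(names: list[str]) -> list[str]:
    """Term labels in canonical order: intercept, linear, interactions, squares."""
    terms = ["Intercept"] + list(names)
    terms += [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
    terms += [f"{n}^2" for n in names]
    return terms


def quadratic_model_matrix(coded: np.ndarray) -> np.ndarray:
    """Expand (n, k) coded coordinates into the (n, p) quadratic model matrix."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)] + [coded[:, i] for i in range(k)]
    cols += [coded[:, i] * coded[:, j] for i, j in itertools.combinations(range(k), 2)]
    cols += [coded[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass
class QuadraticFit:
    """OLS estimates of the full quadratic model on coded units."""

    factor_names: list[str]
    terms: list[str]
    beta: np.ndarray
    cov: np.ndarray
    X: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    resid: np.ndarray
    sst: float
    ssr: float
    sse: float
    df_model: int
    df_resid: int
    basis: str = "means"
    _sm_result: object = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.factor_names)

    @property
    def n_params(self) -> int:
        return len(self.terms)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    def coef(self, term: str) -> float:
        """Coefficient by term label, e.g. ``"time"`` or ``"pH:time"``."""
        try:
            return float(self.beta[self.terms.index(term)])
        except ValueError:
            # interaction labels are order-insensitive
            if ":" in term:
                a, b = term.split(":")
                return float(self.beta[self.terms.index(f"{b}:{a}")])
            raise

    @property
    def linear(self) -> np.ndarray:
        return self.beta[1 : 1 + self.k]

    @property
    def quadratic(self) -> np.ndarray:
        return self.beta[-self.k :]

    @property
    def interactions(self) -> dict[tuple[str, str], float]:
        pairs = list(itertools.combinations(self.factor_names, 2))
        off = 1 + self.k
        return {p: float(self.beta[off + i]) for i, p in enumerate(pairs)}

    def curvature_matrix(self) -> np.ndarray:
        """Symmetric matrix B with quadratic terms on the diagonal and half
        the interaction coefficients off-diagonal, so that the fitted
        surface is ``b0 + b'x + x'Bx``."""
        B = np.diag(self.quadratic.astype(float))
        off = 1 + self.k
        for idx, (i, j) in enumerate(itertools.combinations(range(self.k), 2)):
            B[i, j] = B[j, i] = self.beta[off + idx] / 2.0
        return B

    @property
    def is_perfect(self) -> bool:
        return self.sse <= _PERFECT_FIT_TOL * max(self.sst, 1.0)

    def leverage(self) -> np.ndarray:
        """Hat-matrix diagonal h_ii for the fit's own observations."""
        return self._sm_result.get_influence().hat_matrix_diag


def _expand_replicates(dataset: ResponseDataset):
    """Turn each run's mean ± SE into n_rep pseudo-replicates that reproduce
    the mean exactly and the sample SD = SE·sqrt(n_rep)."""
    coded = dataset.design.coded
    rows, ys = [], []
    for i in range(dataset.design.n_runs):
        n = int(dataset.n_rep[i])
        if n < 1:
            raise InvalidInputError(f"run {i + 1}: n_rep must be >= 1")
        s = dataset.y_se[i] * np.sqrt(n)
        z = np.arange(n, dtype=float) - (n - 1) / 2.0
        if n > 1:
            z /= z.std(ddof=1)
        rows.append(np.repeat(coded[i : i + 1], n, axis=0))
        ys.append(dataset.y_mean[i] + s * z)
    return np.vstack(rows), np.concatenate(ys)


def fit_quadratic(dataset: ResponseDataset, basis: str = "means") -> QuadraticFit:
    """Fit the full quadratic polynomial by OLS on coded units.

    ``basis="means"`` (default) fits the per-run mean responses;
    ``basis="replicates"`` expands each run into pseudo-replicates from its
    mean and standard error before fitting.  On a balanced design both give
    the same coefficients; residual degrees of freedom differ.
    """
    if basis == "means":
        coded, y = dataset.design.coded, dataset.y_mean
    elif basis == "replicates":
        coded, y = _expand_replicates(dataset)
    else:
        raise InvalidInputError(f"unknown basis {basis!r}")

    names = dataset.design.factor_names
    terms = quadratic_terms(names)
    X = quadratic_model_matrix(coded)
    n, p = X.shape
    if n < p:
        raise SingularDesignError(terms)
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify dependent columns via rank-revealing QR pivoting
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        raise SingularDesignError([terms[i] for i in sorted(piv[rank:])])

    res = sm.OLS(y, X).fit()
    fitted = np.asarray(res.fittedvalues)
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(resid @ resid)
    return QuadraticFit(
        factor_names=list(names),
        terms=terms,
        beta=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        X=X,
        y=np.asarray(y, dtype=float),
        fitted=fitted,
        resid=resid,
        sst=sst,
        ssr=sst - sse,
        sse=sse,
        df_model=p - 1,
        df_resid=n - p,
        basis=basis,
        _sm_result=res,
    )


@dataclass
class AnovaReport:
    """Whole-model ANOVA and summary statistics for a quadratic fit."""

    f_value: float
    p_value: float
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    cv: float
    mse: float
    coef_table: pd.DataFrame
    perfect_fit: bool = False
    press_undefined_runs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "f_value": self.f_value,
            "p_value": self.p_value,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "pred_r2": self.pred_r2,
            "press": self.press,
            "cv": self.cv,
            "mse": self.mse,
            "perfect_fit": self.perfect_fit,
            "coefficients": self.coef_table.to_dict(orient="index"),
        }
        return d


def press_statistic(fit: QuadraticFit):
    """Leave-one-out PRESS = Σ (e_i / (1 − h_ii))², in closed form.

    Returns (press, undefined_runs); runs with leverage 1 are excluded from
    the sum and reported as undefined.
    """
    h = fit.leverage()
    undef = [int(i) for i in np.flatnonzero(1.0 - h < 1e-12)]
    ok = np.setdiff1d(np.arange(fit.n_obs), undef)
    press = float(np.sum((fit.resid[ok] / (1.0 - h[ok])) ** 2))
    return press, undef


def anova(fit: QuadraticFit) -> AnovaReport:
    """Compute the ANOVA report for a fitted quadratic model."""
    if fit.df_resid < 1:
        raise UndefinedStatisticError("no residual degrees of freedom")
    n = fit.n_obs
    mse = fit.sse / fit.df_resid
    r2 = 1.0 - fit.sse / fit.sst
    adj_r2 = 1.0 - (fit.sse / fit.df_resid) / (fit.sst / (n - 1))
    press, undef = press_statistic(fit)
    pred_r2 = 1.0 - press / fit.sst
    cv = 100.0 * np.sqrt(mse) / fit.y.mean()
    perfect = fit.is_perfect
    if perfect:
        f_value, p_value = np.inf, 0.0
    else:
        f_value = (fit.ssr / fit.df_model) / mse
        p_value = float(stats.f.sf(f_value, fit.df_model, fit.df_resid))

    se = np.sqrt(np.diag(fit.cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.beta / se
    p = 2.0 * stats.t.sf(np.abs(t), fit.df_resid)
    coef_table = pd.DataFrame(
        {"coef": fit.beta, "se": se, "t": t, "p": p}, index=fit.terms
    )
    return AnovaReport(
        f_value=float(f_value),
        p_value=float(p_value),
        r2=float(r2),
        adj_r2=float(adj_r2),
        pred_r2=float(pred_r2),
        press=float(press),
        cv=float(cv),
        mse=float(mse),
        coef_table=coef_table,
        perfect_fit=perfect,
        press_undefined_runs=undef,
    )


def predict(fit: QuadraticFit, points, se: bool = False):
    """Evaluate the fitted polynomial at coded points.

    ``points`` is a length-k vector or an (n, k) array.  With ``se=True``
    returns ``(yhat, se_mean)`` where the standard error of the predicted
    mean is ``sqrt(x' Cov(beta) x)``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != fit.k:
        raise InvalidInputError(
            f"points have dimension {pts.shape[1]}, model has k={fit.k}"
        )
    Xp = quadratic_model_matrix(pts)
    yhat = Xp @ fit.beta
    scalar = np.asarray(points).ndim == 1
    if not se:
        return float(yhat[0]) if scalar else yhat
    var = np.einsum("ij,jk,ik->i", Xp, fit.cov, Xp)
    sem = np.sqrt(np.maximum(var, 0.0))
    if scalar:
        return float(yhat[0]), float(sem[0])
    return yhat, sem


@dataclass
class DiagnosticsTable:
    """Per-observation influence measures for a quadratic fit."""

    table: pd.DataFrame  # columns: leverage, student_internal, student_external, cooks_d

    @property
    def leverage(self) -> np.ndarray:
        return self.table["leverage"].to_numpy()

    @property
    def cooks_d(self) -> np.ndarray:
        return self.table["cooks_d"].to_numpy()


def diagnostics(fit: QuadraticFit) -> DiagnosticsTable:
    """Leverage, internally/externally studentized residuals and Cook's distance.

    Runs with leverage numerically equal to 1 get NaN studentized residuals
    and Cook's distance (undefined) rather than raising.
    """
    if fit.df_resid < 2:
        raise UndefinedStatisticError("diagnostics need residual df >= 2")
    infl = fit._sm_result.get_influence()
    h = infl.hat_matrix_diag
    bad = 1.0 - h < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        r_int = infl.resid_studentized_internal
        r_ext = infl.resid_studentized_external
        cooks = infl.cooks_distance[0]
    tab = pd.DataFrame(
        {
            "run": np.arange(1, fit.n_obs + 1),
            "leverage": h,
            "student_internal": np.where(bad, np.nan, r_int),
            "student_external": np.where(bad, np.nan, r_ext),
            "cooks_d": np.where(bad, np.nan, cooks),
        }
    ).set_index("run")
    return DiagnosticsTable(tab)


# -- compact letter display -------------------------------------------------


def group_letters(means, se, n_rep, alpha: float = 0.05) -> list[str]:
    """Compact letter display from all-pairs LSD tests on run means.

    Uses the pooled within-run variance (from each run's SE and replicate
    count) and Fisher's least-significant-difference rule at level
    ``alpha``: runs whose means differ by more than
    ``t_{1-alpha/2,df} * sqrt(s2p*(1/n_i+1/n_j))`` are significantly
    different and share no letter.  Letters are assigned to maximal groups
    of mutually non-significant runs, scanning means in descending order.

    With zero pooled variance the comparison degenerates to exact mean
    equality.
    """
    means = np.asarray(means, dtype=float)
    se = np.asarray(se, dtype=float)
    n_rep = np.asarray(n_rep, dtype=int)
    m = len(means)
    if np.any(n_rep < 2):
        raise InvalidInputError("letter grouping needs n_rep >= 2 for every run")
    # pooled within-run variance; s_i = se_i * sqrt(n_i)
    s2 = (se * np.sqrt(n_rep)) ** 2
    df = int(np.sum(n_rep - 1))
    s2p = float(np.sum((n_rep - 1) * s2) / df)

    if s2p <= 0.0:
        sig = means[:, None] != means[None, :]
    else:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        lsd = tcrit * np.sqrt(s2p * (1.0 / n_rep[:, None] + 1.0 / n_rep[None, :]))
        sig = np.abs(means[:, None] - means[None, :]) > lsd

    # Sweep means in ascending order: from each start, grow the maximal
    # interval of mutually non-significant runs, then keep only intervals
    # not contained in another (the groups of the compact letter display).
    order = np.argsort(means, kind="stable")
    intervals: list[list[int]] = []
    for i in range(m):
        members = [int(order[i])]
        j = i
        while j + 1 < m and not any(sig[order[j + 1], t] for t in members):
            members.append(int(order[j + 1]))
            j += 1
        intervals.append(members)
    groups = [
        g
        for idx, g in enumerate(intervals)
        if not any(set(g) < set(other) for other in intervals)
        and (idx == 0 or set(g) != set(intervals[idx - 1]))
    ]
    if len(groups) > 52:
        raise InvalidInputError("more than 52 letter groups; refusing to label")
    alphabet = string.ascii_lowercase + string.ascii_uppercase
    letters = ["" for _ in range(m)]
    for gi, members in enumerate(groups):
        for run in members:
            letters[run] += alphabet[gi]
    return letters
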