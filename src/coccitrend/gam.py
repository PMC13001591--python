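"""Penalized cubic-regression-spline GAM for overdispersed trap counts.

The model for a response series of yearly capture totals is

    E[captures_i] = mu_i,   log mu_i = beta_0 + f(year_i) + log(effort_i),
    Var[captures_i] = phi * mu_i                       (quasi-Poisson),

where ``f`` is a cubic regression spline on year with a fixed number of
knots and a curvature penalty ``sp * integral f''(x)^2 dx`` added to the
working normal equations of an iteratively reweighted least squares (IRLS)
fit.  The effort offset converts modeled counts to per-trap rates, so
predictions can be standardized to a common sampling effort.

With a habitat partition the linear predictor becomes habitat-specific
intercepts plus one centered smooth per habitat level, and the two model
forms are compared by generalized cross-validation,
``GCV = n * D / (n - total_edf)^2`` with ``D`` the quasi-deviance — lower
is better.

Basis construction follows the classical natural cubic regression spline:
the coefficients are the spline's values at the knots, interior second
derivatives come from the banded interpolation system, and the penalty
matrix is the exact integrated squared second derivative, whose null space
is the straight lines (so an infinitely strong penalty leaves a log-linear
trend, effective degrees of freedom 1 per smooth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space

__all__ = [
    "GAMConfig",
    "SplineBasis",
    "GAMFit",
    "SmoothTest",
    "build_basis",
    "knot_count",
    "fit_gam",
    "gcv_score",
    "smooth_significance",
    "predict_standardized",
    "GAMError",
    "BasisError",
    "ConvergenceError",
]


class GAMError(Exception):
    pass


class BasisError(GAMError):
    pass


class ConvergenceError(GAMError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class GAMConfig:
    """Fitting configuration.

    ``sp`` multiplies the curvature penalty directly in the working normal
    equations; it is faithful in role to the reference analysis' smoothing
    parameter but not numerically interchangeable with other software's
    internally rescaled parameter.  The knot cap is one knot per 6 years of
    data, at most 5 (the full-length series value); at least 3 knots are
    required to fit a smooth.
    """

    sp: float = 0.5
    max_knots: int = 5
    years_per_knot: int = 6
    min_knots: int = 3
    standard_effort: float = 50.0
    alpha: float = 0.05
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self):
        if self.sp <= 0:
            raise ValueError("sp must be > 0")


def knot_count(n_years: int, config: GAMConfig = GAMConfig()) -> int:
    """Knot allowance for a series spanning ``n_years`` distinct years."""
    k = min(config.max_knots, n_years // config.years_per_knot)
    if k < config.min_knots:
        raise BasisError(
            f"{n_years} distinct years allows only {k} knots; "
            f"need at least {config.min_knots}"
        )
    return k


class SplineBasis:
    """Natural cubic regression spline with quantile-placed knots.

    Coefficients are the spline's values at the knots.  ``design(x)``
    evaluates the cardinal basis; ``penalty`` is the exact
    integrated-squared-second-derivative matrix (symmetric PSD, straight
    lines in its null space).
    """

    def __init__(self, knots: Sequence[float]):
        knots = np.asarray(sorted(knots), float)
        if len(knots) < 3 or np.any(np.diff(knots) <= 0):
            raise BasisError("need >= 3 strictly increasing knots")
        self.knots = knots
        k = len(knots)
        h = np.diff(knots)
        # banded system mapping knot values to interior second derivatives
        D = np.zeros((k - 2, k))
        B = np.zeros((k - 2, k - 2))
        for i in range(k - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        Finv = np.linalg.solve(B, D)           # (k-2) x k
        self._F = np.zeros((k, k))             # knot values -> f'' at all knots
        self._F[1:-1] = Finv
        self.penalty = D.T @ Finv              # integral of f''^2, exact
        self.penalty = 0.5 * (self.penalty + self.penalty.T)
        self._h = h

    @property
    def k(self) -> int:
        return len(self.knots)

    def design(self, x) -> np.ndarray:
        """Basis matrix rows for points ``x`` within the knot range."""
        x = np.atleast_1d(np.asarray(x, float))
        lo, hi = self.knots[0], self.knots[-1]
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            raise BasisError(f"evaluation outside knot range [{lo}, {hi}]")
        x = np.clip(x, lo, hi)
        j = np.clip(np.searchsorted(self.knots, x, side="right") - 1, 0, self.k - 2)
        hj = self._h[j]
        xl = self.knots[j]
        xr = self.knots[j + 1]
        am = (xr - x) / hj
        ap = (x - xl) / hj
        cm = ((xr - x) ** 3 / hj - hj * (xr - x)) / 6.0
        cp = ((x - xl) ** 3 / hj - hj * (x - xl)) / 6.0
        X = np.zeros((len(x), self.k))
        rows = np.arange(len(x))
        X[rows, j] += am
        X[rows, j + 1] += ap
        X += cm[:, None] * self._F[j] + cp[:, None] * self._F[j + 1]
        return X

    def second_derivative(self, x) -> np.ndarray:
        """Map from knot values to f'' at points ``x`` (piecewise linear)."""
        x = np.atleast_1d(np.asarray(x, float))
        j = np.clip(np.searchsorted(self.knots, x, side="right") - 1, 0, self.k - 2)
        hj = self._h[j]
        t = (x - self.knots[j]) / hj
        return (1 - t)[:, None] * self._F[j] + t[:, None] * self._F[j + 1]


def build_basis(years: Sequence[float], k: int) -> SplineBasis:
    """Basis with ``k`` knots at empirical quantiles of the distinct years
    (boundary knots at min/max)."""
    distinct = np.unique(np.asarray(years, float))
    if len(distinct) < k:
        raise BasisError(f"{len(distinct)} distinct years < {k} knots")
    knots = np.quantile(distinct, np.linspace(0, 1, k))
    if len(np.unique(knots)) < k:
        raise BasisError("quantile knots are not distinct")
    return SplineBasis(knots)


# ---------------------------------------------------------------------------


@dataclass
class _SmoothTerm:
    label: str                 # "s(year)" or "s(year):<habitat>"
    habitat: str | None
    basis: SplineBasis
    Z: np.ndarray              # k x (k-1) sum-to-zero reparameterization
    cols: slice                # columns in the full design
    year_range: tuple[float, float]

    def design(self, years) -> np.ndarray:
        return self.basis.design(years) @ self.Z


@dataclass
class SmoothTest:
    label: str
    edf: float
    ref_df: float
    F: float
    p_value: float
    significant: bool


@dataclass
class GAMFit:
    """Converged penalized quasi-Poisson fit."""

    beta: np.ndarray
    cov: np.ndarray            # phi-scaled Bayesian covariance of beta
    edf_by_term: dict[str, float]
    total_edf: float
    dispersion: float          # Pearson phi-hat
    gcv: float
    deviance: float
    pearson: float
    n: int
    config: GAMConfig
    by_habitat: bool
    habitat_levels: list[str] = field(default_factory=list)
    smooths: list[_SmoothTerm] = field(default_factory=list)
    n_param: int = 1           # leading parametric columns
    iterations: int = 0
    trace: list[float] = field(default_factory=list)
    n_dropped_zero_effort: int = 0

    @property
    def smooth_labels(self) -> list[str]:
        return [s.label for s in self.smooths]


def _quasi_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_gam(
    units: pd.DataFrame,
    config: GAMConfig = GAMConfig(),
    by_habitat: bool = False,
) -> GAMFit:
    """Fit the penalized-spline quasi-Poisson model to analysis units.

    Parameters
    ----------
    units : DataFrame with columns ``year``, ``captures`` or ``response``
        (nonnegative; the predation score is accepted as a nonnegative
        real), ``effort`` (> 0; zero-effort rows are dropped and counted),
        and ``habitat`` when ``by_habitat``.
    by_habitat : fit habitat intercepts plus one centered smooth per habitat
        level instead of a single pooled smooth.
    """
    df = units.copy()
    n_dropped = int((df["effort"] <= 0).sum())
    df = df[df["effort"] > 0]
    if len(df) < 10:
        raise GAMError(f"need >= 10 units with positive effort, have {len(df)}")

    resp_col = "response" if "response" in df.columns else "captures"
    y = df[resp_col].to_numpy(float)
    if np.any(y < 0):
        raise GAMError("negative responses are not allowed")
    years = df["year"].to_numpy(float)
    offset = np.log(df["effort"].to_numpy(float))
    n = len(y)

    smooths: list[_SmoothTerm] = []
    if by_habitat:
        if "habitat" not in df.columns:
            raise GAMError("by_habitat fit requires a 'habitat' column")
        levels = sorted(df["habitat"].unique())
        counts = df["habitat"].value_counts()
        too_small = [lv for lv in levels if counts[lv] < 10]
        if too_small:
            raise GAMError(f"habitat levels with < 10 units: {too_small}")
        Xp = np.column_stack([(df["habitat"] == lv).to_numpy(float) for lv in levels])
        blocks = [Xp]
        col = len(levels)
        for lv in levels:
            mask = (df["habitat"] == lv).to_numpy()
            yrs = years[mask]
            basis = build_basis(yrs, knot_count(len(np.unique(yrs)), config))
            Xs = basis.design(yrs)
            Z = null_space(Xs.sum(axis=0, keepdims=True))
            Xz = np.zeros((n, Z.shape[1]))
            Xz[mask] = Xs @ Z
            smooths.append(
                _SmoothTerm(
                    label=f"s(year):{lv}",
                    habitat=lv,
                    basis=basis,
                    Z=Z,
                    cols=slice(col, col + Z.shape[1]),
                    year_range=(yrs.min(), yrs.max()),
                )
            )
            blocks.append(Xz)
            col += Z.shape[1]
        X = np.hstack(blocks)
        n_param = len(levels)
    else:
        levels = []
        basis = build_basis(years, knot_count(len(np.unique(years)), config))
        Xs = basis.design(years)
        Z = null_space(Xs.sum(axis=0, keepdims=True))
        smooths.append(
            _SmoothTerm(
                label="s(year)",
                habitat=None,
                basis=basis,
                Z=Z,
                cols=slice(1, 1 + Z.shape[1]),
                year_range=(years.min(), years.max()),
            )
        )
        X = np.hstack([np.ones((n, 1)), Xs @ Z])
        n_param = 1

    p = X.shape[1]
    P = np.zeros((p, p))
    for s in smooths:
        P[s.cols, s.cols] = config.sp * (s.Z.T @ s.basis.penalty @ s.Z)

    # IRLS with step-halving on the penalized quasi-deviance
    mu = y + 0.5
    eta = np.log(mu)
    beta = np.zeros(p)
    pdev_old = np.inf
    trace: list[float] = []
    converged = False
    for it in range(1, config.max_iter + 1):
        w = mu
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X
        rhs = XtW @ z
        beta_new = np.linalg.solve(A + P, rhs)

        step = 1.0
        for _ in range(40):
            b = beta + step * (beta_new - beta) if it > 1 else beta_new
            eta_t = np.clip(X @ b + offset, -30, 30)
            mu_t = np.exp(eta_t)
            pdev = _quasi_deviance(y, mu_t) + float(b @ P @ b)
            if np.isfinite(pdev) and (pdev <= pdev_old + 1e-10 or it == 1):
                break
            step /= 2.0
        beta, eta, mu = b, eta_t, mu_t
        trace.append(pdev)
        if abs(pdev_old - pdev) < config.tol * (abs(pdev) + 0.1):
            converged = True
            break
        pdev_old = pdev
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {config.max_iter} iterations", trace
        )

    w = mu
    A = (X.T * w) @ X
    H = np.linalg.solve(A + P, np.eye(p))
    edf_diag = np.diag(H @ A)
    total_edf = float(edf_diag.sum())
    if total_edf >= n:
        raise GAMError("effective degrees of freedom reached the sample size")
    pearson = float(np.sum((y - mu) ** 2 / mu))
    dispersion = pearson / (n - total_edf)
    deviance = _quasi_deviance(y, mu)
    gcv = n * deviance / (n - total_edf) ** 2
    cov = dispersion * H

    edf_by_term = {"parametric": float(edf_diag[:n_param].sum())}
    for s in smooths:
        edf_by_term[s.label] = float(edf_diag[s.cols].sum())

    return GAMFit(
        beta=beta,
        cov=cov,
        edf_by_term=edf_by_term,
        total_edf=total_edf,
        dispersion=dispersion,
        gcv=gcv,
        deviance=deviance,
        pearson=pearson,
        n=n,
        config=config,
        by_habitat=by_habitat,
        habitat_levels=list(levels),
        smooths=smooths,
        n_param=n_param,
        iterations=len(trace),
        trace=trace,
        n_dropped_zero_effort=n_dropped,
    )


def gcv_score(fit: GAMFit) -> float:
    """Generalized cross-validation score ``n * D / (n - total_edf)^2``."""
    return fit.gcv


def compare_gcv(fit_a: GAMFit, fit_b: GAMFit, rtol: float = 1e-9) -> int:
    """-1 if ``fit_a`` is strictly better (lower GCV), 1 if ``fit_b``, 0 on tie."""
    a, b = fit_a.gcv, fit_b.gcv
    if np.isclose(a, b, rtol=rtol):
        return 0
    return -1 if a < b else 1


def smooth_significance(fit: GAMFit, smooth: str | None = None) -> SmoothTest:
    """Wald-type F test of one smooth's coefficients against zero.

    The statistic is ``beta_s' V_s^+ beta_s / edf_s`` with ``V_s`` the
    phi-scaled covariance block, referenced to F(edf_s, n - total_edf);
    the reported reference df is the rank of the smooth's coefficient block.
    """
    labels = fit.smooth_labels
    if smooth is None:
        if len(labels) != 1:
            raise GAMError(f"specify one of the smooths: {labels}")
        smooth = labels[0]
    try:
        term = next(s for s in fit.smooths if s.label == smooth)
    except StopIteration:
        raise GAMError(f"no smooth labelled {smooth!r}; have {labels}") from None

    b = fit.beta[term.cols]
    V = fit.cov[term.cols, term.cols]
    Vinv = np.linalg.pinv(V, rcond=1e-12)
    ref_df = float(np.linalg.matrix_rank(V, tol=1e-12))
    edf = fit.edf_by_term[smooth]
    stat = float(b @ Vinv @ b)
    F = stat / edf
    df2 = fit.n - fit.total_edf
    p = float(stats.f.sf(F, edf, df2))
    return SmoothTest(
        label=smooth,
        edf=edf,
        ref_df=ref_df,
        F=F,
        p_value=p,
        significant=bool(p < fit.config.alpha),
    )


def predict_standardized(
    fit: GAMFit,
    years: Sequence[float],
    standard_effort: float | None = None,
    habitat: str | None = None,
) -> pd.DataFrame:
    """Response-scale predicted captures at a standard sampling effort.

    Predictions are the link-scale fit plus ``ln(standard_effort)``,
    exponentiated; the ribbon is ``exp(link +/- 1 SE)`` with the SE from the
    delta method on the coefficient covariance.  Years outside the fitted
    range raise (no extrapolation).  For a by-habitat fit, either pass one
    ``habitat`` or receive a long frame over all fitted levels.
    """
    if standard_effort is None:
        standard_effort = fit.config.standard_effort
    if standard_effort <= 0:
        raise ValueError("standard_effort must be > 0")
    years = np.asarray(years, float)

    if fit.by_habitat:
        levels = [habitat] if habitat is not None else fit.habitat_levels
        frames = []
        for lv in levels:
            if lv not in fit.habitat_levels:
                raise GAMError(f"habitat {lv!r} not in fit ({fit.habitat_levels})")
            term = next(s for s in fit.smooths if s.habitat == lv)
            frames.append(_predict_one(fit, term, years, standard_effort, lv))
        return pd.concat(frames, ignore_index=True)
    return _predict_one(fit, fit.smooths[0], years, standard_effort, None)


def _predict_one(fit, term, years, standard_effort, habitat_level):
    lo, hi = term.year_range
    if np.any(years < lo) or np.any(years > hi):
        raise GAMError(
            f"prediction years outside fitted range [{lo:g}, {hi:g}] "
            f"for {term.label}: extrapolation is not supported"
        )
    p = len(fit.beta)
    X = np.zeros((len(years), p))
    if fit.by_habitat:
        X[:, fit.habitat_levels.index(habitat_level)] = 1.0
    else:
        X[:, 0] = 1.0
    X[:, term.cols] = term.design(years)
    link = X @ fit.beta
    se = np.sqrt(np.maximum(np.sum((X @ fit.cov) * X, axis=1), 0.0))
    eta = link + np.log(standard_effort)
    out = pd.DataFrame(
        {
            "year": years,
            "fit": np.exp(eta),
            "se_link": se,
            "lower": np.exp(eta - se),
            "upper": np.exp(eta + se),
        }
    )
    if habitat_level is not None:
        out.insert(1, "habitat", habitat_level)
    return out
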