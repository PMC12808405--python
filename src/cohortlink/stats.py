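"""Self-contained linear-model kernel used by every analysis stage.

Implements ordinary least squares with treatment-coded categorical terms
and numeric x categorical interactions, nested-model partial F-tests,
per-group (cohort) slope inference from interaction fits, Tukey-style
pairwise contrasts of covariate-adjusted means via the studentized-range
distribution, Benjamini-Hochberg FDR (optionally within groups), DFFITS
influence diagnostics, adjusted sample skewness, and paired t-tests.

The kernel is deliberately thin and fast: the association-network stage
refits tens of thousands of small designs, so everything is dense numpy
with a QR factorization per fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps


class ModelError(ValueError):
    """Invalid model specification or degenerate design."""


# ---------------------------------------------------------------------------
# design construction


@dataclass(frozen=True)
class DesignSpec:
    """Model specification: a response plus ordered model terms.

    ``terms`` is an ordered sequence of ``(name, role)`` with role in
    ``{"numeric", "categorical", "interaction"}``.  Interaction terms are
    written ``"x:factor"`` and require both parts to be previously declared.
    ``levels`` maps each categorical term to its ordered levels, reference
    level first (treatment coding).
    """

    response: str
    terms: tuple
    levels: dict = field(default_factory=dict)

    def __post_init__(self):
        declared = set()
        for name, role in self.terms:
            if role == "interaction":
                num, cat = name.split(":")
                if num not in declared or cat not in declared:
                    raise ModelError(
                        f"interaction {name!r} references undeclared terms"
                    )
            declared.add(name)

    def dropping(self, *names) -> "DesignSpec":
        """A reduced spec without the named terms (and their interactions)."""
        doomed = set(names)
        kept = tuple(
            (n, r)
            for n, r in self.terms
            if n not in doomed and not (r == "interaction" and set(n.split(":")) & doomed)
        )
        return DesignSpec(self.response, kept, dict(self.levels))


def build_design(data: pd.DataFrame, spec: DesignSpec):
    """Build the dense design matrix for ``spec`` from ``data``.

    Returns ``(X, names)`` where ``names[0]`` is the intercept.  Categorical
    terms are treatment-coded against their first listed level; an
    interaction ``x:factor`` contributes one ``x:factor[level]`` column per
    non-reference level.
    """
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for name, role in spec.terms:
        if role == "numeric":
            cols.append(data[name].to_numpy(dtype=float))
            names.append(name)
        elif role == "categorical":
            for lev in _nonref_levels(data, spec, name):
                cols.append((data[name].to_numpy() == lev).astype(float))
                names.append(f"{name}[{lev}]")
        elif role == "interaction":
            num, cat = name.split(":")
            x = data[num].to_numpy(dtype=float)
            for lev in _nonref_levels(data, spec, cat):
                cols.append(x * (data[cat].to_numpy() == lev).astype(float))
                names.append(f"{num}:{cat}[{lev}]")
        else:
            raise ModelError(f"unknown term role {role!r}")
    return np.column_stack(cols), names


def _nonref_levels(data: pd.DataFrame, spec: DesignSpec, factor: str):
    if factor in spec.levels:
        levels = list(spec.levels[factor])
    else:
        levels = sorted(pd.unique(data[factor]))
    present = set(pd.unique(data[factor]))
    return [lev for lev in levels[1:] if lev in present]


# ---------------------------------------------------------------------------
# OLS fit


@dataclass
class FitResult:
    """A least-squares fit with everything downstream inference needs."""

    names: list
    beta: np.ndarray
    residuals: np.ndarray
    rss: float
    df_residual: int
    rank: int
    leverage: np.ndarray
    xtx_inv: np.ndarray  # (X'X)^-1 ; scale by sigma2 for the coef covariance
    rank_deficient: bool = False
    y_ss: float = 0.0  # sum of squared responses, for near-zero RSS detection
    _cov: np.ndarray = None

    @property
    def perfect(self) -> bool:
        """True when the fit is exact up to floating-point rounding."""
        return self.rss <= 1e-24 * max(self.y_ss, 1.0)

    @property
    def n(self) -> int:
        return len(self.residuals)

    @property
    def sigma2(self) -> float:
        return self.rss / self.df_residual if self.df_residual > 0 else np.nan

    @property
    def cov(self) -> np.ndarray:
        if self._cov is None:
            self._cov = self.sigma2 * self.xtx_inv
        return self._cov

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def contrast(self, weights: np.ndarray):
        """Estimate and standard error of ``weights @ beta``."""
        weights = np.asarray(weights, dtype=float)
        est = float(weights @ self.beta)
        se = float(np.sqrt(max(weights @ self.cov @ weights, 0.0)))
        return est, se


def fit_ols(X: np.ndarray, y: np.ndarray, names=None) -> FitResult:
    """Least-squares fit via QR; flags (rather than fails on) rank deficiency."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    deficient = rank < p
    if deficient:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        # leverage from an orthonormal basis of the column space
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        keep = s > (s.max() * max(n, p) * np.finfo(float).eps if s.size else 0)
        lev = np.sum(U[:, keep] ** 2, axis=1)
        xtx_inv = np.linalg.pinv(X.T @ X)
    else:
        qty = Q.T @ y
        beta = np.linalg.solve(R, qty)
        fitted = Q @ qty
        lev = np.sum(Q**2, axis=1)
        r_inv = np.linalg.solve(R, np.eye(p))
        xtx_inv = r_inv @ r_inv.T
    resid = y - fitted
    rss = float(resid @ resid)
    return FitResult(
        names=list(names),
        beta=beta,
        residuals=resid,
        rss=rss,
        df_residual=n - rank,
        rank=int(rank),
        leverage=lev,
        xtx_inv=xtx_inv,
        rank_deficient=deficient,
        y_ss=float(y @ y),
    )


def fit_linear_model(y, spec: DesignSpec, data: pd.DataFrame) -> FitResult:
    """Fit ``y ~ spec`` over the rows of ``data`` (listwise-complete)."""
    X, names = build_design(data, spec)
    y = np.asarray(y, dtype=float)
    if len(y) != X.shape[0]:
        raise ModelError("response length does not match data")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ModelError("missing values in design or response; drop them first")
    if len(y) <= X.shape[1]:
        raise ModelError(f"n={len(y)} too small for {X.shape[1]} design columns")
    return fit_ols(X, y, names)


# ---------------------------------------------------------------------------
# nested model comparison


@dataclass(frozen=True)
class NestedComparison:
    F: float
    df_num: int
    df_den: int
    p: float
    rss_full: float
    rss_reduced: float
    degenerate: bool = False


def partial_f_test(full: FitResult, reduced: FitResult) -> NestedComparison:
    """Partial F-test of a full model against a nested reduced model.

    ``F = ((RSS_r - RSS_f) / (df_r - df_f)) / (RSS_f / df_f)``.
    """
    df_num = reduced.df_residual - full.df_residual
    if df_num <= 0:
        raise ModelError("reduced model must have strictly more residual df")
    if full.n != reduced.n:
        raise ModelError("models fitted on different numbers of samples")
    df_den = full.df_residual
    delta = max(reduced.rss - full.rss, 0.0)
    if df_den == 0 or full.perfect:
        # saturated or exact full model: infinitely strong evidence unless
        # the reduced model is (numerically) exact too
        if delta <= 1e-24 * max(reduced.y_ss, 1.0):
            return NestedComparison(0.0, df_num, df_den, 1.0, full.rss, reduced.rss, True)
        return NestedComparison(np.inf, df_num, df_den, 0.0, full.rss, reduced.rss, True)
    F = (delta / df_num) / (full.rss / df_den)
    p = float(special.fdtrc(df_num, df_den, F))
    return NestedComparison(float(F), df_num, df_den, p, full.rss, reduced.rss)


# ---------------------------------------------------------------------------
# per-cohort slopes from an interaction model


@dataclass(frozen=True)
class SlopeEstimate:
    level: str
    slope: float
    se: float
    p: float


def cohort_slopes(full: FitResult, predictor: str, cohort_term: str, levels) -> list:
    """Slopes of ``predictor`` within each level of ``cohort_term``.

    The model must contain the predictor main effect and the
    ``predictor:cohort_term`` interaction (treatment coding, first level is
    the reference).  The reference slope is the main-effect coefficient;
    each other level adds its interaction coefficient.  Standard errors come
    from the corresponding linear combination of the coefficient covariance,
    p-values from a two-sided t with the model's residual df.
    """
    if predictor not in full.names:
        raise ModelError(f"model has no main effect for {predictor!r}")
    main_idx = full.names.index(predictor)
    out = []
    for k, lev in enumerate(levels):
        w = np.zeros(len(full.names))
        w[main_idx] = 1.0
        if k > 0:
            name = f"{predictor}:{cohort_term}[{lev}]"
            if name not in full.names:
                raise ModelError(f"model has no interaction column {name!r}")
            w[full.names.index(name)] = 1.0
        est, se = full.contrast(w)
        if se > 0:
            p = float(2.0 * special.stdtr(full.df_residual, -abs(est) / se))
        else:
            p = 1.0 if est == 0.0 else 0.0
        out.append(SlopeEstimate(level=lev, slope=est, se=se, p=p))
    return out


# ---------------------------------------------------------------------------
# multiplicity


def bh_adjust(p, group=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, within optional groups."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ModelError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if group is None:
        group = np.zeros(p.shape, dtype=int)
    group = np.asarray(group)
    for g in pd.unique(group):
        mask = group == g
        out[mask] = _bh_one(p[mask])
    return out


def _bh_one(p: np.ndarray) -> np.ndarray:
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# influence and shape diagnostics


def dffits(fit: FitResult) -> np.ndarray:
    """DFFITS for each observation: ``t_i * sqrt(h_i / (1 - h_i))``.

    ``t_i`` is the externally studentized residual.  Equals the change in
    the i-th fitted value under leave-one-out refitting, scaled by
    ``s_(i) * sqrt(h_i)``.  A perfect fit (RSS = 0) yields all zeros by
    convention; observations with leverage 1 yield NaN.
    """
    if fit.df_residual < 2:
        raise ModelError("DFFITS needs residual df >= 2")
    if fit.perfect:
        return np.zeros(fit.n)
    h = np.clip(fit.leverage, 0.0, 1.0)
    e = fit.residuals
    out = np.full(fit.n, np.nan)
    ok = h < 1.0 - 1e-12
    s2_loo = (fit.rss - e[ok] ** 2 / (1.0 - h[ok])) / (fit.df_residual - 1)
    s2_loo = np.clip(s2_loo, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ext = e[ok] / np.sqrt(s2_loo * (1.0 - h[ok]))
        out[ok] = t_ext * np.sqrt(h[ok] / (1.0 - h[ok]))
    # 0/0 from an exactly-zero residual with zero LOO variance: no influence
    out[np.isnan(out) & ok] = 0.0
    return out


def sample_skewness(x) -> float:
    """Adjusted Fisher-Pearson skewness ``g1 * sqrt(n(n-1)) / (n-2)``.

    Zero-variance input returns 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ModelError("skewness needs at least 3 values")
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    if s2 <= 0.0:
        return 0.0
    g1 = np.mean((x - m) ** 3) / s2**1.5
    return float(g1 * np.sqrt(n * (n - 1)) / (n - 2))


# ---------------------------------------------------------------------------
# pairwise contrasts and paired tests


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple
    estimate: float
    se: float
    p_unadjusted: float
    adjusted_p: float


def tukey_pairwise(fit: FitResult, factor: str, levels) -> list:
    """All pairwise differences of covariate-adjusted level means.

    With treatment coding the adjusted-mean difference between two levels is
    the difference of their level coefficients (covariates cancel).  The
    family-wise adjusted p uses the studentized-range distribution with the
    number of levels and the model's residual df.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ModelError("factor needs at least 2 levels")
    k = len(levels)
    idx = {}
    for lev in levels[1:]:
        name = f"{factor}[{lev}]"
        if name not in fit.names:
            raise ModelError(f"model has no column {name!r}")
        idx[lev] = fit.names.index(name)
    out = []
    for a in range(k):
        for b in range(a + 1, k):
            w = np.zeros(len(fit.names))
            if levels[a] in idx:
                w[idx[levels[a]]] = 1.0
            if levels[b] in idx:
                w[idx[levels[b]]] -= 1.0
            est, se = fit.contrast(w)
            if se > 0:
                t = abs(est) / se
                p_un = float(2.0 * sps.t.sf(t, fit.df_residual))
                p_adj = float(
                    np.clip(
                        sps.studentized_range.sf(t * np.sqrt(2.0), k, fit.df_residual),
                        0.0,
                        1.0,
                    )
                )
            else:
                p_un = 1.0 if est == 0.0 else 0.0
                p_adj = p_un
            out.append(
                ContrastResult(
                    pair=(levels[a], levels[b]),
                    estimate=est,
                    se=se,
                    p_unadjusted=p_un,
                    adjusted_p=max(p_adj, p_un),
                )
            )
    return out


def paired_t_test(a, b):
    """Two-sided paired t-test on ``a - b``; returns ``(t, p)``.

    All-zero differences give ``(0, 1)``; zero-variance nonzero differences
    give ``(inf-signed t, 0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ModelError("paired t-test needs two equal-length vectors, n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    p = float(2.0 * sps.t.sf(abs(t), d.size - 1))
    return float(t), p
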