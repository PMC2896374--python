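"""Phylogenetic generalized least squares with Pagel's lambda.

The model: for n species with response vector y and design matrix X,

    y = X beta + e,     e ~ N(0, sigma^2 * V(lambda)),

where V(lambda) multiplies the off-diagonal entries of the Brownian-motion
tree covariance by lambda and leaves the diagonal untouched.  lambda = 1 is
pure Brownian motion, lambda = 0 phylogenetic independence (a star tree).
lambda is estimated by maximizing the profile log-likelihood; beta, its
standard errors, t statistics and the coefficient of determination are then
evaluated at the maximum.

All solves go through Cholesky/QR factorizations (never an explicit matrix
inverse).  The maximum-likelihood sigma^2 uses the divisor n; standard errors
use the unbiased divisor n - k.  Degrees of freedom for t tests default to
the number of taxa (the convention of the analysis this package reproduces),
with the textbook n - k available; both one- and two-sided p-values are
always computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .trees import CovMatrix

__all__ = [
    "DesignMatrix",
    "PglsFit",
    "PglsOptions",
    "lambda_transform",
    "lambda_max",
    "gls_fit",
    "profile_loglik",
    "fit_pgls",
    "coefficient_tests",
    "r_squared",
]

logger = logging.getLogger("edphylo")


class DesignMatrix(NamedTuple):
    """Ordered species labels, model matrix (intercept first), column names."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    names: tuple[str, ...]

    @classmethod
    def build(
        cls,
        labels: Sequence[str],
        columns: dict[str, np.ndarray],
        add_intercept: bool = True,
    ) -> "DesignMatrix":
        names = list(columns)
        cols = [np.asarray(columns[c], dtype=float) for c in names]
        if add_intercept:
            names = ["intercept"] + names
            cols = [np.ones(len(labels))] + cols
        X = np.column_stack(cols)
        dm = cls(tuple(labels), X, tuple(names))
        dm.validate()
        return dm

    def validate(self) -> None:
        X = self.matrix
        if X.shape[0] != len(self.labels) or X.shape[1] != len(self.names):
            raise ValueError("design matrix dimensions do not match labels/names")
        if self.names and self.names[0] == "intercept":
            if not np.all(X[:, 0] == 1.0):
                raise ValueError("intercept column must be all ones")
            for j, name in enumerate(self.names[1:], start=1):
                if np.ptp(X[:, j]) == 0:
                    logger.warning(
                        "design column %r is constant; it is collinear "
                        "with the intercept",
                        name,
                    )


@dataclass(frozen=True)
class PglsFit:
    """Result of a lambda-ML phylogenetic regression."""

    lambda_hat: float
    lambda_indeterminate: bool
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_one_sided: np.ndarray
    p_two_sided: np.ndarray
    sigma2_hat: float
    log_likelihood: float
    r_squared: float
    df_used: int
    n_taxa: int
    names: tuple[str, ...]
    df_convention: str
    tail: str

    def __post_init__(self) -> None:
        if not np.allclose(self.t_stat * self.se, self.beta, equal_nan=True):
            raise ValueError("t statistics inconsistent with beta / se")


@dataclass(frozen=True)
class PglsOptions:
    """Fitting options.

    lambda_mode
        ``"estimate"`` (profile ML over [0, lambda_upper]) or ``"fixed"``.
    lambda_value
        The value used when ``lambda_mode == "fixed"``.
    lambda_upper
        Upper search bound; 1.0 by default, or ``"max"`` for the algebraic
        bound keeping V(lambda) positive definite.
    df_convention
        ``"n_taxa"`` (df = n, the reproduced analysis' stated convention) or
        ``"n_minus_k"``.
    tail
        Which p-value drives the significance markers: ``"one"`` or ``"two"``.
    """

    lambda_mode: Literal["estimate", "fixed"] = "estimate"
    lambda_value: float = 1.0
    lambda_upper: float | Literal["max"] = 1.0
    df_convention: Literal["n_taxa", "n_minus_k"] = "n_taxa"
    tail: Literal["one", "two"] = "one"
    n_starts: int = 5
    xatol: float = 1e-8


# ---------------------------------------------------------------------------
# The lambda transform
# ---------------------------------------------------------------------------


def lambda_max(V: CovMatrix | np.ndarray) -> float:
    """Largest lambda keeping the transformed matrix positive definite.

    V(lambda) = D + lambda (V - D) with D = diag(V); the bound is
    -1 / min_eig(D^{-1/2} (V - D) D^{-1/2}).
    """
    A = V.values if isinstance(V, CovMatrix) else np.asarray(V, float)
    d = np.diag(A)
    if np.any(d <= 0):
        raise ValueError("covariance diagonal must be positive")
    s = 1.0 / np.sqrt(d)
    M = (A - np.diag(d)) * np.outer(s, s)
    mu = np.linalg.eigvalsh(M)[0]
    if mu >= 0:
        return np.inf
    return -1.0 / mu


def lambda_transform(V: CovMatrix, lam: float) -> CovMatrix:
    """Multiply off-diagonal covariances by lambda, keeping the diagonal."""
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if lam > 1.0 and lam > lambda_max(V):
        raise ValueError(
            f"lambda = {lam} exceeds the positive-definite bound "
            f"{lambda_max(V):.6g}"
        )
    C = lam * V.values
    np.fill_diagonal(C, np.diag(V.values))
    return CovMatrix(V.labels, C)


# ---------------------------------------------------------------------------
# GLS core
# ---------------------------------------------------------------------------


class _GlsInternals(NamedTuple):
    beta: np.ndarray
    sigma2_ml: float
    log_likelihood: float
    rss_w: float
    R: np.ndarray  # upper-triangular factor of the whitened design
    y_w: np.ndarray
    one_w: np.ndarray  # whitened intercept column (for r^2)


def _check_rank(Xw: np.ndarray, names: Sequence[str] | None) -> np.ndarray:
    Q, R = np.linalg.qr(Xw)
    diag = np.abs(np.diag(R))
    tol = Xw.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.nonzero(diag <= tol)[0]
    if bad.size:
        j = int(bad[0])
        col = names[j] if names else f"column {j}"
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient at {col!r}"
        )
    return R


def _gls_core(
    y: np.ndarray, X: np.ndarray, V: np.ndarray, names: Sequence[str] | None
) -> _GlsInternals:
    n = y.shape[0]
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance matrix is not positive definite: {exc}"
        ) from None
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    y_w = linalg.solve_triangular(L, y, lower=True)
    X_w = linalg.solve_triangular(L, X, lower=True)
    one_w = linalg.solve_triangular(L, np.ones(n), lower=True)
    R = _check_rank(X_w, names)
    beta, *_ = np.linalg.lstsq(X_w, y_w, rcond=None)
    resid = y_w - X_w @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0:
        # perfect fit: the Gaussian likelihood degenerates
        ll = np.inf
    else:
        ll = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet - 0.5 * n
    return _GlsInternals(beta, sigma2, ll, rss, R, y_w, one_w)


def _as_xy(
    y: Sequence[float] | np.ndarray,
    X: DesignMatrix | np.ndarray,
    V: CovMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...] | None]:
    yv = np.asarray(y, dtype=float)
    if isinstance(X, DesignMatrix):
        Xv, names = X.matrix, X.names
        if isinstance(V, CovMatrix) and X.labels != V.labels:
            V = V.submatrix(X.labels)  # reconcile by name, never position
    else:
        Xv, names = np.asarray(X, dtype=float), None
    Vv = V.values if isinstance(V, CovMatrix) else np.asarray(V, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    if not (yv.shape[0] == Xv.shape[0] == Vv.shape[0]):
        raise ValueError("y, X and V dimensions do not agree")
    return yv, Xv, Vv, names


def gls_fit(
    y: Sequence[float] | np.ndarray,
    X: DesignMatrix | np.ndarray,
    V: CovMatrix | np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Generalized least squares under covariance V.

    Returns ``(beta, sigma2_ml, log_likelihood)`` where
    beta = (X' V^-1 X)^-1 X' V^-1 y (computed by whitening + QR),
    sigma2_ml = RSS_w / n, and the log-likelihood is the profile Gaussian
    log-likelihood at those values.
    """
    yv, Xv, Vv, names = _as_xy(y, X, V)
    g = _gls_core(yv, Xv, Vv, names)
    return g.beta, g.sigma2_ml, g.log_likelihood


def profile_loglik(
    lam: float,
    y: Sequence[float] | np.ndarray,
    X: DesignMatrix | np.ndarray,
    V: CovMatrix,
) -> float:
    """Log-likelihood of the GLS fit at the lambda-transformed covariance."""
    return gls_fit(y, X, lambda_transform(V, lam))[2]


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------


def _optimize_lambda(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
    names: tuple[str, ...] | None,
    upper: float,
    n_starts: int,
    xatol: float,
) -> float:
    def nll(lam: float) -> float:
        C = lam * V
        np.fill_diagonal(C, np.diag(V))
        return -_gls_core(y, X, C, names).log_likelihood

    candidates: list[tuple[float, float]] = []
    for lam in (0.0, upper):
        candidates.append((nll(lam), lam))
    edges = np.linspace(0.0, upper, n_starts + 1)
    for lo, hi in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
        )
        if not res.success:  # pragma: no cover - bounded Brent rarely fails
            continue
        candidates.append((float(res.fun), float(res.x)))
    if not any(np.isfinite(f) for f, _ in candidates):
        trace = ", ".join(f"({l:.3f}: {f:.3f})" for f, l in candidates)
        raise RuntimeError(
            f"lambda optimization failed to converge; profile trace: {trace}"
        )
    best = min(candidates)
    logger.info(
        "lambda profile: ll(0)=%.6f ll(%g)=%.6f -> lambda_hat=%.8f",
        -candidates[0][0],
        upper,
        -candidates[1][0],
        best[1],
    )
    return best[1]


def fit_pgls(
    y: Sequence[float] | np.ndarray,
    X: DesignMatrix | np.ndarray,
    V: CovMatrix,
    options: PglsOptions | None = None,
) -> PglsFit:
    """Maximum-likelihood lambda PGLS fit.

    lambda is profiled over [0, lambda_upper] with bounded scalar
    minimization from ``n_starts`` equally spaced brackets (plus both
    endpoints); beta, standard errors, t and p statistics and r^2 are then
    evaluated at the maximizing lambda.  On a star tree (all off-diagonal
    covariances zero) lambda is unidentifiable: the fit equals OLS and
    ``lambda_hat`` is NaN with ``lambda_indeterminate`` set.
    """
    opts = options or PglsOptions()
    yv, Xv, Vv, names = _as_xy(y, X, V)
    n, k = Xv.shape
    if n <= k:
        raise ValueError(f"need more taxa ({n}) than coefficients ({k})")

    diag = np.diag(Vv)
    off = Vv - np.diag(diag)
    star = np.max(np.abs(off)) <= 1e-12 * max(np.max(diag), 1.0)

    upper = (
        lambda_max(Vv) * (1 - 1e-9)
        if opts.lambda_upper == "max"
        else float(opts.lambda_upper)
    )
    if star:
        lam_hat, indet = 1.0, True
    elif opts.lambda_mode == "fixed":
        lam_hat, indet = float(opts.lambda_value), False
        if not 0.0 <= lam_hat <= max(upper, 1.0):
            raise ValueError(f"fixed lambda {lam_hat} outside [0, {upper}]")
    else:
        lam_hat = _optimize_lambda(
            yv, Xv, Vv, names, upper, opts.n_starts, opts.xatol
        )
        indet = False

    C = lam_hat * Vv
    np.fill_diagonal(C, diag)
    g = _gls_core(yv, Xv, C, names)

    sigma2_unbiased = g.rss_w / (n - k)
    Rinv = linalg.solve_triangular(g.R, np.eye(k), lower=False)
    cov_beta = sigma2_unbiased * (Rinv @ Rinv.T)
    se = np.sqrt(np.diag(cov_beta))
    if np.any(se == 0):
        raise ZeroDivisionError("degenerate model: zero standard error")
    t = g.beta / se
    df = n if opts.df_convention == "n_taxa" else n - k
    p_two = 2.0 * stats.t.sf(np.abs(t), df)
    p_one = stats.t.sf(np.abs(t), df)

    # r^2 in the whitened space, TSS around the GLS intercept-only fit
    r2 = _r_squared_core(g, n)

    return PglsFit(
        lambda_hat=float("nan") if indet else float(lam_hat),
        lambda_indeterminate=indet,
        beta=g.beta,
        se=se,
        t_stat=t,
        p_one_sided=p_one,
        p_two_sided=p_two,
        sigma2_hat=g.sigma2_ml,
        log_likelihood=g.log_likelihood,
        r_squared=r2,
        df_used=df,
        n_taxa=n,
        names=names or tuple(f"x{j}" for j in range(k)),
        df_convention=opts.df_convention,
        tail=opts.tail,
    )


def _r_squared_core(g: _GlsInternals, n: int) -> float:
    denom = float(g.one_w @ g.one_w)
    mu = float(g.one_w @ g.y_w) / denom  # GLS intercept-only estimate
    tss = float(np.sum((g.y_w - mu * g.one_w) ** 2))
    if tss <= 0:
        raise ZeroDivisionError("degenerate response: zero total sum of squares")
    return max(0.0, min(1.0, 1.0 - g.rss_w / tss))


def r_squared(
    fit: PglsFit,
    y: Sequence[float] | np.ndarray,
    X: DesignMatrix | np.ndarray,
    V_transformed: CovMatrix | np.ndarray,
) -> float:
    """Coefficient of determination in the whitened space.

    Response and design are premultiplied by the inverse Cholesky factor of
    the (already lambda-transformed) covariance; the total sum of squares is
    taken around the GLS intercept-only fit, so models with an intercept give
    a value in [0, 1].
    """
    yv, Xv, Vv, names = _as_xy(y, X, V_transformed)
    g = _gls_core(yv, Xv, Vv, names)
    return _r_squared_core(g, yv.shape[0])


def coefficient_tests(
    fit: PglsFit,
    df_convention: Literal["n_taxa", "n_minus_k"] | None = None,
    tail: Literal["one", "two"] | None = None,
) -> list[tuple[str, float, float, str]]:
    """Per-coefficient (name, t, p, marker) rows.

    t = coefficient / standard error; p comes from a Student-t distribution
    with df per the chosen convention.  Markers: ``**`` for p < 0.01, ``*``
    for p < 0.05, empty otherwise.
    """
    conv = df_convention or fit.df_convention
    tl = tail or fit.tail
    df = fit.n_taxa if conv == "n_taxa" else fit.n_taxa - len(fit.beta)
    rows = []
    for name, b, s in zip(fit.names, fit.beta, fit.se):
        if s == 0:
            raise ZeroDivisionError(f"zero standard error for {name!r}")
        t = b / s
        p_abs = stats.t.sf(abs(t), df)
        p = p_abs if tl == "one" else 2.0 * p_abs
        marker = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows.append((name, float(t), float(p), marker))
    return rows


def standardized_coefficients(
    fit: PglsFit, y: np.ndarray, X: DesignMatrix
) -> np.ndarray:
    """Fully z-scored coefficients: beta_j * sd(x_j) / sd(y).

    Optional alternative to the raw partial regression coefficients that the
    main fit reports (the intercept entry is NaN).
    """
    sy = float(np.std(np.asarray(y, float), ddof=1))
    out = np.full(len(fit.beta), np.nan)
    for j, name in enumerate(fit.names):
        if name == "intercept":
            continue
        sx = float(np.std(X.matrix[:, j], ddof=1))
        out[j] = fit.beta[j] * sx / sy
    return out
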