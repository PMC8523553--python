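"""REML estimation of repeated-measures linear models.

The models fitted here are marginal (generalized least squares) models:
subjects are independent, and the observations of one subject are
jointly Gaussian with a structured covariance over the repeated cells —
fully unstructured over the four condition cells for similarity indices,
or a Kronecker product ``unstructured(conditions) (x)
compound-symmetry-correlation(blocks)`` for block-level behavior.

Covariance parameters are estimated by restricted maximum likelihood on
an unconstrained parameterization (log-Cholesky for the unstructured
factor, a z-transform for the compound-symmetry correlation), maximized
by Fisher scoring with step halving, with analytic score and expected
information.  Fixed-effect F tests use Satterthwaite denominator degrees
of freedom:

    nu = 2 (c' Phi c)^2 / (g' A g)

where ``Phi`` is the fixed-effect covariance, ``g`` the gradient of
``c' Phi c`` in the covariance parameters (analytic), and ``A`` the
inverse expected REML information.  Multi-df effects combine the
per-eigencontrast ``nu`` values by the usual harmonic rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats as sps

from .exceptions import ConfigError, MvcsError

logger = logging.getLogger(__name__)

__all__ = [
    "Unstructured",
    "KroneckerCS",
    "RemlFit",
    "reml_fit",
    "satterthwaite_df",
    "satterthwaite_nu",
    "wald_f_test",
]


# ---------------------------------------------------------------------------
# covariance structures


class Unstructured:
    """Fully parameterized SPD matrix via a log-Cholesky parameterization.

    theta holds the lower-triangular Cholesky factor in row-major
    ``tril_indices`` order, with the diagonal stored on the log scale, so
    every theta describes a valid covariance matrix.
    """

    def __init__(self, dim: int):
        if dim < 1:
            raise ConfigError("covariance dimension must be >= 1")
        self.dim = dim
        self._rows, self._cols = np.tril_indices(dim)
        self.n_params = self._rows.size

    def _chol(self, theta: np.ndarray) -> np.ndarray:
        L = np.zeros((self.dim, self.dim))
        L[self._rows, self._cols] = theta
        d = np.arange(self.dim)
        L[d, d] = np.exp(np.clip(np.diag(L), -200, 200))
        return L

    def build(self, theta: np.ndarray) -> np.ndarray:
        L = self._chol(theta)
        return L @ L.T

    def derivs(self, theta: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        L = self._chol(theta)
        V = L @ L.T
        dVs = []
        for k in range(self.n_params):
            i, j = self._rows[k], self._cols[k]
            dL = np.zeros_like(L)
            dL[i, j] = L[i, j] if i == j else 1.0
            dVs.append(dL @ L.T + L @ dL.T)
        return V, dVs

    def initial(self, S: np.ndarray) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        w, Q = np.linalg.eigh((S + S.T) / 2.0)
        floor = max(1e-6 * max(np.mean(np.diag(S)), 1e-12), 1e-12)
        w = np.clip(w, floor, None)
        L = np.linalg.cholesky(Q @ np.diag(w) @ Q.T)
        theta = L[self._rows, self._cols].copy()
        diag_pos = self._rows == self._cols
        theta[diag_pos] = np.log(L[np.arange(self.dim), np.arange(self.dim)])
        return theta


class KroneckerCS:
    """``unstructured(u_dim) (x) compound-symmetry-correlation(b_dim)``.

    The compound-symmetry block has a unit diagonal (a correlation
    matrix), so all scale lives in the unstructured factor and the
    product is identified.  The correlation is parameterized as
    ``r = tanh(z)``; positive definiteness (``r > -1/(b-1)``) is enforced
    through the likelihood.
    """

    def __init__(self, u_dim: int, b_dim: int):
        if b_dim < 2:
            raise ConfigError(
                "KroneckerCS needs >= 2 blocks; use Unstructured otherwise"
            )
        self.u = Unstructured(u_dim)
        self.u_dim = u_dim
        self.b_dim = b_dim
        self.n_params = self.u.n_params + 1
        self.dim = u_dim * b_dim

    def _r(self, z: float) -> float:
        return float(np.tanh(z))

    def corr(self, theta: np.ndarray) -> float:
        return self._r(theta[-1])

    def is_valid(self, theta: np.ndarray) -> bool:
        return self._r(theta[-1]) > -1.0 / (self.b_dim - 1) + 1e-10

    def build(self, theta: np.ndarray) -> np.ndarray:
        U = self.u.build(theta[:-1])
        r = self._r(theta[-1])
        R = np.full((self.b_dim, self.b_dim), r)
        np.fill_diagonal(R, 1.0)
        return np.kron(U, R)

    def derivs(self, theta: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        U, dUs = self.u.derivs(theta[:-1])
        r = self._r(theta[-1])
        R = np.full((self.b_dim, self.b_dim), r)
        np.fill_diagonal(R, 1.0)
        V = np.kron(U, R)
        dVs = [np.kron(dU, R) for dU in dUs]
        dR = (1.0 - r**2) * (np.ones((self.b_dim, self.b_dim))
                             - np.eye(self.b_dim))
        dVs.append(np.kron(U, dR))
        return V, dVs

    def initial(self, U0: np.ndarray, r0: float = 0.1) -> np.ndarray:
        lo = -1.0 / (self.b_dim - 1)
        r0 = float(np.clip(r0, lo + 0.02, 0.95))
        return np.concatenate([self.u.initial(U0), [np.arctanh(r0)]])


# ---------------------------------------------------------------------------
# REML core


@dataclass
class _Group:
    """Subjects sharing an observed-cell pattern (same unit indices)."""

    units: np.ndarray  # (n,) indices into the full covariance dimension
    X: np.ndarray  # (s, n, p)
    y: np.ndarray  # (s, n)
    subjects: list


@dataclass
class RemlFit:
    """Converged REML fit with the pieces Satterthwaite tests need."""

    theta: np.ndarray
    beta: np.ndarray
    phi: np.ndarray  # fixed-effect covariance (X' V^-1 X)^-1
    V: np.ndarray  # fitted full covariance matrix
    loglik: float
    converged: bool
    n_iter: int
    message: str
    history: list[float] = field(default_factory=list)
    H: list[np.ndarray] = field(default_factory=list)  # d(X'WX)/dtheta_k
    info: np.ndarray | None = None  # expected REML information
    A: np.ndarray | None = None  # inverse information
    n_obs: int = 0
    n_subjects: int = 0
    column_names: list[str] = field(default_factory=list)
    degenerate: bool = False
    #: the fitted covariance is (numerically) singular — small-sample
    #: REML optima can sit on the boundary of the parameter space
    boundary: bool = False


def _make_groups(
    y: np.ndarray, X: np.ndarray, subject_ids: np.ndarray, unit_idx: np.ndarray
) -> list[_Group]:
    groups: dict[tuple, list] = {}
    for sid in np.unique(subject_ids):
        rows = np.flatnonzero(subject_ids == sid)
        order = rows[np.argsort(unit_idx[rows], kind="stable")]
        units = unit_idx[order]
        if np.unique(units).size != units.size:
            raise ConfigError(
                f"subject {sid!r} has duplicated repeated-measure cells"
            )
        groups.setdefault(tuple(units.tolist()), []).append(
            (sid, X[order], y[order])
        )
    out = []
    for units, members in groups.items():
        out.append(
            _Group(
                units=np.asarray(units, dtype=int),
                X=np.stack([m[1] for m in members]),
                y=np.stack([m[2] for m in members]),
                subjects=[m[0] for m in members],
            )
        )
    return out


def _loglik_only(groups, V, p_fixed):
    """REML log-likelihood (constants dropped); None if V not usable."""
    XtWX = np.zeros((p_fixed, p_fixed))
    XtWy = np.zeros(p_fixed)
    yWy = 0.0
    logdet = 0.0
    cache = []
    for g in groups:
        S = V[np.ix_(g.units, g.units)]
        try:
            cf = scipy.linalg.cho_factor(S, lower=True)
        except scipy.linalg.LinAlgError:
            return None, None
        s_count = g.X.shape[0]
        logdet += s_count * 2.0 * np.sum(np.log(np.diag(cf[0])))
        M = scipy.linalg.cho_solve(cf, np.eye(S.shape[0]))
        B = np.einsum("nm,smp->snp", M, g.X)
        XtWX += np.einsum("snp,snq->pq", g.X, B)
        XtWy += np.einsum("snp,sn->p", B, g.y)
        yWy += float(np.einsum("sn,nm,sm->", g.y, M, g.y))
        cache.append((M, B))
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return None, None
    beta = np.linalg.solve(XtWX, XtWy)
    ypy = yWy - float(XtWy @ beta)
    ll = -0.5 * (logdet + logdet_xwx + ypy)
    return ll, (XtWX, XtWy, beta, cache)


def _score_info(groups, V, dVs, state):
    """Analytic REML score and expected information at the current theta."""
    XtWX, XtWy, beta, cache = state
    p_theta = len(dVs)
    phi = np.linalg.inv(XtWX)
    T1 = np.zeros(p_theta)
    T3 = np.zeros(p_theta)
    H = [np.zeros_like(XtWX) for _ in range(p_theta)]
    I1 = np.zeros((p_theta, p_theta))
    G_tr = np.zeros((p_theta, p_theta))  # tr(Phi G_jk)
    for g, (M, B) in zip(groups, cache):
        s_count = g.X.shape[0]
        ix = np.ix_(g.units, g.units)
        D = [dv[ix] for dv in dVs]
        MD = [M @ d for d in D]
        resid = g.y - np.einsum("snp,p->sn", g.X, beta)
        m = np.einsum("nm,sm->sn", M, resid)
        Cs = [np.einsum("nm,smp->snp", d, B) for d in D]
        MCs = [np.einsum("nm,smp->snp", M, c) for c in Cs]
        for k in range(p_theta):
            T1[k] += s_count * np.trace(MD[k])
            T3[k] += float(np.einsum("sn,nm,sm->", m, D[k], m))
            H[k] += np.einsum("snp,snq->pq", g.X, MCs[k])
        for j in range(p_theta):
            for k in range(j, p_theta):
                I1[j, k] += s_count * float(np.sum(MD[j] * MD[k].T))
                Gjk = np.einsum("snp,snq->pq", Cs[j], MCs[k])
                G_tr[j, k] += float(np.sum(phi * Gjk))
    score = np.empty(p_theta)
    T2 = np.array([float(np.sum(phi * Hk)) for Hk in H])
    score[:] = -0.5 * (T1 - T2 - T3)
    info = np.zeros((p_theta, p_theta))
    PH = [phi @ Hk for Hk in H]
    for j in range(p_theta):
        for k in range(j, p_theta):
            val = 0.5 * (
                I1[j, k] - 2.0 * G_tr[j, k] + float(np.sum(PH[j] * PH[k].T))
            )
            info[j, k] = info[k, j] = val
    return score, info, phi, H


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    subject_ids: np.ndarray,
    unit_idx: np.ndarray,
    cov,
    theta0: np.ndarray | None = None,
    *,
    column_names: list[str] | None = None,
    max_iter: int = 200,
    grad_tol: float = 1e-9,
) -> RemlFit:
    """Fit a repeated-measures GLS model by REML Fisher scoring.

    Parameters
    ----------
    y, X:
        Stacked response and full-rank fixed-effects design.
    subject_ids:
        Grouping labels; observations of different subjects are
        independent.
    unit_idx:
        For each row, the index of its repeated-measure cell in the
        covariance structure's dimension.
    cov:
        An :class:`Unstructured` or :class:`KroneckerCS` instance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    unit_idx = np.asarray(unit_idx, dtype=int)
    subject_ids = np.asarray(subject_ids)
    n_obs, p_fixed = X.shape
    if np.linalg.matrix_rank(X) < p_fixed:
        raise ConfigError("fixed-effects design matrix is rank deficient")
    groups = _make_groups(y, X, subject_ids, unit_idx)
    n_subjects = sum(g.X.shape[0] for g in groups)

    if np.ptp(y) == 0:
        # constant response: every effect is exactly zero, covariance is
        # degenerate; report a flagged zero fit instead of failing
        beta = np.zeros(p_fixed)
        beta[np.argmax(np.abs(X).sum(axis=0) == n_obs)] = y[0] if n_obs else 0
        return RemlFit(
            theta=np.zeros(cov.n_params), beta=beta,
            phi=np.zeros((p_fixed, p_fixed)), V=np.zeros((cov.dim, cov.dim)),
            loglik=np.nan, converged=True, n_iter=0,
            message="degenerate fit: constant response", degenerate=True,
            H=[np.zeros((p_fixed, p_fixed)) for _ in range(cov.n_params)],
            info=np.eye(cov.n_params), A=np.eye(cov.n_params),
            n_obs=n_obs, n_subjects=n_subjects,
            column_names=column_names or [],
        )

    theta = np.asarray(
        theta0 if theta0 is not None else _default_theta0(groups, X, y, cov),
        dtype=float,
    )

    def valid(th):
        return cov.is_valid(th) if hasattr(cov, "is_valid") else True

    V = cov.build(theta)
    ll, state = _loglik_only(groups, V, p_fixed)
    if ll is None:
        raise MvcsError("initial covariance is not positive definite")
    history = [ll]
    converged = False
    message = "maximum iterations reached"
    it = 0
    for it in range(1, max_iter + 1):
        V, dVs = cov.derivs(theta)
        score, info, phi, H = _score_info(groups, V, dVs, state)
        if np.max(np.abs(score)) < grad_tol * (1.0 + abs(ll)):
            converged = True
            message = "gradient converged"
            break
        try:
            step = np.linalg.solve(
                info + 1e-10 * np.eye(len(score)), score
            )
        except np.linalg.LinAlgError:
            step = score
        lam = 1.0
        improved = False
        for _ in range(40):
            cand = theta + lam * step
            if valid(cand):
                V_c = cov.build(cand)
                ll_c, state_c = _loglik_only(groups, V_c, p_fixed)
                if ll_c is not None and ll_c > ll + 1e-14 * (1.0 + abs(ll)):
                    theta, ll, state = cand, ll_c, state_c
                    improved = True
                    break
            lam /= 2.0
        history.append(ll)
        if not improved:
            # no step improves the criterion beyond machine precision:
            # the optimum is attained (possibly on the boundary of the
            # parameter space, where the gradient need not vanish)
            converged = True
            message = (
                "converged (no improving step; possibly a boundary optimum)"
                if np.max(np.abs(score)) >= 1e-6 * (1.0 + abs(ll))
                else "converged (no further improvement)"
            )
            break
        if len(history) > 2 and abs(history[-1] - history[-2]) < 1e-13 * (
            1.0 + abs(ll)
        ) and np.max(np.abs(score)) < 1e-6 * (1.0 + abs(ll)):
            converged = True
            message = "log-likelihood converged"
            break

    V, dVs = cov.derivs(theta)
    score, info, phi, H = _score_info(groups, V, dVs, state)
    if not converged and np.max(np.abs(score)) < 1e-6 * (1.0 + abs(ll)):
        converged = True
        message = "gradient converged"
    try:
        A = np.linalg.inv(info)
        if not np.all(np.isfinite(A)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(info, rcond=1e-12)
    _, _, beta, _ = state
    eigs = np.linalg.eigvalsh(V)
    boundary = bool(eigs[0] < 1e-7 * max(eigs[-1], 1e-300))
    if boundary:
        logger.warning(
            "fitted covariance is near-singular (condition ~ %.1e); "
            "small-sample boundary optimum", eigs[-1] / max(eigs[0], 1e-300),
        )
    return RemlFit(
        theta=theta, beta=beta, phi=phi, V=V, loglik=ll,
        converged=converged, n_iter=it, message=message, history=history,
        H=H, info=info, A=A, n_obs=n_obs, n_subjects=n_subjects,
        column_names=column_names or [], boundary=boundary,
    )


def _default_theta0(groups, X, y, cov) -> np.ndarray:
    """Moment-based starting values from OLS residuals."""
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    if isinstance(cov, Unstructured):
        dim = cov.dim
        S = np.zeros((dim, dim))
        counts = np.zeros((dim, dim))
        for g in groups:
            resid = g.y - np.einsum("snp,p->sn", g.X, beta_ols)
            ix = np.ix_(g.units, g.units)
            S[ix] += np.einsum("sn,sm->nm", resid, resid)
            counts[ix] += g.X.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(counts > 0, S / np.maximum(counts, 1), 0.0)
        mean_var = np.mean(np.diag(S)[np.diag(counts) > 0]) if np.any(
            np.diag(counts) > 0
        ) else 1.0
        bad = np.diag(counts) == 0
        if bad.any():
            S[bad, bad] = max(mean_var, 1e-8)
        return cov.initial(S)
    if isinstance(cov, KroneckerCS):
        u_dim, b_dim = cov.u_dim, cov.b_dim
        U = np.zeros((u_dim, u_dim))
        counts = np.zeros((u_dim, u_dim))
        r_num, r_den = 0.0, 0.0
        for g in groups:
            resid = g.y - np.einsum("snp,p->sn", g.X, beta_ols)
            cells = g.units // b_dim
            blocks = g.units % b_dim
            for b in np.unique(blocks):
                sel = blocks == b
                cs = cells[sel]
                sub = resid[:, sel]
                ix = np.ix_(cs, cs)
                U[ix] += np.einsum("sn,sm->nm", sub, sub)
                counts[ix] += sub.shape[0]
            for c in np.unique(cells):
                sel = cells == c
                if sel.sum() < 2:
                    continue
                sub = resid[:, sel]
                gram = np.einsum("sn,sm->nm", sub, sub)
                nb = sel.sum()
                off = (gram.sum() - np.trace(gram)) / (nb * (nb - 1))
                var = np.trace(gram) / nb
                r_num += off * sub.shape[0]
                r_den += var * sub.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            U = np.where(counts > 0, U / np.maximum(counts, 1), 0.0)
        mean_var = np.mean(np.diag(U)[np.diag(counts) > 0]) if np.any(
            np.diag(counts) > 0
        ) else 1.0
        bad = np.diag(counts) == 0
        if bad.any():
            U[bad, bad] = max(mean_var, 1e-8)
        r0 = r_num / r_den if r_den > 0 else 0.1
        return cov.initial(U, r0)
    raise ConfigError(f"unsupported covariance structure {type(cov)!r}")


# ---------------------------------------------------------------------------
# Satterthwaite machinery


def satterthwaite_nu(v: float, g: np.ndarray, A: np.ndarray) -> float:
    """``nu = 2 v^2 / (g' A g)`` with a residual-df style fallback."""
    with np.errstate(invalid="ignore", over="ignore"):
        denom = float(g @ A @ g)
    if not np.isfinite(denom) or denom <= 0:
        return np.inf
    return 2.0 * v**2 / denom


def satterthwaite_df(fit: RemlFit, contrast: np.ndarray) -> float:
    """Satterthwaite denominator df for a single contrast of beta."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.phi.shape[0],):
        raise ConfigError("contrast length must match the fixed-effect count")
    return _contrast_nu(fit, c)


def _satterthwaite_gradient(fit: RemlFit, c: np.ndarray) -> np.ndarray:
    # d(c' Phi c)/dtheta_k = c' Phi H_k Phi c  (since dPhi = Phi H_k Phi)
    pc = fit.phi @ c
    return np.array([float(pc @ Hk @ pc) for Hk in fit.H])


def _contrast_nu(fit: RemlFit, c: np.ndarray) -> float:
    v = float(c @ fit.phi @ c)
    g = _satterthwaite_gradient(fit, c)
    if not np.all(np.isfinite(g)):
        logger.warning(
            "non-finite Satterthwaite gradient; falling back to residual df"
        )
        return float(max(fit.n_obs - fit.phi.shape[0], 1))
    return satterthwaite_nu(v, g, fit.A)


@dataclass
class FTestResult:
    effect: str
    f: float
    df_num: int
    df_den: float
    p: float
    estimate: float | None = None


def wald_f_test(fit: RemlFit, L: np.ndarray, name: str = "") -> FTestResult:
    """Type-III style F test of ``L beta = 0`` with Satterthwaite df."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = L.shape[0]
    if fit.degenerate:
        return FTestResult(name, 0.0, q, float(max(fit.n_obs - 1, 1)), 1.0)
    M = L @ fit.phi @ L.T
    Lb = L @ fit.beta
    try:
        f_stat = float(Lb @ np.linalg.solve(M, Lb)) / q
    except np.linalg.LinAlgError:
        f_stat = float(Lb @ np.linalg.pinv(M) @ Lb) / q
    f_stat = max(f_stat, 0.0)
    if q == 1:
        nu = _contrast_nu(fit, L[0])
    else:
        w, P = np.linalg.eigh((M + M.T) / 2.0)
        keep = w > max(w.max(), 0) * 1e-12
        nus = [
            _contrast_nu(fit, L.T @ P[:, i])
            for i in np.flatnonzero(keep)
        ]
        e_sum = sum(nu_i / (nu_i - 2.0) for nu_i in nus if nu_i > 2.0)
        nu = 2.0 * e_sum / (e_sum - q) if e_sum > q else float(
            max(fit.n_obs - fit.phi.shape[0], 1)
        )
    if not np.isfinite(nu) or nu <= 0:
        nu = float(max(fit.n_obs - fit.phi.shape[0], 1))
    p = float(sps.f.sf(f_stat, q, nu)) if f_stat > 0 else 1.0
    p = min(max(p, np.finfo(float).tiny), 1.0)
    est = float(Lb[0]) if q == 1 else None
    return FTestResult(name, f_stat, q, float(nu), p, est)
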