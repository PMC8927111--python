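"""Average-information REML engines for the pedigree animal model.

Two fitting paths, numerically equivalent to maximizing the restricted
log-likelihood of y = X beta + a + e with cov(a) = sigma2_a * A:

* univariate: the family-block structure of A is diagonalized once
  (A_f = U L U' per family), turning every likelihood evaluation into O(n)
  work on flat arrays;
* bivariate: per-family dense covariance templates, grouped by identical
  (A-block, missingness-pattern) so each distinct template is factorized
  once per iteration.

Both use AI (average-information) updates with monotone step-halving and a
gradient-scaled EM-style fallback; variance parameters are kept inside the
parameter cone (non-negative variances, PSD trait covariance matrices) by
eigenvalue clipping, and estimates stuck at the cone boundary are flagged
rather than silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_LOG2PI = np.log(2.0 * np.pi)


class RemlError(RuntimeError):
    """Non-convergence or degenerate model; carries the iteration trace."""

    def __init__(self, msg: str, trace: list | None = None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class RemlResult:
    theta: np.ndarray  # variance parameters at the optimum
    loglik: float
    cov_theta: np.ndarray  # inverse average-information matrix
    n_iter: int
    converged: bool
    boundary: bool
    gradient_norm: float
    trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# univariate: diagonalized likelihood
# ---------------------------------------------------------------------------


def _eval_diag(sa: float, se: float, lam, y, X):
    """Restricted loglik, score and AI matrix for theta = (sigma2_a, sigma2_e)."""
    n, p = X.shape
    d = sa * lam + se
    if d.min() <= 0:
        return None
    di = 1.0 / d
    Xd = X * di[:, None]
    M = X.T @ Xd
    b = Xd.T @ y
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0:
        return None
    Minv = np.linalg.inv(M)
    yPy = float(y @ (di * y) - b @ Minv @ b)
    ll = -0.5 * (np.log(d).sum() + logdetM + yPy + (n - p) * _LOG2PI)

    Py = di * y - Xd @ (Minv @ b)

    def P(v):
        dv = di * v
        return dv - Xd @ (Minv @ (X.T @ dv))

    score = np.empty(2)
    AI = np.empty((2, 2))
    us = []
    for k, lamk in enumerate((lam, None)):
        w = lamk * di if lamk is not None else di
        tr_vinv = w.sum()
        H = X.T @ (X * (w * di)[:, None])
        tr_p = tr_vinv - np.trace(Minv @ H)
        u = lamk * Py if lamk is not None else Py.copy()
        us.append(u)
        score[k] = -0.5 * (tr_p - Py @ u)
    Pu = [P(u) for u in us]
    for k in range(2):
        for l in range(k, 2):
            AI[k, l] = AI[l, k] = 0.5 * float(us[k] @ Pu[l])
    return ll, score, AI, Minv


def reml_univariate_diag(
    lam: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
    fix_sigma_a: float | None = None,
) -> RemlResult:
    """Maximize the diagonalized restricted log-likelihood.

    Parameters
    ----------
    lam : eigenvalues of the (block) relationship matrix, one per record.
    y, X : response and fixed-effect design in the same rotated basis.
    fix_sigma_a : if given, sigma2_a is held at this value (used for the
        null model of the boundary likelihood-ratio test).
    """
    n, p = X.shape
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    vary = max(float(resid @ resid) / max(n - p, 1), 1e-12)
    floor = 1e-8 * vary

    fixed_a = fix_sigma_a is not None
    theta = np.array(
        [fix_sigma_a if fixed_a else 0.5 * vary, 0.5 * vary if not fixed_a else vary]
    )
    out = _eval_diag(theta[0], theta[1], lam, y, X)
    if out is None:
        raise RemlError("restricted likelihood undefined at starting values")
    ll, score, AI, _ = out
    trace = [(0, ll, theta.copy())]
    free = [1] if fixed_a else [0, 1]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # active set: free parameters not pinned at the zero boundary
        active = [
            k for k in free if not (theta[k] <= floor * (1 + 1e-9) and score[k] < 0)
        ]
        if not active:
            converged = True
            break
        s_act = score[active]
        A_act = AI[np.ix_(active, active)]
        try:
            delta = np.linalg.solve(A_act, s_act)
        except np.linalg.LinAlgError:
            delta = s_act * theta[active] ** 2 / n  # EM-style fallback direction
        slack = 1e-10 * (1.0 + abs(ll))  # numerical noise floor of the loglik
        new_ll = None
        for half in range(40):
            cand = theta.copy()
            cand[active] = np.maximum(theta[active] + delta, floor)
            out = _eval_diag(cand[0], cand[1], lam, y, X)
            if out is not None and out[0] >= ll - slack:
                new_ll = out[0]
                break
            delta = 0.5 * delta
            if half == 19:  # switch to EM-style direction
                delta = s_act * theta[active] ** 2 / n
        if new_ll is None:
            # no ascent direction left; at a numerically stationary point
            if len(trace) > 1 and abs(trace[-1][1] - trace[-2][1]) < 1e-3:
                converged = True
            break
        theta = cand
        dll = new_ll - ll
        ll, score, AI, _ = out
        trace.append((it, ll, theta.copy()))
        # loglik differences below its numerical resolution are unresolvable
        if abs(dll) < max(tol, 1e-9 * (1 + abs(ll))):
            converged = True
            break

    boundary = bool(theta[0] <= floor * (1 + 1e-9) or theta[1] <= floor * (1 + 1e-9))
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    if not converged and not boundary:
        raise RemlError(f"REML did not converge in {max_iter} iterations", trace)
    return RemlResult(
        theta=theta,
        loglik=ll,
        cov_theta=cov,
        n_iter=it,
        converged=converged,
        boundary=boundary,
        gradient_norm=float(np.linalg.norm(score)),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# bivariate: grouped dense templates
# ---------------------------------------------------------------------------
# parameter order: (G11, G12, G22, R11, R12, R22)

_DG = [
    np.array([[1.0, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 1.0], [1.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 1.0]]),
]


@dataclass
class TemplateGroup:
    """Families sharing one covariance template.

    K : list of 6 basis matrices (dV/dtheta_p), shape (m, m).
    Y : stacked observation vectors, (n_fam, m).
    X : stacked fixed-effect designs, (n_fam, m, q).
    """

    K: list[np.ndarray]
    Y: np.ndarray
    X: np.ndarray


def make_basis(A: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> list[np.ndarray]:
    """Covariance basis matrices for one family's observed entries.

    idx1/idx2: positions (into the family A block) of individuals with
    trait 1 / trait 2 observed; the observation vector stacks trait 1 then
    trait 2.
    """
    m1, m2 = len(idx1), len(idx2)
    m = m1 + m2
    A11 = A[np.ix_(idx1, idx1)]
    A12 = A[np.ix_(idx1, idx2)]
    A22 = A[np.ix_(idx2, idx2)]
    E12 = (idx1[:, None] == idx2[None, :]).astype(float)

    def emb(B11, B12, B22):
        K = np.zeros((m, m))
        K[:m1, :m1] = B11
        K[:m1, m1:] = B12
        K[m1:, :m1] = B12.T
        K[m1:, m1:] = B22
        return K

    Z1 = np.zeros((m1, m1))
    Z2 = np.zeros((m2, m2))
    Z12 = np.zeros((m1, m2))
    return [
        emb(A11, Z12, Z2),
        emb(Z1, A12, Z2),
        emb(Z1, Z12, A22),
        emb(np.eye(m1), Z12, Z2),
        emb(Z1, E12, Z2),
        emb(Z1, Z12, np.eye(m2)),
    ]


def _theta_to_GR(theta):
    G = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    R = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return G, R


def _project_cone(theta, floor):
    """Clip G and R eigenvalues into the PSD cone (R kept PD)."""
    G, R = _theta_to_GR(theta)
    out = []
    for M, fl in ((G, 0.0), (R, floor)):
        w, U = np.linalg.eigh(M)
        M2 = (U * np.maximum(w, fl)) @ U.T
        out.extend([M2[0, 0], M2[0, 1], M2[1, 1]])
    return np.asarray(out)


def _eval_biv(theta, groups: list[TemplateGroup], n: int, q: int):
    Vs, Ws = [], []
    logdetV = 0.0
    yWy = 0.0
    M = np.zeros((q, q))
    r = np.zeros(q)
    for g in groups:
        V = sum(t * K for t, K in zip(theta, g.K))
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        W = np.linalg.inv(V)
        Vs.append(V)
        Ws.append(W)
        logdetV += 2.0 * len(g.Y) * np.log(np.diag(c)).sum()
        WY = g.Y @ W
        yWy += float(np.einsum("fm,fm->", g.Y, WY))
        WX = np.einsum("mn,fnq->fmq", W, g.X)
        M += np.einsum("fmq,fmr->qr", g.X, WX)
        r += np.einsum("fmq,fm->q", WX, g.Y)
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0:
        return None
    Minv = np.linalg.inv(M)
    beta = Minv @ r
    yPy = yWy - float(r @ beta)
    ll = -0.5 * (logdetV + logdetM + yPy + (n - q) * _LOG2PI)

    npar = len(theta)
    tr_vinv = np.zeros(npar)
    TX = np.zeros((npar, q, q))
    yPKPy = np.zeros(npar)
    quad = np.zeros((npar, npar))
    c_vec = np.zeros((npar, q))
    for g, W in zip(groups, Ws):
        res = g.Y - np.einsum("fmq,q->fm", g.X, beta)
        PY = res @ W
        WX = np.einsum("mn,fnq->fmq", W, g.X)
        us, Wus = [], []
        for k, K in enumerate(g.K):
            tr_vinv[k] += len(g.Y) * float(np.einsum("mn,nm->", W, K))
            U = np.einsum("mn,fnq->fmq", K, WX)
            TX[k] += np.einsum("fmq,fmr->qr", WX, U)
            u = PY @ K
            us.append(u)
            Wus.append(u @ W)
            yPKPy[k] += float(np.einsum("fm,fm->", PY, u))
            c_vec[k] += np.einsum("fmq,fm->q", WX, u)
        for k in range(npar):
            for l in range(k, npar):
                quad[k, l] += float(np.einsum("fm,fm->", us[k], Wus[l]))
    score = np.empty(npar)
    AI = np.empty((npar, npar))
    for k in range(npar):
        tr_p = tr_vinv[k] - float(np.trace(Minv @ TX[k]))
        score[k] = -0.5 * (tr_p - yPKPy[k])
        for l in range(k, npar):
            AI[k, l] = AI[l, k] = 0.5 * (quad[min(k, l), max(k, l)] - c_vec[k] @ Minv @ c_vec[l])
    return ll, score, AI, beta


def reml_bivariate_groups(
    groups: list[TemplateGroup],
    theta0: np.ndarray,
    n: int,
    q: int,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> RemlResult:
    """AI-REML over grouped family templates; theta = (G11,G12,G22,R11,R12,R22)."""
    scale = max(theta0[0] + theta0[3], theta0[2] + theta0[5], 1e-12)
    floor = 1e-8 * scale
    theta = _project_cone(np.asarray(theta0, dtype=float), floor)
    out = _eval_biv(theta, groups, n, q)
    if out is None:
        raise RemlError("restricted likelihood undefined at starting values")
    ll, score, AI, _ = out
    trace = [(0, ll, theta.copy())]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(AI + 1e-12 * scale * np.eye(6), score)
        except np.linalg.LinAlgError:
            delta = score * (np.abs(theta) + 0.1 * scale) ** 2 / n
        slack = 1e-10 * (1.0 + abs(ll))
        new = None
        for half in range(40):
            cand = _project_cone(theta + delta, floor)
            out = _eval_biv(cand, groups, n, q)
            if out is not None and out[0] >= ll - slack:
                new = out
                break
            delta = 0.5 * delta
            if half == 19:
                delta = score * (np.abs(theta) + 0.1 * scale) ** 2 / n
        if new is None:
            if len(trace) > 1 and abs(trace[-1][1] - trace[-2][1]) < 1e-3:
                converged = True
            break
        dll = new[0] - ll
        theta = cand
        ll, score, AI, _ = new
        trace.append((it, ll, theta.copy()))
        if abs(dll) < max(tol, 1e-9 * (1 + abs(ll))):
            converged = True
            break

    G, R = _theta_to_GR(theta)
    eigG = np.linalg.eigvalsh(G)
    eigR = np.linalg.eigvalsh(R)
    boundary = bool(eigG.min() <= floor * 10 or eigR.min() <= floor * 10)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.full((6, 6), np.nan)
    if not converged and not boundary:
        raise RemlError(f"bivariate REML did not converge in {max_iter} iterations", trace)
    return RemlResult(
        theta=theta,
        loglik=ll,
        cov_theta=cov,
        n_iter=it,
        converged=converged,
        boundary=boundary,
        gradient_norm=float(np.linalg.norm(score)),
        trace=trace,
    )
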