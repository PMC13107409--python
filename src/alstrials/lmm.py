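"""Likelihood machinery for the longitudinal models.

Two fitters live here:

``fit_lmm``
    Linear mixed model with a random intercept or a random intercept+slope
    (unstructured 2x2 covariance) per patient.  The residual variance and the
    fixed effects are profiled out of the REML criterion; the scaled
    random-effect covariance is parametrized by its Cholesky factor and
    optimized with BFGS.  All per-patient quantities reduce to 2x2 algebra via
    the Woodbury identity, so one criterion evaluation is a handful of
    vectorized operations over patients — fast enough to sit inside a
    permutation loop.

``fit_mmrm``
    Multivariate-normal regression of the post-baseline responses on a
    patient-level design with a visit-specific mean and an unstructured
    within-patient covariance, maximized by EM over the ignorable missingness
    pattern.  This is the classical MMRM; with a single post-baseline visit it
    collapses to ANCOVA.

Both report Wald tests against the standard normal reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class FitError(RuntimeError):
    """A model fit could not be completed on this dataset."""


@dataclass(frozen=True)
class LmmFit:
    params: np.ndarray          # fixed effects
    cov_params: np.ndarray      # their covariance (Wald, normal reference)
    sigma2: float               # residual variance
    re_cov: np.ndarray          # random-effect covariance (on the data scale)
    converged: bool
    n_groups: int
    n_obs: int

    def wald(self, idx: int) -> tuple[float, float, float, float]:
        """(estimate, se, z, two-sided p) for fixed-effect ``idx``."""
        est = float(self.params[idx])
        se = float(np.sqrt(self.cov_params[idx, idx]))
        z = est / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        return est, se, z, p


def _group_stats(y, X, Z, groups, m):
    """Per-group Z'Z, Z'X, Z'y and global X'X, X'y, y'y."""
    q = Z.shape[1]
    p = X.shape[1]
    A = np.zeros((m, q, q))
    B = np.zeros((m, q, p))
    c = np.zeros((m, q))
    np.add.at(A, groups, Z[:, :, None] * Z[:, None, :])
    np.add.at(B, groups, Z[:, :, None] * X[:, None, :])
    np.add.at(c, groups, Z * y[:, None])
    return A, B, c, X.T @ X, X.T @ y, float(y @ y)


def _criterion(L, A, B, c, XtX, Xty, yty, N, p, with_grad=False):
    """Profiled -2 REML log-likelihood at scaled RE covariance Gamma = LL'.

    With ``with_grad`` also returns the gradient with respect to the free
    entries of ``L`` (log-parametrized diagonal handled by the caller).
    """
    Gamma = L @ L.T
    q = Gamma.shape[0]
    M = np.eye(q)[None, :, :] + A @ Gamma            # (m, q, q)
    sign, logdet = np.linalg.slogdet(M)
    if np.any(sign <= 0):
        return None
    P = np.linalg.inv(M)                             # (I + A Gamma)^-1
    K = Gamma[None, :, :] @ P                        # (Gamma^-1 + A)^-1
    XtVX = XtX - np.einsum("mqp,mqr,mrs->ps", B, K, B)
    XtVy = Xty - np.einsum("mqp,mqr,mr->p", B, K, c)
    ytVy = yty - np.einsum("mq,mqr,mr->", c, K, c)
    if not (np.all(np.isfinite(XtVX)) and np.all(np.isfinite(XtVy)) and np.isfinite(ytVy)):
        return None
    try:
        cho = np.linalg.cholesky(XtVX)
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return None
    rss = ytVy - beta @ XtVy
    if rss <= 0:
        return None
    sigma2 = rss / (N - p)
    crit = (
        (N - p) * np.log(sigma2)
        + logdet.sum()
        + 2.0 * np.log(np.diag(cho)).sum()
    )
    if not with_grad:
        return crit, beta, sigma2, XtVX

    # dK = P' dGamma P; envelope theorem handles the implicit beta-hat.
    Cinv = np.linalg.inv(XtVX)
    PB = np.einsum("mqr,mrp->mqp", P, B)             # P_i B_i
    d = c - np.einsum("mqp,p->mq", B, beta)          # Z_i' residuals
    Pd = np.einsum("mqr,mr->mq", P, d)
    G = (
        np.einsum("mqr,msr->qs", A, P)               # sum A_i P_i'
        - np.einsum("mqp,pr,msr->qs", PB, Cinv, PB)
        - (N - p) / rss * np.einsum("mq,ms->qs", Pd, Pd)
    )
    grad_L = (G + G.T) @ L
    return crit, beta, sigma2, XtVX, grad_L


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    times: np.ndarray | None = None,
    random_slope: bool = True,
) -> LmmFit:
    """REML fit of ``y = X beta + Z_i u_i + eps`` with per-group random
    intercept (and slope on ``times`` when ``random_slope``).

    ``groups`` are integer codes 0..m-1; ``times`` is required for the
    random-slope model.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    N, p = X.shape
    m = int(groups.max()) + 1
    if N - p <= 0 or m < 2:
        raise FitError("too few observations for a mixed-model fit")
    if random_slope:
        if times is None:
            raise FitError("random-slope model needs observation times")
        Z = np.column_stack([np.ones(N), np.asarray(times, dtype=float)])
    else:
        Z = np.ones((N, 1))
    q = Z.shape[1]
    A, B, c, XtX, Xty, yty = _group_stats(y, X, Z, groups, m)

    # theta holds log-diagonal entries and raw off-diagonals of L.
    diag_pos = [0] if q == 1 else [0, 2]

    def unpack(theta):
        L = np.zeros((q, q))
        L[np.tril_indices(q)] = theta
        for i, pos in enumerate(diag_pos):
            L[i, i] = np.exp(theta[pos])
        return L

    def objective(theta):
        L = unpack(theta)
        out = _criterion(L, A, B, c, XtX, Xty, yty, N, p, with_grad=True)
        if out is None:
            return 1e12, np.zeros_like(theta)
        crit, _, _, _, grad_L = out
        grad = grad_L[np.tril_indices(q)].copy()
        for i, pos in enumerate(diag_pos):
            grad[pos] = grad_L[i, i] * L[i, i]       # chain rule for log-diag
        return crit, grad

    x0 = _moment_start(y, X, Z, groups, m, A, q, diag_pos)
    best = optimize.minimize(
        objective, x0, jac=True, method="BFGS", options={"gtol": 1e-4, "maxiter": 200}
    )
    converged = bool(best.fun < 1e11)
    grad_norm = float(np.linalg.norm(best.jac)) if converged else np.inf
    if not best.success and (not converged or grad_norm > 0.5):
        # Precision-loss endings with a flat gradient are fine; a simplex
        # polish guards genuine failures.
        res = optimize.minimize(
            lambda th: objective(th)[0],
            best.x if converged else x0,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000},
        )
        if res.fun <= best.fun:
            best = res
        converged = bool(best.fun < 1e11)
    if not converged:
        raise FitError("mixed-model REML optimization failed")
    out = _criterion(unpack(best.x), A, B, c, XtX, Xty, yty, N, p)
    if out is None:
        raise FitError("mixed-model REML criterion degenerate at optimum")
    _, beta, sigma2, XtVX = out
    cov = sigma2 * np.linalg.inv(XtVX)
    L = unpack(best.x)
    return LmmFit(
        params=beta,
        cov_params=cov,
        sigma2=float(sigma2),
        re_cov=sigma2 * (L @ L.T),
        converged=converged,
        n_groups=m,
        n_obs=N,
    )


def _moment_start(y, X, Z, groups, m, A, q, diag_pos):
    """Starting values from shrunken per-group OLS coefficients."""
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta0
    cr = np.zeros((m, q))
    np.add.at(cr, groups, Z * r[:, None])
    b = np.linalg.solve(A + 1e-4 * np.eye(q), cr[:, :, None])[:, :, 0]
    emp = np.atleast_2d(np.cov(b.T)) if m > 1 else np.eye(q)
    s2 = max(float(np.var(r)) - float(emp[0, 0]) * 0.5, float(np.var(r)) * 0.1, 1e-6)
    G0 = emp / s2 + 1e-4 * np.eye(q)
    try:
        L0 = np.linalg.cholesky(G0)
    except np.linalg.LinAlgError:
        L0 = np.diag(np.sqrt(np.maximum(np.diag(G0), 1e-4)))
    theta = L0[np.tril_indices(q)].copy()
    for i, pos in enumerate(diag_pos):
        theta[pos] = np.log(max(L0[i, i], 1e-4))
    return theta


# ---------------------------------------------------------------------------
# MMRM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MmrmFit:
    coef: np.ndarray            # stacked coefficients, see fit_mmrm
    cov_coef: np.ndarray
    sigma: np.ndarray           # within-patient covariance (k x k)
    coef_names: list[str]
    converged: bool
    structure: str              # "unstructured" or "compound_symmetric"
    n_patients: int


def _design_components(arm, baseline, covariates, k):
    """The patient design factorizes as M_i = sum_r c_ri D_r with c_i =
    (1, arm_i, baseline_i, covs_i) and fixed (k x q) blocks D_r: visit
    intercepts, visit-specific arm effects, and common covariate slopes.
    This keeps every GLS/EM contraction O(k^2 q) instead of O(n k q^2)."""
    C = np.column_stack([np.ones_like(arm), arm, baseline, covariates])
    m_c = C.shape[1]
    q = 2 * k + (m_c - 2)
    D = np.zeros((m_c, k, q))
    D[0, :, :k] = np.eye(k)
    D[1, :, k : 2 * k] = np.eye(k)
    for e in range(m_c - 2):
        D[2 + e, :, 2 * k + e] = 1.0
    return C, D, q


def fit_mmrm(
    Y: np.ndarray,
    arm: np.ndarray,
    baseline: np.ndarray,
    covariates: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MmrmFit:
    """ML fit of the MMRM: ``Y`` is (n_patients, k) change-from-baseline at
    the k post-baseline visits with NaN at missed visits; the mean has a
    visit-specific intercept and arm effect plus common baseline (and
    covariate) slopes; the within-patient covariance is unstructured,
    estimated by EM under ignorable missingness.

    Falls back to a compound-symmetric covariance (with a warning) when the
    unstructured matrix is not estimable.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    arm = np.asarray(arm, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if covariates is None:
        covariates = np.empty((n, 0))
    obs = ~np.isnan(Y)
    keep = obs.any(axis=1)
    Y, arm, baseline, covariates, obs = (
        Y[keep], arm[keep], baseline[keep], covariates[keep], obs[keep]
    )
    n = Y.shape[0]
    if n < 4 or obs.sum(axis=0).min() < 2:
        raise FitError("a post-baseline visit has fewer than 2 observations")
    C, D, q = _design_components(arm, baseline, covariates, k)

    structure = "unstructured"
    if n <= k + q / k:  # more visits than patients: unstructured not estimable
        structure = "compound_symmetric"
        warnings.warn(
            "unstructured covariance not estimable; falling back to "
            "compound symmetry",
            stacklevel=2,
        )

    # Missingness patterns are fixed; group patients once.
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    groups = [
        (np.where(inverse == pi)[0], np.where(pat)[0], np.where(~pat)[0])
        for pi, pat in enumerate(patterns)
    ]

    def mean_of(theta):
        return C @ np.tensordot(D, theta, axes=([2], [0]))

    # OLS start on observed cells
    i_idx, j_idx = np.where(obs)
    Mo_rows = np.einsum("xr,xrq->xq", C[i_idx], D[:, j_idx, :].transpose(1, 0, 2))
    theta, *_ = np.linalg.lstsq(Mo_rows, Y[obs], rcond=None)
    sigma = _moment_sigma(Y - mean_of(theta), obs, structure)

    CtC = C.T @ C
    converged = False
    for _ in range(max_iter):
        theta_old = theta
        mu = mean_of(theta)
        r = Y - mu
        # E-step: completed residuals and conditional covariance per pattern
        S = np.zeros((k, k))
        Rhat = np.zeros((n, k))
        for idx, o, mi in groups:
            Soo = sigma[np.ix_(o, o)]
            ro = r[np.ix_(idx, o)]
            Rhat[np.ix_(idx, o)] = ro
            if mi.size:
                Smo = sigma[np.ix_(mi, o)]
                G = np.linalg.solve(Soo, Smo.T).T        # Smo Soo^-1
                Rhat[np.ix_(idx, mi)] = ro @ G.T
                S[np.ix_(mi, mi)] += len(idx) * (sigma[np.ix_(mi, mi)] - G @ Smo.T)
        # M-step: GLS for theta on completed data, then sigma update
        W = np.linalg.inv(sigma)
        Yhat = mu + Rhat
        DWD = np.einsum("rka,kl,slb->rsab", D, W, D)
        lhs = np.einsum("rs,rsab->ab", CtC, DWD)
        m_r = C.T @ Yhat
        rhs = np.einsum("rka,kl,rl->a", D, W, m_r)
        theta = np.linalg.solve(lhs, rhs)
        r_new = Yhat - mean_of(theta)
        sigma_new = (S + r_new.T @ r_new) / n
        if structure == "compound_symmetric":
            sigma_new = _project_cs(sigma_new)
        if not np.all(np.isfinite(sigma_new)):
            raise FitError("MMRM covariance update diverged")
        sigma = sigma_new
        if np.max(np.abs(theta - theta_old)) < tol:
            converged = True
            break

    # Wald covariance from the observed-data GLS information at sigma-hat
    info = np.zeros((q, q))
    for idx, o, _mi in groups:
        Soo_inv = np.linalg.inv(sigma[np.ix_(o, o)])
        Cp = C[idx]
        Do = D[:, o, :]
        DWDp = np.einsum("rka,kl,slb->rsab", Do, Soo_inv, Do)
        info += np.einsum("rs,rsab->ab", Cp.T @ Cp, DWDp)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("MMRM information matrix singular") from exc
    # REML-style scale correction (q/k effective mean parameters per visit);
    # with a single complete visit this reproduces the ANCOVA variance.
    ddf = n - q / k
    if ddf <= 0:
        raise FitError("no residual degrees of freedom in MMRM")
    cov = cov * (n / ddf)
    sigma = sigma * (n / ddf)

    names = (
        [f"visit_{j}" for j in range(k)]
        + [f"arm:visit_{j}" for j in range(k)]
        + ["baseline"]
        + [f"cov_{j}" for j in range(covariates.shape[1])]
    )
    return MmrmFit(
        coef=theta,
        cov_coef=cov,
        sigma=sigma,
        coef_names=names,
        converged=converged,
        structure=structure,
        n_patients=n,
    )


def _moment_sigma(resid, obs, structure):
    k = resid.shape[1]
    R = np.where(obs, resid, 0.0)
    counts = obs.T.astype(float) @ obs.astype(float)
    S = (R.T @ R) / np.maximum(counts, 1.0)
    v = np.diag(S).mean()
    if structure == "compound_symmetric":
        return _project_cs(S)
    # shrink toward the diagonal enough to be positive definite
    for lam in (0.0, 0.1, 0.3, 0.6, 0.9):
        cand = (1 - lam) * S + lam * v * np.eye(k)
        if np.all(np.linalg.eigvalsh(cand) > 1e-10):
            return cand
    return v * np.eye(k)


def _project_cs(S):
    k = S.shape[0]
    v = float(np.diag(S).mean())
    off = (S.sum() - np.trace(S)) / (k * (k - 1)) if k > 1 else 0.0
    rho = np.clip(off / v, -1.0 / max(k - 1, 1) + 1e-6, 1 - 1e-6)
    return v * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))


def mmrm_final_visit_contrast(fit: MmrmFit) -> tuple[float, float, float, float]:
    """(estimate, se, z, p) for the arm contrast at the final visit."""
    k = (len(fit.coef_names) - 1 - sum(n.startswith("cov_") for n in fit.coef_names)) // 2
    idx = fit.coef_names.index(f"arm:visit_{k - 1}")
    est = float(fit.coef[idx])
    se = float(np.sqrt(fit.cov_coef[idx, idx]))
    z = est / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return est, se, z, p
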