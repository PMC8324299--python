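"""Hierarchical Bayesian machinery shared by the psychometric and neurometric
choice models.

Model structure (P parameters per session, D sessions, M subjects):

    theta_d  ~ N(theta_m[d], Sigma)        session level
    theta_m  ~ N(theta_*,    Sigma*)       subject level
    theta_*  ~ N(mu0, diag(sigma0^2))      grand level (weakly informative)

Both covariance matrices are decomposed into per-parameter scales and a
correlation matrix; scales get HalfCauchy(0, 1) priors and correlation
matrices LKJ(2) priors.  Bounded parameters (e.g. the contrast exponent) are
handled by a scaled-logit change of variables; the hierarchical Gaussians
are evaluated on the constrained values.

Two fitting paths:

* ``fit_map`` — the fast default.  Each session's likelihood is replaced by
  its Gaussian (Laplace) approximation at the session MLE; session and
  subject effects then marginalise analytically, leaving a 3P-dimensional
  marginal posterior over (theta_*, tau, tau*) that is maximised and
  Laplace-approximated.  Joint draws of subject and session parameters are
  recovered from their conditional Gaussians.  Marginalising before
  maximising avoids the degenerate mode of the joint hierarchical posterior
  (scales collapsing to zero), which would over-shrink sessions and bias
  pooled psychometric slopes downward.  Correlation matrices are held at the
  identity (the mode of LKJ(2)) on this path.
* ``fit_mcmc`` — affine-invariant ensemble MCMC (emcee) over the full joint
  model including the correlation matrices, parameterised by canonical
  partial correlations whose per-entry Beta densities reproduce the LKJ
  prior exactly.  Convergence is summarised by rank-normalised split R-hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import solve_triangular

__all__ = [
    "HierarchicalModel",
    "PosteriorDraws",
    "SamplerConfig",
    "Interval",
    "fit_map",
    "fit_mcmc",
]


# ---------------------------------------------------------------------------
# Transforms for bounded coordinates
# ---------------------------------------------------------------------------


def _sigmoid(u):
    u = np.asarray(u, dtype=float)
    with np.errstate(over="ignore"):
        return np.where(u >= 0, 1.0 / (1.0 + np.exp(-u)), np.exp(u) / (1.0 + np.exp(u)))


@dataclass(frozen=True)
class Interval:
    """Scaled-logit transform onto (lo, hi)."""

    lo: float
    hi: float

    def constrain(self, u):
        return self.lo + (self.hi - self.lo) * _sigmoid(u)

    def unconstrain(self, c):
        p = (np.asarray(c, dtype=float) - self.lo) / (self.hi - self.lo)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return np.log(p) - np.log1p(-p)

    def dconstrain(self, u):
        s = _sigmoid(u)
        return (self.hi - self.lo) * s * (1.0 - s)

    def log_jac(self, u):
        s = _sigmoid(u)
        return float(np.log(self.hi - self.lo) + np.log(s) + np.log1p(-s))

    def clip(self, c, margin: float = 0.0):
        return np.clip(c, self.lo + margin, self.hi - margin)


# ---------------------------------------------------------------------------
# Model interface and containers
# ---------------------------------------------------------------------------


class HierarchicalModel:
    """A concrete model supplies the per-session likelihood and priors.

    Attributes
    ----------
    param_names : tuple of str, length P.
    transforms : per-parameter ``Interval`` or None (unbounded).
    mu0, sigma0 : grand-level Gaussian hyperprior mean and s.d. (length P),
        on the constrained scale.
    """

    param_names: tuple[str, ...]
    transforms: tuple
    mu0: np.ndarray
    sigma0: np.ndarray

    def loglik_grad(self, theta: np.ndarray, data) -> tuple[float, np.ndarray]:
        """Log likelihood of one session and gradient w.r.t. constrained theta."""
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return len(self.param_names)


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 500
    samples: int = 500
    walkers: int | None = None  # emcee walkers; default 2*ndim+2
    thin: int = 1


@dataclass
class PosteriorDraws:
    """Joint posterior draws on the constrained scale.

    ``grand``/``subject``/``session`` have shapes (n_draws, P),
    (n_draws, M, P), (n_draws, D, P).  ``scales``/``scales_subject`` are the
    session- and subject-level standard deviations (n_draws, P).
    ``diagnostics`` carries convergence summaries: the MAP path reports the
    optimiser status, the MCMC path rank-normalised split R-hat per grand
    parameter and the mean acceptance fraction.
    """

    param_names: tuple[str, ...]
    grand: np.ndarray
    subject: np.ndarray
    session: np.ndarray
    subject_ids: tuple[str, ...]
    session_ids: tuple[str, ...]
    session_subject_index: np.ndarray
    scales: np.ndarray | None = None
    scales_subject: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)
    method: str = "map"

    @property
    def n_draws(self) -> int:
        return self.grand.shape[0]

    def grand_summary(self) -> dict[str, tuple[float, float, float, float]]:
        """Per-parameter (mean, sd, 2.5%, 97.5%) of the grand-level posterior."""
        out = {}
        for p, name in enumerate(self.param_names):
            col = self.grand[:, p]
            lo, hi = np.percentile(col, [2.5, 97.5])
            out[name] = (float(col.mean()), float(col.std(ddof=1)), float(lo), float(hi))
        return out


# ---------------------------------------------------------------------------
# Session-level MLE and Laplace approximation
# ---------------------------------------------------------------------------


def _session_mle(model: HierarchicalModel, data, x0_c: np.ndarray):
    """MLE of one session on the constrained scale and covariance of the
    Gaussian (Laplace) approximation to its likelihood."""
    P = model.n_params
    bounds = []
    for tr in model.transforms:
        bounds.append((None, None) if tr is None else (tr.lo, tr.hi))

    def neg(theta):
        ll, g = model.loglik_grad(theta, data)
        return -ll, -g

    res = optimize.minimize(
        neg, np.asarray(x0_c, dtype=float), jac=True, method="L-BFGS-B", bounds=bounds
    )
    theta_hat = res.x.copy()
    # keep bounded coordinates strictly interior for the curvature evaluation
    for p, tr in enumerate(model.transforms):
        if tr is not None:
            theta_hat[p] = tr.clip(theta_hat[p], margin=1e-4)
    H = np.empty((P, P))
    h = 1e-5 * (1.0 + np.abs(theta_hat))
    for k in range(P):
        e = np.zeros(P); e[k] = h[k]
        gp = model.loglik_grad(theta_hat + e, data)[1]
        gm = model.loglik_grad(theta_hat - e, data)[1]
        H[:, k] = -(gp - gm) / (2 * h[k])
    H = 0.5 * (H + H.T)
    # regularise: flat directions (e.g. saturated parameters) get wide, not
    # infinite, likelihood curvature
    w, Q = np.linalg.eigh(H)
    w = np.maximum(w, 1e-4)
    V = (Q / w) @ Q.T
    return theta_hat, V


# ---------------------------------------------------------------------------
# Marginalised hyperparameter posterior (diagonal covariances)
# ---------------------------------------------------------------------------


def _grand_unconstrain(model, grand_c):
    u = np.asarray(grand_c, dtype=float).copy()
    for p, tr in enumerate(model.transforms):
        if tr is not None:
            u[p] = tr.unconstrain(grand_c[p])
    return u


def _grand_constrain(model, grand_u):
    c = np.asarray(grand_u, dtype=float).copy()
    for p, tr in enumerate(model.transforms):
        if tr is not None:
            c[p] = tr.constrain(grand_u[p])
    return c


def _marginal_neg_log_post(model, phi, theta_hats, Vs, subject_of, M):
    """-log posterior of phi = [grand_u (P) | log tau (P) | log tau* (P)],
    with session/subject effects marginalised under the Gaussian session
    approximations.

    For subject m with sessions d in S_m the stacked session MLEs are
    jointly Gaussian: mean 1 (x) theta_*, covariance
    blockdiag(V_d + diag(tau^2)) + J (x) diag(tau*^2).
    """
    P = model.n_params
    grand_u = phi[:P]
    ltau = phi[P : 2 * P]
    ltau_s = phi[2 * P :]
    if np.any(np.abs(phi) > 40):
        return np.inf
    tau2 = np.exp(2 * ltau)
    tau_s2 = np.exp(2 * ltau_s)
    grand_c = _grand_constrain(model, grand_u)

    lp = 0.0
    for m in range(M):
        ds = np.flatnonzero(subject_of == m)
        n_m = len(ds)
        dim = n_m * P
        cov = np.zeros((dim, dim))
        resid = np.empty(dim)
        for a, d in enumerate(ds):
            sl = slice(a * P, (a + 1) * P)
            cov[sl, sl] = Vs[d] + np.diag(tau2)
            resid[sl] = theta_hats[d] - grand_c
        for a in range(n_m):
            for b in range(n_m):
                cov[a * P : (a + 1) * P, b * P : (b + 1) * P] += np.diag(tau_s2)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            return np.inf
        sol = np.linalg.solve(cov, resid)
        lp += -0.5 * (logdet + resid @ sol + dim * np.log(2 * np.pi))

    # grand hyperprior + Jacobians of bounded grand coordinates
    r = (grand_c - model.mu0) / model.sigma0
    lp += -0.5 * float(r @ r)
    for p, tr in enumerate(model.transforms):
        if tr is not None:
            lp += tr.log_jac(grand_u[p])
    # HalfCauchy(0,1) scales with log-scale Jacobian (+log tau)
    for lt in (ltau, ltau_s):
        t = np.exp(lt)
        lp += float(np.sum(-np.log1p(t * t) + lt))
    return -lp if np.isfinite(lp) else np.inf


def _conditional_draws(model, phi, theta_hats, Vs, subject_of, M, rng):
    """Draw (theta_m, theta_d) from their Gaussians conditional on phi."""
    P = model.n_params
    grand_c = _grand_constrain(model, phi[:P])
    tau2 = np.exp(2 * phi[P : 2 * P])
    tau_s2 = np.exp(2 * phi[2 * P :])
    D = len(theta_hats)
    subj = np.empty((M, P))
    sess = np.empty((D, P))
    prior_prec_m = np.diag(1.0 / tau_s2)
    for m in range(M):
        ds = np.flatnonzero(subject_of == m)
        prec = prior_prec_m.copy()
        rhs = prior_prec_m @ grand_c
        for d in ds:
            W = np.linalg.inv(Vs[d] + np.diag(tau2))
            prec += W
            rhs += W @ theta_hats[d]
        cov_m = np.linalg.inv(prec)
        mean_m = cov_m @ rhs
        subj[m] = rng.multivariate_normal(mean_m, cov_m)
        prior_prec_d = np.diag(1.0 / tau2)
        for d in ds:
            Wd = np.linalg.inv(Vs[d])
            prec_d = prior_prec_d + Wd
            cov_d = np.linalg.inv(prec_d)
            mean_d = cov_d @ (prior_prec_d @ subj[m] + Wd @ theta_hats[d])
            sess[d] = rng.multivariate_normal(mean_d, cov_d)
    # respect bounded domains
    for p, tr in enumerate(model.transforms):
        if tr is not None:
            subj[:, p] = tr.clip(subj[:, p], margin=0.0)
            sess[:, p] = tr.clip(sess[:, p], margin=0.0)
    return subj, sess


def fit_map(
    model: HierarchicalModel,
    datasets: Sequence,
    subject_of_session: Sequence[int],
    subject_ids: Sequence[str],
    session_ids: Sequence[str],
    seed: int = 0,
    n_draws: int = 1000,
    init_grand: np.ndarray | None = None,
) -> PosteriorDraws:
    """Marginalised MAP + Laplace fit (see module docstring)."""
    D, M, P = len(datasets), len(subject_ids), model.n_params
    subject_of = np.asarray(subject_of_session, dtype=int)
    start_c = np.array(model.mu0 if init_grand is None else init_grand, dtype=float)

    theta_hats, Vs = [], []
    for data in datasets:
        th, V = _session_mle(model, data, start_c)
        theta_hats.append(th)
        Vs.append(V)
    theta_hats = np.array(theta_hats)

    phi0 = np.concatenate(
        [_grand_unconstrain(model, theta_hats.mean(axis=0)),
         np.full(P, -1.0), np.full(P, -1.0)]
    )

    def neg(phi):
        return _marginal_neg_log_post(model, phi, theta_hats, Vs, subject_of, M)

    res = optimize.minimize(neg, phi0, method="L-BFGS-B", options={"maxiter": 2000})
    phi_map = res.x
    if not res.success:
        warnings.warn(f"hyperparameter optimisation did not converge: {res.message}")

    # Laplace over phi (numeric Hessian of the marginal negative log posterior)
    n = phi_map.size
    H = np.empty((n, n))
    h = 1e-4 * (1.0 + np.abs(phi_map))
    f0 = neg(phi_map)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = neg(phi_map + ei + ej)
            fpm = neg(phi_map + ei - ej)
            fmp = neg(phi_map - ei + ej)
            fmm = neg(phi_map - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    jitter = 1e-8 * max(1.0, float(np.abs(np.diag(H)).max()))
    for _ in range(12):
        try:
            Lc = np.linalg.cholesky(H + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter *= 10.0
    else:  # pragma: no cover - pathological curvature
        raise RuntimeError("Laplace Hessian could not be regularised")

    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_draws, n))
    Phi = phi_map + solve_triangular(Lc, Z.T, lower=True, trans="T").T

    grand = np.empty((n_draws, P))
    subj = np.empty((n_draws, M, P))
    sess = np.empty((n_draws, D, P))
    scales = np.empty((n_draws, P))
    scales_s = np.empty((n_draws, P))
    for i, phi in enumerate(Phi):
        grand[i] = _grand_constrain(model, phi[:P])
        scales[i] = np.exp(phi[P : 2 * P])
        scales_s[i] = np.exp(phi[2 * P :])
        subj[i], sess[i] = _conditional_draws(
            model, phi, theta_hats, Vs, subject_of, M, rng
        )
    diagnostics = {
        "method": "marginal-map+laplace",
        "converged": bool(res.success),
        "optimizer_message": str(res.message),
        "neg_log_posterior": float(res.fun),
        "n_iter": int(res.nit),
        "hessian_jitter": float(jitter),
        "session_mles": theta_hats,
    }
    return PosteriorDraws(
        model.param_names, grand, subj, sess,
        tuple(subject_ids), tuple(session_ids), subject_of,
        scales=scales, scales_subject=scales_s,
        diagnostics=diagnostics, method="map",
    )


# ---------------------------------------------------------------------------
# Full joint posterior for the ensemble sampler
# ---------------------------------------------------------------------------


class _Layout:
    """Flat unconstrained vector:

    [session (D*P) | subject (M*P) | grand (P) | log tau (P) | log tau* (P)
     | corr y (K) | corr* y (K)]    with K = P(P-1)/2.
    """

    def __init__(self, P: int, D: int, M: int):
        self.P, self.D, self.M = P, D, M
        self.K = P * (P - 1) // 2
        self.n = D * P + M * P + 3 * P + 2 * self.K

    def split(self, x):
        P, D, M, K = self.P, self.D, self.M, self.K
        i = 0
        sess = x[i : i + D * P].reshape(D, P); i += D * P
        subj = x[i : i + M * P].reshape(M, P); i += M * P
        grand = x[i : i + P]; i += P
        ltau = x[i : i + P]; i += P
        ltau_s = x[i : i + P]; i += P
        y1 = x[i : i + K]; i += K
        y2 = x[i : i + K]
        return sess, subj, grand, ltau, ltau_s, y1, y2

    def join(self, sess, subj, grand, ltau, ltau_s, y1, y2):
        return np.concatenate(
            [sess.ravel(), subj.ravel(), grand, ltau, ltau_s, y1, y2]
        )


def _constrain_rows(model, u_rows):
    c = np.array(u_rows, dtype=float, copy=True)
    for p, tr in enumerate(model.transforms):
        if tr is not None:
            c[..., p] = tr.constrain(u_rows[..., p])
    return c


def _cpc_to_cholesky(y: np.ndarray, P: int, eta: float = 2.0):
    """Canonical partial correlations -> Cholesky factor of a correlation
    matrix, plus the LKJ(eta) log prior including transform Jacobians.

    Under the vine construction, LKJ(eta) corresponds to independent
    z_ij = tanh(y_ij) with density proportional to (1 - z^2)^(a_j - 1),
    a_j = eta + (P - 2 - j)/2 for column j; combined with the tanh Jacobian
    the log density in y is sum_j a_j * log(1 - z_ij^2).
    """
    z = np.tanh(y)
    L = np.zeros((P, P))
    L[0, 0] = 1.0
    lp = 0.0
    k = 0
    for i in range(1, P):
        rem = 1.0
        for j in range(i):
            a = eta + (P - 2 - j) / 2.0
            zij = z[k]
            lp += a * np.log1p(-zij * zij)
            L[i, j] = zij * np.sqrt(max(rem, 0.0))
            rem -= L[i, j] ** 2
            k += 1
        L[i, i] = np.sqrt(max(rem, 1e-300))
    return L, lp


def _mvn_logpdf_chol(x_minus_mu: np.ndarray, chol: np.ndarray) -> float:
    z = solve_triangular(chol, x_minus_mu.T, lower=True).T
    n, P = x_minus_mu.shape
    logdet = np.sum(np.log(np.diag(chol)))
    return float(-0.5 * np.sum(z * z) - n * (logdet + 0.5 * P * np.log(2 * np.pi)))


def _log_post_full(model, layout, datasets, subject_of, x):
    P = layout.P
    if np.any(np.abs(x) > 50):
        return -np.inf
    sess_u, subj_u, grand_u, ltau, ltau_s, y1, y2 = layout.split(x)
    tau, tau_s = np.exp(ltau), np.exp(ltau_s)
    sess_c = _constrain_rows(model, sess_u)
    subj_c = _constrain_rows(model, subj_u)
    grand_c = _constrain_rows(model, grand_u[None, :])[0]

    L1, lp_corr1 = _cpc_to_cholesky(y1, P)
    L2, lp_corr2 = _cpc_to_cholesky(y2, P)
    lp = lp_corr1 + lp_corr2
    for d, data in enumerate(datasets):
        lp += model.loglik_grad(sess_c[d], data)[0]
    lp += _mvn_logpdf_chol(sess_c - subj_c[subject_of], tau[:, None] * L1)
    lp += _mvn_logpdf_chol(subj_c - grand_c[None, :], tau_s[:, None] * L2)
    r = (grand_c - model.mu0) / model.sigma0
    lp += -0.5 * float(r @ r)
    for t, lt in ((tau, ltau), (tau_s, ltau_s)):
        lp += float(np.sum(-np.log1p(t * t) + lt))
    for p, tr in enumerate(model.transforms):
        if tr is None:
            continue
        lp += float(np.sum([tr.log_jac(v) for v in sess_u[:, p]]))
        lp += float(np.sum([tr.log_jac(v) for v in subj_u[:, p]]))
        lp += tr.log_jac(grand_u[p])
    return lp if np.isfinite(lp) else -np.inf


def fit_mcmc(
    model: HierarchicalModel,
    datasets: Sequence,
    subject_of_session: Sequence[int],
    subject_ids: Sequence[str],
    session_ids: Sequence[str],
    seed: int = 0,
    sampler: SamplerConfig | None = None,
    init_grand: np.ndarray | None = None,
) -> PosteriorDraws:
    """Full-model posterior sampling with an affine-invariant ensemble.

    ``sampler.chains`` independent ensembles are run; each discards
    ``warmup`` steps and retains ``samples``.  Split R-hat across ensembles
    is computed on the grand-level parameters (target < 1.05).
    """
    import emcee

    cfg = sampler or SamplerConfig()
    D, M, P = len(datasets), len(subject_ids), model.n_params
    layout = _Layout(P, D, M)
    subject_of = np.asarray(subject_of_session, dtype=int)

    # centre the ensembles on the marginalised-MAP solution
    warm = fit_map(
        model, datasets, subject_of_session, subject_ids, session_ids,
        seed=seed, n_draws=2, init_grand=init_grand,
    )
    theta_hats = warm.diagnostics["session_mles"]
    grand_c = np.median(warm.grand, axis=0)
    subj_c = np.tile(grand_c, (M, 1))
    sess_u = np.array(theta_hats)
    for p, tr in enumerate(model.transforms):
        if tr is not None:
            sess_u[:, p] = tr.unconstrain(tr.clip(sess_u[:, p], margin=1e-4))
            subj_c[:, p] = tr.unconstrain(subj_c[:, p])
    grand_u = _grand_unconstrain(model, grand_c)
    x0 = layout.join(
        sess_u, subj_c, grand_u, np.full(P, -1.0), np.full(P, -1.0),
        np.zeros(layout.K), np.zeros(layout.K),
    )

    def logp(x):
        return _log_post_full(model, layout, datasets, subject_of, x)

    ndim = layout.n
    nwalkers = cfg.walkers or max(2 * ndim + 2, 8)
    rng = np.random.default_rng(seed)
    chains_grand, all_draws, acc = [], [], []
    for _ in range(cfg.chains):
        p0 = x0 + 0.02 * rng.standard_normal((nwalkers, ndim))
        es = emcee.EnsembleSampler(nwalkers, ndim, logp)
        es.random_state = np.random.RandomState(int(rng.integers(2**31))).get_state()
        state = es.run_mcmc(p0, cfg.warmup, progress=False)
        es.reset()
        es.run_mcmc(state, cfg.samples, thin_by=cfg.thin, progress=False)
        chain = es.get_chain()  # (steps, walkers, ndim)
        acc.append(float(np.mean(es.acceptance_fraction)))
        all_draws.append(chain.reshape(-1, ndim))
        g_cols = slice((D + M) * P, (D + M) * P + P)
        chains_grand.append(chain[:, :, g_cols].mean(axis=1))
    X = np.concatenate(all_draws, axis=0)

    n = X.shape[0]
    sess = np.empty((n, D, P))
    subj = np.empty((n, M, P))
    grand = np.empty((n, P))
    scales = np.empty((n, P))
    scales_s = np.empty((n, P))
    for i, x in enumerate(X):
        s_u, m_u, g_u, lt, lts, _, _ = layout.split(x)
        sess[i] = _constrain_rows(model, s_u)
        subj[i] = _constrain_rows(model, m_u)
        grand[i] = _constrain_rows(model, g_u[None, :])[0]
        scales[i] = np.exp(lt)
        scales_s[i] = np.exp(lts)

    rhat = _split_rhat(np.stack(chains_grand))
    diagnostics = {
        "method": "emcee",
        "split_rhat_grand": {nm: float(r) for nm, r in zip(model.param_names, rhat)},
        "max_split_rhat": float(np.max(rhat)),
        "mean_acceptance_fraction": float(np.mean(acc)),
        "converged": bool(np.max(rhat) < 1.05),
    }
    if np.max(rhat) >= 1.05:
        warnings.warn(
            f"ensemble chains may not have converged: max split R-hat = {np.max(rhat):.3f}"
        )
    return PosteriorDraws(
        model.param_names, grand, subj, sess,
        tuple(subject_ids), tuple(session_ids), subject_of,
        scales=scales, scales_subject=scales_s,
        diagnostics=diagnostics, method="mcmc",
    )


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Rank-normalised split R-hat per parameter; ``chains`` (C, steps, P)."""
    import arviz as az

    C, S, P = chains.shape
    half = S // 2
    split = np.concatenate([chains[:, :half, :], chains[:, half : 2 * half, :]], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(az.convert_to_dataset(split))
    return np.asarray(r.to_array()).reshape(-1)
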