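"""Move-persistence mixed-effects model (MPMM).

Latent move persistence gamma_t in (0,1) scales the previous displacement
of a first-difference correlated random walk,

    d_t = gamma_t * d_{t-1} + eta_t,      eta_t ~ N(0, Sigma_d),
    logit(gamma_t,k) = beta_0 + b_k + sum_j beta_j x_{t,j} + eps_t,

with individual random intercepts b_k ~ N(0, sigma_b^2) and iid step noise
eps_t ~ N(0, sigma_gamma^2).  The marginal likelihood integrates the latent
vector (b_k, eps_t) by a Laplace approximation: an inner Newton solve for
the joint-density mode exploiting the arrowhead sparsity of the Hessian
(eps are conditionally independent given b), then a Gaussian curvature
correction.  Fixed parameters are estimated by quasi-Newton ML; the free
parameters are beta, log sigma_b, log sigma_gamma and the three-parameter
displacement covariance (two log-SDs and an atanh correlation), so the
covariate-free model has k = 6 estimated parameters and each added fixed
covariate adds one.

Also provides AIC ranking with the within-2-dAIC fewest-parameters rule,
leave-one-individual-out cross validation, one-step-ahead residuals, and a
brute-force adaptive Gauss-Hermite quadrature marginal likelihood used as
an independent cross-check on tiny instances.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_hess1


def _central_grad(f, x, h):
    g = np.zeros(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi

#: candidate set naming scheme: environmental (env), prey-informed (fish),
#: diversity (div) and intercept-only (null) models
DEFAULT_MODEL_SET = {
    "env1": ("sst", "bathy"),
    "env2": ("bathy",),
    "env3": ("sst",),
    "fish1": ("biomass_all",),
    "fish2": ("biomass_arctic_cod",),
    "fish3": ("biomass_capelin",),
    "fish4": ("biomass_n_sand_lance",),
    "fish5": ("biomass_all", "bathy"),
    "fish6": ("biomass_arctic_cod", "bathy"),
    "fish7": ("biomass_capelin", "bathy"),
    "fish8": ("biomass_n_sand_lance", "bathy"),
    "div1": ("diversity",),
    "div2": ("diversity", "bathy"),
    "null1": (),
}


class FormulaError(ValueError):
    pass


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class MpmmFormula:
    """``gamma ~ cov1 + cov2 + (1|id)``: fixed covariates plus a random
    intercept per individual (random slopes are not supported)."""

    covariates: tuple

    @property
    def text(self) -> str:
        terms = list(self.covariates) + ["(1 | id)"]
        return "gamma ~ " + " + ".join(terms) if self.covariates else "gamma ~ (1 | id)"


def parse_formula(text: str) -> MpmmFormula:
    """Parse the mini-language ``gamma ~ a + b + (1|id)`` (or ``~ ...``)."""
    rhs = text.split("~", 1)[1] if "~" in text else text
    terms = [t.strip() for t in rhs.split("+") if t.strip()]
    covs = []
    saw_ri = False
    for t in terms:
        if re.fullmatch(r"\(\s*1\s*\|\s*id\s*\)", t):
            saw_ri = True
        elif t == "1":
            continue
        elif re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", t):
            covs.append(t)
        else:
            raise FormulaError(f"unsupported term {t!r} (random slopes are not supported)")
    if not saw_ri:
        raise FormulaError("formula must include the (1|id) random intercept")
    return MpmmFormula(tuple(covs))


# ---------------------------------------------------------------------------
# data container


@dataclass
class MpmmData:
    """Flattened modelled steps for one or more individuals.

    One row per modelled displacement: its predecessor ``dprev``, the
    displacement itself ``dcur`` (both km), the design row ``X`` (intercept
    plus scaled covariates), and individual/segment/time bookkeeping.
    """

    ind_ids: list
    covariate_names: tuple
    dprev: np.ndarray  # (n, 2)
    dcur: np.ndarray  # (n, 2)
    X: np.ndarray  # (n, 1 + p)
    ind: np.ndarray  # (n,) individual index into ind_ids
    seg_id: np.ndarray  # (n,) segment label per step
    time: np.ndarray  # (n,) datetime64 of the step's origin position

    @property
    def n_steps(self) -> int:
        return len(self.ind)

    @property
    def n_individuals(self) -> int:
        return len(self.ind_ids)

    def with_covariates(self, names) -> "MpmmData":
        """Restrict the design matrix to (intercept + the named covariates)."""
        idx = [0] + [1 + list(self.covariate_names).index(nm) for nm in names]
        return MpmmData(self.ind_ids, tuple(names), self.dprev, self.dcur,
                        self.X[:, idx], self.ind, self.seg_id, self.time)

    def drop_individual(self, ind_id) -> "MpmmData":
        k = self.ind_ids.index(ind_id)
        keep = self.ind != k
        ids = [i for i in self.ind_ids if i != ind_id]
        remap = np.array([ids.index(i) if i != ind_id else -1 for i in self.ind_ids])
        return MpmmData(ids, self.covariate_names, self.dprev[keep], self.dcur[keep],
                        self.X[keep], remap[self.ind[keep]], self.seg_id[keep],
                        self.time[keep])


def build_data(regular_tracks: list, cov_table: pd.DataFrame, covariate_names) -> MpmmData:
    """Assemble MpmmData from regularized tracks and a scaled covariate table.

    ``cov_table`` must hold one row per (seg_id, date) with ``<name>_z``
    columns for every requested covariate; steps whose origin location is
    unmatched are dropped (with a logged count).  Segments of the same
    individual share that individual's random intercept; the first
    displacement of every segment is conditioned on, never modelled.
    """
    names = tuple(covariate_names)
    zcols = [f"{nm}_z" for nm in names]
    tab = cov_table.set_index(["seg_id", pd.to_datetime(cov_table["date"])])
    ind_ids = sorted({t.individual for t in regular_tracks})
    rows_dprev, rows_dcur, rows_X, rows_ind, rows_seg, rows_time = [], [], [], [], [], []
    n_dropped = 0
    for tr in regular_tracks:
        pos = np.column_stack([tr.x_km, tr.y_km])
        d = np.diff(pos, axis=0)  # (L-1, 2)
        if len(d) < 2:
            continue
        for i in range(1, len(d)):
            key = (tr.seg_id, tr.times[i])
            try:
                row = tab.loc[key]
            except KeyError:
                n_dropped += 1
                continue
            z = np.asarray([row[c] for c in zcols], dtype=float)
            if ("matched" in row and not bool(row["matched"])) or not np.all(np.isfinite(z)):
                n_dropped += 1
                continue
            rows_dprev.append(d[i - 1])
            rows_dcur.append(d[i])
            rows_X.append(np.concatenate([[1.0], z]))
            rows_ind.append(ind_ids.index(tr.individual))
            rows_seg.append(tr.seg_id)
            rows_time.append(tr.times[i].to_datetime64())
    if n_dropped:
        logger.warning("dropped %d modelled steps lacking matched covariates", n_dropped)
    return MpmmData(
        ind_ids, names,
        np.asarray(rows_dprev, dtype=float), np.asarray(rows_dcur, dtype=float),
        np.asarray(rows_X, dtype=float), np.asarray(rows_ind, dtype=int),
        np.asarray(rows_seg, dtype=object), np.asarray(rows_time),
    )


def build_data_from_truth(truths: list, covariate_names, rescale: bool = False) -> MpmmData:
    """MpmmData straight from simulated truth tracks (no SSM stage).

    Used for estimator-only studies: displacements from the true lattice
    positions, covariates exactly as the simulator standardized them (per
    field SD), so estimates are on the same scale as the generative
    coefficients.  ``rescale=True`` re-z-scores over the modelled rows
    instead, mimicking the pipeline's within-year scaling (which changes
    the estimand by the ratio of along-track to field SD).
    """
    names = tuple(covariate_names)
    ind_ids = [t.individual for t in truths]
    dprev, dcur, X, ind, seg, tm = [], [], [], [], [], []
    for k, tr in enumerate(truths):
        pos = np.column_stack([tr.x_km, tr.y_km])
        d = np.diff(pos, axis=0)
        for i in range(1, len(d)):
            dprev.append(d[i - 1])
            dcur.append(d[i])
            X.append(np.concatenate([[1.0], [tr.covariates[nm][i] for nm in names]]))
            ind.append(k)
            seg.append(tr.individual)
            tm.append(tr.times[i].to_datetime64())
    X = np.asarray(X, dtype=float)
    if rescale and X.shape[1] > 1:
        mu = X[:, 1:].mean(axis=0)
        sd = X[:, 1:].std(axis=0, ddof=1)
        X[:, 1:] = (X[:, 1:] - mu) / sd
    return MpmmData(ind_ids, names, np.asarray(dprev), np.asarray(dcur), X,
                    np.asarray(ind, dtype=int), np.asarray(seg, dtype=object),
                    np.asarray(tm))


def simulate_instance(theta, n_steps: int, n_ind: int, seed: int) -> MpmmData:
    """Simulate a minimal model-consistent dataset at parameters ``theta``.

    Draws covariate values iid N(0,1), intercepts and step noise from the
    model, and displacement chains from the first-difference CRW.  Used
    for likelihood-level studies (e.g. quadrature cross-checks) where the
    full spatial simulator would be overkill.
    """
    rng = np.random.default_rng(seed)
    p = len(theta) - 6
    beta, sigma_b, sigma_g, Sd = _unpack(np.asarray(theta, dtype=float), p)
    chol = np.linalg.cholesky(Sd)
    dprev, dcur, X, ind = [], [], [], []
    for k in range(n_ind):
        b = rng.normal(0.0, sigma_b)
        d = chol @ rng.standard_normal(2)
        for _ in range(n_steps):
            x = rng.normal(0.0, 1.0, p)
            z = beta[0] + float(x @ beta[1:]) + b + rng.normal(0.0, sigma_g)
            d_new = expit(z) * d + chol @ rng.standard_normal(2)
            dprev.append(d)
            dcur.append(d_new)
            X.append(np.concatenate([[1.0], x]))
            ind.append(k)
            d = d_new
    n = len(ind)
    return MpmmData(
        [f"i{k}" for k in range(n_ind)], tuple(f"x{j}" for j in range(p)),
        np.asarray(dprev), np.asarray(dcur), np.asarray(X),
        np.asarray(ind, dtype=int), np.asarray([f"i{k}_s0" for k in ind], dtype=object),
        np.arange(n).astype("datetime64[s]"),
    )


# ---------------------------------------------------------------------------
# Laplace marginal likelihood


def _unpack(theta: np.ndarray, p: int):
    beta = theta[: p + 1]
    sigma_b = np.exp(theta[p + 1])
    sigma_g = np.exp(theta[p + 2])
    s1, s2 = np.exp(theta[p + 3]), np.exp(theta[p + 4])
    rho = np.tanh(theta[p + 5])
    Sd = np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])
    return beta, sigma_b, sigma_g, Sd


def n_params(n_covariates: int) -> int:
    """Estimated-parameter count: intercept, sigma_b, sigma_gamma, three
    displacement-covariance parameters, plus one slope per covariate."""
    return 6 + n_covariates


class _LaplaceNll:
    """Callable negative Laplace marginal log-likelihood with mode caching."""

    def __init__(self, data: MpmmData, inner_tol: float = 1e-9, inner_maxit: int = 100):
        self.data = data
        self.inner_tol = inner_tol
        self.inner_maxit = inner_maxit
        self._u = np.zeros(data.n_steps + data.n_individuals)
        # per-step quadratic-form constants depend on Sigma_d only
        self._Sd_key = None

    def _quadforms(self, Sd):
        key = Sd.tobytes()
        if key != self._Sd_key:
            Si = np.linalg.inv(Sd)
            dp, dc = self.data.dprev, self.data.dcur
            self._q = np.einsum("ni,ij,nj->n", dp, Si, dp)
            self._c = np.einsum("ni,ij,nj->n", dp, Si, dc)
            self._a = np.einsum("ni,ij,nj->n", dc, Si, dc)
            self._Sd_key = key
        return self._q, self._c, self._a

    def _joint_parts(self, eps, b, beta, sigma_b, sigma_g, Sd):
        d = self.data
        q, c, a = self._quadforms(Sd)
        z = d.X @ beta + b[d.ind] + eps
        gam = expit(z)
        logdet_Sd = np.log(Sd[0, 0] * Sd[1, 1] - Sd[0, 1] * Sd[1, 0])
        f = (
            d.n_steps * (np.log(_TWO_PI) + 0.5 * logdet_Sd)
            + 0.5 * np.sum(a - 2.0 * gam * c + gam * gam * q)
            + d.n_steps * 0.5 * np.log(_TWO_PI * sigma_g**2)
            + 0.5 * np.sum(eps * eps) / sigma_g**2
            + d.n_individuals * 0.5 * np.log(_TWO_PI * sigma_b**2)
            + 0.5 * np.sum(b * b) / sigma_b**2
        )
        return f, z, gam, q, c

    def __call__(self, theta: np.ndarray) -> float:
        d = self.data
        p = len(d.covariate_names)
        beta, sigma_b, sigma_g, Sd = _unpack(np.asarray(theta, dtype=float), p)
        n, K = d.n_steps, d.n_individuals
        eps = self._u[:n].copy()
        b = self._u[n:].copy()

        f, z, gam, q, c = self._joint_parts(eps, b, beta, sigma_b, sigma_g, Sd)
        ivg, ivb = 1.0 / sigma_g**2, 1.0 / sigma_b**2
        for _ in range(self.inner_maxit):
            gp = gam * (1.0 - gam)
            s = gam * q - c
            dfdz = s * gp
            w = np.maximum(gp * gp * q + s * gp * (1.0 - 2.0 * gam), 1e-9)
            g_eps = dfdz + eps * ivg
            g_b = np.bincount(d.ind, weights=dfdz, minlength=K) + b * ivb
            if max(np.max(np.abs(g_eps)), np.max(np.abs(g_b))) < self.inner_tol:
                break
            h = w + ivg
            B = np.bincount(d.ind, weights=w, minlength=K) + ivb
            schur = B - np.bincount(d.ind, weights=w * w / h, minlength=K)
            rhs_b = g_b - np.bincount(d.ind, weights=w * g_eps / h, minlength=K)
            db = -rhs_b / schur
            deps = -(g_eps + w * db[d.ind]) / h
            # backtracking on the joint density; stop when no measurable
            # progress is possible (mode located to numerical precision)
            step = 1.0
            accepted = False
            for _ in range(25):
                f_new, z_t, gam_t, q, c = self._joint_parts(
                    eps + step * deps, b + step * db, beta, sigma_b, sigma_g, Sd)
                if f_new <= f + 1e-11 * (1.0 + abs(f)):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            eps = eps + step * deps
            b = b + step * db
            converged_f = f - f_new < 1e-13 * (1.0 + abs(f))
            f, z, gam = f_new, z_t, gam_t
            if converged_f:
                break

        self._u = np.concatenate([eps, b])
        # curvature at the mode (exact Hessian, arrowhead structure)
        gp = gam * (1.0 - gam)
        s = gam * q - c
        w = gp * gp * q + s * gp * (1.0 - 2.0 * gam)
        h = np.maximum(w + ivg, 1e-10)
        B = np.bincount(d.ind, weights=w, minlength=K) + ivb
        schur = np.maximum(B - np.bincount(d.ind, weights=w * w / h, minlength=K), 1e-10)
        logdet = np.sum(np.log(h)) + np.sum(np.log(schur))
        return f - 0.5 * (n + K) * np.log(_TWO_PI) + 0.5 * logdet

    def latent_mode(self, theta):
        """(eps_hat, b_hat, gamma_hat) at the cached mode for ``theta``."""
        self(theta)
        d = self.data
        eps, b = self._u[: d.n_steps], self._u[d.n_steps:]
        p = len(d.covariate_names)
        beta = np.asarray(theta, dtype=float)[: p + 1]
        z = d.X @ beta + b[d.ind] + eps
        return eps, b, expit(z)

    def aghq(self, theta: np.ndarray, n_nodes: int = 7) -> float:
        """Nested adaptive Gauss-Hermite marginal negative log-likelihood.

        Exploits the model's conditional-independence structure: given the
        individual's intercept b, the per-step latents eps_t factorize, so
        the marginal is a 1-D integral over b of a product of 1-D integrals
        over eps_t.  Each 1-D integral is adaptive Gauss-Hermite centered
        at its conditional mode; the b grid is centered at the joint-mode b
        with the Laplace (Schur-complement) curvature.  Much more accurate
        than the plain Laplace value at small T, at a constant-factor cost.
        """
        d = self.data
        p = len(d.covariate_names)
        beta, sigma_b, sigma_g, Sd = _unpack(np.asarray(theta, dtype=float), p)
        self(theta)  # locate the joint mode (cached in self._u)
        n, K = d.n_steps, d.n_individuals
        eps_hat = self._u[:n].copy()
        b_hat = self._u[n:].copy()
        ivg, ivb = 1.0 / sigma_g**2, 1.0 / sigma_b**2
        q, c, a = self._quadforms(Sd)
        logdet_Sd = np.log(Sd[0, 0] * Sd[1, 1] - Sd[0, 1] * Sd[1, 0])
        const_step = (np.log(_TWO_PI) + 0.5 * logdet_Sd
                      + 0.5 * np.log(_TWO_PI * sigma_g**2))
        xb = d.X @ beta

        # outer scale for b from the arrowhead curvature at the joint mode
        z = xb + b_hat[d.ind] + eps_hat
        gam = expit(z)
        gp = gam * (1.0 - gam)
        s = gam * q - c
        w = gp * gp * q + s * gp * (1.0 - 2.0 * gam)
        h = np.maximum(w + ivg, 1e-10)
        B = np.bincount(d.ind, weights=w, minlength=K) + ivb
        schur = np.maximum(B - np.bincount(d.ind, weights=w * w / h, minlength=K), 1e-10)
        sb_hat = 1.0 / np.sqrt(schur)

        nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
        lognw = np.log(wts) + nodes**2
        logq = np.empty((K, n_nodes))
        for m in range(n_nodes):
            b_m = b_hat + np.sqrt(2.0) * sb_hat * nodes[m]
            zb = xb + b_m[d.ind]
            e = eps_hat.copy()
            for _ in range(50):
                ze = zb + e
                gam = expit(ze)
                gp = gam * (1.0 - gam)
                st = gam * q - c
                g1 = st * gp + e * ivg
                h1 = np.maximum(gp * gp * q + st * gp * (1.0 - 2.0 * gam), 0.0) + ivg
                step = g1 / h1
                e -= step
                if np.max(np.abs(step)) < 1e-10:
                    break
            ze = zb + e
            gam = expit(ze)
            gp = gam * (1.0 - gam)
            st = gam * q - c
            h_e = np.maximum(gp * gp * q + st * gp * (1.0 - 2.0 * gam) + ivg, 1e-10)
            sd_e = 1.0 / np.sqrt(h_e)
            acc = np.full(n, -np.inf)
            for j in range(n_nodes):
                ej = e + np.sqrt(2.0) * sd_e * nodes[j]
                gj = expit(zb + ej)
                phi = (0.5 * (a - 2.0 * gj * c + gj * gj * q) + const_step
                       + 0.5 * ej * ej * ivg)
                acc = np.logaddexp(acc, lognw[j] - phi)
            log_g = 0.5 * np.log(2.0) + np.log(sd_e) + acc
            logq[:, m] = (np.bincount(d.ind, weights=log_g, minlength=K)
                          - 0.5 * np.log(_TWO_PI * sigma_b**2)
                          - 0.5 * b_m * b_m * ivb)
        log_lik = (0.5 * np.log(2.0) + np.log(sb_hat)
                   + logsumexp(lognw[None, :] + logq, axis=1))
        return -float(np.sum(log_lik))


def mpmm_negloglik(theta, data: MpmmData, method: str = "aghq",
                   n_nodes: int = 7) -> float:
    """Negative marginal log-likelihood of the displacements at ``theta``.

    ``theta`` = (beta_0..beta_p, log sigma_b, log sigma_gamma, log sd1,
    log sd2, atanh rho); the transform keeps every reachable point in the
    feasible region (positive SDs, |rho| < 1, positive-definite Sigma_d).

    ``method="aghq"`` (default) integrates the latents by nested adaptive
    Gauss-Hermite quadrature seeded at the Laplace mode; ``"laplace"``
    returns the plain Laplace approximation (faster, biased by O(1e-2) on
    very short series).
    """
    nll = _LaplaceNll(data)
    if method == "laplace":
        return nll(theta)
    if method == "aghq":
        return nll.aghq(theta, n_nodes=n_nodes)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# quadrature cross-check (independent path: generic optimizer + tensor GH)


def ghq_marginal_nll(theta, data: MpmmData, n_nodes: int = 12) -> float:
    """Adaptive Gauss-Hermite marginal negative log-likelihood.

    Brute force over all latent dimensions (eps per step + b per
    individual); only feasible for tiny instances (<= ~5 latent dims).
    Centering/scaling uses a generic BFGS mode search and a numerical
    Hessian, independent of the arrowhead Newton machinery.
    """
    d = data
    p = len(d.covariate_names)
    beta, sigma_b, sigma_g, Sd = _unpack(np.asarray(theta, dtype=float), p)
    Si = np.linalg.inv(Sd)
    _, logdet_Sd = np.linalg.slogdet(Sd)
    n, K = d.n_steps, d.n_individuals
    dim = n + K
    if dim > 6:
        raise ValueError("quadrature cross-check limited to <= 6 latent dimensions")

    def f(u):
        eps, b = u[:n], u[n:]
        z = d.X @ beta + b[d.ind] + eps
        gam = expit(z)
        r = d.dcur - gam[:, None] * d.dprev
        val = n * (np.log(_TWO_PI) + 0.5 * logdet_Sd)
        val += 0.5 * np.einsum("ni,ij,nj->", r, Si, r)
        val += n * 0.5 * np.log(_TWO_PI * sigma_g**2) + 0.5 * np.sum(eps**2) / sigma_g**2
        val += K * 0.5 * np.log(_TWO_PI * sigma_b**2) + 0.5 * np.sum(b**2) / sigma_b**2
        return val

    res = minimize(f, np.zeros(dim), method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    mode = res.x
    H = approx_hess1(mode, f)
    H = 0.5 * (H + H.T)
    L = np.linalg.cholesky(np.linalg.inv(H))

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(weights) + nodes**2  # absorb the e^{-x^2} GH weight
    total = -np.inf
    f0 = f(mode)
    for combo in itertools.product(range(n_nodes), repeat=dim):
        zvec = np.sqrt(2.0) * nodes[list(combo)]
        u = mode + L @ zvec
        lw = np.sum(logw[list(combo)]) - (f(u) - f0)
        total = np.logaddexp(total, lw)
    # integral = |L| * 2^{dim/2} * sum(w_i e^{x^2} e^{-f}) with f shifted by f0
    log_integral = total - f0 + np.linalg.slogdet(L)[1] + 0.5 * dim * np.log(2.0)
    return -log_integral


# ---------------------------------------------------------------------------
# fitting


@dataclass
class MpmmFit:
    """ML fit of the move-persistence mixed-effects model."""

    formula: MpmmFormula
    beta: np.ndarray
    beta_se: np.ndarray
    beta_ci: np.ndarray  # (p+1, 2) Wald 95% intervals
    sigma_b: float
    sigma_gamma: float
    disp_cov: np.ndarray
    b_hat: np.ndarray
    gamma_hat: np.ndarray
    loglik: float
    k: int
    aic: float
    converged: bool
    grad_norm: float
    theta: np.ndarray = field(repr=False, default=None)
    n_steps: int = 0
    ind_ids: list = field(default_factory=list)
    seg_id: np.ndarray = field(repr=False, default=None)
    time: np.ndarray = field(repr=False, default=None)

    @property
    def term_names(self) -> list:
        return ["(Intercept)"] + list(self.formula.covariates)

    def gamma_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"seg_id": self.seg_id, "date": self.time,
                             "gamma_hat": self.gamma_hat})

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.term_names, "estimate": self.beta, "se": self.beta_se,
            "ci_lo": self.beta_ci[:, 0], "ci_hi": self.beta_ci[:, 1],
        })


def fit_mpmm(data: MpmmData, formula: MpmmFormula | str, grad_tol: float = 1e-3,
             maxiter: int = 300, likelihood: str = "aghq",
             theta_start: np.ndarray | None = None) -> MpmmFit:
    """Maximize the marginal likelihood by L-BFGS-B.

    Starting values: beta = 0, sigma_b = sigma_gamma = 0.5, Sigma_d from
    the empirical displacement covariance.  Standard errors come from the
    inverse numerical Hessian of the negative marginal log-likelihood;
    CIs are Wald (+- 1.96 SE).
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if data.n_individuals < 2:
        raise ValueError("need >= 2 individuals to identify sigma_b")
    sub = data.with_covariates(formula.covariates)
    p = len(formula.covariates)
    engine = _LaplaceNll(sub)
    nll = engine.aghq if likelihood == "aghq" else engine

    emp = np.cov(sub.dcur.T, ddof=0)
    s1 = max(np.sqrt(emp[0, 0]), 1e-3)
    s2 = max(np.sqrt(emp[1, 1]), 1e-3)
    rho = np.clip(emp[0, 1] / (s1 * s2), -0.95, 0.95)
    theta0 = np.concatenate([
        np.zeros(p + 1),
        [np.log(0.5), np.log(0.5), np.log(s1), np.log(s2), np.arctanh(rho)],
    ])
    # sigma_b and sigma_gamma live on the logit scale: beyond an SD of ~2
    # the logistic-normal law on gamma turns U-shaped (mass piles at 0/1),
    # the model degenerates into an unidentifiable per-step switch with a
    # spurious likelihood spike, and mode-centred integration loses its
    # unimodality assumption — the feasible box stops before that regime
    bounds = [(None, None)] * (p + 1) + [(-7, 0.7), (-7, 0.7), (-8, 6), (-8, 6), (-5, 5)]
    if theta_start is not None:
        # e.g. a warm start from a fit on closely related data (LOO refits)
        theta0 = np.asarray(theta_start, dtype=float).copy()
    elif likelihood == "aghq":
        # cheap Laplace pass to land near the optimum, then AGHQ refinement
        pre = minimize(engine, theta0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-5,
                                "eps": 1e-5})
        if np.all(np.isfinite(pre.x)):
            theta0 = pre.x
    res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7,
                            "eps": 1e-5})
    theta = res.x
    grad_norm = float(np.max(np.abs(_central_grad(nll, theta, 1e-3))))
    converged = bool(res.success) and np.all(np.isfinite(theta))
    if not converged:
        logger.warning("MPMM fit did not converge (%s; grad inf-norm %.3g)",
                       res.message, grad_norm)

    # Hessian step sized well above the inner-solver noise floor
    H = approx_hess1(theta, nll, epsilon=2e-3)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_all = np.full(len(theta), np.nan)
    beta, sigma_b, sigma_g, Sd = _unpack(theta, p)
    beta_se = se_all[: p + 1]
    ci = np.column_stack([beta - 1.96 * beta_se, beta + 1.96 * beta_se])

    _, b_hat, gamma_hat = engine.latent_mode(theta)
    loglik = -float(nll(theta))
    k = n_params(p)
    return MpmmFit(
        formula=formula, beta=beta, beta_se=beta_se, beta_ci=ci,
        sigma_b=float(sigma_b), sigma_gamma=float(sigma_g), disp_cov=Sd,
        b_hat=b_hat, gamma_hat=gamma_hat, loglik=loglik, k=k,
        aic=2.0 * k - 2.0 * loglik, converged=converged, grad_norm=grad_norm,
        theta=theta, n_steps=sub.n_steps, ind_ids=list(sub.ind_ids),
        seg_id=sub.seg_id, time=sub.time,
    )


# ---------------------------------------------------------------------------
# ranking, cross validation, residuals


def rank_models(fits: dict) -> pd.DataFrame:
    """AIC table with the parsimony tie rule.

    Sorted ascending by AIC; among models with dAIC < 2 of the best, the
    one with fewest parameters is selected (ties on k broken by lower
    AIC).  Refuses unconverged fits or fits on differing data sizes.
    """
    if not fits:
        raise RankingError("no fits to rank")
    sizes = {f.n_steps for f in fits.values()}
    if len(sizes) != 1:
        raise RankingError(f"fits were run on differing data sizes: {sorted(sizes)}")
    bad = [name for name, f in fits.items() if not f.converged]
    if bad:
        raise RankingError(f"unconverged fits cannot be ranked: {bad}")
    rows = [
        {"model": name, "formula": f.formula.text, "k": f.k, "aic": f.aic,
         "loglik": f.loglik}
        for name, f in fits.items()
    ]
    tab = pd.DataFrame(rows).sort_values(["aic", "k"], kind="stable").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    near = tab[tab["delta_aic"] < 2.0]
    sel = near.sort_values(["k", "aic"], kind="stable").index[0]
    tab["selected"] = False
    tab.loc[sel, "selected"] = True
    return tab


@dataclass
class LooResult:
    """Leave-one-individual-out refits and CI coverage of the full model."""

    left_out: list
    estimates: np.ndarray  # (n_refits, p+1)
    inside: np.ndarray  # boolean, same shape
    coverage: float
    n_failed: int


def loo_cv(data: MpmmData, formula: MpmmFormula | str, full_fit: MpmmFit | None = None) -> LooResult:
    """Refit once per left-out individual; coverage is the fraction of
    refitted fixed-effect estimates inside the full model's 95% CIs."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if data.n_individuals < 3:
        raise ValueError("leave-one-out needs >= 3 individuals")
    if full_fit is None:
        full_fit = fit_mpmm(data, formula)
    left_out, est, inside = [], [], []
    n_failed = 0
    for ind_id in data.ind_ids:
        sub = data.drop_individual(ind_id)
        refit = fit_mpmm(sub, formula, theta_start=full_fit.theta)
        if not refit.converged:
            n_failed += 1
            logger.warning("LOO refit without %s did not converge; excluded", ind_id)
            continue
        left_out.append(ind_id)
        est.append(refit.beta)
        inside.append((refit.beta >= full_fit.beta_ci[:, 0])
                      & (refit.beta <= full_fit.beta_ci[:, 1]))
    est = np.asarray(est)
    inside = np.asarray(inside)
    coverage = float(inside.mean()) if inside.size else np.nan
    return LooResult(left_out, est, inside, coverage, n_failed)


def osa_residuals(fit: MpmmFit, data: MpmmData) -> pd.DataFrame:
    """One-step-ahead displacement residuals from a converged fit.

    The prediction uses the fixed effects and the individual's estimated
    intercept only (eps_t predicted at zero, so no information from the
    current displacement leaks in):  resid = (d_t - gamma_pred * d_{t-1})
    / sd, standardized per coordinate by the displacement-noise SD.
    """
    if not fit.converged:
        raise ValueError("residuals require a converged fit")
    sub = data.with_covariates(fit.formula.covariates)
    z = sub.X @ fit.beta + fit.b_hat[sub.ind]
    gam = expit(z)
    r = sub.dcur - gam[:, None] * sub.dprev
    sd = np.sqrt(np.diag(fit.disp_cov))
    r = r / sd
    return pd.DataFrame({"seg_id": sub.seg_id, "date": sub.time,
                         "resid_x": r[:, 0], "resid_y": r[:, 1]})
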