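"""Dive-metric summaries and AR1 mixed-model validation.

Dives are matched to regularized locations within +-2 h (half the 4-h
lattice spacing, so at most one candidate location per dive except exact
boundary ties, which go to the later location).  Eight per-location metrics
are computed: number of dives, mean maximum depth, sum of dive time, mean
depth, cumulative (summed maximum) depth, mean bottom time, sum of bottom
time, and the mean proportion of the water column reached.

Validation models are linear mixed models y = a + b x + u_g + e with a
random intercept per track segment and AR1-correlated within-track
residuals, fitted by maximum likelihood with the fixed effects profiled
out by GLS; the slope SE comes from the GLS information (X' V^-1 X)^-1 and
the p-value is Wald.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

DIVE_METRICS = (
    "n_dives",
    "mean_max_depth",
    "sum_dive_time",
    "mean_depth",
    "cum_depth",
    "mean_bottom_time",
    "sum_bottom_time",
    "prop_water_column",
)


def summarize_dives(dives_df: pd.DataFrame, track_df: pd.DataFrame,
                    window_h: float = 2.0) -> pd.DataFrame:
    """Per-location dive metrics within +-``window_h`` hours.

    ``dives_df``: columns id, start, dur_s, max_dep_m, mean_dep_m, bottom_s.
    ``track_df``: one row per regularized location with id, seg_id, date and
    a ``bathy`` column (m elevation) for the water-column proportion.
    Returns ``track_df`` with the eight metric columns appended (metrics
    other than ``n_dives`` are NaN where no dive matched); dives with no
    location within the window are counted and logged.
    """
    out = track_df.copy().reset_index(drop=True)
    out["date"] = pd.to_datetime(out["date"])
    metrics = {m: np.full(len(out), np.nan) for m in DIVE_METRICS}
    metrics["n_dives"] = np.zeros(len(out))
    n_unassigned = 0
    n_capped = 0

    dv = dives_df.copy()
    dv["start"] = pd.to_datetime(dv["start"])
    for ind, dgrp in dv.groupby("id"):
        rows = out.index[out["id"] == ind]
        if len(rows) == 0:
            n_unassigned += len(dgrp)
            continue
        loc_t = out.loc[rows, "date"].to_numpy()
        order = np.argsort(loc_t)
        loc_t = loc_t[order]
        rows = rows.to_numpy()[order]
        starts = dgrp["start"].to_numpy()
        # nearest location; exact +-window ties resolve to the later one
        # because searchsorted('left') picks the right neighbour on a tie
        pos = np.searchsorted(loc_t, starts)
        cand_prev = np.clip(pos - 1, 0, len(loc_t) - 1)
        cand_next = np.clip(pos, 0, len(loc_t) - 1)
        dt_prev = np.abs((starts - loc_t[cand_prev]) / np.timedelta64(1, "h"))
        dt_next = np.abs((loc_t[cand_next] - starts) / np.timedelta64(1, "h"))
        pick = np.where(dt_next <= dt_prev, cand_next, cand_prev)
        dt = np.minimum(dt_prev, dt_next)
        ok = dt <= window_h
        n_unassigned += int((~ok).sum())

        assigned = pd.DataFrame({
            "row": rows[pick[ok]],
            "dur": dgrp["dur_s"].to_numpy()[ok],
            "maxd": dgrp["max_dep_m"].to_numpy()[ok],
            "meand": dgrp["mean_dep_m"].to_numpy()[ok],
            "bott": dgrp["bottom_s"].to_numpy()[ok],
        })
        for row, g in assigned.groupby("row"):
            metrics["n_dives"][row] = len(g)
            metrics["mean_max_depth"][row] = g["maxd"].mean()
            metrics["sum_dive_time"][row] = g["dur"].sum()
            metrics["mean_depth"][row] = g["meand"].mean()
            metrics["cum_depth"][row] = g["maxd"].sum()
            metrics["mean_bottom_time"][row] = g["bott"].mean()
            metrics["sum_bottom_time"][row] = g["bott"].sum()
            if "bathy" in out.columns and np.isfinite(out.loc[row, "bathy"]):
                depth_col = abs(float(out.loc[row, "bathy"]))
                prop = g["maxd"].to_numpy() / max(depth_col, 1e-9)
                n_capped += int(np.sum(prop > 1.0))
                metrics["prop_water_column"][row] = float(np.minimum(prop, 1.0).mean())

    for m in DIVE_METRICS:
        out[m] = metrics[m]
    if n_unassigned:
        logger.info("%d dives had no location within %.1f h", n_unassigned, window_h)
    if n_capped:
        logger.info("%d dives exceeded charted depth; proportion capped at 1", n_capped)
    return out


# ---------------------------------------------------------------------------
# AR1 random-intercept LMM


@dataclass
class LmmFit:
    """ML fit of y = a + b x + u_group + AR1 residuals."""

    intercept: float
    slope: float
    slope_se: float
    p_value: float
    sigma_u: float
    phi: float
    sigma_e: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool


def fit_lmm_ar1(df: pd.DataFrame, response: str, predictor: str,
                group: str = "seg_id", fix_phi: float | None = None,
                fix_sigma_u: float | None = None) -> LmmFit:
    """ML linear mixed model with a group intercept and AR1 residuals.

    Within-group observations must be time-ordered; the AR1 correlation is
    on observation order (the regular lattice makes this a time lag).
    Groups with a single observation carry no AR1 information but still
    inform the intercept and slope.  ``fix_phi`` / ``fix_sigma_u`` pin
    those components instead of estimating them (with both pinned at zero
    the fit is exactly weighted-free OLS).
    """
    sub = df[[response, predictor, group]].dropna()
    groups = [g[[response, predictor]].to_numpy(dtype=float)
              for _, g in sub.groupby(group, sort=True)]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    ys = [g[:, 0] for g in groups]
    Xs = [np.column_stack([np.ones(len(g)), g[:, 1]]) for g in groups]
    n = sum(len(y) for y in ys)

    def profile(theta):
        phi = np.tanh(theta[0]) if fix_phi is None else float(fix_phi)
        s2u = np.exp(2.0 * theta[1]) if fix_sigma_u is None else float(fix_sigma_u) ** 2
        s2e = np.exp(2.0 * theta[2])
        XtVX = np.zeros((2, 2))
        XtVy = np.zeros(2)
        Vinvs, logdets = [], 0.0
        for y, X in zip(ys, Xs):
            m = len(y)
            idx = np.arange(m)
            V = s2u + s2e * phi ** np.abs(idx[:, None] - idx[None, :])
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return None
            Vi = np.linalg.inv(V)
            Vinvs.append(Vi)
            logdets += ld
            XtVX += X.T @ Vi @ X
            XtVy += X.T @ Vi @ y
        coef = np.linalg.solve(XtVX, XtVy)
        quad = 0.0
        for y, X, Vi in zip(ys, Xs, Vinvs):
            r = y - X @ coef
            quad += r @ Vi @ r
        ll = -0.5 * (n * np.log(2.0 * np.pi) + logdets + quad)
        return ll, coef, XtVX

    def nll(theta):
        out = profile(theta)
        return 1e12 if out is None else -out[0]

    y_all = np.concatenate(ys)
    x_all = np.concatenate([X[:, 1] for X in Xs])
    s0 = max(np.std(y_all - np.polyval(np.polyfit(x_all, y_all, 1), x_all)), 1e-6)
    theta0 = np.array([0.0, np.log(s0 / 2.0), np.log(s0)])
    res = minimize(nll, theta0, method="L-BFGS-B",
                   bounds=[(-5, 5), (-12, 6), (-12, 6)],
                   options={"maxiter": 300, "ftol": 1e-12})
    # quasi-Newton line searches can stall on this profiled surface;
    # a simplex polish from the incumbent is cheap and rescues those cases
    polish = minimize(nll, res.x, method="Nelder-Mead",
                      options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1000})
    if polish.fun < res.fun:
        res = polish
    ll, coef, XtVX = profile(res.x)
    cov = np.linalg.inv(XtVX)
    se = float(np.sqrt(cov[1, 1]))
    z = coef[1] / se if se > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(z)))
    phi = float(np.tanh(res.x[0])) if fix_phi is None else float(fix_phi)
    sigma_u = float(np.exp(res.x[1])) if fix_sigma_u is None else float(fix_sigma_u)
    fit = LmmFit(
        intercept=float(coef[0]), slope=float(coef[1]), slope_se=se, p_value=p,
        sigma_u=sigma_u, phi=phi, sigma_e=float(np.exp(res.x[2])),
        loglik=float(ll), n_obs=n, n_groups=len(groups),
        converged=bool(res.success),
    )
    if not fit.converged:
        logger.warning("AR1 LMM %s ~ %s did not converge", response, predictor)
    return fit


# ---------------------------------------------------------------------------
# the validation battery


def relation_pairs(prey_species_col: str = "biomass_n_sand_lance") -> list:
    """(response, predictor) pairs of the standard validation battery."""
    pairs = [("gamma_hat", m) for m in DIVE_METRICS]
    for metric in ("n_dives", "mean_max_depth"):
        for cov in (prey_species_col, "diversity", "bathy"):
            pairs.append((metric, cov))
    pairs.append(("prop_water_column", "bathy"))
    return pairs


def relation_table(table: pd.DataFrame, pairs: list | None = None,
                   group: str = "seg_id", alpha: float = 0.05) -> pd.DataFrame:
    """Fit one AR1 LMM per (response, predictor) pair.

    ``table`` holds per-location gamma estimates, dive metrics, and
    covariates; rows with a missing response or predictor drop pairwise.
    Returns a frame with slope, SE, raw Wald p (no multiplicity
    correction), sample size, and a significance flag at ``alpha``.
    """
    if pairs is None:
        pairs = relation_pairs()
    rows = []
    for resp, pred in pairs:
        sub = table[[resp, pred, group]].dropna()
        n_dropped = len(table) - len(sub)
        try:
            fit = fit_lmm_ar1(sub, resp, pred, group=group)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("skipping %s ~ %s: %s", resp, pred, exc)
            continue
        rows.append({
            "response": resp, "predictor": pred, "slope": fit.slope,
            "se": fit.slope_se, "p": fit.p_value, "phi": fit.phi,
            "sigma_u": fit.sigma_u, "sigma_e": fit.sigma_e, "n": fit.n_obs,
            "n_dropped": n_dropped, "significant": fit.p_value < alpha,
        })
    return pd.DataFrame(rows)
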