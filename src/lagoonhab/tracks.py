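"""Raw-fix processing: quality/speed filtering, gap segmentation, on-land
relocation, and hourly interpolation with a continuous-time correlated
random walk (CRW).

The CRW treats velocity as an Ornstein–Uhlenbeck process, integrated to give
position. Parameters: beta, the log mean-reversion rate of velocity
(velocity autocorrelation), bounded in [-3, 4] and penalized by a
Normal(0.5, 2) prior; sigma, the velocity noise scale, unconstrained.
Observation noise is fixed at 10 m. Fitting is maximum penalized likelihood
via an exact-discretization Kalman filter; interpolation uses the
fixed-interval (RTS) smoother on a grid that merges fix times with the
on-the-hour marks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from shapely.geometry import Point
from shapely.ops import nearest_points

from .core import LagoonGeometry

log = logging.getLogger(__name__)

VALID_QUALITIES = {"valid"}
DEFAULT_ERROR_SD_M = 10.0
BETA_BOUNDS = (-3.0, 4.0)
BETA_PRIOR_MEAN = 0.5
BETA_PRIOR_SD = 2.0


# ---------------------------------------------------------------------------
# filtering / segmentation
# ---------------------------------------------------------------------------


def filter_locations(
    fixes: pd.DataFrame, max_speed_kmh: float = 10.0
) -> pd.DataFrame:
    """Drop uncertain/unresolved fixes, then speed-filter the remainder.

    The speed filter is a forward pass with recheck: the fix terminating any
    step implying more than ``max_speed_kmh`` is removed and the step is
    recomputed from the last retained fix, until no violation remains.
    Returns the surviving fixes (possibly empty, with a warning).
    """
    fixes = fixes.sort_values("timestamp").reset_index(drop=True)
    good = fixes[fixes["quality"].isin(VALID_QUALITIES)].reset_index(drop=True)
    if len(good) == 0:
        log.warning("all fixes removed by quality filter")
        return good
    t = pd.DatetimeIndex(good["timestamp"]).asi8 / 3.6e12  # hours
    x, y = good["x"].to_numpy(), good["y"].to_numpy()
    keep = [0]
    for j in range(1, len(good)):
        i = keep[-1]
        dt = t[j] - t[i]
        if dt <= 0:
            continue
        speed = math.hypot(x[j] - x[i], y[j] - y[i]) / 1000.0 / dt
        if speed <= max_speed_kmh:
            keep.append(j)
    return good.iloc[keep].reset_index(drop=True)


def split_segments(fixes: pd.DataFrame, max_gap_h: float = 10.0) -> list[pd.DataFrame]:
    """Cut a filtered track at every inter-fix gap strictly longer than
    ``max_gap_h`` hours. Singleton segments are retained (interpolation skips
    them)."""
    if len(fixes) == 0:
        return []
    t = pd.DatetimeIndex(fixes["timestamp"]).asi8 / 3.6e12
    gaps = np.diff(t)
    cut = np.flatnonzero(gaps > max_gap_h) + 1
    out = []
    starts = np.concatenate([[0], cut])
    ends = np.concatenate([cut, [len(fixes)]])
    for i, (s, e) in enumerate(zip(starts, ends)):
        seg = fixes.iloc[s:e].reset_index(drop=True).copy()
        seg["segment"] = i
        out.append(seg)
    return out


# ---------------------------------------------------------------------------
# on-land relocation
# ---------------------------------------------------------------------------


def relocate_to_water(
    x: float,
    y: float,
    geometry: LagoonGeometry,
    offset_m: float = 1.0,
    max_search_m: float = 5000.0,
) -> tuple[float, float]:
    """Shift a point erroneously located on land to the nearest water.

    Points already in water are returned unchanged. On-land points are
    projected to the nearest point of the water polygon (the domain minus all
    land, so an islet point moves to that islet's shore) and displaced
    ``offset_m`` past the boundary into water. A point farther than
    ``max_search_m`` from any water indicates a geometry problem and errors.
    """
    land = geometry.land_union()
    p = Point(x, y)
    if not land.covers(p):
        return float(x), float(y)
    water = geometry.domain.difference(land)
    bp = nearest_points(p, water)[1]
    d = bp.distance(p)
    if d > max_search_m:
        raise ValueError(f"point {d:.0f} m from water; geometry looks wrong")
    if d < 1e-9:
        for ang in np.linspace(0, 2 * np.pi, 16, endpoint=False):
            q = Point(bp.x + offset_m * math.cos(ang), bp.y + offset_m * math.sin(ang))
            if water.covers(q):
                return q.x, q.y
        raise ValueError("no water found adjacent to boundary point")
    ux, uy = (bp.x - x) / d, (bp.y - y) / d
    q = Point(bp.x + ux * offset_m, bp.y + uy * offset_m)
    if not water.covers(q):
        for extra in (5.0, 25.0, 100.0):
            q = Point(bp.x + ux * extra, bp.y + uy * extra)
            if water.covers(q):
                break
        else:
            raise ValueError("relocation failed: displaced point still on land")
    return q.x, q.y


def relocate_frame(df: pd.DataFrame, geometry: LagoonGeometry) -> pd.DataFrame:
    """Apply `relocate_to_water` to the x/y columns of a frame."""
    import shapely

    land = geometry.land_union()
    pts = shapely.points(df["x"].to_numpy(), df["y"].to_numpy())
    on_land = shapely.covers(land, pts)
    if not on_land.any():
        return df
    df = df.copy()
    for i in np.flatnonzero(on_land):
        nx, ny = relocate_to_water(df["x"].iat[i], df["y"].iat[i], geometry)
        df.iloc[i, df.columns.get_loc("x")] = nx
        df.iloc[i, df.columns.get_loc("y")] = ny
    return df


# ---------------------------------------------------------------------------
# CRW fitting (integrated Ornstein–Uhlenbeck, Kalman filter)
# ---------------------------------------------------------------------------


@dataclass
class CRWFit:
    beta: float
    sigma: float
    loglik: float
    converged: bool
    se_beta: float
    se_sigma: float
    error_sd: float
    n_fixes: int


def _discretize(theta: float, s2: float, dt: float):
    """Exact transition (phi, psi) and process covariance for the
    position/velocity state over a step of dt hours."""
    e = math.exp(-theta * dt)
    e2 = math.exp(-2 * theta * dt)
    psi = (1 - e) / theta
    qvv = s2 * (1 - e2) / (2 * theta)
    qxv = s2 * (1 - 2 * e + e2) / (2 * theta**2)
    qxx = s2 * (dt - 2 * (1 - e) / theta + (1 - e2) / (2 * theta)) / theta**2
    return e, psi, qxx, qxv, qvv


def _kalman_loglik(beta, log_sigma, t, obs, err_sd):
    """Summed Gaussian log-likelihood of both coordinates.

    t: hours, strictly increasing; obs: (n, 2) metres.
    """
    theta = math.exp(beta)
    s2 = math.exp(2 * log_sigma)
    r = err_sd**2
    ll = 0.0
    for c in range(2):
        z = obs[:, c]
        mx, mv = z[0], 0.0
        pxx, pxv, pvv = r, 0.0, s2 / (2 * theta)
        for k in range(1, len(t)):
            dt = t[k] - t[k - 1]
            e, psi, qxx, qxv, qvv = _discretize(theta, s2, dt)
            # predict
            mx = mx + psi * mv
            mv = e * mv
            nxx = pxx + 2 * psi * pxv + psi * psi * pvv + qxx
            nxv = e * (pxv + psi * pvv) + qxv
            nvv = e * e * pvv + qvv
            # update with scalar observation of position
            s = nxx + r
            innov = z[k] - mx
            ll += -0.5 * (math.log(2 * math.pi * s) + innov * innov / s)
            g_x = nxx / s
            g_v = nxv / s
            mx += g_x * innov
            mv += g_v * innov
            pxx = nxx - g_x * nxx
            pxv = nxv - g_x * nxv
            pvv = nvv - g_v * nxv
        # first observation under the initial state
        ll += -0.5 * (math.log(2 * math.pi * r))
    return ll


def fit_crw(
    segment: pd.DataFrame,
    error_sd: float = DEFAULT_ERROR_SD_M,
    beta_bounds=BETA_BOUNDS,
    beta_prior=(BETA_PRIOR_MEAN, BETA_PRIOR_SD),
) -> CRWFit:
    """Fit the CRW to one track segment by maximum penalized likelihood.

    Requires at least 4 fixes spanning at least 3 h. Standard errors come
    from the curvature of the penalized log-likelihood at the optimum.
    """
    t = pd.DatetimeIndex(segment["timestamp"]).asi8 / 3.6e12
    t = t - t[0]
    if len(t) < 4 or t[-1] < 3.0:
        raise ValueError("segment too short for CRW fitting (need >=4 fixes over >=3 h)")
    obs = segment[["x", "y"]].to_numpy(float)

    v_emp = np.diff(obs, axis=0) / np.maximum(np.diff(t), 1e-6)[:, None]
    v_sd = max(np.std(v_emp), 10.0)
    theta0 = math.exp(BETA_PRIOR_MEAN)
    ls0 = 0.5 * math.log(max(v_sd**2 * 2 * theta0, 1e-6))

    pm, ps = beta_prior

    def nll(p):
        b, ls = p
        try:
            ll = _kalman_loglik(b, ls, t, obs, error_sd)
        except (OverflowError, ValueError):
            return 1e12
        return -ll + (b - pm) ** 2 / (2 * ps**2)

    res = minimize(
        nll,
        x0=[BETA_PRIOR_MEAN, ls0],
        method="L-BFGS-B",
        bounds=[beta_bounds, (ls0 - 12, ls0 + 12)],
    )
    beta, ls = res.x
    # curvature-based SEs (central differences)
    h = np.array([1e-4, 1e-4])
    H = np.zeros((2, 2))
    f0 = nll(res.x)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            H[i, j] = H[j, i] = (
                nll(res.x + ei + ej) - nll(res.x + ei - ej)
                - nll(res.x - ei + ej) + nll(res.x - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se_b = math.sqrt(max(cov[0, 0], 0.0))
        se_ls = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_b = se_ls = float("nan")
    sigma = math.exp(ls)
    return CRWFit(
        beta=float(beta),
        sigma=float(sigma),
        loglik=float(-f0),
        converged=bool(res.success),
        se_beta=float(se_b),
        se_sigma=float(sigma * se_ls),
        error_sd=error_sd,
        n_fixes=len(t),
    )


def _smooth_positions(beta, sigma, t_obs, obs, t_query, err_sd):
    """RTS-smoothed position means at ``t_query`` (hours, same origin)."""
    theta = math.exp(beta)
    s2 = sigma**2
    r = err_sd**2
    t_all = np.unique(np.concatenate([t_obs, t_query]))
    obs_idx = {round(v, 9): i for i, v in enumerate(t_obs)}
    n = len(t_all)
    outx = outy = None
    for c in range(2):
        z = obs[:, c]
        mf = np.zeros((n, 2))
        Pf = np.zeros((n, 3))
        mp = np.zeros((n, 2))
        Pp = np.zeros((n, 3))
        trans = np.zeros((n, 2))  # (e, psi) used to reach step k
        k0 = obs_idx.get(round(t_all[0], 9))
        if k0 is not None:
            mf[0] = (z[k0], 0.0)
            Pf[0] = (r, 0.0, s2 / (2 * theta))
        else:
            mf[0] = (z[0], 0.0)
            Pf[0] = (1e10, 0.0, s2 / (2 * theta))
        mp[0], Pp[0] = mf[0], Pf[0]
        for k in range(1, n):
            dt = t_all[k] - t_all[k - 1]
            e, psi, qxx, qxv, qvv = _discretize(theta, s2, dt)
            trans[k] = (e, psi)
            mx = mf[k - 1, 0] + psi * mf[k - 1, 1]
            mv = e * mf[k - 1, 1]
            pxx, pxv, pvv = Pf[k - 1]
            nxx = pxx + 2 * psi * pxv + psi * psi * pvv + qxx
            nxv = e * (pxv + psi * pvv) + qxv
            nvv = e * e * pvv + qvv
            mp[k] = (mx, mv)
            Pp[k] = (nxx, nxv, nvv)
            kobs = obs_idx.get(round(t_all[k], 9))
            if kobs is not None:
                s = nxx + r
                innov = z[kobs] - mx
                g_x, g_v = nxx / s, nxv / s
                mf[k] = (mx + g_x * innov, mv + g_v * innov)
                Pf[k] = (nxx - g_x * nxx, nxv - g_x * nxv, nvv - g_v * nxv)
            else:
                mf[k] = (mx, mv)
                Pf[k] = (nxx, nxv, nvv)
        # backward (RTS) pass
        ms = mf.copy()
        for k in range(n - 2, -1, -1):
            e, psi = trans[k + 1]
            pxx, pxv, pvv = Pf[k]
            nxx, nxv, nvv = Pp[k + 1]
            # A = [[1, psi], [0, e]];  C = Pf A^T
            cxx = pxx + psi * pxv
            cxv = e * pxv
            cvx = pxv + psi * pvv
            cvv = e * pvv
            det = nxx * nvv - nxv * nxv
            if abs(det) < 1e-30:
                continue
            ixx, ixv, ivv = nvv / det, -nxv / det, nxx / det
            # J = C P_pred^{-1}
            jxx = cxx * ixx + cxv * ixv
            jxv = cxx * ixv + cxv * ivv
            jvx = cvx * ixx + cvv * ixv
            jvv = cvx * ixv + cvv * ivv
            dx = ms[k + 1, 0] - mp[k + 1, 0]
            dv = ms[k + 1, 1] - mp[k + 1, 1]
            ms[k, 0] = mf[k, 0] + jxx * dx + jxv * dv
            ms[k, 1] = mf[k, 1] + jvx * dx + jvv * dv
        sel = np.searchsorted(t_all, t_query)
        if c == 0:
            outx = ms[sel, 0]
        else:
            outy = ms[sel, 0]
    return np.column_stack([outx, outy])


def interpolate_hourly(
    fit: CRWFit,
    segment: pd.DataFrame,
    geometry: LagoonGeometry | None = None,
) -> pd.DataFrame:
    """Smoothed positions at every on-the-hour timestamp inside the segment
    span; relocated off land if a geometry is supplied."""
    if not fit.converged:
        raise ValueError("refusing to interpolate from a non-converged CRW fit")
    ts = pd.DatetimeIndex(segment["timestamp"])
    t0 = ts[0]
    t_h = (ts.asi8 - ts.asi8[0]) / 3.6e12
    first_hour = t0.ceil("h")
    last_hour = ts[-1].floor("h")
    if last_hour < first_hour:
        return pd.DataFrame(columns=["timestamp", "x", "y"])
    hours = pd.date_range(first_hour, last_hour, freq="h")
    tq = (hours.asi8 - ts.asi8[0]) / 3.6e12
    xy = _smooth_positions(
        fit.beta, fit.sigma, t_h, segment[["x", "y"]].to_numpy(float), tq, fit.error_sd
    )
    out = pd.DataFrame({"timestamp": hours, "x": xy[:, 0], "y": xy[:, 1]})
    if geometry is not None:
        out = relocate_frame(out, geometry)
    return out


def simulate_crw(
    beta: float,
    sigma: float,
    n: int,
    dt_h: float = 0.5,
    error_sd: float = DEFAULT_ERROR_SD_M,
    start=(0.0, 0.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a track from the exact discrete CRW (for self-consistency tests)."""
    rng = np.random.default_rng(seed)
    theta = math.exp(beta)
    s2 = sigma**2
    e, psi, qxx, qxv, qvv = _discretize(theta, s2, dt_h)
    Q = np.array([[qxx, qxv], [qxv, qvv]])
    L = np.linalg.cholesky(Q + 1e-12 * np.eye(2))
    rows = []
    t0 = pd.Timestamp("2013-01-01")
    for c, x00 in enumerate(start):
        x, v = x00, rng.normal(0, math.sqrt(s2 / (2 * theta)))
        col = []
        for k in range(n):
            col.append(x + rng.normal(0, error_sd))
            w = L @ rng.standard_normal(2)
            x = x + psi * v + w[0]
            v = e * v + w[1]
        rows.append(col)
    return pd.DataFrame(
        {
            "timestamp": t0 + pd.to_timedelta(np.arange(n) * dt_h, unit="h"),
            "x": rows[0],
            "y": rows[1],
            "quality": "valid",
        }
    )
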