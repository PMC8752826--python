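"""Residence time along hourly-interpolated tracks.

Residence time (RT) at a track location is the total time the animal spends
inside a circle of radius rho centred there, accumulated both backward and
forward along the path, where an excursion outside the circle longer than
tau terminates the scan in that direction. High RT flags area-restricted
search; low RT flags transit. The hourly path is treated as piecewise
linear, so circle entry/exit times are exact roots of per-step quadratics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EDGE_TRIM_H = 3  # RT/speed not estimated over the first/last 3 h of a segment
LOG_RT_OFFSET_H = 0.1


def _segment_inside_interval(ax, ay, bx, by, cx, cy, rho):
    """Sub-interval [s0, s1] of s in [0,1] where a+(b-a)s is inside the
    rho-circle at c; None if the segment stays outside."""
    dx, dy = bx - ax, by - ay
    fx, fy = ax - cx, ay - cy
    A = dx * dx + dy * dy
    C = fx * fx + fy * fy - rho * rho
    if A < 1e-18:
        return (0.0, 1.0) if C <= 0 else None
    B = 2 * (fx * dx + fy * dy)
    disc = B * B - 4 * A * C
    if disc < 0:
        return None
    sq = np.sqrt(disc)
    s0, s1 = (-B - sq) / (2 * A), (-B + sq) / (2 * A)
    s0, s1 = max(s0, 0.0), min(s1, 1.0)
    if s1 <= s0:
        return None
    return (s0, s1)


def _scan(x, y, t, i, rho, tau, direction):
    """Inside-circle time scanning from focal index i in +/-1 direction."""
    cx, cy = x[i], y[i]
    n = len(x)
    inside_time = 0.0
    outside_run = 0.0
    j = i
    while (j + direction >= 0) and (j + direction < n):
        k = j + direction
        seg = _segment_inside_interval(x[j], y[j], x[k], y[k], cx, cy, rho)
        dt = abs(t[k] - t[j])
        if seg is None:
            outside_run += dt
            if outside_run > tau:
                break
        else:
            s0, s1 = seg
            # leading outside part (in scan direction the segment runs 0->1)
            outside_run += s0 * dt
            if outside_run > tau:
                break
            inside_time += (s1 - s0) * dt
            if s1 < 1.0:
                outside_run = (1.0 - s1) * dt
                if outside_run > tau:
                    break
            else:
                outside_run = 0.0
        j = k
    return inside_time


def residence_time(
    track: pd.DataFrame,
    rho: float = 1000.0,
    tau_h: float = 2.0,
) -> pd.DataFrame:
    """Residence time (hours) at every hourly location of one segment.

    Returns the track with rt, speed (km/h) and valid columns; valid is False
    within EDGE_TRIM_H of the segment ends. Tracks shorter than
    2*EDGE_TRIM_H + 1 locations come back all-invalid.
    """
    tr = track.reset_index(drop=True)
    x = tr["x"].to_numpy(float)
    y = tr["y"].to_numpy(float)
    t = pd.DatetimeIndex(tr["timestamp"]).asi8 / 3.6e12
    t = t - t[0]
    n = len(tr)
    rt = np.full(n, np.nan)
    for i in range(n):
        fwd = _scan(x, y, t, i, rho, tau_h, +1)
        bwd = _scan(x, y, t, i, rho, tau_h, -1)
        rt[i] = fwd + bwd
    speed = np.full(n, np.nan)
    if n > 1:
        speed[1:] = np.hypot(np.diff(x), np.diff(y)) / 1000.0 / np.maximum(np.diff(t), 1e-9)
    valid = np.ones(n, dtype=bool)
    if n < 2 * EDGE_TRIM_H + 1:
        valid[:] = False
    else:
        valid[:EDGE_TRIM_H] = False
        valid[n - EDGE_TRIM_H:] = False
    out = tr.copy()
    out["rt"] = rt
    out["speed"] = speed
    out["valid"] = valid
    return out


def residence_time_oracle(
    track: pd.DataFrame, rho: float = 1000.0, tau_h: float = 2.0
) -> np.ndarray:
    """Independent RT computation: enumerate every inside interval of the
    whole path per focal circle, then merge intervals whose separating gap is
    within tau, outward from the focal time."""
    tr = track.reset_index(drop=True)
    x = tr["x"].to_numpy(float)
    y = tr["y"].to_numpy(float)
    t = pd.DatetimeIndex(tr["timestamp"]).asi8 / 3.6e12
    t = t - t[0]
    n = len(tr)
    out = np.zeros(n)
    for i in range(n):
        intervals = []
        for j in range(n - 1):
            seg = _segment_inside_interval(x[j], y[j], x[j + 1], y[j + 1], x[i], y[i], rho)
            if seg is not None:
                ta = t[j] + seg[0] * (t[j + 1] - t[j])
                tb = t[j] + seg[1] * (t[j + 1] - t[j])
                if intervals and abs(ta - intervals[-1][1]) < 1e-12:
                    intervals[-1] = (intervals[-1][0], tb)
                else:
                    intervals.append((ta, tb))
        # forward from focal time
        total = 0.0
        prev_end = t[i]
        for a, b in intervals:
            if b <= t[i]:
                continue
            a_eff = max(a, t[i])
            if a_eff - prev_end > tau_h:
                break
            total += b - a_eff
            prev_end = b
        # account for trailing outside time beyond the last interval
        if intervals and prev_end < t[-1] and t[-1] - prev_end > tau_h:
            pass  # scan would stop, but no inside time is at stake
        # backward from focal time
        prev_start = t[i]
        for a, b in reversed(intervals):
            if a >= t[i]:
                continue
            b_eff = min(b, t[i])
            if prev_start - b_eff > tau_h:
                break
            total += b_eff - a
            prev_start = a
        out[i] = total
    return out


def smooth_rt(rt: np.ndarray, order: int = 4) -> np.ndarray:
    """Centred moving average of even order (standard half-weight endpoints);
    the half-window at each end is left unsmoothed."""
    rt = np.asarray(rt, float)
    half = order // 2
    w = np.full(order + 1, 1.0 / order)
    w[0] = w[-1] = 1.0 / (2 * order)
    out = rt.copy()
    if len(rt) < order + 1:
        return out
    conv = np.convolve(rt, w, mode="valid")
    out[half:len(rt) - half] = conv
    return out


def select_scale(
    series_by_individual: dict[str, list[pd.DataFrame]],
    radii_m=(1000.0, 2000.0, 3000.0, 4000.0),
    tau_h: float = 2.0,
) -> dict:
    """Pick the analysis radius by per-individual argmax of the variance of
    log RT, decided by majority vote (ties toward the smaller radius).

    ``series_by_individual`` maps individual id to its list of hourly
    segments (x, y, timestamp).
    """
    votes = {}
    var_table = {}
    for ind, segments in series_by_individual.items():
        variances = {}
        for rho in radii_m:
            vals = []
            for seg in segments:
                rs = residence_time(seg, rho=rho, tau_h=tau_h)
                vals.append(np.log(rs.loc[rs["valid"], "rt"] + LOG_RT_OFFSET_H))
            allv = pd.concat(vals) if vals else pd.Series(dtype=float)
            variances[rho] = float(allv.var(ddof=1)) if len(allv) > 1 else np.nan
        var_table[ind] = variances
        finite = {r: v for r, v in variances.items() if np.isfinite(v)}
        if finite:
            best = max(sorted(finite), key=lambda r: (finite[r], -r))
            votes[ind] = best
    if not votes:
        raise ValueError("no individual produced a valid residence-time series")
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts.max()
    chosen = min(r for r in counts.index if counts[r] == top)
    return {"chosen_radius_m": float(chosen), "votes": votes, "variances": var_table}


def test_sex_effect(data: pd.DataFrame) -> dict:
    """Linear mixed model of log RT on sex with an individual random
    intercept (ML fit). Needs columns id, sex, log_rt and both sexes present.
    """
    import statsmodels.formula.api as smf

    sexes = data["sex"].unique()
    if len(sexes) < 2:
        raise ValueError("both sexes are required for the comparison")
    model = smf.mixedlm("log_rt ~ C(sex)", data, groups=data["id"])
    res = model.fit(reml=False)
    name = [p for p in res.params.index if p.startswith("C(sex)")][0]
    coef, se = res.params[name], res.bse[name]
    chi2 = (coef / se) ** 2
    from scipy.stats import chi2 as chi2_dist

    return {
        "effect": float(coef),
        "se": float(se),
        "chi2": float(chi2),
        "p": float(chi2_dist.sf(chi2, 1)),
        "n": int(len(data)),
    }
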