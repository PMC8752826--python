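"""Tidal and diel cycles: phase classification, cyclic mixed models on
residence time and used depth range, and excursion timing.

Tidal phase is high/low within 1 h of a detected peak of the 20-min gauge
series, else neither; ebb/flood is the falling/rising limb. The diel cycle
is a fixed local-clock partition: dawn 03-09, day 09-15, dusk 15-21, night
21-03. Depth at a location is binned shallow [0,2] m, medium (2,10] m,
deep >10 m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import chi2 as chi2_dist
from scipy.stats import studentized_range

log = logging.getLogger(__name__)

DIEL_ORDER = ["dawn", "day", "dusk", "night"]
TIDE_WINDOW_H = 1.0
DEPTH_BIN_EDGES = (2.0, 10.0)
MIN_LOCATIONS_PER_ECOREGION = 10


# ---------------------------------------------------------------------------
# phase classification
# ---------------------------------------------------------------------------


def classify_diel(timestamps) -> pd.Series:
    """Diel phase per timestamp (half-open boundaries, boundary minute
    belongs to the later phase)."""
    ts = pd.DatetimeIndex(timestamps)
    hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    idx = (((hours - 3.0) % 24.0) // 6.0).astype(int)
    return pd.Series(np.array(DIEL_ORDER)[idx], index=range(len(ts)), name="diel")


def classify_tide(tide, timestamps) -> pd.DataFrame:
    """Tidal phase (high/low/neither) and ebb/flood state per timestamp.

    Peaks are local extrema of the gauge series; a timestamp within
    TIDE_WINDOW_H (inclusive) of a maximum is high, of a minimum low.
    Errors if a timestamp falls outside the gauge record.
    """
    rec = tide.records
    t = pd.DatetimeIndex(rec["time"]).asi8 / 3.6e12
    h = rec["height_m"].to_numpy()
    ts = pd.DatetimeIndex(timestamps)
    q = ts.asi8 / 3.6e12
    if len(q) and (q.min() < t[0] - 1e-9 or q.max() > t[-1] + TIDE_WINDOW_H):
        raise ValueError("timestamp outside the tide-gauge record")
    # light smoothing so gauge noise does not split peaks
    k = 3
    hs = np.convolve(h, np.ones(k) / k, mode="same")
    imax = argrelextrema(hs, np.greater_equal, order=9)[0]
    imin = argrelextrema(hs, np.less_equal, order=9)[0]
    # deduplicate plateaus
    imax = imax[np.concatenate([[True], np.diff(t[imax]) > 3.0])] if len(imax) else imax
    imin = imin[np.concatenate([[True], np.diff(t[imin]) > 3.0])] if len(imin) else imin
    t_hi, t_lo = t[imax], t[imin]

    def near(qv, peaks):
        if len(peaks) == 0:
            return np.zeros(len(qv), dtype=bool)
        j = np.searchsorted(peaks, qv)
        d = np.full(len(qv), np.inf)
        for off in (-1, 0):
            jj = np.clip(j + off, 0, len(peaks) - 1)
            d = np.minimum(d, np.abs(qv - peaks[jj]))
        return d <= TIDE_WINDOW_H + 1e-9

    hi = near(q, t_hi)
    lo = near(q, t_lo)
    tidal = np.where(hi, "high", np.where(lo, "low", "neither"))
    # ebb = falling limb; from the sign of the smoothed derivative
    dh = np.gradient(hs, t)
    slope = np.interp(q, t, dh)
    state = np.where(slope < 0, "ebb", "flood")
    return pd.DataFrame({"tidal": tidal, "ebb_flood": state})


def bin_depth(depth_m) -> pd.Series:
    """shallow [0,2] m, medium (2,10] m, deep >10 m."""
    d = np.atleast_1d(np.asarray(depth_m, float))
    if np.any(d < 0):
        raise ValueError("negative depth: location appears to be on land")
    lab = np.where(d <= DEPTH_BIN_EDGES[0], "shallow",
                   np.where(d <= DEPTH_BIN_EDGES[1], "medium", "deep"))
    return pd.Series(lab, name="depth_bin")


DEPTH_BIN_ORDINAL = {"shallow": 1, "medium": 2, "deep": 3}


# ---------------------------------------------------------------------------
# cyclic mixed models
# ---------------------------------------------------------------------------


def _wald_terms(res, data) -> dict:
    """Type III Wald chi² for tidal, diel and their interaction, from a
    sum-coded MixedLM fit."""
    params = res.params
    cov = res.cov_params()
    groups = {
        "tidal": [n for n in res.fe_params.index if "tidal" in n and ":" not in n],
        "diel": [n for n in res.fe_params.index if "diel" in n and ":" not in n],
        "tidal_x_diel": [n for n in res.fe_params.index if ":" in n],
    }
    out = {}
    for term, names in groups.items():
        if not names:
            continue
        b = params[names].to_numpy()
        V = cov.loc[names, names].to_numpy()
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            chi2 = float(b @ np.linalg.pinv(V) @ b)
        out[term] = {"chi2": chi2, "df": len(names), "p": float(chi2_dist.sf(chi2, len(names)))}
    return out


def _r2_nakagawa(res) -> tuple[float, float]:
    """Marginal / conditional R² from the fixed-effect, random-intercept and
    residual variance components."""
    X = res.model.exog
    var_f = float(np.var(X @ res.fe_params.to_numpy()))
    var_re = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
    var_e = float(res.scale)
    tot = var_f + var_re + var_e
    return var_f / tot, (var_f + var_re) / tot


def fit_cycle_lmm(
    data: pd.DataFrame,
    response: str,
    min_locations: int = MIN_LOCATIONS_PER_ECOREGION,
) -> dict:
    """Mixed model of ``response`` on tidal * diel with individual random
    intercepts (ML fit), within one ecoregion.

    Only high/low-labelled locations enter; individuals with fewer than
    ``min_locations`` rows are removed, and at least two individuals are
    required. Reports Type III Wald chi² per term, marginal and conditional
    R², and Tukey-corrected pairwise contrasts of the tidal x diel cell
    means.
    """
    import statsmodels.formula.api as smf

    d = data[data["tidal"].isin(["high", "low"])].copy()
    counts = d.groupby("id")[response].count()
    keep = counts[counts >= min_locations].index
    d = d[d["id"].isin(keep)]
    if d["id"].nunique() < 2:
        raise ValueError("fewer than two individuals with enough locations")
    model = smf.mixedlm(
        f"{response} ~ C(tidal, Sum) * C(diel, Sum)", d, groups=d["id"]
    )
    res = model.fit(reml=False)
    terms = _wald_terms(res, d)
    r2m, r2c = _r2_nakagawa(res)

    # Tukey-adjusted pairwise contrasts of the 8 cell marginal means
    cells = [(t, dl) for t in ["high", "low"] for dl in DIEL_ORDER]
    design = pd.DataFrame([{"tidal": t, "diel": dl, response: 0.0, "id": d["id"].iloc[0]} for t, dl in cells])
    import patsy

    X = patsy.build_design_matrices([res.model.data.design_info], design)[0]
    X = np.asarray(X)
    beta = res.fe_params.to_numpy()
    V = res.cov_params().loc[res.fe_params.index, res.fe_params.index].to_numpy()
    means = X @ beta
    k = len(cells)
    df_resid = len(d) - X.shape[1]
    posthoc = []
    for i in range(k):
        for j in range(i + 1, k):
            c = X[i] - X[j]
            se = float(np.sqrt(c @ V @ c))
            diff = float(means[i] - means[j])
            qstat = abs(diff) / se * np.sqrt(2.0)
            p = float(studentized_range.sf(qstat, k, df_resid))
            posthoc.append(
                {
                    "cell_a": f"{cells[i][0]}-{cells[i][1]}",
                    "cell_b": f"{cells[j][0]}-{cells[j][1]}",
                    "diff": diff,
                    "se": se,
                    "p_tukey": p,
                }
            )
    return {
        "n_ind": int(d["id"].nunique()),
        "n_loc": int(len(d)),
        "terms": terms,
        "marginal_r2": float(r2m),
        "conditional_r2": float(r2c),
        "cell_means": pd.DataFrame({"tidal": [c[0] for c in cells], "diel": [c[1] for c in cells], "mean": means}),
        "posthoc": pd.DataFrame(posthoc),
        "result": res,
    }


# ---------------------------------------------------------------------------
# excursions past the barrier reef
# ---------------------------------------------------------------------------


@dataclass
class Excursion:
    individual: str
    t_out: pd.Timestamp
    t_in: pd.Timestamp | None
    diel_out: str
    diel_in: str | None
    tidal_out: str
    tidal_in: str | None
    ebb_flood_out: str
    ebb_flood_in: str | None
    duration_h: float | None
    mean_rt_h: float | None
    open_ended: bool


def _crossing_time(geometry, x0, y0, t0, x1, y1, t1, tol_m=10.0):
    """Barrier-crossing time on a step, by bisection on seaward state."""
    s_lo, s_hi = 0.0, 1.0
    sw0 = bool(geometry.is_seaward(x0, y0)[0])
    for _ in range(25):
        sm = 0.5 * (s_lo + s_hi)
        xm, ym = x0 + sm * (x1 - x0), y0 + sm * (y1 - y0)
        if bool(geometry.is_seaward(xm, ym)[0]) == sw0:
            s_lo = sm
        else:
            s_hi = sm
        if np.hypot(x1 - x0, y1 - y0) * (s_hi - s_lo) < tol_m:
            break
    s = 0.5 * (s_lo + s_hi)
    return t0 + (t1 - t0) * s


def detect_excursions(
    series_by_individual: dict[str, pd.DataFrame],
    geometry,
    tide,
) -> list[Excursion]:
    """Maximal runs of consecutive hourly locations seaward of the barrier,
    annotated with crossing-time diel/tidal/ebb-flood states.

    A track ending mid-excursion yields an open-ended record excluded from
    duration statistics.
    """
    out = []
    for ind, ser in series_by_individual.items():
        ser = ser.reset_index(drop=True)
        sea = geometry.is_seaward(ser["x"].to_numpy(), ser["y"].to_numpy())
        ts = pd.DatetimeIndex(ser["timestamp"])
        i = 0
        n = len(ser)
        while i < n:
            if not sea[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and sea[j + 1]:
                j += 1
            # crossing times by interpolation of the crossing steps
            if i > 0:
                t_out = _crossing_time(
                    geometry,
                    ser["x"][i - 1], ser["y"][i - 1], ts[i - 1],
                    ser["x"][i], ser["y"][i], ts[i],
                )
            else:
                t_out = ts[i]
            open_ended = j + 1 >= n
            if not open_ended:
                t_in = _crossing_time(
                    geometry,
                    ser["x"][j], ser["y"][j], ts[j],
                    ser["x"][j + 1], ser["y"][j + 1], ts[j + 1],
                )
            else:
                t_in = None
            lab_out = classify_tide(tide, [t_out]).iloc[0]
            lab_in = classify_tide(tide, [t_in]).iloc[0] if t_in is not None else None
            rt = ser["rt"][i:j + 1].mean() if "rt" in ser else np.nan
            out.append(
                Excursion(
                    individual=ind,
                    t_out=t_out,
                    t_in=t_in,
                    diel_out=classify_diel([t_out]).iloc[0],
                    diel_in=classify_diel([t_in]).iloc[0] if t_in is not None else None,
                    tidal_out=str(lab_out["tidal"]),
                    tidal_in=str(lab_in["tidal"]) if lab_in is not None else None,
                    ebb_flood_out=str(lab_out["ebb_flood"]),
                    ebb_flood_in=str(lab_in["ebb_flood"]) if lab_in is not None else None,
                    duration_h=(t_in - t_out).total_seconds() / 3600.0 if t_in is not None else None,
                    mean_rt_h=float(rt) if np.isfinite(rt) else None,
                    open_ended=open_ended,
                )
            )
            i = j + 1
    return out


def excursion_timing_test(
    excursions: list[Excursion] | list[str],
    direction: str = "outward",
    n_replicates: int = 2000,
    seed: int = 0,
) -> dict:
    """Chi² goodness-of-fit of excursion diel timing against uniformity, with
    a Monte-Carlo p-value: p = (1 + #{chi²_rep >= chi²_obs}) / (replicates+1).
    """
    if excursions and isinstance(excursions[0], Excursion):
        labels = [
            e.diel_out if direction == "outward" else e.diel_in
            for e in excursions
            if (direction == "outward") or (e.diel_in is not None)
        ]
    else:
        labels = list(excursions)
    if len(labels) == 0:
        raise ValueError("no excursions to test")
    obs = np.array([labels.count(c) for c in DIEL_ORDER])
    n = obs.sum()
    expected = n / 4.0
    chi2_obs = float(np.sum((obs - expected) ** 2 / expected))
    rng = np.random.default_rng(seed)
    reps = rng.multinomial(n, [0.25] * 4, size=n_replicates)
    chi2_rep = np.sum((reps - expected) ** 2 / expected, axis=1)
    p = (1 + int(np.sum(chi2_rep >= chi2_obs - 1e-12))) / (n_replicates + 1)
    return {"counts": dict(zip(DIEL_ORDER, obs.tolist())), "chi2": chi2_obs, "p": float(p), "n": int(n)}
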