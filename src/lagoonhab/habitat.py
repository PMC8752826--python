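"""Per-ecoregion habitat model of intensity of use on the 500-m grid.

Intensity of use in a cell is an individual's mean residence time there,
divided by the cell's water area (h/km²); the response is the maximum over
individuals. It is modelled as a negative-binomial GAM: hours are rounded to
counts with log water-area as offset, smooths are penalized B-splines with
basis size capped at 5, one independent model per ecoregion. Predictors
surviving a pairwise collinearity screen (|r| > 0.7 in more than one
ecoregion drops the worse-connected member) enter each model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.genmod.families import NegativeBinomial

log = logging.getLogger(__name__)

DEFAULT_PREDICTORS = [
    "depth_log",
    "slope_log",
    "dist_coast",
    "dist_barrier_signed",
    "dist_reef",
    "dist_seagrass",
    "seagrass_cov",
]
BASIS_SIZE = 5


def intensity_of_use(
    series_by_individual: dict[str, pd.DataFrame],
    covariates: pd.DataFrame,
    grid,
    rt_col: str = "rt_smooth",
) -> pd.DataFrame:
    """Observed intensity of use per grid cell (h/km²).

    For each individual: mean residence time over its valid hourly locations
    in the cell, divided by the cell's water area. The cell response is the
    maximum across individuals; unvisited water cells get 0.
    """
    cell_area_km2 = (grid.resolution / 1000.0) ** 2
    out = covariates[["cell_id", "x", "y", "water_fraction"]].copy()
    water_km2 = out["water_fraction"].to_numpy() * cell_area_km2
    per_ind = {}
    night_hours = {}
    tot_hours = {}
    for ind, ser in series_by_individual.items():
        ok = ser[ser["valid"] & np.isfinite(ser[rt_col])]
        if len(ok) == 0:
            continue
        cid = grid.cell_of(ok["x"].to_numpy(), ok["y"].to_numpy())
        df = pd.DataFrame({"cell_id": cid, "rt": ok[rt_col].to_numpy()})
        hours = pd.DatetimeIndex(ok["timestamp"]).hour.to_numpy()
        df["night"] = ((hours >= 15) | (hours < 3)).astype(float)  # dusk+night
        df = df[df["cell_id"] >= 0]
        g = df.groupby("cell_id").agg(rt=("rt", "mean"), night=("night", "sum"), n=("rt", "size"))
        per_ind[ind] = g["rt"]
        night_hours[ind] = g["night"]
        tot_hours[ind] = g["n"]
    if not per_ind:
        raise ValueError("no valid residence series supplied")
    mean_rt = pd.DataFrame(per_ind).reindex(out["cell_id"]).max(axis=1)
    out["mean_rt_h"] = mean_rt.fillna(0.0).to_numpy()
    out["n_individuals_visiting"] = (
        pd.DataFrame(per_ind).notna().sum(axis=1).reindex(out["cell_id"]).fillna(0).to_numpy()
    )
    out["intensity"] = np.where(water_km2 > 0, out["mean_rt_h"] / water_km2, 0.0)
    night = pd.DataFrame(night_hours).sum(axis=1)
    tot = pd.DataFrame(tot_hours).sum(axis=1)
    nf = (night / tot).reindex(out["cell_id"]).fillna(0.0)
    out["night_fraction"] = nf.to_numpy()
    return out


def screen_collinearity(
    covariates: pd.DataFrame,
    ecoregion: pd.Series,
    predictors=DEFAULT_PREDICTORS,
    r_threshold: float = 0.7,
) -> list[str]:
    """Drop predictors with |Pearson r| > threshold to another predictor in
    more than one ecoregion; the member of an offending pair with the larger
    mean absolute correlation goes first. Errors if fewer than two survive.
    """
    regions = sorted(pd.Series(ecoregion).unique())
    if len(regions) < 2:
        raise ValueError("need at least two ecoregions for the screen")
    preds = [p for p in predictors if p in covariates.columns]
    retained = list(preds)
    while True:
        exceed = {}
        corr_by_region = []
        for reg in regions:
            sub = covariates.loc[np.asarray(ecoregion) == reg, retained].dropna()
            if len(sub) < 3:
                continue
            corr_by_region.append(sub.corr().abs())
        mean_abs = (
            pd.concat(corr_by_region).groupby(level=0).mean() if corr_by_region else None
        )
        for a_i, a in enumerate(retained):
            for b in retained[a_i + 1:]:
                n_bad = sum(
                    1
                    for c in corr_by_region
                    if np.isfinite(c.loc[a, b]) and c.loc[a, b] > r_threshold
                )
                if n_bad > 1:
                    exceed[(a, b)] = n_bad
        if not exceed:
            break
        worst_pair = max(exceed, key=exceed.get)
        a, b = worst_pair
        conn = {
            p: mean_abs.loc[p, [q for q in retained if q != p]].mean() for p in (a, b)
        }
        if abs(conn[a] - conn[b]) < 0.02:
            # near-tie: drop the later-listed (lower-priority) predictor
            drop = b if retained.index(a) < retained.index(b) else a
        else:
            drop = max(conn, key=conn.get)
        log.info("collinearity screen drops %s", drop)
        retained.remove(drop)
        if len(retained) < 2:
            raise ValueError("collinearity screen left fewer than two predictors")
    return retained


@dataclass
class HabitatModel:
    predictors: list[str]
    results: dict  # ecoregion -> fitted GLMGam results
    smoothers: dict  # ecoregion -> BSplines
    alpha_nb: dict  # ecoregion -> NB dispersion
    terms: pd.DataFrame  # ecoregion, predictor, chi2, edf, p
    deviance_explained_pct: float
    train_ranges: dict = field(default_factory=dict)
    offsets: dict = field(default_factory=dict)


def _nb_alpha_moment(y, mu) -> float:
    """Method-of-moments NB2 dispersion: Var = mu + alpha mu^2."""
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    return float(np.clip(num / den if den > 0 else 0.1, 0.01, 10.0))


def _fit_one_region(y, X, offset, n_basis, gcv_grid):
    smoother = BSplines(
        X, df=[n_basis] * X.shape[1], degree=[3] * X.shape[1], include_intercept=False
    )
    alpha_nb = 1.0
    res, best = None, (np.inf, None)
    for _ in range(3):
        fam = NegativeBinomial(alpha=alpha_nb)
        best = (np.inf, None, None)
        for lam in gcv_grid:
            try:
                m = GLMGam(
                    y,
                    exog=np.ones((len(y), 1)),
                    smoother=smoother,
                    alpha=[lam] * X.shape[1],
                    family=fam,
                    offset=offset,
                )
                r = m.fit(maxiter=100)
            except Exception:  # singular fits on degenerate penalties
                continue
            edf = float(np.sum(r.edf))
            n = len(y)
            gcv = r.deviance / max(n - 1.1 * edf, 1.0) ** 2 * n
            if np.isfinite(gcv) and gcv < best[0]:
                best = (gcv, r, lam)
        if best[1] is None:
            raise RuntimeError("habitat GAM failed to converge on every penalty")
        res = best[1]
        alpha_new = _nb_alpha_moment(y, res.fittedvalues)
        if abs(alpha_new - alpha_nb) < 0.05:
            alpha_nb = alpha_new
            break
        alpha_nb = alpha_new
    return res, smoother, alpha_nb, best[2]


def fit_gam(
    use_grid: pd.DataFrame,
    predictors: list[str],
    ecoregion_col: str = "ecoregion",
    response_col: str = "mean_rt_h",
    min_cells: int = 50,
    n_basis: int = BASIS_SIZE,
    gcv_grid=(0.1, 1.0, 10.0, 100.0, 1000.0),
) -> HabitatModel:
    """Negative-binomial GAM of intensity of use, one model per ecoregion.

    The response is the cell's max mean residence time rounded to whole
    hours, with log water area (km²) as offset, so exp(smooth terms) is on
    the h/km² intensity scale. Penalty weights are selected by GCV on a
    shared grid; the NB dispersion by method-of-moments outer iteration.
    Reports per-term Wald chi², edf and p, and pooled % deviance explained.
    """
    results, smoothers, alphas, ranges, offs = {}, {}, {}, {}, {}
    rows = []
    dev_tot = null_tot = 0.0
    for reg, sub in use_grid.groupby(ecoregion_col):
        sub = sub.dropna(subset=predictors)
        y = np.round(sub[response_col].to_numpy()).astype(int)
        if len(sub) < min_cells:
            log.warning("ecoregion %s has %d cells (<%d); skipped", reg, len(sub), min_cells)
            continue
        if (y > 0).sum() == 0:
            log.warning("ecoregion %s response all zero; skipped", reg)
            continue
        X = sub[predictors].to_numpy(float)
        area = np.clip(sub["water_fraction"].to_numpy() * 0.25, 1e-6, None)
        offset = np.log(area)
        res, smoother, alpha_nb, lam = _fit_one_region(y, X, offset, n_basis, gcv_grid)
        results[reg] = res
        smoothers[reg] = smoother
        alphas[reg] = alpha_nb
        offs[reg] = offset
        ranges[reg] = {p: (sub[p].min(), sub[p].max()) for p in predictors}

        # per-term Wald tests on the spline coefficient blocks
        cov = res.cov_params()
        params = np.asarray(res.params)
        edf = np.asarray(res.edf)
        col = 1  # first column is the intercept
        for j, p in enumerate(predictors):
            k = smoother.smoothers[j].dim_basis
            b = params[col:col + k]
            V = np.asarray(cov)[col:col + k, col:col + k]
            try:
                chi2 = float(b @ np.linalg.solve(V, b))
            except np.linalg.LinAlgError:
                chi2 = float(b @ np.linalg.pinv(V) @ b)
            term_edf = float(edf[col:col + k].sum())
            df_test = max(term_edf, 1.0)
            rows.append(
                {
                    "ecoregion": reg,
                    "predictor": p,
                    "chi2": chi2,
                    "edf": term_edf,
                    "p": float(chi2_dist.sf(chi2, df_test)),
                    "penalty": lam,
                    "nb_alpha": alpha_nb,
                }
            )
            col += k
        dev_tot += res.deviance
        null_tot += res.null_deviance
    if not results:
        raise RuntimeError("no ecoregion could be modelled")
    dev_expl = 100.0 * (1.0 - dev_tot / null_tot) if null_tot > 0 else np.nan
    return HabitatModel(
        predictors=list(predictors),
        results=results,
        smoothers=smoothers,
        alpha_nb=alphas,
        terms=pd.DataFrame(rows),
        deviance_explained_pct=float(dev_expl),
        train_ranges=ranges,
        offsets=offs,
    )


def predict_intensity(
    model: HabitatModel,
    cells: pd.DataFrame,
    ecoregion_col: str = "ecoregion",
) -> pd.DataFrame:
    """Expected intensity of use (h/km²) per cell, on the response scale.

    Cells with covariates outside the model's training range are still
    predicted but flagged ``extrapolated``.
    """
    out = cells.copy()
    pred = np.full(len(cells), np.nan)
    extrap = np.zeros(len(cells), dtype=bool)
    for reg, res in model.results.items():
        mask = (cells[ecoregion_col] == reg).to_numpy()
        if not mask.any():
            continue
        sub = cells.loc[mask, model.predictors]
        rng = model.train_ranges[reg]
        clipped = sub.copy()
        for p in model.predictors:
            lo, hi = rng[p]
            extrap[mask] |= ((sub[p] < lo) | (sub[p] > hi)).to_numpy()
            clipped[p] = sub[p].clip(lo, hi)
        basis = model.smoothers[reg].transform(clipped.to_numpy(float))
        exog = np.column_stack([np.ones(len(sub)), basis])
        eta = exog @ np.asarray(model.results[reg].params)
        pred[mask] = np.exp(eta)  # offset excluded: per-km² intensity
    out["predicted"] = pred
    out["extrapolated"] = extrap
    return out


def partial_dependence(
    model: HabitatModel,
    predictor: str,
    ecoregion,
    cells: pd.DataFrame,
    n_points: int = 100,
    crop_quantile: float = 0.05,
    ecoregion_col: str = "ecoregion",
) -> pd.DataFrame:
    """Centred smooth-term effect of one predictor with an approximate 95%
    band, over the predictor's observed range (5% most extreme values
    cropped)."""
    if predictor not in model.predictors:
        raise ValueError(f"{predictor} is not a model term")
    res = model.results[ecoregion]
    smoother = model.smoothers[ecoregion]
    j = model.predictors.index(predictor)
    vals = cells.loc[cells[ecoregion_col] == ecoregion, predictor].dropna()
    lo, hi = vals.quantile([crop_quantile / 2, 1 - crop_quantile / 2])
    grid = np.linspace(lo, hi, n_points)
    # basis for the full covariate vector at reference (median) values
    ref = cells.loc[cells[ecoregion_col] == ecoregion, model.predictors].median()
    Xg = np.tile(ref.to_numpy(float), (n_points, 1))
    Xg[:, j] = grid
    basis = smoother.transform(Xg)
    # columns of this predictor's block within the stacked basis
    start = sum(smoother.smoothers[i].dim_basis for i in range(j))
    k = smoother.smoothers[j].dim_basis
    B = basis[:, start:start + k]
    b = np.asarray(res.params)[1 + start:1 + start + k]
    V = np.asarray(res.cov_params())[1 + start:1 + start + k, 1 + start:1 + start + k]
    eff = B @ b
    eff = eff - eff.mean()
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))
    return pd.DataFrame(
        {"value": grid, "effect": eff, "lower": eff - 2 * se, "upper": eff + 2 * se}
    )
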