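"""End-to-end analysis: simulate -> tracks -> residence -> ecoregions ->
habitat model -> tidal/diel models -> cross-validation.

Wired for the synthetic study system, but every stage takes the same
containers a real study would provide (fix tables, gauge series, vector
layers, bathymetry).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crossval as cvl
from . import ecoregions as eco
from . import environment as env
from . import habitat as hab
from . import residence as rsd
from . import synthetic as syn
from . import temporal as tmp
from . import tracks as trk

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    geometry: object
    bathymetry: object
    tide: object
    sim: object
    hourly: dict  # individual -> list of hourly segment frames
    series: dict  # individual -> residence series (rho = chosen radius)
    scale: dict
    sex_test: dict
    grid: object
    covariates: pd.DataFrame
    slices: pd.DataFrame
    profiles: pd.DataFrame
    partition: object
    use_grid: pd.DataFrame
    predictors: list
    model: object
    predicted: pd.DataFrame
    cycle_reports: dict
    excursions: list
    excursion_tests: dict
    density: pd.DataFrame
    crossval: object
    summary: dict = field(default_factory=dict)


def _interpolate_individual(fixes, geometry, max_speed=10.0, max_gap_h=10.0):
    filt = trk.filter_locations(fixes, max_speed)
    if len(filt) == 0:
        return [], 0
    filt = trk.relocate_frame(filt, geometry)
    segs = trk.split_segments(filt, max_gap_h)
    hourly = []
    for seg in segs:
        span_h = (seg["timestamp"].iloc[-1] - seg["timestamp"].iloc[0]).total_seconds() / 3600
        if len(seg) < 4 or span_h < 3:
            continue
        try:
            fit = trk.fit_crw(seg)
        except ValueError:
            continue
        if not fit.converged:
            log.warning("CRW fit did not converge; segment skipped")
            continue
        h = trk.interpolate_hourly(fit, seg, geometry)
        if len(h):
            h["segment"] = seg["segment"].iloc[0]
            hourly.append(h)
    return hourly, len(filt)


def run_pipeline(
    seed: int = 0,
    regions=syn.DEFAULT_REGIONS,
    sim_config: syn.SimulationConfig | None = None,
    tide_span=("2013-10-01", "2013-11-20"),
    rho_m: float | None = None,
    daytime_bias: float = 0.8,
    select_radius: bool = True,
) -> PipelineResult:
    """Run the full analysis on one synthetic realization.

    ``seed`` drives geometry, tides, tracks and the density surface through
    independent substreams. If ``rho_m`` is None the residence radius is
    chosen by the log-variance vote across individuals.
    """
    warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")
    rng = np.random.default_rng(seed)
    s_geo, s_tide, s_trk, s_dens = rng.integers(0, 2**31 - 1, 4)

    geometry, bathy = syn.generate_lagoon(regions, seed=int(s_geo))
    tide = syn.generate_tide_series(*tide_span, seed=int(s_tide))
    cfg = sim_config or syn.SimulationConfig(seed=int(s_trk))
    sim = syn.simulate_tracks(geometry, bathy, tide, cfg)

    # --- tracks -> hourly positions ---------------------------------------
    hourly = {}
    n_filtered = 0
    for ind, fixes in sim.fixes.groupby("id"):
        segs, nf = _interpolate_individual(fixes, geometry)
        n_filtered += nf
        if segs:
            hourly[ind] = segs

    # --- residence time ----------------------------------------------------
    if rho_m is None and select_radius:
        scale = rsd.select_scale(hourly)
        rho = scale["chosen_radius_m"]
    else:
        rho = rho_m or 1000.0
        scale = {"chosen_radius_m": rho, "votes": {}, "variances": {}}

    series = {}
    for ind, segs in hourly.items():
        parts = []
        for seg in segs:
            r = rsd.residence_time(seg, rho=rho)
            r["rt_smooth"] = rsd.smooth_rt(r["rt"].to_numpy())
            parts.append(r)
        series[ind] = pd.concat(parts, ignore_index=True)

    sexes = sim.fixes.drop_duplicates("id").set_index("id")["sex"]
    sex_rows = []
    for ind, ser in series.items():
        ok = ser[ser["valid"]]
        sex_rows.append(
            pd.DataFrame(
                {
                    "id": ind,
                    "sex": sexes[ind],
                    "log_rt": np.log(ok["rt"] + rsd.LOG_RT_OFFSET_H),
                }
            )
        )
    sex_data = pd.concat(sex_rows, ignore_index=True)
    try:
        sex_test = rsd.test_sex_effect(sex_data)
    except ValueError as e:
        sex_test = {"error": str(e)}

    # --- environment + ecoregions ------------------------------------------
    grid = env.build_grid(geometry)
    covariates = env.derive_covariates(grid, bathy, geometry)
    slices = eco.slice_lagoon(geometry)
    profiles = eco.summarize_slices(slices, covariates, geometry)
    partition = eco.cluster_slices(profiles, slices=slices)
    covariates = covariates.copy()
    covariates["ecoregion"] = eco.label_cells(covariates, slices, partition).to_numpy()

    # --- habitat model ------------------------------------------------------
    use = hab.intensity_of_use(series, covariates, grid)
    use_grid = covariates.merge(
        use[["cell_id", "mean_rt_h", "intensity", "night_fraction", "n_individuals_visiting"]],
        on="cell_id",
    )
    predictors = hab.screen_collinearity(use_grid, use_grid["ecoregion"])
    model = hab.fit_gam(use_grid, predictors)
    predicted = hab.predict_intensity(model, use_grid)

    # --- tidal / diel cycles ------------------------------------------------
    loc_rows = []
    for ind, ser in series.items():
        ok = ser[ser["valid"]].copy()
        d = bathy.sample(ok["x"].to_numpy(), ok["y"].to_numpy())
        ok["depth_m"] = np.clip(np.where(np.isnan(d), 0.5, d), 0.0, None)
        ok["id"] = ind
        loc_rows.append(ok)
    locs = pd.concat(loc_rows, ignore_index=True)
    tl = tmp.classify_tide(tide, locs["timestamp"])
    locs["tidal"] = tl["tidal"].to_numpy()
    locs["diel"] = tmp.classify_diel(locs["timestamp"]).to_numpy()
    locs["depth_bin"] = tmp.bin_depth(locs["depth_m"].to_numpy()).to_numpy()
    locs["depth_ord"] = locs["depth_bin"].map(tmp.DEPTH_BIN_ORDINAL)
    locs["log_rt"] = np.log(locs["rt"] + rsd.LOG_RT_OFFSET_H)
    locs["ecoregion"] = eco.label_cells(locs, slices, partition).to_numpy()

    cycle_reports = {}
    for reg, sub in locs.groupby("ecoregion"):
        rep = {}
        for resp in ("log_rt", "depth_ord"):
            try:
                rep[resp] = tmp.fit_cycle_lmm(sub, resp)
            except (ValueError, np.linalg.LinAlgError) as e:
                rep[resp] = {"error": str(e)}
        cycle_reports[reg] = rep

    excursions = tmp.detect_excursions(series, geometry, tide)
    closed = [e for e in excursions if not e.open_ended]
    excursion_tests = {}
    if closed:
        excursion_tests["outward"] = tmp.excursion_timing_test(closed, "outward", seed=int(s_dens))
        excursion_tests["inward"] = tmp.excursion_timing_test(closed, "inward", seed=int(s_dens) + 1)

    # --- cross-validation ---------------------------------------------------
    density = syn.generate_density_surface(
        use_grid.rename(columns={"intensity": "intensity"}),
        daytime_bias=daytime_bias,
        seed=int(s_dens),
    )
    cells = predicted.copy()
    cells["habitat_class"] = cvl.classify_habitat(cells["predicted"].to_numpy()).to_numpy()
    cells = cvl.align_density(cells, density)
    report = cvl.discrepancy(cells)

    n_hourly = int(sum(len(s) for s in series.values()))
    summary = {
        "n_raw_fixes": int(len(sim.fixes)),
        "n_filtered_fixes": int(n_filtered),
        "n_hourly_locations": n_hourly,
        "n_rt_locations": int(locs.shape[0]),
        "chosen_radius_km": rho / 1000.0,
        "selected_k": partition.k,
        "n_slices": int(len(profiles)),
        "deviance_explained_pct": model.deviance_explained_pct,
        "overall_pearson_r": report.overall_r,
        "pct_newly_predicted": report.pct_newly_predicted,
        "pct_omitted": report.pct_omitted,
        "n_excursions": len(closed),
        "mean_excursion_duration_h": float(
            np.mean([e.duration_h for e in closed]) if closed else np.nan
        ),
    }
    if "chi2" in sex_test:
        summary["sex_effect_chi2"] = sex_test["chi2"]
        summary["sex_effect_p"] = sex_test["p"]

    return PipelineResult(
        geometry=geometry,
        bathymetry=bathy,
        tide=tide,
        sim=sim,
        hourly=hourly,
        series=series,
        scale=scale,
        sex_test=sex_test,
        grid=grid,
        covariates=covariates,
        slices=slices,
        profiles=profiles,
        partition=partition,
        use_grid=use_grid,
        predictors=predictors,
        model=model,
        predicted=predicted,
        cycle_reports=cycle_reports,
        excursions=excursions,
        excursion_tests=excursion_tests,
        density=density,
        crossval=report,
        summary=summary,
    )
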