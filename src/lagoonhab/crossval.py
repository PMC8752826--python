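"""Cross-validation of predicted intensity of use against an independent
density surface.

Predictions are sqrt-transformed and the top/bottom 10% classified as highly
suitable / poor habitat. Each 500-m cell inherits the density of the 1.6-km
cell containing its centroid; densities are classed low (0), medium (0,
0.10), high [0.10, 0.50] and very high (>0.50 dugongs/km²). Cells suitable
but low-density are "newly predicted"; poor but high/very-high are
"omitted". Pearson correlations are reported overall and within four depth
strata: shallow [0,2], medium (2,10], deep (10,60] and very deep >60 m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

log = logging.getLogger(__name__)

DENSITY_BREAKS = (0.10, 0.50)  # high in [0.10, 0.50], very high above
DEPTH_STRATA = [
    ("shallow", 0.0, 2.0),
    ("medium", 2.0, 10.0),
    ("deep", 10.0, 60.0),
    ("very_deep", 60.0, np.inf),
]


def classify_habitat(predicted: np.ndarray, q: float = 0.10) -> pd.Series:
    """suitable / intermediate / poor classes of a predicted surface.

    The surface is sqrt-transformed; cells strictly above the (1-q) quantile
    are suitable, strictly below the q quantile poor. Quantiles use the
    inclusive linear-interpolation definition; cells tied with a threshold
    fall in the intermediate class (deterministic lower-rank rule). A
    constant surface is all-intermediate, with a warning.
    """
    v = np.sqrt(np.asarray(predicted, float))
    if np.nanmax(v) - np.nanmin(v) < 1e-12:
        log.warning("constant predicted surface: habitat classes degenerate")
        return pd.Series(np.full(len(v), "intermediate"))
    lo, hi = np.nanquantile(v, [q, 1 - q])
    lab = np.where(v > hi, "suitable", np.where(v < lo, "poor", "intermediate"))
    return pd.Series(lab, name="habitat_class")


def classify_density(density: np.ndarray) -> pd.Series:
    """low (0), medium (0, 0.10), high [0.10, 0.50], very_high (>0.50)."""
    d = np.asarray(density, float)
    lab = np.where(
        d <= 0,
        "low",
        np.where(d < DENSITY_BREAKS[0], "medium", np.where(d <= DENSITY_BREAKS[1], "high", "very_high")),
    )
    return pd.Series(lab, name="density_class")


def align_density(
    cells: pd.DataFrame,
    density: pd.DataFrame,
    resolution: float = 1600.0,
) -> pd.DataFrame:
    """Attach the parent 1.6-km density value/class to each 500-m cell.

    ``density`` carries px, py parent indices (floor(x/resolution)) and a
    density column. Cells without density coverage are dropped with a logged
    count.
    """
    out = cells.copy()
    out["px"] = np.floor(out["x"] / resolution).astype(int)
    out["py"] = np.floor(out["y"] / resolution).astype(int)
    merged = out.merge(density[["px", "py", "density"]], on=["px", "py"], how="left")
    n_missing = int(merged["density"].isna().sum())
    if n_missing:
        log.info("%d cells outside density coverage excluded", n_missing)
        merged = merged.dropna(subset=["density"])
    merged["density_class"] = classify_density(merged["density"].to_numpy()).to_numpy()
    return merged


@dataclass
class CrossValReport:
    overall_r: float
    overall_t: float
    overall_p: float
    pct_newly_predicted: float
    pct_omitted: float
    by_stratum: pd.DataFrame
    cells: pd.DataFrame = field(repr=False, default=None)


def discrepancy(
    cells: pd.DataFrame,
    depth_col: str = "depth",
    pred_col: str = "predicted",
) -> CrossValReport:
    """Discrepancy mapping and correlation between predictions and density.

    ``cells`` must carry habitat_class, density_class, a predicted intensity
    and a raw depth (m). newly_predicted = suitable & low density; omitted =
    poor & (high | very_high). Percentages are over compared cells within
    each stratum.
    """
    df = cells.copy()
    df["discrepancy"] = "concordant"
    newly = (df["habitat_class"] == "suitable") & (df["density_class"] == "low")
    omitted = (df["habitat_class"] == "poor") & (
        df["density_class"].isin(["high", "very_high"])
    )
    df.loc[newly, "discrepancy"] = "newly_predicted"
    df.loc[omitted, "discrepancy"] = "omitted"

    def _corr(sub):
        if len(sub) < 3 or sub[pred_col].std() == 0 or sub["density"].std() == 0:
            return np.nan, np.nan, np.nan
        r, p = pearsonr(sub[pred_col], sub["density"])
        t = r * np.sqrt((len(sub) - 2) / max(1 - r**2, 1e-12))
        return r, t, p

    r, t, p = _corr(df)
    rows = []
    for name, lo, hi in DEPTH_STRATA:
        sub = df[(df[depth_col] > lo) & (df[depth_col] <= hi)] if name != "shallow" else df[
            (df[depth_col] >= 0) & (df[depth_col] <= hi)
        ]
        sr, st, sp = _corr(sub)
        n = len(sub)
        rows.append(
            {
                "stratum": name,
                "n": n,
                "r": sr,
                "t": st,
                "p": sp,
                "pct_newly_predicted": 100.0 * (sub["discrepancy"] == "newly_predicted").mean() if n else np.nan,
                "pct_omitted": 100.0 * (sub["discrepancy"] == "omitted").mean() if n else np.nan,
            }
        )
    return CrossValReport(
        overall_r=float(r) if np.isfinite(r) else np.nan,
        overall_t=float(t) if np.isfinite(t) else np.nan,
        overall_p=float(p) if np.isfinite(p) else np.nan,
        pct_newly_predicted=100.0 * float(newly.mean()),
        pct_omitted=100.0 * float(omitted.mean()),
        by_stratum=pd.DataFrame(rows),
        cells=df,
    )
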