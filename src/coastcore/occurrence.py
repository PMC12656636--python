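"""Occurrence-record cleaning, site consolidation and change analysis.

Survey records (x, y, date, count) carry detections (count > 0) and
non-detections (count = 0).  This module assigns national-survey period
labels, consolidates records into unique sites with DBSCAN so clumped
duplicates and GPS scatter do not inflate counts, computes per-period
detection rates with bootstrap confidence intervals, classifies 500 m
grid cells into persistence/loss/gain/no-detection between a past and a
recent era, and exports de-identified per-cell aggregates that carry no
raw coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

__all__ = [
    "PERIOD_YEARS",
    "assign_periods",
    "consolidate_sites",
    "unique_sites_per_period",
    "detection_rate_ci",
    "percent_change",
    "grid_change_classify",
    "deidentify_export",
]

# National-survey review periods (inclusive year ranges).
PERIOD_YEARS: dict[str, tuple[int, int]] = {
    "P1": (2008, 2008),
    "P2": (2014, 2016),
    "P3": (2020, 2022),
    "P4": (2023, 2024),
}


def assign_periods(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label records with survey periods from their dates.

    Years inside no window get the label ``"none"``.  Records whose date
    cannot be parsed are excluded and returned in a separate error frame.

    Returns (labeled table, error records).
    """
    table = table.copy()
    dates = pd.to_datetime(table["date"], errors="coerce", format="ISO8601")
    bad = dates.isna()
    errors = table.loc[bad].copy()
    errors["error"] = "unparseable date"
    table = table.loc[~bad].copy()
    years = dates.loc[~bad].dt.year
    period = pd.Series("none", index=table.index, dtype=object)
    for label, (y0, y1) in PERIOD_YEARS.items():
        period[(years >= y0) & (years <= y1)] = label
    table["period"] = period
    table["presence"] = table["count"] > 0
    return table, errors


def consolidate_sites(points: np.ndarray, eps_m: float = 30.0, min_pts: int = 1) -> np.ndarray:
    """Cluster point records into unique sites (DBSCAN, Euclidean meters).

    With ``min_pts=1`` the clusters are exactly the connected components
    of the graph joining points within ``eps_m``, so every point is
    assigned (no noise label).  Returns integer labels, one per point,
    with consecutive ids in order of first appearance.
    """
    if eps_m <= 0:
        raise ValueError("eps_m must be positive")
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return np.empty(0, dtype=int)
    labels = DBSCAN(eps=eps_m, min_samples=min_pts).fit_predict(points)
    # with min_samples=1 there is no noise; relabel in first-appearance order
    order = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        out[i] = order.setdefault(lab, len(order))
    return out


def site_representatives(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Centroid of each cluster, indexed by label id."""
    points = np.asarray(points, dtype=float)
    n = labels.max() + 1 if len(labels) else 0
    return np.array([points[labels == k].mean(axis=0) for k in range(n)])


def unique_sites_per_period(table: pd.DataFrame, eps_m: float = 30.0) -> pd.DataFrame:
    """Unique presence sites per period after spatial consolidation.

    Consolidation is applied per period over presence records.  Returns a
    frame with period, number of unique presence sites, and the number of
    surveyed sites (unique sites among all records, detections or not).
    """
    rows = []
    for period in PERIOD_YEARS:
        sub = table[table["period"] == period]
        if len(sub) == 0:
            rows.append((period, 0, 0))
            continue
        # one clustering over all records (detections and non-detections):
        # a presence site is a surveyed site with at least one detection,
        # so presence sites can never outnumber surveyed sites
        labels = consolidate_sites(sub[["x", "y"]].to_numpy(), eps_m)
        n_surv = labels.max() + 1
        n_pres = len(np.unique(labels[sub["presence"].to_numpy()]))
        rows.append((period, n_pres, n_surv))
    return pd.DataFrame(rows, columns=["period", "n_presence_sites", "n_surveyed_sites"])


def detection_rate_ci(
    n_presence_sites: int,
    n_surveyed_sites: int,
    R: int = 1000,
    seed: int = 42,
) -> dict[str, float]:
    """Detection rate with a percentile bootstrap 95% CI.

    The rate is presence sites / surveyed sites; the bootstrap resamples
    the site-level Bernoulli outcomes (R resamples, 2.5/97.5 percentiles).
    """
    if n_surveyed_sites < 1:
        raise ValueError("need at least one surveyed site")
    if not 0 <= n_presence_sites <= n_surveyed_sites:
        raise ValueError("presence sites must be within [0, surveyed sites]")
    outcomes = np.zeros(n_surveyed_sites)
    outcomes[:n_presence_sites] = 1.0
    rate = outcomes.mean()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_surveyed_sites, size=(R, n_surveyed_sites))
    boot = outcomes[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {"rate": float(rate), "ci_low": float(lo), "ci_high": float(hi)}


def percent_change(peak_count: int, recent_count: int) -> float:
    """Signed percent change from a peak count, one-decimal reporting."""
    if peak_count <= 0:
        raise ValueError("peak_count must be positive")
    return round(100.0 * (recent_count - peak_count) / peak_count, 1)


def _grid_index(table: pd.DataFrame, cell_m: float, origin: tuple[float, float]):
    ci = np.floor((table["x"].to_numpy() - origin[0]) / cell_m).astype(int)
    cj = np.floor((table["y"].to_numpy() - origin[1]) / cell_m).astype(int)
    return ci, cj


def grid_change_classify(
    table: pd.DataFrame,
    cell_m: float = 500.0,
    past_periods: tuple[str, ...] = ("P1", "P2", "P3"),
    recent_periods: tuple[str, ...] = ("P4",),
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Classify grid cells into persistence / loss / gain / no_detection.

    Detections are pooled into a past and a recent era; per cell:
    persistence = presence in both, loss = past only, gain = recent only,
    no_detection = surveyed but never detected.  The grid is anchored at
    the study-bounds lower-left unless an explicit origin is given.
    """
    if origin is None:
        origin = (float(table["x"].min()), float(table["y"].min()))
    ci, cj = _grid_index(table, cell_m, origin)
    df = table.copy()
    df["cell_i"], df["cell_j"] = ci, cj
    past = df["period"].isin(past_periods) & df["presence"]
    recent = df["period"].isin(recent_periods) & df["presence"]
    grouped = df.groupby(["cell_i", "cell_j"]).apply(
        lambda g: pd.Series(
            {
                "past": bool(past.loc[g.index].any()),
                "recent": bool(recent.loc[g.index].any()),
            }
        ),
        include_groups=False,
    )

    def classify(row):
        if row["past"] and row["recent"]:
            return "persistence"
        if row["past"]:
            return "loss"
        if row["recent"]:
            return "gain"
        return "no_detection"

    grouped["class"] = grouped.apply(classify, axis=1)
    return grouped.reset_index()[["cell_i", "cell_j", "class"]]


def deidentify_export(
    table: pd.DataFrame,
    cell_m: float = 500.0,
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Aggregate records to grid cells, dropping all raw coordinates.

    The export carries only cell indices and counts (records, presences),
    conserving record totals, so it is safe to publish for a species
    whose precise localities must stay withheld.
    """
    if origin is None:
        origin = (float(table["x"].min()), float(table["y"].min()))
    ci, cj = _grid_index(table, cell_m, origin)
    df = pd.DataFrame(
        {
            "cell_i": ci,
            "cell_j": cj,
            "n_records": 1,
            "n_presence": (table["count"] > 0).astype(int),
        }
    )
    return df.groupby(["cell_i", "cell_j"], as_index=False).sum()
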