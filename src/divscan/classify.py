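"""Scenario classification of windows from z-standardized statistics.

For each pairwise comparison the window statistics (F_ST, D_XY, and the
two populations' Pi averaged) are standardized to z-scores against the
comparison-wide mean and population (divide-by-N) standard deviation, then
pushed through four threshold rules in fixed precedence order:

1. divergence with gene flow:  z_fst > 2,  z_dxy > 3,  z_pi below the
   upper boundary (+3)
2. allopatric selection:       z_fst > 2,  z_dxy below +3,  z_pi < -1
3. recurrent selection:        z_fst > 1,  z_dxy < -1,  z_pi < -1
4. balancing selection:        z_fst below +3,  z_dxy > 3,  z_pi > 3

The "< k SD" clauses are read against the *upper* boundary for k = 3 and
the *lower* boundary for k = 1 (the band semantics drawn in the study's
scatter figure); an all-above-mean reading is available via
``ClassifierConfig(semantics="upper")``.  First match wins, so the
allopatric/recurrent overlap cannot double-count.  Windows with any
undefined statistic are excluded from the mean/sd and never classified.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import SCENARIOS, ClassifierConfig
from .errors import ConfigurationError


def standardize(values, ddof: int = 0):
    """z-scores against the mean/sd of the defined entries.

    Returns (z, flagged): all-NaN z and ``flagged=True`` when fewer than two
    defined values exist or the sd is zero.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        return np.full_like(x, np.nan), True
    mu = x[ok].mean()
    sd = x[ok].std(ddof=ddof)
    if sd == 0:
        return np.full_like(x, np.nan), True
    z = np.full_like(x, np.nan)
    z[ok] = (x[ok] - mu) / sd
    return z, False


def classify_window(z_fst, z_dxy, z_pi, semantics: str = "band") -> str:
    """Assign one window a scenario (or "none") from its three z-scores."""
    if not (np.isfinite(z_fst) and np.isfinite(z_dxy) and np.isfinite(z_pi)):
        return "none"
    if semantics == "band":
        lo1 = -1.0  # "< 1 SD": below the lower boundary
        hi3 = 3.0   # "< 3 SD": below the upper boundary
    elif semantics == "upper":
        lo1 = 1.0
        hi3 = 3.0
    else:
        raise ConfigurationError("semantics must be 'band' or 'upper'")
    if z_fst > 2 and z_dxy > 3 and z_pi < hi3:
        return "divergence_with_gene_flow"
    if z_fst > 2 and z_dxy < hi3 and z_pi < lo1:
        return "allopatric_selection"
    if z_fst > 1 and z_dxy < lo1 and z_pi < lo1:
        return "recurrent_selection"
    if z_fst < hi3 and z_dxy > 3 and z_pi > 3:
        return "balancing_selection"
    return "none"


def pair_window_table(stats: pd.DataFrame, pair) -> pd.DataFrame:
    """Wide per-window frame for one comparison: fst, dxy and averaged pi.

    ``pair`` is (pop_a, pop_b); Pi is the mean of the two populations'
    window Pi, matching how the comparison-wide Pi axis is built.
    """
    a, b = pair
    label = f"{a}|{b}"
    alt = f"{b}|{a}"
    keys = ["chrom", "window_start", "window_end"]

    def _pick(stat, who):
        sub = stats[(stats["stat"] == stat) & (stats["pop"].isin(who))]
        if sub.empty:
            raise ConfigurationError(f"no {stat} rows for comparison {label}")
        return sub.set_index(keys)["value"]

    fst = _pick("fst", [label, alt])
    dxy = _pick("dxy", [label, alt])
    pi_a = _pick("pi", [a])
    pi_b = _pick("pi", [b])
    out = pd.DataFrame({"fst": fst, "dxy": dxy, "pi_a": pi_a, "pi_b": pi_b})
    out["pi"] = (out["pi_a"] + out["pi_b"]) / 2.0
    return out.reset_index()


def classify_pair(stats: pd.DataFrame, pair,
                  cfg: ClassifierConfig | None = None) -> pd.DataFrame:
    """ScenarioCall frame for one comparison: z-scores + assigned scenario."""
    cfg = (cfg or ClassifierConfig()).validate()
    tab = pair_window_table(stats, pair)
    z = {}
    flagged = False
    for col in ("fst", "dxy", "pi"):
        z[col], bad = standardize(tab[col], ddof=cfg.sd_ddof)
        flagged |= bad
    tab["z_fst"], tab["z_dxy"], tab["z_pi"] = z["fst"], z["dxy"], z["pi"]
    tab["pair"] = f"{pair[0]}|{pair[1]}"
    if flagged:
        tab["scenario"] = "none"
        tab.attrs["degenerate"] = True
        return tab
    tab["scenario"] = [
        classify_window(f, d, p, cfg.semantics)
        for f, d, p in zip(tab["z_fst"], tab["z_dxy"], tab["z_pi"])
    ]
    tab.attrs["degenerate"] = False
    return tab


def dxy_pi_relationship(pair_table: pd.DataFrame):
    """OLS slope of D_XY on averaged Pi and the Spearman rank correlation.

    Returns (slope, rho); both NaN when fewer than three windows have both
    statistics defined or the Pi variance is degenerate.
    """
    sub = pair_table[["pi", "dxy"]].dropna()
    if len(sub) < 3 or sub["pi"].nunique() < 2:
        return math.nan, math.nan
    fit = sps.linregress(sub["pi"], sub["dxy"])
    rho = sps.spearmanr(sub["pi"], sub["dxy"]).statistic
    return float(fit.slope), float(rho)


def fst_outlier_windows(calls: pd.DataFrame, regions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Windows with z_fst strictly above +3, mapped to overlapping genic
    regions (empty gene list when none overlaps)."""
    out = calls[calls["z_fst"] > 3].copy()
    genes = []
    if regions is not None and len(regions):
        genic = regions[regions["genic"].astype(int) == 1]
        by_chrom = {c: g for c, g in genic.groupby("chrom")}
        for row in out.itertuples(index=False):
            g = by_chrom.get(row.chrom)
            if g is None:
                genes.append([])
                continue
            # window [start, end] 1-based vs region [start, end) 0-based
            hit = g[(g["start"] < row.window_end) & (g["end"] > row.window_start - 1)]
            genes.append(sorted(hit["region_id"]))
    else:
        genes = [[] for _ in range(len(out))]
    out["genes"] = genes
    return out


def pair_summary(calls: pd.DataFrame, pair) -> dict:
    """Scenario counts, total analyzed windows, and the D_XY~Pi slope/rho
    for one comparison (one row of the per-pair summary table)."""
    analyzed = calls[np.isfinite(calls["z_fst"]) & np.isfinite(calls["z_dxy"])
                     & np.isfinite(calls["z_pi"])]
    slope, rho = dxy_pi_relationship(calls)
    row = {"pair": f"{pair[0]}|{pair[1]}"}
    for s in SCENARIOS:
        row[s] = int((analyzed["scenario"] == s).sum())
    row["total_windows"] = int(len(analyzed))
    row["slope"] = slope
    row["rho"] = rho
    return row


def summarize_pairs(stats: pd.DataFrame, pairs,
                    cfg: ClassifierConfig | None = None):
    """Classify every comparison; returns (per-pair summary frame,
    dict pair -> ScenarioCall frame)."""
    rows, calls = [], {}
    for pair in pairs:
        c = classify_pair(stats, pair, cfg)
        calls[tuple(pair)] = c
        rows.append(pair_summary(c, pair))
    return pd.DataFrame(rows), calls
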