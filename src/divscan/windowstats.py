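"""Missing-data-aware windowed Pi, D_XY, Hudson's F_ST and Tajima's D.

Every window statistic here is a ratio of sums over sites (counts of
differences over counts of comparisons), never a mean of per-site ratios.
That choice is what makes the estimators unbiased under per-genotype
missingness: a site genotyped in fewer haplotypes simply contributes fewer
comparisons, and invariant sites contribute comparisons without
differences, keeping the per-bp scale honest.

The F_ST site estimator is the Hudson form with the Bhatia et al. sample-
size correction; the window value is the ratio of summed numerators to
summed denominators ("ratio of averages") and is deliberately not clamped
at zero so that downstream z-standardization stays unbiased.

Tajima's D is computed per window per population on complete-case sites:
any site with a missing genotype in the focal population is excluded and n
stays at the full haplotype count, matching the fixed-n formula of the
classic implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .ingest import WindowAssignment
from .table import GenotypeTable

# ---------------------------------------------------------------------------
# site-level estimators (exact integer/rational arithmetic where possible)
# ---------------------------------------------------------------------------

def site_pi(c1, n):
    """Within-population differences and comparisons at one site.

    c1 ALT alleles among n genotyped haplotypes; returns
    (c0*c1, n*(n-1)/2).  Needs n >= 2; an invariant site yields
    (0, comparisons).
    """
    if n < 2:
        raise ConfigurationError("site_pi needs at least two genotyped haplotypes")
    return c1 * (n - c1), n * (n - 1) // 2


def site_dxy(c1a, na, c1b, nb):
    """Between-population differences and comparisons at one site:
    (cA0*cB1 + cA1*cB0, nA*nB).  Needs nA >= 1 and nB >= 1."""
    if na < 1 or nb < 1:
        raise ConfigurationError("site_dxy needs a genotyped haplotype on each side")
    return c1a * (nb - c1b) + (na - c1a) * c1b, na * nb


def hudson_fst_site(p1, n1, p2, n2, corrected=True):
    """Hudson F_ST numerator/denominator at one site.

    With the Bhatia-style sample-size correction (default):
        num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)
    Uncorrected form uses the plug-in within-heterozygosity instead.
    """
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("hudson_fst_site needs n >= 2 on both sides")
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if corrected:
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    else:
        num = den - p1 * (1 - p1) - p2 * (1 - p2)
    return num, den


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Tajima's normalizing constants for n haplotypes."""
    if n < 2:
        raise ConfigurationError("Tajima's D needs at least two haplotypes")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(S, theta_pi, n):
    """Standardized difference D = (theta_pi - S/a1) / sd for one window.

    ``theta_pi`` is the sum of per-site pairwise-difference proportions over
    the window's segregating sites; undefined (NaN) when S == 0.
    """
    if S == 0:
        return math.nan
    k = tajima_constants(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    return (theta_pi - S / k.a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# vectorized window aggregation
# ---------------------------------------------------------------------------

def _bincount(widx, weights, n_win):
    return np.bincount(widx, weights=weights, minlength=n_win)[:n_win]


def window_pi(c1, n, widx, n_win, min_sites=1):
    """Per-window Pi for one population from per-site ALT counts.

    Returns (pi, n_sites_used, n_variant_sites); pi is NaN where the
    comparison count is zero or fewer than ``min_sites`` sites were usable.
    """
    usable = n >= 2
    diffs = np.where(usable, c1 * (n - c1), 0).astype(np.float64)
    comps = np.where(usable, n * (n - 1) // 2, 0).astype(np.float64)
    sum_d = _bincount(widx, diffs, n_win)
    sum_c = _bincount(widx, comps, n_win)
    n_sites = _bincount(widx, usable.astype(np.float64), n_win)
    variant = usable & (c1 > 0) & (c1 < n)
    n_var = _bincount(widx, variant.astype(np.float64), n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where((sum_c > 0) & (n_sites >= min_sites), sum_d / sum_c, np.nan)
    return pi, n_sites.astype(int), n_var.astype(int)


def window_dxy(c1a, na, c1b, nb, widx, n_win, min_sites=1):
    """Per-window D_XY for one population pair (ratio of sums)."""
    usable = (na >= 1) & (nb >= 1)
    diffs = np.where(usable, c1a * (nb - c1b) + (na - c1a) * c1b, 0).astype(np.float64)
    comps = np.where(usable, na * nb, 0).astype(np.float64)
    sum_d = _bincount(widx, diffs, n_win)
    sum_c = _bincount(widx, comps, n_win)
    n_sites = _bincount(widx, usable.astype(np.float64), n_win)
    variant = usable & (((c1a > 0) & (c1a < na)) | ((c1b > 0) & (c1b < nb)) |
                        (np.where(na > 0, c1a == na, False) != np.where(nb > 0, c1b == nb, False)))
    n_var = _bincount(widx, variant.astype(np.float64), n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        dxy = np.where((sum_c > 0) & (n_sites >= min_sites), sum_d / sum_c, np.nan)
    return dxy, n_sites.astype(int), n_var.astype(int)


def window_fst(c1a, na, c1b, nb, widx, n_win, corrected=True, min_sites=1):
    """Per-window Hudson F_ST: summed numerators over summed denominators.

    May be negative; NaN where the total denominator is zero.
    """
    usable = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(usable, c1a / np.maximum(na, 1), 0.0)
        p2 = np.where(usable, c1b / np.maximum(nb, 1), 0.0)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if corrected:
            num = (p1 - p2) ** 2 \
                - p1 * (1 - p1) / np.maximum(na - 1, 1) \
                - p2 * (1 - p2) / np.maximum(nb - 1, 1)
        else:
            num = den - p1 * (1 - p1) - p2 * (1 - p2)
        num = np.where(usable, num, 0.0)
        den = np.where(usable, den, 0.0)
    sum_n = _bincount(widx, num, n_win)
    sum_d = _bincount(widx, den, n_win)
    n_sites = _bincount(widx, usable.astype(np.float64), n_win)
    n_var = _bincount(widx, (den > 0).astype(np.float64), n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where((sum_d > 0) & (n_sites >= min_sites), sum_n / sum_d, np.nan)
    return fst, n_sites.astype(int), n_var.astype(int)


def window_tajimas_d(c1, n, n_hap, widx, n_win):
    """Per-window Tajima's D for one population (complete-case sites).

    Sites with any missing genotype in the population (n < n_hap) are
    excluded; n stays at the full haplotype count ``n_hap``.
    """
    complete = n == n_hap
    seg = complete & (c1 > 0) & (c1 < n_hap)
    S = _bincount(widx, seg.astype(np.float64), n_win)
    pair_prop = np.where(seg, c1 * (n_hap - c1) / (n_hap * (n_hap - 1) / 2.0), 0.0)
    theta_pi = _bincount(widx, pair_prop, n_win)
    k = tajima_constants(n_hap)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = k.e1 * S + k.e2 * S * (S - 1)
        d = np.where(S > 0, (theta_pi - S / k.a1) / np.sqrt(np.where(var > 0, var, 1.0)), np.nan)
    n_complete = _bincount(widx, complete.astype(np.float64), n_win)
    return d, n_complete.astype(int), S.astype(int)


# ---------------------------------------------------------------------------
# tidy driver
# ---------------------------------------------------------------------------

def compute_window_stats(table: GenotypeTable, assignment: WindowAssignment,
                         pairs=None, min_sites: int = 1,
                         fst_corrected: bool = True,
                         with_tajima: bool = True) -> pd.DataFrame:
    """All window statistics for every population and population pair.

    Returns a tidy frame with one row per window x statistic:
    chrom, window_start, window_end, pop (or "A|B" pair), stat
    (pi | dxy | fst | tajima_d), value, n_sites, n_variant_sites.
    """
    pops = table.populations
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    widx = assignment.window_index
    win = assignment.windows
    n_win = len(win)

    counts = {}
    n_hap = {}
    for p in pops:
        idx = table.population_indices(p)
        counts[p] = table.allele_counts(idx)
        n_hap[p] = 2 * len(idx)

    frames = []
    base = win[["chrom", "window_start", "window_end"]]

    def _emit(stat, who, value, n_sites, n_var):
        df = base.copy()
        df["pop"] = who
        df["stat"] = stat
        df["value"] = value
        df["n_sites"] = n_sites
        df["n_variant_sites"] = n_var
        frames.append(df)

    for p in pops:
        c1, n = counts[p]
        pi, ns, nv = window_pi(c1, n, widx, n_win, min_sites)
        _emit("pi", p, pi, ns, nv)
        if with_tajima:
            d, ns, nv = window_tajimas_d(c1, n, n_hap[p], widx, n_win)
            _emit("tajima_d", p, d, ns, nv)

    for a, b in pairs:
        c1a, na = counts[a]
        c1b, nb = counts[b]
        label = f"{a}|{b}"
        dxy, ns, nv = window_dxy(c1a, na, c1b, nb, widx, n_win, min_sites)
        _emit("dxy", label, dxy, ns, nv)
        fst, ns, nv = window_fst(c1a, na, c1b, nb, widx, n_win, fst_corrected, min_sites)
        _emit("fst", label, fst, ns, nv)

    return pd.concat(frames, ignore_index=True)


def write_stats_tsv(stats: pd.DataFrame, path, header_comment=None):
    with open(path, "w") as fh:
        if header_comment:
            for line in str(header_comment).splitlines():
                fh.write(f"# {line}\n")
        stats.to_csv(fh, sep="\t", index=False, na_rep="NA")
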