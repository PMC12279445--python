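"""Independent brute-force oracles used to validate the estimators.

These deliberately share no code with the package: diversity statistics
are computed by exhaustive enumeration of haplotype pairs, and Tajima's
constants with exact rational arithmetic, so agreement is evidence rather
than tautology.
"""

from fractions import Fraction
from itertools import combinations
from math import sqrt


def haplotypes_at_site(genotypes_row, sample_idx):
    """Observed haplotype alleles at one site for the given samples,
    skipping genotypes with any missing allele."""
    out = []
    for j in sample_idx:
        a, b = genotypes_row[j]
        if a >= 0 and b >= 0:
            out.extend([int(a), int(b)])
    return out


def enum_pi(table, sample_idx, site_mask=None):
    """Window Pi by enumerating every within-population haplotype pair,
    summing difference and comparison *counts* across sites."""
    diffs = comps = 0
    for s in range(table.n_sites):
        if site_mask is not None and not site_mask[s]:
            continue
        hap = haplotypes_at_site(table.genotypes[s], sample_idx)
        if len(hap) < 2:
            continue
        for x, y in combinations(hap, 2):
            diffs += x != y
            comps += 1
    return diffs / comps if comps else float("nan")


def enum_dxy(table, idx_a, idx_b, site_mask=None):
    """Window D_XY by enumerating every cross-population haplotype pair."""
    diffs = comps = 0
    for s in range(table.n_sites):
        if site_mask is not None and not site_mask[s]:
            continue
        ha = haplotypes_at_site(table.genotypes[s], idx_a)
        hb = haplotypes_at_site(table.genotypes[s], idx_b)
        if not ha or not hb:
            continue
        for x in ha:
            for y in hb:
                diffs += x != y
                comps += 1
    return diffs / comps if comps else float("nan")


def enum_hudson_fst(table, idx_a, idx_b, site_mask=None):
    """Window Hudson F_ST via the identity
    num = dxy_site - (hw_a + hw_b)/2, den = dxy_site,
    with hw the enumerated (unbiased) within-population pairwise-difference
    proportion -- an independent route to the Bhatia-corrected estimator."""
    num = den = 0.0
    for s in range(table.n_sites):
        if site_mask is not None and not site_mask[s]:
            continue
        ha = haplotypes_at_site(table.genotypes[s], idx_a)
        hb = haplotypes_at_site(table.genotypes[s], idx_b)
        if len(ha) < 2 or len(hb) < 2:
            continue
        dxy = sum(x != y for x in ha for y in hb) / (len(ha) * len(hb))
        hw_a = _pairwise_prop(ha)
        hw_b = _pairwise_prop(hb)
        num += dxy - (hw_a + hw_b) / 2.0
        den += dxy
    return num / den if den else float("nan")


def _pairwise_prop(hap):
    pairs = list(combinations(hap, 2))
    return sum(x != y for x, y in pairs) / len(pairs)


def exact_tajimas_d(allele_counts, n):
    """Tajima's D from per-site (alt_count, n) pairs using exact rational
    constants; ``allele_counts`` lists segregating-candidate sites with all
    n haplotypes observed."""
    seg = [c for c in allele_counts if 0 < c < n]
    S = len(seg)
    if S == 0:
        return float("nan")
    theta_pi = sum(Fraction(c * (n - c), n * (n - 1) // 2) for c in seg)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float(theta_pi - S / a1) / sqrt(float(var))
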