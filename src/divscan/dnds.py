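"""Degenerate-site dN/dS per gene x population against the outgroup.

The approximation treats every codon as 4-fold degenerate: positions 1-2
are counted as non-synonymous sites and position 3 as synonymous,
regardless of the actual genetic code.  For each gene and population, only
sites with at most 50% missing genotypes in the population and at least
one genotyped outgroup allele are retained; a fixed difference is a site
where the allele sets observed in the population and in the outgroup are
disjoint.  dN is fixed non-synonymous differences over covered
non-synonymous sites, dS the synonymous analogue, and a gene enters the
ratio only with at least one fixed site of each class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DnDsConfig
from .errors import ConfigurationError
from .table import GenotypeTable

EXCLUDED, NONSYN, SYN = 0, 1, 2


def codon_site_classes(length_bp: int, frame) -> np.ndarray:
    """Per-position class labels for a gene of ``length_bp`` bases.

    The first ``frame`` bases and any trailing partial codon are excluded;
    codon offsets 1-2 are non-synonymous, offset 3 synonymous.
    """
    if frame == ".":
        raise ConfigurationError("gene has no reading frame")
    frame = int(frame)
    labels = np.full(length_bp, EXCLUDED, dtype=np.int8)
    usable = length_bp - frame
    n_codons = usable // 3
    offs = frame + np.arange(n_codons * 3)
    cls = np.arange(n_codons * 3) % 3
    labels[offs[cls < 2]] = NONSYN
    labels[offs[cls == 2]] = SYN
    return labels


def _observed_sets(genotypes):
    """(n_sites,) arrays: has_ref, has_alt, any_observed over a sample block
    (biallelic assumption; multi-allelic records must be filtered first)."""
    ok = (genotypes >= 0).all(axis=2)
    n = 2 * ok.sum(axis=1)
    c1 = np.where(ok, genotypes.sum(axis=2), 0).sum(axis=1)
    has_alt = c1 > 0
    has_ref = c1 < n
    return has_ref & (n > 0), has_alt, n


def is_fixed_difference(pop_alleles, outgroup_alleles) -> bool:
    """True iff the observed allele sets are disjoint (both nonempty)."""
    pop, og = set(pop_alleles), set(outgroup_alleles)
    return bool(pop) and bool(og) and not (pop & og)


def gene_dnds(table: GenotypeTable, region_row, population,
              cfg: DnDsConfig | None = None) -> dict:
    """dN/dS record for one gene x population.

    ``region_row`` needs chrom/start/end/frame (manifest semantics,
    0-based half-open).  The returned dict always carries the covered and
    fixed counts; ``ratio`` is NaN and ``excluded_reason`` is set when a
    gate fails.
    """
    cfg = (cfg or DnDsConfig()).validate()
    chrom = region_row["chrom"] if isinstance(region_row, dict) else region_row.chrom
    start = int(region_row["start"] if isinstance(region_row, dict) else region_row.start)
    end = int(region_row["end"] if isinstance(region_row, dict) else region_row.end)
    frame = region_row["frame"] if isinstance(region_row, dict) else region_row.frame
    gene_id = region_row["region_id"] if isinstance(region_row, dict) else region_row.region_id

    rec = dict(gene=gene_id, population=population,
               covered_nonsyn_sites=0, covered_syn_sites=0,
               fixed_nonsyn=0, fixed_syn=0,
               dN=np.nan, dS=np.nan, ratio=np.nan, excluded_reason="")

    if frame == "." or frame is None:
        rec["excluded_reason"] = "no_frame"
        return rec

    labels = codon_site_classes(end - start, frame)
    mask = (table.chrom == chrom) & (table.pos > start) & (table.pos <= end)
    if not mask.any():
        rec["excluded_reason"] = "no_sites"
        return rec
    pos0 = table.pos[mask] - 1 - start
    site_cls = labels[pos0]

    pop_idx = table.population_indices(population)
    og_idx = table.outgroup_indices()
    if len(pop_idx) == 0:
        raise ConfigurationError(f"population {population!r} has no samples")

    gp = table.genotypes[mask][:, pop_idx, :]
    pop_missing = (gp < 0).any(axis=2).mean(axis=1)
    pop_ref, pop_alt, pop_n = _observed_sets(gp)

    if len(og_idx):
        go = table.genotypes[mask][:, og_idx, :]
        og_ref, og_alt, og_n = _observed_sets(go)
    else:
        og_ref = og_alt = np.zeros(mask.sum(), dtype=bool)
        og_n = np.zeros(mask.sum(), dtype=int)

    covered = (pop_missing <= cfg.max_missing_fraction) & (pop_n > 0)
    if cfg.require_outgroup:
        covered &= og_n > 0

    # allele-set disjointness; on biallelic data this coincides with the
    # strict "both monomorphic, for different alleles" reading
    if cfg.fixed_rule == "strict":
        fixed = covered & (
            ((pop_alt & ~pop_ref) & (og_ref & ~og_alt))
            | ((pop_ref & ~pop_alt) & (og_alt & ~og_ref))
        )
    else:
        fixed = covered & (
            (~(pop_ref & og_ref)) & (~(pop_alt & og_alt))
        ) & (pop_ref | pop_alt) & (og_ref | og_alt)

    is_n = site_cls == NONSYN
    is_s = site_cls == SYN
    rec["covered_nonsyn_sites"] = int((covered & is_n).sum())
    rec["covered_syn_sites"] = int((covered & is_s).sum())
    rec["fixed_nonsyn"] = int((fixed & is_n).sum())
    rec["fixed_syn"] = int((fixed & is_s).sum())

    if rec["covered_nonsyn_sites"] == 0 or rec["covered_syn_sites"] == 0:
        rec["excluded_reason"] = "no_covered_sites"
        return rec
    rec["dN"] = rec["fixed_nonsyn"] / rec["covered_nonsyn_sites"]
    rec["dS"] = rec["fixed_syn"] / rec["covered_syn_sites"]
    if rec["fixed_nonsyn"] < 1 or rec["fixed_syn"] < 1:
        rec["excluded_reason"] = "fixed_site_gate"
        rec["dN"] = rec["dS"] = np.nan
        return rec
    rec["ratio"] = rec["dN"] / rec["dS"]
    return rec


def gene_dnds_table(table: GenotypeTable, regions: pd.DataFrame,
                    populations=None, cfg: DnDsConfig | None = None) -> pd.DataFrame:
    """dN/dS records for every genic region x population."""
    cfg = (cfg or DnDsConfig()).validate()
    populations = populations or table.populations
    genic = regions[regions["genic"].astype(int) == 1]
    rows = []
    for row in genic.itertuples(index=False):
        for p in populations:
            rows.append(gene_dnds(table, row, p, cfg))
    return pd.DataFrame(rows)


def dnds_outliers(genes: pd.DataFrame, sd_ddof: int = 0):
    """Per-population outlier genes: ratio strictly above mean + 3 sd.

    Returns a dict with per-population thresholds and gene sets, the
    cross-population overlap counts, and the union set.
    """
    per_pop = {}
    for p, grp in genes.groupby("population"):
        ratios = grp["ratio"].dropna()
        if len(ratios) < 2:
            per_pop[p] = dict(mean=np.nan, sd=np.nan, threshold=np.nan,
                              outliers=set(), flagged=True)
            continue
        mu, sd = ratios.mean(), ratios.std(ddof=sd_ddof)
        if sd == 0:
            per_pop[p] = dict(mean=mu, sd=0.0, threshold=np.nan,
                              outliers=set(), flagged=True)
            continue
        thr = mu + 3 * sd
        hits = set(grp.loc[grp["ratio"] > thr, "gene"])
        per_pop[p] = dict(mean=float(mu), sd=float(sd), threshold=float(thr),
                          outliers=hits, flagged=False)
    pops = sorted(per_pop)
    overlap = pd.DataFrame(
        [[len(per_pop[a]["outliers"] & per_pop[b]["outliers"]) for b in pops] for a in pops],
        index=pops, columns=pops,
    )
    union = set().union(*(per_pop[p]["outliers"] for p in pops)) if pops else set()
    return dict(per_population=per_pop, overlap=overlap, union=union)


def divergent_selection_genes(fst_outlier_genes, dnds_outlier_genes) -> list:
    """Genes with both outstanding divergence and outstanding positive
    selection: the intersection of the two outlier gene sets."""
    return sorted(set(fst_outlier_genes) & set(dnds_outlier_genes))
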