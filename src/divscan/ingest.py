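"""Reading VCFs with invariant sites and applying the study's filters.

The filter chain mirrors the VCFtools parameters used for the original
joint VCF: per-genotype quality >= 20 and depth in [15, 50] (failing
genotypes become missing), then sites with more than 10% missing genotypes
or more than two alleles are dropped.  Invariant sites survive every rule
except missingness -- they are what makes the window denominators honest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FilterConfig
from .errors import ConfigurationError, ParseError
from .table import MISSING, GenotypeTable


def read_popmap(path) -> dict:
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 'sample<TAB>population'")
            out[parts[0]] = parts[1]
    return out


def read_sample_list(path) -> list:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def read_regions(path) -> pd.DataFrame:
    """BED-like manifest: region_id, chrom, start, end, genic, frame
    (0-based half-open coordinates; frame is 0/1/2 or '.')."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{ln}: expected 6 tab-separated columns")
            frame = parts[5]
            rows.append(dict(
                region_id=parts[0], chrom=parts[1], start=int(parts[2]),
                end=int(parts[3]), genic=int(parts[4]),
                frame="." if frame == "." else int(frame),
            ))
    return pd.DataFrame(rows)


def read_vcf(path, popmap, outgroup_list=None) -> GenotypeTable:
    """Load a VCF (plain or gzipped) including invariant-site records.

    ``popmap`` / ``outgroup_list`` may be paths or an already-parsed
    dict / iterable.  Every VCF sample must appear in one of the two.
    """
    from cyvcf2 import VCF

    population_of = popmap if isinstance(popmap, dict) else read_popmap(popmap)
    if outgroup_list is None:
        outgroup = set()
    elif isinstance(outgroup_list, (list, set, tuple)):
        outgroup = set(outgroup_list)
    else:
        outgroup = set(read_sample_list(outgroup_list))

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in population_of and s not in outgroup]
    if unknown:
        raise ConfigurationError(
            "VCF samples absent from popmap/outgroup list: " + ", ".join(unknown)
        )

    chrom, pos, ref, alts, genos, depths, quals = [], [], [], [], [], [], []
    have_dp = have_rq = True
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alts.append(tuple(a for a in (v.ALT or []) if a != "<NON_REF>"))
        g = np.array([gt[:2] for gt in v.genotypes], dtype=np.int8)
        # half-calls collapse to fully missing
        g[(g < 0).any(axis=1)] = MISSING
        genos.append(g)
        dp = _format_field(v, "DP") if have_dp else None
        if dp is None:
            have_dp = False
        else:
            depths.append(np.where(dp[:, 0] < 0, 0, dp[:, 0]).astype(np.int32))
        rq = _format_field(v, "RQ") if have_rq else None
        if rq is None:
            have_rq = False
        else:
            quals.append(rq[:, 0].astype(np.float64))

    if not pos:
        raise ParseError(f"VCF {path} contains no records")

    n_sites = len(pos)
    alt_arr = np.empty(n_sites, dtype=object)
    alt_arr[:] = alts
    table = GenotypeTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alts=alt_arr,
        genotypes=np.stack(genos),
        depth=np.stack(depths) if have_dp and depths else None,
        quality=np.stack(quals).astype(np.int16) if have_rq and quals else None,
        samples=samples,
        population_of={s: p for s, p in population_of.items() if s in set(samples)},
        outgroup={s for s in outgroup if s in set(samples)},
    )
    _check_sorted(table)
    return table


def _format_field(variant, key):
    try:
        return variant.format(key)
    except KeyError:
        return None


def _check_sorted(table):
    prev_chrom, prev_pos = None, -1
    for c, p in zip(table.chrom, table.pos):
        if c == prev_chrom and p <= prev_pos:
            raise ParseError(f"positions not strictly increasing at {c}:{p}")
        if c != prev_chrom:
            prev_chrom = c
        prev_pos = p


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_genotypes(table: GenotypeTable, cfg: FilterConfig | None = None) -> GenotypeTable:
    """Set genotypes failing the depth/quality bounds to missing.

    Bounds are inclusive: depth 15 and 50 and quality 20 all survive.
    A table without depth/quality annotation passes through unchanged.
    """
    cfg = (cfg or FilterConfig()).validate()
    out = table.copy()
    if table.depth is not None:
        bad = (table.depth < cfg.min_depth) | (table.depth > cfg.max_depth)
        out.genotypes[bad] = MISSING
    if table.quality is not None:
        out.genotypes[table.quality < cfg.min_quality] = MISSING
    return out


def filter_sites(table: GenotypeTable, cfg: FilterConfig | None = None) -> GenotypeTable:
    """Drop sites exceeding the missingness bound or carrying > 2 alleles.

    Missingness counts fully-missing genotypes over all samples in the VCF
    (ingroup + outgroup) by default; invariant sites are never removed by
    the biallelic rule.
    """
    cfg = (cfg or FilterConfig()).validate()
    if cfg.missing_denominator == "ingroup":
        cols = table.sample_indices([s for s in table.samples if s in table.population_of])
    else:
        cols = np.arange(table.n_samples)
    if len(cols) == 0:
        raise ConfigurationError("no samples available for the missingness denominator")
    miss = (table.genotypes[:, cols, :] < 0).any(axis=2)
    frac = miss.mean(axis=1)
    keep = frac <= cfg.max_missing_fraction
    if cfg.biallelic_only:
        keep &= table.n_alleles <= 2
    out = table.subset_sites(keep)
    if out.n_sites == 0:
        import warnings

        warnings.warn("all sites removed by filters", stacklevel=2)
    return out


def apply_filters(table: GenotypeTable, cfg: FilterConfig | None = None) -> GenotypeTable:
    cfg = cfg or FilterConfig()
    return filter_sites(filter_genotypes(table, cfg), cfg)


# ---------------------------------------------------------------------------
# window assignment
# ---------------------------------------------------------------------------

@dataclass
class WindowAssignment:
    """Site-to-window mapping plus the full window catalog.

    ``window_index`` maps each site of the table to a row of ``windows``;
    the catalog enumerates every tile of every manifest region, so windows
    with zero genotyped sites are present with a site count of 0.  Sites
    outside all regions fall back to a chromosome-level tiling and carry
    ``in_region == False``.
    """

    window_index: np.ndarray
    windows: pd.DataFrame


def assign_windows(table: GenotypeTable, regions: pd.DataFrame | None = None,
                   window_bp: int = 10000) -> WindowAssignment:
    """Tile regions (or bare chromosomes) into non-overlapping windows of
    ``window_bp`` and map every site to exactly one window.

    Window w of a region starting at 0 covers 1-based positions
    [(w-1)*L + 1, w*L]; a trailing window may be short.
    """
    if window_bp <= 0:
        raise ConfigurationError("window_bp must be positive")

    rows = []           # window catalog rows, in construction order
    region_lookup = {}  # chrom -> (starts, ends, region_ids, first-window idx)
    if regions is not None and len(regions):
        for ch, grp in regions.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            offsets = []
            for row in grp.itertuples(index=False):
                offsets.append(len(rows))
                for w0 in range(row.start, row.end, window_bp):
                    rows.append(dict(chrom=ch, window_start=w0 + 1,
                                     window_end=min(w0 + window_bp, row.end),
                                     region_id=row.region_id, in_region=True))
            region_lookup[ch] = (
                grp["start"].to_numpy(), grp["end"].to_numpy(),
                grp["region_id"].to_numpy(), np.array(offsets, dtype=np.int64),
            )

    window_index = np.empty(table.n_sites, dtype=np.int64)
    extra = {}  # (chrom, w0) -> catalog idx, for sites outside every region
    chrom_codes, chrom_names = pd.factorize(pd.Series(table.chrom))
    for ci, ch in enumerate(chrom_names):
        m = chrom_codes == ci
        p0 = table.pos[m] - 1  # 0-based
        widx = np.full(p0.shape, -1, dtype=np.int64)
        if ch in region_lookup:
            starts, ends, _rids, offs = region_lookup[ch]
            cand = np.searchsorted(starts, p0, side="right") - 1
            safe = np.clip(cand, 0, None)
            ok = (cand >= 0) & (p0 < ends[safe])
            widx[ok] = offs[cand[ok]] + (p0[ok] - starts[cand[ok]]) // window_bp
        out = widx < 0
        if out.any():
            for j in np.flatnonzero(out):
                w0 = int(p0[j] // window_bp) * window_bp
                key = (ch, w0)
                if key not in extra:
                    extra[key] = len(rows)
                    rows.append(dict(chrom=ch, window_start=w0 + 1,
                                     window_end=w0 + window_bp,
                                     region_id=None, in_region=False))
                widx[j] = extra[key]
        window_index[m] = widx

    return WindowAssignment(window_index=window_index, windows=pd.DataFrame(rows))
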