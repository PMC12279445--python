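"""Pipeline orchestration, pairwise planning and scenario aggregation.

Also carries the published per-comparison scenario counts for the three
Geonoma undata complex comparisons in the Northern Colombian Andes, used
as input to the aggregation operation (study metadata, analogous to a
static annotation table).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SCENARIOS, PipelineConfig
from .errors import ConfigurationError

log = logging.getLogger("divscan")

#: Window scenario counts reported for three population comparisons of the
#: G. undata complex (WCC = Western/Central cordilleras, EC = Eastern
#: cordillera, CM = Colombian Massif).
GEONOMA_SCENARIO_COUNTS = pd.DataFrame(
    [
        ("WCC1|WCC2", 1, 242, 513, 57, 3969),
        ("WCC2|EC", 1, 234, 533, 61, 4103),
        ("EC|CM", 5, 214, 523, 49, 3971),
    ],
    columns=["pair", *SCENARIOS, "total_windows"],
)

#: Target-capture kit composition of the same study: 4,184 regions of which
#: 4,051 are genic-coding and 133 non-genic.
GEONOMA_KIT_COMPOSITION = dict(total=4184, genic=4051, nongenic=133)


def pairwise_plan(populations) -> list:
    """All unordered pairs of distinct population labels, lexicographic.

    Duplicate labels collapse to one population; fewer than two distinct
    labels is an error.
    """
    labels = sorted(set(populations))
    if len(labels) < 2:
        raise ConfigurationError("need at least two distinct populations")
    return list(itertools.combinations(labels, 2))


def aggregate_scenarios(summary: pd.DataFrame) -> dict:
    """Column sums of a per-comparison scenario-count table.

    Expects one row per comparison and one column per scenario (plus
    ``total_windows``); returns per-scenario totals and the grand total of
    windows analyzed.
    """
    missing = [s for s in SCENARIOS if s not in summary.columns]
    if missing:
        raise ConfigurationError(f"summary table lacks scenario columns: {missing}")
    out = {s: int(summary[s].sum()) for s in SCENARIOS}
    if "total_windows" in summary.columns:
        out["total_windows"] = int(summary["total_windows"].sum())
    return out


def validate_region_manifest(regions: pd.DataFrame, expected_total=None,
                             expected_genic=None, expected_nongenic=None) -> dict:
    """Check manifest composition: genic + non-genic must equal the total."""
    genic = int((regions["genic"].astype(int) == 1).sum())
    nongenic = int((regions["genic"].astype(int) == 0).sum())
    total = len(regions)
    if genic + nongenic != total:
        raise ConfigurationError("genic flags must be 0/1 for every region")
    for name, got, want in (("total", total, expected_total),
                            ("genic", genic, expected_genic),
                            ("nongenic", nongenic, expected_nongenic)):
        if want is not None and got != want:
            raise ConfigurationError(f"region manifest {name} count {got} != expected {want}")
    return dict(total=total, genic=genic, nongenic=nongenic)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig):
    with open(path, "w") as fh:
        fh.write(f"# divscan output; seed={cfg.seed}; window_bp={cfg.window_bp}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Ingest -> filter -> window stats -> classify -> dN/dS -> reports.

    Writes TSV outputs plus a checksummed manifest into ``cfg.outdir`` and
    returns the in-memory frames.  Reruns on identical inputs produce
    identical files.
    """
    from . import classify as cl
    from . import dnds as dn
    from . import ingest, windowstats

    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    table = ingest.read_vcf(cfg.vcf, cfg.popmap, cfg.outgroup_list)
    regions = ingest.read_regions(cfg.regions) if cfg.regions else None
    log.info("ingest: %d sites, %d samples (%.1fs)", table.n_sites, table.n_samples,
             time.time() - t0)

    table = ingest.apply_filters(table, cfg.filters)
    log.info("filters: %d sites retained", table.n_sites)

    assignment = ingest.assign_windows(table, regions, cfg.window_bp)
    stats = windowstats.compute_window_stats(
        table, assignment, min_sites=cfg.min_sites, fst_corrected=cfg.fst_corrected
    )

    pops = table.populations
    pairs = cfg.pairs or pairwise_plan(pops)
    pairs = [tuple(p) for p in pairs]
    summary, calls = cl.summarize_pairs(stats, pairs, cfg.classifier)
    totals = aggregate_scenarios(summary)

    outlier_frames = []
    fst_genes = set()
    for pair, c in calls.items():
        o = cl.fst_outlier_windows(c, regions)
        outlier_frames.append(o)
        for gs in o["genes"]:
            fst_genes.update(gs)
    outliers = pd.concat(outlier_frames, ignore_index=True) if outlier_frames else pd.DataFrame()
    if len(outliers):
        outliers = outliers.assign(genes=[";".join(g) for g in outliers["genes"]])

    results = dict(stats=stats, summary=summary, totals=totals,
                   fst_outliers=outliers, fst_outlier_genes=sorted(fst_genes))

    if regions is not None and len(table.outgroup):
        genes = dn.gene_dnds_table(table, regions, cfg=cfg.dnds)
        out = dn.dnds_outliers(genes, sd_ddof=cfg.dnds.sd_ddof)
        genes["outlier"] = [
            g in out["per_population"].get(p, {}).get("outliers", set())
            for g, p in zip(genes["gene"], genes["population"])
        ]
        divergent = dn.divergent_selection_genes(fst_genes, out["union"])
        results.update(genes=genes, dnds_outliers=out, divergent_selection=divergent)

    files = {}
    _write_tsv(stats, outdir / "window_stats.tsv", cfg)
    files["window_stats.tsv"] = _sha256(outdir / "window_stats.tsv")
    scen = pd.concat([c for c in calls.values()], ignore_index=True)
    _write_tsv(scen.drop(columns=[c for c in ("genes",) if c in scen]),
               outdir / "window_scenarios.tsv", cfg)
    files["window_scenarios.tsv"] = _sha256(outdir / "window_scenarios.tsv")
    _write_tsv(summary, outdir / "pair_summary.tsv", cfg)
    files["pair_summary.tsv"] = _sha256(outdir / "pair_summary.tsv")
    if len(outliers):
        _write_tsv(outliers, outdir / "fst_outlier_windows.tsv", cfg)
        files["fst_outlier_windows.tsv"] = _sha256(outdir / "fst_outlier_windows.tsv")
    if "genes" in results:
        _write_tsv(results["genes"], outdir / "gene_dnds.tsv", cfg)
        files["gene_dnds.tsv"] = _sha256(outdir / "gene_dnds.tsv")
        pd.DataFrame({"gene": results["divergent_selection"]}).pipe(
            _write_tsv, outdir / "divergent_selection_genes.tsv", cfg
        )
        files["divergent_selection_genes.tsv"] = _sha256(outdir / "divergent_selection_genes.tsv")

    manifest = dict(seed=cfg.seed, window_bp=cfg.window_bp, totals=totals, files=files)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    log.info("pipeline done in %.1fs", time.time() - t0)
    return results
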