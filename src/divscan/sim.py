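"""Synthetic multi-population genotype generator with known truth.

The generative model is deliberately simple and closed-form checkable:

* Shared ancestral polymorphism.  Each site is ancestrally variable with
  probability ``s`` and its frequency is drawn from the neutral spectrum
  f(x) ~ 1/x truncated at ``sfs_min_freq``; ``s`` is calibrated so that the
  expected heterozygosity per site equals ``ancestral_theta``.
* Drift.  Each population's frequency at a shared site is perturbed by
  Balding-Nichols sampling, p_i ~ Beta(p0(1-F)/F, q0(1-F)/F), with
  F_i = 1 - exp(-b_i / theta) tied to that population's branch length b_i.
  Drift leaves E[D_XY] untouched and shrinks E[Pi] by (1 - F).
* New fixed differences.  On a star tree each population privately fixes a
  derived allele at rate b_i per site, so a pair's expected added divergence
  is b_i + b_j (= 2*mu*T), giving E[D_XY] = theta + 2*mu*T.
* Expansion mode adds private low-frequency variants (excess rare alleles,
  hence negative Tajima's D), and the outgroup carries its own fixed
  divergence at rate ``outgroup_divergence`` used by the dN/dS stage.

Scenario injections rescale these rates inside single windows so that the
window's expected statistics land in the target region of the classifier's
(F_ST, D_XY, Pi) space; coding injections place additional population-vs-
outgroup fixed differences at synonymous/non-synonymous codon positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_SCENARIO_EFFECTS,
    CodingInjection,
    ScenarioEffect,
    ScenarioInjection,
    SimulationConfig,
    canonical_scenario,
)
from .errors import ConfigurationError
from .table import MISSING, GenotypeTable, concatenate_tables

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# frequency spectrum helpers
# ---------------------------------------------------------------------------

def sample_sfs(rng, size, lo, hi=1.0, alpha=1.0):
    """Draw frequencies from f(x) ~ x**-alpha truncated to (lo, hi)."""
    u = rng.random(size)
    if abs(alpha - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    a = 1.0 - alpha
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def expected_het_sfs(lo, hi=1.0, alpha=1.0):
    """E[2p(1-p)] under the truncated x**-alpha spectrum (exact)."""

    def moment(k):  # integral of x**(k - alpha) over (lo, hi)
        e = k - alpha + 1.0
        if abs(e) < 1e-12:
            return np.log(hi / lo)
        return (hi**e - lo**e) / e

    z = moment(0)
    return 2.0 * (moment(1) - moment(2)) / z


def expected_freq_sfs(lo, hi=1.0, alpha=1.0):
    """E[p] under the truncated x**-alpha spectrum."""

    def moment(k):
        e = k - alpha + 1.0
        if abs(e) < 1e-12:
            return np.log(hi / lo)
        return (hi**e - lo**e) / e

    return moment(1) / moment(0)


def expected_het_uniform(a, b):
    mean = 0.5 * (a + b)
    second = (b - a) ** 2 / 12.0 + mean**2
    return 2.0 * (mean - second)


# ---------------------------------------------------------------------------
# per-window generative model
# ---------------------------------------------------------------------------

@dataclass
class WindowModel:
    """Generative parameters for one window; injections transform this."""

    length: int
    shared_rate: float
    sfs_lo: float
    branch: np.ndarray          # per-population private fixed-difference rate
    drift_f: np.ndarray         # per-population Balding-Nichols F
    expansion_rate: np.ndarray  # per-population private rare-variant rate
    expansion_hi: float
    balanced_rate: float = 0.0
    balanced_freq: tuple = (0.3, 0.7)
    balanced_drift_mult: float = 1.0
    label: str = "neutral"

    # Closed-form expectations (per site, i.e. already per-bp); used both to
    # document the construction and to sanity-check injections in tests.
    def expected_pi(self, i) -> float:
        pi = self.shared_rate * expected_het_sfs(self.sfs_lo) * (1.0 - self.drift_f[i])
        pi += self.balanced_rate * expected_het_uniform(*self.balanced_freq) * (
            1.0 - self.drift_f[i] * self.balanced_drift_mult
        )
        pi += self.expansion_rate[i] * expected_het_sfs(self.sfs_lo, self.expansion_hi)
        return pi

    def expected_dxy(self, i, j) -> float:
        d = self.shared_rate * expected_het_sfs(self.sfs_lo)
        d += self.balanced_rate * expected_het_uniform(*self.balanced_freq)
        bi, bj = self.branch[i], self.branch[j]
        d += bi + bj - 2.0 * bi * bj
        ep = expected_freq_sfs(self.sfs_lo, self.expansion_hi)
        d += (self.expansion_rate[i] + self.expansion_rate[j]) * ep
        return d


def inject_scenario(model: WindowModel, label: str, effect: ScenarioEffect | None = None) -> WindowModel:
    """Return a copy of ``model`` rescaled so the window lands in ``label``'s
    region of the classifier's statistic space."""
    label = canonical_scenario(label)
    eff = effect or DEFAULT_SCENARIO_EFFECTS[label]
    return dataclasses.replace(
        model,
        shared_rate=model.shared_rate * eff.shared_mult,
        branch=model.branch * eff.divergence_mult,
        balanced_rate=model.shared_rate * eff.balanced_extra_rate,
        balanced_freq=tuple(eff.balanced_freq),
        balanced_drift_mult=eff.drift_mult,
        label=label,
    )


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Simulator ground truth: exhaustive per-window scenario labels,
    per-pair divergence parameters, per-gene injected fixed-difference
    counts, and the resolved demographic parameters."""

    windows: pd.DataFrame
    pairs: pd.DataFrame
    genes: pd.DataFrame
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def _negative_binomial_params(mean, var):
    if var <= mean:
        return None  # fall back to Poisson
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return r, p


def simulate_genotypes(config: SimulationConfig, rng=None):
    """Simulate the full multi-region genotype table plus its truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng

    k = config.n_populations
    pops = config.pop_names()
    branch = config.resolve_branch_lengths()
    theta = config.ancestral_theta
    eps = config.sfs_min_freq
    het = expected_het_sfs(eps)
    shared_rate = theta / het if theta > 0 else 0.0
    if config.drift_scale > 0 and theta > 0:
        drift_f = 1.0 - np.exp(-config.drift_scale * branch / theta)
    else:
        drift_f = np.zeros(k)
    expansion = np.array(config.expansion_flags(), dtype=bool)
    exp_rate = np.where(expansion, config.expansion_theta_factor * shared_rate, 0.0)

    samples, population_of = [], {}
    for p, npop in zip(pops, config.samples_per_population):
        for i in range(npop):
            name = f"{p}_{i + 1:03d}"
            samples.append(name)
            population_of[name] = p
    outgroup = [f"outgroup_{i + 1}" for i in range(config.n_outgroup)]
    samples = samples + outgroup
    n_samples = len(samples)
    pop_cols = []
    off = 0
    for npop in config.samples_per_population:
        pop_cols.append(np.arange(off, off + npop))
        off += npop
    og_cols = np.arange(off, off + config.n_outgroup)

    mig = {tuple(sorted(p)) for p in config.migration_pairs}

    scen_by_window = {}
    for inj in config.scenario_injections:
        scen_by_window[(inj.region_index, inj.window_index)] = inj
    coding_by_region = {}
    for cj in config.coding_injections:
        coding_by_region.setdefault(cj.region_index, []).append(cj)

    L = config.region_length_bp
    W = config.window_length_bp
    n_genic = max(config.n_regions - config.n_nongenic, 0)

    nb = _negative_binomial_params(config.depth_mean, config.depth_var) if config.with_depth else None

    base_model = WindowModel(
        length=W,
        shared_rate=shared_rate,
        sfs_lo=eps,
        branch=branch.copy(),
        drift_f=drift_f,
        expansion_rate=exp_rate,
        expansion_hi=config.expansion_freq_max,
    )

    blocks = []
    truth_windows = []
    truth_genes = []

    for r in range(config.n_regions):
        chrom = f"chr{r + 1}"
        region_id = f"r{r + 1:05d}"
        genic = r < n_genic
        geno = np.zeros((L, n_samples, 2), dtype=np.int8)
        ref = rng.choice(4, size=L).astype(np.int8)

        w_starts = list(range(0, L, W))
        for wi, ws in enumerate(w_starts):
            wlen = min(W, L - ws)
            model = dataclasses.replace(base_model, length=wlen)
            inj = scen_by_window.get((r, wi))
            if inj is not None:
                model = inject_scenario(model, inj.label, inj.effect)
            truth_windows.append(
                dict(region_id=region_id, chrom=chrom, window_start=ws + 1,
                     window_end=ws + wlen, scenario=model.label)
            )
            _realize_window(rng, model, geno[ws:ws + wlen], pop_cols, og_cols,
                            mig, config.migration_share)

        # background outgroup divergence: fixed ALT in the outgroup only
        if config.n_outgroup and config.outgroup_divergence > 0:
            n_div = rng.binomial(L, config.outgroup_divergence)
            div_pos = rng.choice(L, size=n_div, replace=False)
            geno[np.ix_(div_pos, og_cols)] = 1

        # coding injections: extra population-vs-outgroup fixed differences
        for cj in coding_by_region.get(r, []):
            if not genic:
                raise ConfigurationError(f"coding injection targets non-genic region {region_id}")
            pi = pops.index(cj.population)
            syn_pos, nonsyn_pos = _coding_positions(L, frame=0)
            _place_fixed(rng, geno, pop_cols[pi], nonsyn_pos, cj.n_fixed_nonsyn)
            _place_fixed(rng, geno, pop_cols[pi], syn_pos, cj.n_fixed_syn)
            truth_genes.append(
                dict(region_id=region_id, population=cj.population,
                     n_fixed_syn=cj.n_fixed_syn, n_fixed_nonsyn=cj.n_fixed_nonsyn,
                     target_ratio=cj.target_ratio)
            )

        if config.missing_rate > 0:
            miss = rng.random((L, n_samples)) < config.missing_rate
            geno[miss] = MISSING

        depth = quality = None
        if config.with_depth:
            if nb is not None:
                depth = rng.negative_binomial(nb[0], nb[1], size=(L, n_samples)).astype(np.int32)
            else:
                depth = rng.poisson(config.depth_mean, size=(L, n_samples)).astype(np.int32)
            quality = np.where(
                rng.random((L, n_samples)) < config.low_quality_rate,
                config.low_quality, config.base_quality,
            ).astype(np.int16)

        blocks.append(_block_to_table(chrom, L, ref, geno, depth, quality,
                                      samples, population_of, set(outgroup)))

    table = concatenate_tables(blocks)

    pair_rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = branch[i] + branch[j]
            if (i, j) in mig:
                d *= 1.0 - config.migration_share
            pair_rows.append(dict(pop_a=pops[i], pop_b=pops[j],
                                  divergence=d, migration=(i, j) in mig))
    truth = TruthTable(
        windows=pd.DataFrame(truth_windows),
        pairs=pd.DataFrame(pair_rows),
        genes=pd.DataFrame(truth_genes, columns=["region_id", "population",
                                                 "n_fixed_syn", "n_fixed_nonsyn",
                                                 "target_ratio"]),
        params=dict(branch_lengths=branch.tolist(), drift_f=drift_f.tolist(),
                    shared_site_rate=shared_rate, theta=theta, seed=config.seed),
    )
    return table, truth


def _drifted(rng, p0, F):
    """Balding-Nichols perturbation of ancestral frequencies (vectorized)."""
    if F <= 0:
        return p0.copy()
    scale = (1.0 - F) / F
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def _realize_window(rng, model: WindowModel, geno, pop_cols, og_cols,
                    migration_pairs, migration_share=0.5):
    """Fill a (wlen, n_samples, 2) slice in place from the window model.

    Layers are applied in order (shared polymorphism, balanced polymorphism,
    private fixed differences, private rare variants); a later layer
    overwrites a colliding position, which happens with negligible
    probability at the default rates.
    """
    wlen = geno.shape[0]
    k = len(pop_cols)
    layer_pos, layer_freq = [], []

    n_shared = rng.binomial(wlen, min(model.shared_rate, 1.0))
    if n_shared:
        positions = rng.choice(wlen, size=n_shared, replace=False)
        p0 = sample_sfs(rng, n_shared, model.sfs_lo)
        f = np.column_stack([_drifted(rng, p0, model.drift_f[i]) for i in range(k)])
        layer_pos.append(positions)
        layer_freq.append(f)

    if model.balanced_rate > 0:
        n_bal = rng.binomial(wlen, min(model.balanced_rate, 1.0))
        if n_bal:
            positions = rng.choice(wlen, size=n_bal, replace=False)
            p0 = rng.uniform(*model.balanced_freq, size=n_bal)
            f = np.column_stack(
                [_drifted(rng, p0, model.drift_f[i] * model.balanced_drift_mult)
                 for i in range(k)]
            )
            layer_pos.append(positions)
            layer_freq.append(f)

    # private fixed differences on the star tree; migration lets a fraction
    # of one member's private mutations leak into the other pair member
    carriers = {}
    for i in range(k):
        n_fix = rng.binomial(wlen, min(model.branch[i], 1.0))
        if n_fix:
            for pos in rng.choice(wlen, size=n_fix, replace=False):
                carriers.setdefault(int(pos), set()).add(i)
    for (i, j) in migration_pairs:
        for pos, who in carriers.items():
            if i in who and j not in who and rng.random() < migration_share:
                who.add(j)
            elif j in who and i not in who and rng.random() < migration_share:
                who.add(i)
    if carriers:
        positions = np.fromiter(carriers.keys(), dtype=np.intp)
        f = np.zeros((len(positions), k))
        for row, pos in enumerate(positions):
            f[row, list(carriers[pos])] = 1.0
        layer_pos.append(positions)
        layer_freq.append(f)

    for i in range(k):
        rate = model.expansion_rate[i]
        if rate <= 0:
            continue
        n_priv = rng.binomial(wlen, min(rate, 1.0))
        if n_priv:
            positions = rng.choice(wlen, size=n_priv, replace=False)
            f = np.zeros((n_priv, k))
            f[:, i] = sample_sfs(rng, n_priv, model.sfs_lo, model.expansion_hi)
            layer_pos.append(positions)
            layer_freq.append(f)

    if not layer_pos:
        return
    positions = np.concatenate(layer_pos)
    fmat = np.concatenate(layer_freq, axis=0)  # (n_active, k)
    # later layers overwrite earlier ones at colliding positions
    order = np.arange(len(positions))
    keep = {}
    for idx in order:
        keep[int(positions[idx])] = idx
    sel = np.fromiter(keep.values(), dtype=np.intp)
    positions, fmat = positions[sel], fmat[sel]
    for i, cols in enumerate(pop_cols):
        p = fmat[:, i][:, None, None]
        draws = rng.random((len(positions), len(cols), 2)) < p
        geno[np.ix_(positions, cols)] = draws.astype(np.int8)
    # outgroup stays at the ancestral (REF) allele inside windows


def _coding_positions(length_bp, frame):
    """Synonymous (codon offset 3) and non-synonymous (offsets 1-2) 0-based
    positions under the 4-fold-degeneracy approximation."""
    usable = length_bp - frame
    n_codons = usable // 3
    offs = frame + np.arange(n_codons * 3)
    cls = np.arange(n_codons * 3) % 3
    return offs[cls == 2], offs[cls < 2]


def _place_fixed(rng, geno, cols, candidates, n):
    if n == 0:
        return
    if n > len(candidates):
        raise ConfigurationError(
            f"requested {n} fixed differences but only {len(candidates)} sites of that class"
        )
    pos = rng.choice(candidates, size=n, replace=False)
    geno[np.ix_(pos, cols)] = 1


def _block_to_table(chrom, L, ref_idx, geno, depth, quality, samples, population_of, outgroup):
    has_alt = (geno > 0).any(axis=(1, 2))
    ref = _BASES[ref_idx]
    alt_idx = (ref_idx + 1) % 4  # any base different from REF
    alts = np.empty(L, dtype=object)
    alts[:] = [()] * L
    tmp = np.empty(int(has_alt.sum()), dtype=object)
    tmp[:] = [(a,) for a in _BASES[alt_idx[has_alt]]]
    alts[has_alt] = tmp
    return GenotypeTable(
        chrom=np.repeat(np.array([chrom], dtype=object), L),
        pos=np.arange(1, L + 1, dtype=np.int64),
        ref=ref.astype(object),
        alts=alts,
        genotypes=geno,
        depth=depth,
        quality=quality,
        samples=list(samples),
        population_of=dict(population_of),
        outgroup=set(outgroup),
    )


# ---------------------------------------------------------------------------
# coding-gene generators (dN/dS fixtures)
# ---------------------------------------------------------------------------

def simulate_coding_gene(gene_len_codons, n_fixed_syn, n_fixed_nonsyn,
                         missingness=0.0, n_diploids=4, n_outgroup=2,
                         frame=0, seed=0, rng=None, chrom="gene1"):
    """One coding region: exactly the requested population-vs-outgroup fixed
    differences, non-synonymous at codon positions 1-2 and synonymous at
    position 3, everything else invariant.

    Returns ``(GenotypeTable, regions DataFrame)`` ready for the dN/dS stage.
    """
    if gene_len_codons < 1:
        raise ConfigurationError("gene_len_codons must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    L = gene_len_codons * 3 + frame
    syn_pos, nonsyn_pos = _coding_positions(L, frame)
    n_samples = n_diploids + n_outgroup
    geno = np.zeros((L, n_samples, 2), dtype=np.int8)
    og_cols = np.arange(n_diploids, n_samples)
    _place_fixed(rng, geno, og_cols, nonsyn_pos, n_fixed_nonsyn)
    _place_fixed(rng, geno, og_cols, syn_pos, n_fixed_syn)
    if missingness > 0:
        geno[rng.random((L, n_samples)) < missingness] = MISSING
    samples = [f"pop1_{i + 1:03d}" for i in range(n_diploids)] + [
        f"outgroup_{i + 1}" for i in range(n_outgroup)
    ]
    population_of = {s: "pop1" for s in samples[:n_diploids]}
    ref_idx = rng.choice(4, size=L).astype(np.int8)
    table = _block_to_table(chrom, L, ref_idx, geno, None, None,
                            samples, population_of, set(samples[n_diploids:]))
    regions = pd.DataFrame(
        [dict(region_id=chrom, chrom=chrom, start=0, end=L, genic=1, frame=frame)]
    )
    return table, regions


def simulate_neutral_genes(n_genes, gene_len_codons, substitution_rate,
                           n_diploids=4, n_outgroup=2, seed=0):
    """Genes whose outgroup substitutions fall uniformly over all positions:
    the neutral calibration for the degenerate-site dN/dS (expected ratio 1)."""
    rng = np.random.default_rng(seed)
    L = gene_len_codons * 3
    blocks, region_rows = [], []
    for g in range(n_genes):
        chrom = f"gene{g + 1}"
        n_sub = rng.binomial(L, substitution_rate)
        geno = np.zeros((L, n_diploids + n_outgroup, 2), dtype=np.int8)
        if n_sub:
            pos = rng.choice(L, size=n_sub, replace=False)
            geno[np.ix_(pos, np.arange(n_diploids, n_diploids + n_outgroup))] = 1
        samples = [f"pop1_{i + 1:03d}" for i in range(n_diploids)] + [
            f"outgroup_{i + 1}" for i in range(n_outgroup)
        ]
        population_of = {s: "pop1" for s in samples[:n_diploids]}
        ref_idx = rng.choice(4, size=L).astype(np.int8)
        blocks.append(_block_to_table(chrom, L, ref_idx, geno, None, None,
                                      samples, population_of, set(samples[n_diploids:])))
        region_rows.append(dict(region_id=chrom, chrom=chrom, start=0, end=L, genic=1, frame=0))
    return concatenate_tables(blocks), pd.DataFrame(region_rows)


# ---------------------------------------------------------------------------
# writers: VCF 4.2 (GT:DP:RQ), popmap, outgroup list, region manifest
# ---------------------------------------------------------------------------

def write_vcf(table: GenotypeTable, path):
    """Emit the table as a VCF 4.2 text file with variant AND invariant
    records; FORMAT is GT:DP:RQ when depth/quality are present, else GT."""
    if table.n_sites == 0:
        raise ConfigurationError("refusing to write an empty genotype table")
    with_dp = table.depth is not None and table.quality is not None
    lines = ["##fileformat=VCFv4.2", "##source=divscan"]
    # contig lengths: highest observed position per contig
    seen = {}
    for c, p in zip(table.chrom, table.pos):
        if p > seen.get(c, 0):
            seen[c] = p
    for c, ln in seen.items():
        lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
        lines.append('##FORMAT=<ID=RQ,Number=1,Type=Integer,Description="Phred-scaled genotype quality">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples))

    fmt = "GT:DP:RQ" if with_dp else "GT"
    g = table.genotypes
    for s in range(table.n_sites):
        alt = ",".join(table.alts[s]) if len(table.alts[s]) else "."
        cells = []
        row = g[s]
        for j in range(table.n_samples):
            a, b = row[j]
            gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
            if with_dp:
                cells.append(f"{gt}:{table.depth[s, j]}:{table.quality[s, j]}")
            else:
                cells.append(gt)
        lines.append(
            f"{table.chrom[s]}\t{table.pos[s]}\t.\t{table.ref[s]}\t{alt}\t.\t.\t.\t{fmt}\t"
            + "\t".join(cells)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_popmap(table: GenotypeTable, path):
    with open(path, "w") as fh:
        for s in table.samples:
            if s in table.population_of:
                fh.write(f"{s}\t{table.population_of[s]}\n")


def write_outgroup_list(table: GenotypeTable, path):
    with open(path, "w") as fh:
        for s in table.samples:
            if s in table.outgroup:
                fh.write(s + "\n")


def write_regions(regions: pd.DataFrame, path):
    """BED-like manifest: region_id, chrom, start, end (0-based half-open),
    genic 0/1, frame 0/1/2 or '.'."""
    with open(path, "w") as fh:
        fh.write("#region_id\tchrom\tstart\tend\tgenic\tframe\n")
        for row in regions.itertuples(index=False):
            fh.write(f"{row.region_id}\t{row.chrom}\t{row.start}\t{row.end}\t"
                     f"{int(row.genic)}\t{row.frame}\n")


def regions_from_truth(truth: TruthTable, config: SimulationConfig) -> pd.DataFrame:
    """Region manifest matching a simulate_genotypes run."""
    n_genic = max(config.n_regions - config.n_nongenic, 0)
    rows = []
    for r in range(config.n_regions):
        genic = r < n_genic
        rows.append(dict(region_id=f"r{r + 1:05d}", chrom=f"chr{r + 1}", start=0,
                         end=config.region_length_bp, genic=int(genic),
                         frame=0 if genic else "."))
    return pd.DataFrame(rows)
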