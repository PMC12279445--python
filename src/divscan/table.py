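"""In-memory genotype container shared by every pipeline stage.

The table stores diploid genotypes for *all* sites, variant and invariant
alike: invariant sites carry real information here because the per-site
diversity estimators divide by counts of genotyped sites, not by the number
of SNPs.  Dropping them silently would inflate Pi and D_XY.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Sentinel allele index for a missing genotype.  A genotype is either fully
#: observed or fully missing -- half-calls are collapsed to missing on read.
MISSING = -1


@dataclass
class GenotypeTable:
    """Site-by-sample diploid genotypes with per-genotype depth/quality.

    Attributes
    ----------
    chrom, pos : arrays of length n_sites
        Chromosome name and 1-based position, strictly increasing within a
        chromosome.
    ref : array of str
        Reference allele per site.
    alts : object array of tuples
        Alternate alleles; an empty tuple marks an invariant site.
    genotypes : int8 array, shape (n_sites, n_samples, 2)
        Allele indices into (ref, *alts); ``MISSING`` marks a dropped call.
    depth, quality : int arrays, shape (n_sites, n_samples), optional
        Per-genotype sequencing depth and phred-scaled genotype quality.
    samples : list of sample ids, column order of ``genotypes``.
    population_of : mapping sample -> population label (ingroup only).
    outgroup : set of sample ids designated as outgroup.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alts: np.ndarray
    genotypes: np.ndarray
    samples: list
    population_of: dict
    outgroup: set = field(default_factory=set)
    depth: np.ndarray | None = None
    quality: np.ndarray | None = None

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list:
        """Ingroup population labels in order of first appearance."""
        seen, out = set(), []
        for s in self.samples:
            p = self.population_of.get(s)
            if p is not None and p not in seen:
                seen.add(p)
                out.append(p)
        return out

    def sample_indices(self, names) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        return np.array([idx[n] for n in names], dtype=np.intp)

    def population_indices(self, population) -> np.ndarray:
        names = [s for s in self.samples if self.population_of.get(s) == population]
        return self.sample_indices(names)

    def outgroup_indices(self) -> np.ndarray:
        names = [s for s in self.samples if s in self.outgroup]
        return self.sample_indices(names)

    @property
    def n_alleles(self) -> np.ndarray:
        return np.array([1 + len(a) for a in self.alts], dtype=np.int8)

    # -- derived views ---------------------------------------------------
    def missing_genotype_mask(self) -> np.ndarray:
        """(n_sites, n_samples) boolean, True where the genotype is missing."""
        return (self.genotypes < 0).any(axis=2)

    def allele_counts(self, sample_idx) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt_count, n_haplotypes) over genotyped haplotypes.

        Only meaningful for sites with at most two alleles; multi-allelic
        records must be removed by the site filter before calling this.
        """
        g = self.genotypes[:, sample_idx, :]
        ok = (g >= 0).all(axis=2)
        n = 2 * ok.sum(axis=1)
        c1 = np.where(ok, g.sum(axis=2), 0).sum(axis=1)
        return c1.astype(np.int64), n.astype(np.int64)

    def subset_sites(self, mask) -> "GenotypeTable":
        return replace(
            self,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alts=self.alts[mask],
            genotypes=self.genotypes[mask],
            depth=None if self.depth is None else self.depth[mask],
            quality=None if self.quality is None else self.quality[mask],
        )

    def copy(self) -> "GenotypeTable":
        return replace(
            self,
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alts=self.alts.copy(),
            genotypes=self.genotypes.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            quality=None if self.quality is None else self.quality.copy(),
            samples=list(self.samples),
            population_of=dict(self.population_of),
            outgroup=set(self.outgroup),
        )


def concatenate_tables(blocks) -> GenotypeTable:
    """Stack per-region tables (identical sample layout) along the site axis."""
    first = blocks[0]
    return replace(
        first,
        chrom=np.concatenate([b.chrom for b in blocks]),
        pos=np.concatenate([b.pos for b in blocks]),
        ref=np.concatenate([b.ref for b in blocks]),
        alts=np.concatenate([b.alts for b in blocks]),
        genotypes=np.concatenate([b.genotypes for b in blocks]),
        depth=None if first.depth is None else np.concatenate([b.depth for b in blocks]),
        quality=None if first.quality is None else np.concatenate([b.quality for b in blocks]),
    )


def tables_equal(a: GenotypeTable, b: GenotypeTable, check_depth: bool = True) -> bool:
    """Exact equality of two tables (used by round-trip and determinism tests)."""
    if a.samples != b.samples or a.population_of != b.population_of or a.outgroup != b.outgroup:
        return False
    if a.n_sites != b.n_sites:
        return False
    if not (np.array_equal(a.chrom, b.chrom) and np.array_equal(a.pos, b.pos)):
        return False
    if not (np.array_equal(a.ref, b.ref) and all(x == y for x, y in zip(a.alts, b.alts))):
        return False
    if not np.array_equal(a.genotypes, b.genotypes):
        return False
    if check_depth:
        for x, y in ((a.depth, b.depth), (a.quality, b.quality)):
            if (x is None) != (y is None):
                return False
            if x is not None and not np.array_equal(np.asarray(x), np.asarray(y)):
                return False
    return True
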