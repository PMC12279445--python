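"""Configuration objects: simulation, filtering, classification, pipeline.

Defaults mirror the study design this package reimplements: five diploid
populations of unequal size (156 individuals total) plus a two-individual
congeneric outgroup, ~4,200 captured target regions tiled into 10 kb
windows, VCFtools-style genotype/site filters (Q >= 20, 15 <= DP <= 50,
<= 10% missing, biallelic), and the standard-deviation scenario thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigurationError, UnknownScenarioError

#: Canonical scenario labels, in classifier rule-precedence order.
SCENARIOS = (
    "divergence_with_gene_flow",
    "allopatric_selection",
    "recurrent_selection",
    "balancing_selection",
)

#: Short aliases accepted by injection helpers.
SCENARIO_ALIASES = {
    "gene_flow": "divergence_with_gene_flow",
    "allopatric": "allopatric_selection",
    "recurrent": "recurrent_selection",
    "balancing": "balancing_selection",
}


def canonical_scenario(label: str) -> str:
    lab = SCENARIO_ALIASES.get(label, label)
    if lab not in SCENARIOS:
        raise UnknownScenarioError(
            f"unknown scenario label {label!r}; expected one of "
            f"{sorted(SCENARIO_ALIASES)} or {list(SCENARIOS)}"
        )
    return lab


@dataclass
class FilterConfig:
    """Genotype- and site-level filters applied after reading the VCF.

    Bounds are inclusive (a genotype at depth 15 or 50 and quality 20 is
    kept), matching the conventional semantics of VCFtools' --minDP/--maxDP/
    --minGQ.  ``max_missing_fraction`` is likewise inclusive: a site is
    dropped only when *more* than that fraction of genotypes is missing.
    """

    min_quality: float = 20.0
    min_depth: int = 15
    max_depth: int = 50
    max_missing_fraction: float = 0.10
    biallelic_only: bool = True
    #: Denominator for the missingness fraction: "all" counts every sample in
    #: the VCF (ingroup + outgroup, the study filtered one joint VCF);
    #: "ingroup" restricts to mapped populations.
    missing_denominator: str = "all"

    def validate(self):
        if self.min_depth > self.max_depth:
            raise ConfigurationError("min_depth must be <= max_depth")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ConfigurationError("max_missing_fraction must lie in [0, 1]")
        if self.missing_denominator not in ("all", "ingroup"):
            raise ConfigurationError("missing_denominator must be 'all' or 'ingroup'")
        return self


@dataclass
class ScenarioEffect:
    """Multipliers applied to a window's generative parameters by injection.

    shared_mult scales the rate of shared ancestral polymorphism (drives Pi
    and the within-population part of D_XY); divergence_mult scales each
    population's private fixed-difference rate (drives D_XY and F_ST);
    balanced_extra_rate adds intermediate-frequency polymorphism shared
    identically across populations (balancing selection), with drift at
    those sites damped by drift_mult.
    """

    shared_mult: float = 1.0
    divergence_mult: float = 1.0
    balanced_extra_rate: float = 0.0
    balanced_freq: tuple = (0.3, 0.7)
    drift_mult: float = 1.0


#: Default "strong" effects per scenario, derived from the generator's
#: closed-form expected statistics so each label's windows land inside its
#: classification rule region (see docs/methods.md for the arithmetic).
DEFAULT_SCENARIO_EFFECTS = {
    "divergence_with_gene_flow": ScenarioEffect(shared_mult=0.4, divergence_mult=8.0),
    "allopatric_selection": ScenarioEffect(shared_mult=0.25, divergence_mult=3.0),
    "recurrent_selection": ScenarioEffect(shared_mult=0.5, divergence_mult=1.2),
    "balancing_selection": ScenarioEffect(
        shared_mult=1.0, divergence_mult=0.5, balanced_extra_rate=0.7, drift_mult=0.3
    ),
}


@dataclass
class ScenarioInjection:
    """Request to overwrite one window's generative regime with a scenario."""

    region_index: int
    label: str
    window_index: int = 0
    effect: ScenarioEffect | None = None

    def __post_init__(self):
        self.label = canonical_scenario(self.label)


@dataclass
class CodingInjection:
    """Extra fixed differences between one population and the outgroup.

    Counts are placed on top of the background outgroup divergence:
    ``n_fixed_nonsyn`` at codon positions 1-2, ``n_fixed_syn`` at position 3.
    """

    region_index: int
    population: str
    n_fixed_syn: int = 0
    n_fixed_nonsyn: int = 0
    target_ratio: float | None = None


@dataclass
class SimulationConfig:
    """Knobs of the synthetic multi-population genotype generator.

    Divergence is parameterised on the scale of expected added pairwise
    divergence (2*mu*T): either per-population ``branch_lengths`` on a star
    tree, or a per-pair ``divergence_times`` mapping/scalar which is fitted
    to star branch lengths by non-negative least squares.
    """

    n_populations: int = 5
    samples_per_population: tuple = (48, 40, 30, 22, 16)
    population_names: tuple | None = None
    ancestral_theta: float = 0.003
    branch_lengths: tuple | None = None
    divergence_times: dict | float | None = None
    migration_pairs: tuple = ()
    migration_share: float = 0.5
    drift_scale: float = 1.0
    # Site-frequency spectrum: neutral 1/x density truncated below at
    # sfs_min_freq (plays the role of 1/(2N) for N = 500).
    sfs_min_freq: float = 1e-3
    # Expansion mode: excess of private low-frequency variants per population
    # (recent growth after a bottleneck); the study populations all show
    # negative Tajima's D, so the default switches it on everywhere.
    expansion: tuple | bool = True
    expansion_theta_factor: float = 0.6
    expansion_freq_max: float = 0.1
    n_regions: int = 4184
    n_nongenic: int = 133
    region_length_bp: int = 10000
    window_length_bp: int = 10000
    missing_rate: float = 0.05
    depth_mean: float = 30.0
    depth_var: float = 90.0
    base_quality: int = 99
    low_quality: int = 10
    low_quality_rate: float = 0.02
    with_depth: bool = True
    n_outgroup: int = 2
    outgroup_divergence: float = 0.02
    scenario_injections: list = field(default_factory=list)
    coding_injections: list = field(default_factory=list)
    seed: int = 0

    # -- resolved views --------------------------------------------------
    def pop_names(self) -> list:
        if self.population_names is not None:
            return list(self.population_names)
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    def resolve_branch_lengths(self):
        """Per-population star-tree branch lengths (expected private 2*mu*T)."""
        import numpy as np

        k = self.n_populations
        if self.branch_lengths is not None:
            b = np.asarray(self.branch_lengths, dtype=float)
            if len(b) != k:
                raise ConfigurationError("branch_lengths length != n_populations")
            return b
        if self.divergence_times is None:
            default = np.array([0.0002, 0.00025, 0.0003, 0.0004, 0.0006])
            return default[:k] if k <= 5 else np.full(k, 0.0004)
        if isinstance(self.divergence_times, (int, float)):
            return np.full(k, float(self.divergence_times) / 2.0)
        # per-pair mapping -> least-squares star fit, clipped at zero
        pairs = {(min(i, j), max(i, j)): float(d) for (i, j), d in self.divergence_times.items()}
        rows, rhs = [], []
        for (i, j), d in sorted(pairs.items()):
            row = np.zeros(k)
            row[i] = row[j] = 1.0
            rows.append(row)
            rhs.append(d)
        if len(rows) == 1:
            (i, j), d = next(iter(sorted(pairs.items())))
            b = np.zeros(k)
            b[i] = b[j] = d / 2.0
            return b
        sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        return np.clip(sol, 0.0, None)

    def expansion_flags(self):
        if isinstance(self.expansion, bool):
            return tuple([self.expansion] * self.n_populations)
        return tuple(bool(x) for x in self.expansion)

    def validate(self):
        if self.n_populations < 1:
            raise ConfigurationError("n_populations must be positive")
        if len(self.samples_per_population) != self.n_populations:
            raise ConfigurationError("samples_per_population length != n_populations")
        if any(n < 2 for n in self.samples_per_population):
            raise ConfigurationError("each population needs at least 2 diploids")
        for name, p in (
            ("missing_rate", self.missing_rate),
            ("low_quality_rate", self.low_quality_rate),
            ("migration_share", self.migration_share),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.window_length_bp <= 0 or self.region_length_bp <= 0:
            raise ConfigurationError("window/region lengths must be positive")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be positive")
        if not 0.0 <= self.ancestral_theta < 0.1:
            raise ConfigurationError("ancestral_theta must lie in [0, 0.1)")
        self.resolve_branch_lengths()
        return self


@dataclass
class ClassifierConfig:
    """Scenario-rule semantics and standardization convention.

    ``semantics="band"`` reads "< k SD" against the *lower* boundary for
    k = 1 and the *upper* boundary for k = 3 (the published figure draws the
    upper boundary at +3 SD and the lower at -1 SD); ``"upper"`` places every
    threshold above the mean.  Standard deviations divide by N
    (``sd_ddof=0``) by default.
    """

    semantics: str = "band"
    sd_ddof: int = 0

    def validate(self):
        if self.semantics not in ("band", "upper"):
            raise ConfigurationError("semantics must be 'band' or 'upper'")
        return self


@dataclass
class DnDsConfig:
    """Gates for the degenerate-site dN/dS computed against the outgroup."""

    #: A site is covered for a gene x population when at most this fraction
    #: of the population's genotypes is missing (inclusive bound).
    max_missing_fraction: float = 0.5
    #: Require at least one genotyped outgroup allele at a covered site.
    require_outgroup: bool = True
    #: "disjoint": fixed difference when the allele sets observed in the
    #: population and the outgroup share nothing; "strict": both must also be
    #: monomorphic.  Identical on biallelic data.
    fixed_rule: str = "disjoint"
    sd_ddof: int = 0

    def validate(self):
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ConfigurationError("max_missing_fraction must lie in [0, 1]")
        if self.fixed_rule not in ("disjoint", "strict"):
            raise ConfigurationError("fixed_rule must be 'disjoint' or 'strict'")
        return self


@dataclass
class PipelineConfig:
    """End-to-end run: input paths, filter/classifier knobs, output dir."""

    vcf: str = ""
    popmap: str = ""
    regions: str = ""
    outgroup_list: str | None = None
    outdir: str = "divscan_out"
    window_bp: int = 10000
    min_sites: int = 1
    pairs: list | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    dnds: DnDsConfig = field(default_factory=DnDsConfig)
    fst_corrected: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (("filters", FilterConfig), ("classifier", ClassifierConfig), ("dnds", DnDsConfig)):
            if isinstance(raw.get(key), dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def validate(self):
        self.filters.validate()
        self.classifier.validate()
        self.dnds.validate()
        if self.window_bp <= 0:
            raise ConfigurationError("window_bp must be positive")
        return self
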