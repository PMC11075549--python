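"""Synthetic study generator: forward Wright-Fisher simulation of a selfing,
split/bottleneck demography plus trait-architecture, vernalization-response
and structure-correlated environment generators.

The simulator is the test bed for every statistic in the package: it
produces the neutral F_ST null, genotype panels for the GWAS and LD scans,
and noiseless/noisy phenotype designs for the trait extractor.

Discrete generations; offspring self with probability ``selfing_rate`` and
otherwise outcross to a distinct random individual of the same population;
there is no migration.  Mutation follows the infinite-sites idealization on
a fixed grid of ``n_sites`` positions: a site mutates at most once over the
whole simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics_io import GenotypeMatrix, PopulationMap

__all__ = [
    "PopulationSpec",
    "Split",
    "DemographyConfig",
    "TraitArchitecture",
    "EnvModel",
    "SyntheticStudy",
    "simulate_neutral",
    "simulate_panel",
    "generate_vernalization_response",
    "generate_environment",
]


@dataclass
class PopulationSpec:
    """One population: base diploid size, optional bottleneck window, lineage."""

    name: str
    size: int
    bottleneck: tuple[int, int, int] | None = None  # (start_gen, end_gen, size)
    lineage: str | None = None

    def size_at(self, gen: int) -> int:
        if self.bottleneck is not None:
            start, end, size = self.bottleneck
            if start <= gen < end:
                return size
        return self.size


@dataclass
class Split:
    parent: str
    child: str
    generation: int


@dataclass
class DemographyConfig:
    """Parameters of the forward simulation.

    ``standing_variation`` seeds the founder population with that many
    segregating sites whose initial frequencies are drawn uniformly from
    ``standing_freq_range`` (individuals in Hardy-Weinberg proportions);
    it substitutes for a long mutation-drift burn-in when only post-split
    drift matters.
    """

    populations: list[PopulationSpec]
    generations: int
    n_sites: int
    splits: list[Split] = field(default_factory=list)
    selfing_rate: float = 0.99
    mutation_rate: float = 0.0
    recomb: float = 0.5
    sample_sizes: dict[str, int] | None = None
    n_chroms: int = 1
    site_spacing_bp: int = 1000
    standing_variation: int = 0
    standing_freq_range: tuple[float, float] = (0.1, 0.9)
    n_founder_haplotypes: int | None = None
    standing_ld_rho: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        for p in self.populations:
            if p.size < 2:
                raise ValueError(f"population {p.name}: size must be >= 2")
            if p.bottleneck is not None and p.bottleneck[2] < 2:
                raise ValueError(f"population {p.name}: bottleneck size must be >= 2")
        gens = [s.generation for s in self.splits]
        if gens != sorted(gens):
            raise ValueError("splits must be ordered by generation")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        children = [s.child for s in self.splits]
        if len(set(children)) != len(children):
            raise ValueError("each population may be founded by at most one split")
        for s in self.splits:
            if s.parent not in names or s.child not in names:
                raise ValueError(f"split references unknown population: {s}")
        if self.populations and self.populations[0].name in children:
            raise ValueError("the first population is the founder and cannot be a split child")
        for p in self.populations[1:]:
            if p.name not in children:
                raise ValueError(f"population {p.name} is never founded by a split")


def _site_layout(config: DemographyConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chromosome labels, positions, and per-interval crossover probabilities."""
    L = config.n_sites
    per_chrom = np.full(config.n_chroms, L // config.n_chroms, dtype=int)
    per_chrom[: L % config.n_chroms] += 1
    chrom = np.concatenate(
        [np.full(n, f"chr{i + 1}", dtype=object) for i, n in enumerate(per_chrom)]
    )
    pos = np.concatenate(
        [config.site_spacing_bp * (np.arange(n) + 1) for n in per_chrom]
    ).astype(np.int64)
    r_vec = np.full(max(L - 1, 0), config.recomb)
    boundary = np.flatnonzero(chrom[:-1] != chrom[1:])
    r_vec[boundary] = 0.5  # free recombination between chromosomes
    return chrom, pos, r_vec


def _meiosis(parents: np.ndarray, r_vec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete from each (2, L) parent genotype; crossover prob r per interval."""
    n, _, L = parents.shape
    start = rng.integers(0, 2, size=(n, 1))
    if L > 1:
        cross = rng.random((n, L - 1)) < r_vec
        which = (start + np.concatenate(
            [np.zeros((n, 1), dtype=np.int64), np.cumsum(cross, axis=1)], axis=1
        )) % 2
    else:
        which = start
    return np.take_along_axis(parents, which[:, None, :], axis=1)[:, 0, :]


def _reproduce(pop: np.ndarray, n_offspring: int, s: float, r_vec: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    n = pop.shape[0]
    selfs = rng.random(n_offspring) < s
    p1 = rng.integers(0, n, n_offspring)
    p2 = rng.integers(0, n, n_offspring)
    if n > 1:  # outcrossing requires a distinct mate
        clash = ~selfs & (p1 == p2)
        while clash.any():
            p2[clash] = rng.integers(0, n, clash.sum())
            clash = ~selfs & (p1 == p2)
    p2[selfs] = p1[selfs]
    g1 = _meiosis(pop[p1], r_vec, rng)
    g2 = _meiosis(pop[p2], r_vec, rng)
    return np.stack([g1, g2], axis=1)


def simulate_neutral(
    config: DemographyConfig, seed: int, segregating_only: bool = True
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Run the neutral forward simulation and sample diploid genotypes.

    Returns a :class:`GenotypeMatrix` of the pooled per-population samples
    and the matching :class:`PopulationMap` (clade = population name).
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    chrom, pos, r_vec = _site_layout(config)
    L = config.n_sites
    specs = {p.name: p for p in config.populations}
    founder = config.populations[0].name

    pops: dict[str, np.ndarray] = {}
    h0 = np.zeros((specs[founder].size_at(0), 2, L), dtype=np.int8)
    used = np.zeros(L, dtype=bool)
    if config.standing_variation > 0:
        k = min(config.standing_variation, L)
        sites = rng.choice(L, size=k, replace=False)
        lo, hi = config.standing_freq_range
        freqs = rng.uniform(lo, hi, size=k)
        if config.standing_ld_rho is not None:
            # Gaussian-copula AR(1) haplotypes: latent correlation rho per
            # adjacent site gives population LD decaying with distance
            # (reset at chromosome boundaries); per-site frequencies kept.
            from scipy.stats import norm
            rho = config.standing_ld_rho
            n_hap = 2 * h0.shape[0]
            eps = rng.standard_normal((n_hap, L))
            z = eps.copy()
            scale = np.sqrt(1.0 - rho ** 2)
            for i in range(1, L):
                if chrom[i] == chrom[i - 1]:
                    z[:, i] = rho * z[:, i - 1] + scale * eps[:, i]
            thresh = norm.ppf(freqs)
            alleles = (z[:, sites] < thresh[None, :]).astype(np.int8)
            h0[:, :, sites] = alleles.reshape(h0.shape[0], 2, k)
        elif config.n_founder_haplotypes is not None:
            # founder mosaic: a small set of founder haplotypes shared
            # across individuals
            founders = (
                rng.random((config.n_founder_haplotypes, k)) < freqs[None, :]
            ).astype(np.int8)
            pick = rng.integers(0, config.n_founder_haplotypes, (h0.shape[0], 2))
            h0[:, :, sites] = founders[pick]
        else:
            h0[:, :, sites] = (
                rng.random((h0.shape[0], 2, k)) < freqs[None, None, :]
            ).astype(np.int8)
        used[sites] = True
    pops[founder] = h0

    split_by_gen: dict[int, list[Split]] = {}
    for s in config.splits:
        split_by_gen.setdefault(s.generation, []).append(s)

    for gen in range(1, config.generations + 1):
        for sp in split_by_gen.get(gen, ()):
            parent = pops[sp.parent]
            n_child = specs[sp.child].size_at(gen)
            idx = rng.choice(parent.shape[0], size=n_child,
                             replace=n_child > parent.shape[0])
            pops[sp.child] = parent[idx].copy()
        for name in list(pops):
            n_new = specs[name].size_at(gen)
            pops[name] = _reproduce(pops[name], n_new, config.selfing_rate, r_vec, rng)
        if config.mutation_rate > 0:
            for name, h in pops.items():
                lam = 2 * h.shape[0] * L * config.mutation_rate
                n_mut = rng.poisson(lam)
                if n_mut == 0:
                    continue
                free = np.flatnonzero(~used)
                if len(free) < n_mut:
                    warnings.warn("mutable sites exhausted; dropping excess mutations",
                                  stacklevel=2)
                    n_mut = len(free)
                if n_mut == 0:
                    continue
                sites = rng.choice(free, size=n_mut, replace=False)
                ind = rng.integers(0, h.shape[0], n_mut)
                copy = rng.integers(0, 2, n_mut)
                h[ind, copy, sites] = 1
                used[sites] = True

    sample_sizes = config.sample_sizes or {p.name: p.size for p in config.populations}
    dosage_blocks, ids, clade, lineage = [], [], {}, {}
    for name in sorted(sample_sizes):
        if name not in pops:
            raise ValueError(f"population {name} does not exist at sampling time")
        h = pops[name]
        n = sample_sizes[name]
        idx = rng.choice(h.shape[0], size=n, replace=n > h.shape[0])
        dosage_blocks.append(h[idx].sum(axis=1, dtype=np.int8))
        for i in range(n):
            sid = f"{name}_{i:03d}"
            ids.append(sid)
            clade[sid] = name
            lineage[sid] = specs[name].lineage or name
    dosages = np.concatenate(dosage_blocks, axis=0)

    keep = np.arange(L)
    if segregating_only:
        alt = dosages.sum(axis=0)
        keep = np.flatnonzero((alt > 0) & (alt < 2 * dosages.shape[0]))
    gm = GenotypeMatrix(
        dosages=dosages[:, keep],
        chrom=chrom[keep],
        pos=pos[keep],
        qual=np.full(len(keep), 100.0),
        sample_ids=np.array(ids, dtype=object),
    )
    return gm, PopulationMap(clade=clade, lineage=lineage)


# ---------------------------------------------------------------------------
# Trait architecture and phenotype generators
# ---------------------------------------------------------------------------

@dataclass
class TraitArchitecture:
    """Additive genotype-to-trait map for the vernalization phenotypes.

    Each causal site contributes ``effect * dosage / 2`` so that the stated
    effect is the full hom-ref to hom-alt shift (in a selfer dosage is
    almost always 0 or 2).  Baselines: MTD weeks, saturation weeks, and the
    post-return days to flower once saturation is reached; ``mtd_extra_days``
    is how much slower flowering is at exactly MTD than at saturation.
    """

    causal_sites: list[tuple[int, float, float, float]] = field(default_factory=list)
    # (site index, MTD effect weeks, saturation effect weeks, days-to-flower effect)
    baseline: tuple[float, float, float] = (4.0, 8.0, 40.0)  # (MTD0, sat0, speed0)
    mtd_extra_days: float = 14.0
    never_flower_rule=None  # optional callable dosage-row -> bool

    def true_traits(self, gm: GenotypeMatrix,
                    design_durations: list[int] | None = None,
                    snap_to_design: bool = True) -> pd.DataFrame:
        """Per-accession true trait table; missing dosages count as ref."""
        for site, *_ in self.causal_sites:
            if not 0 <= site < gm.n_sites:
                raise IndexError(f"causal site index {site} out of range")
        mtd0, sat0, speed0 = self.baseline
        n = gm.n_accessions
        mtd = np.full(n, float(mtd0))
        sat = np.full(n, float(sat0))
        speed = np.full(n, float(speed0))
        for site, e_mtd, e_sat, e_dtf in self.causal_sites:
            dose = np.maximum(gm.dosages[:, site], 0) / 2.0
            mtd += e_mtd * dose
            sat += e_sat * dose
            speed += e_dtf * dose
        if snap_to_design and design_durations is not None:
            grid = np.asarray(sorted(design_durations), dtype=float)
            mtd = grid[np.argmin(np.abs(mtd[:, None] - grid[None, :]), axis=1)]
            sat = grid[np.argmin(np.abs(sat[:, None] - grid[None, :]), axis=1)]
        sat = np.maximum(sat, mtd)
        never = np.zeros(n, dtype=bool)
        if self.never_flower_rule is not None:
            never = np.array([bool(self.never_flower_rule(gm.dosages[i]))
                              for i in range(n)])
        # a flat response (saturation at MTD) flowers at saturated speed
        days_after_mtd = np.where(sat > mtd, speed + self.mtd_extra_days, speed)
        return pd.DataFrame({
            "accession": gm.sample_ids,
            "mtd_weeks": mtd,
            "days_after_mtd": days_after_mtd,
            "saturation_weeks": sat,
            "days_after_saturation": 7.0 * sat + speed,
            "never_flowered": never,
        })


@dataclass
class EnvModel:
    """Structure-correlated environment: clade-specific MVN means with a
    shared within-clade covariance."""

    clade_means: dict[str, np.ndarray]
    within_sd: np.ndarray | float = 1.0
    corr: np.ndarray | None = None
    var_names: list[str] | None = None

    @property
    def n_vars(self) -> int:
        return len(next(iter(self.clade_means.values())))

    def covariance(self) -> np.ndarray:
        k = self.n_vars
        corr = np.eye(k) if self.corr is None else np.asarray(self.corr, dtype=float)
        sd = np.broadcast_to(np.asarray(self.within_sd, dtype=float), (k,))
        cov = corr * np.outer(sd, sd)
        if np.min(np.linalg.eigvalsh((cov + cov.T) / 2)) < -1e-8:
            raise ValueError("environment covariance is not positive semi-definite")
        return cov


def generate_environment(pop_map: PopulationMap, env: EnvModel, seed: int) -> pd.DataFrame:
    """Draw one environment vector per accession from its clade's MVN."""
    rng = np.random.default_rng(seed)
    cov = env.covariance()
    names = env.var_names or [f"env_{i + 1}" for i in range(env.n_vars)]
    rows = {}
    for acc in pop_map.samples:
        clade = pop_map.clade[acc]
        if clade not in env.clade_means:
            raise KeyError(f"no clade mean defined for {clade!r}")
        mean = np.asarray(env.clade_means[clade], dtype=float)
        rows[acc] = rng.multivariate_normal(mean, cov, method="cholesky") \
            if np.any(cov) else mean
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    df.index.name = "accession"
    return df


def generate_vernalization_response(
    true_traits: pd.DataFrame,
    design_durations: list[int],
    n_replicates: int,
    noise_sd: float,
    seed: int,
    horizon_days: float = 150.0,
    scoring_grid_days: float = 2.0,
) -> pd.DataFrame:
    """Replicated days-to-flower measurements from true trait values.

    Durations below MTD are censored (no flowering).  Between MTD and
    saturation the expected post-return days decline linearly from
    ``days_after_mtd`` to the saturated value; beyond saturation they are
    constant.  Replicate noise is Normal(0, noise_sd) rounded to the
    scoring grid; values past ``horizon_days`` are censored.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if list(design_durations) != sorted(design_durations):
        raise ValueError("design durations must be ascending")
    rng = np.random.default_rng(seed)
    records = []
    for row in true_traits.itertuples(index=False):
        mtd, sat = row.mtd_weeks, row.saturation_weeks
        d_mtd = row.days_after_mtd
        d_sat = row.days_after_saturation - 7.0 * sat  # post-return component
        never = bool(getattr(row, "never_flowered", False))
        for d in design_durations:
            for rep in range(1, n_replicates + 1):
                if never or d < mtd:
                    records.append((row.accession, d, rep, np.nan, False))
                    continue
                if d >= sat or sat == mtd:
                    mean = d_sat
                else:
                    mean = d_sat + (d_mtd - d_sat) * (sat - d) / (sat - mtd)
                days = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                days = max(np.round(days / scoring_grid_days) * scoring_grid_days, 0.0)
                if days > horizon_days:
                    records.append((row.accession, d, rep, np.nan, False))
                else:
                    records.append((row.accession, d, rep, days, True))
    return pd.DataFrame(
        records,
        columns=["accession", "duration_weeks", "replicate", "days_after_return", "flowered"],
    )


@dataclass
class SyntheticStudy:
    genotypes: GenotypeMatrix
    pop_map: PopulationMap
    true_traits: pd.DataFrame
    response: pd.DataFrame
    environment: pd.DataFrame
    design_durations: list[int]
    n_replicates: int


def simulate_panel(
    config: DemographyConfig,
    arch: TraitArchitecture,
    env: EnvModel,
    design_durations: list[int],
    n_replicates: int,
    seed: int,
    noise_sd: float = 0.0,
    genotypes: tuple[GenotypeMatrix, PopulationMap] | None = None,
) -> SyntheticStudy:
    """Full synthetic study: genotypes, phenotype design, environment.

    ``genotypes`` may be passed to reuse an already-simulated panel (e.g.
    after inspecting it to choose causal sites); otherwise the neutral
    simulation is run with the same seed.
    """
    if list(design_durations) != sorted(design_durations):
        raise ValueError("design durations must be ascending")
    gm, pop_map = genotypes if genotypes is not None else simulate_neutral(config, seed)
    true_traits = arch.true_traits(gm, design_durations)
    response = generate_vernalization_response(
        true_traits, design_durations, n_replicates, noise_sd, seed=seed + 1
    )
    environment = generate_environment(pop_map, env, seed=seed + 2)
    return SyntheticStudy(
        genotypes=gm,
        pop_map=pop_map,
        true_traits=true_traits,
        response=response,
        environment=environment,
        design_durations=list(design_durations),
        n_replicates=n_replicates,
    )
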