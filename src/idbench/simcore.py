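"""Forward-time Wright-Fisher simulation with pleiotropic deleterious mutations.

A diploid monoecious population of constant size ``N`` evolves in discrete
generations under mutation, recombination and purifying selection.  Mutations
arise on a single linear genome of ``L`` base pairs at rate ``U`` per haploid
genome per generation.  A fraction ``prop_causal`` of them are QTLs with a
pleiotropic effect on fitness (multiplicative across loci, genotypic values
1 / 1+sh / 1+s) and on a quantitative trait (additive, values 0 / ah / a);
the rest are strictly neutral markers.  Homozygous effects |s| (and |a|) are
gamma distributed with mean |mean_s| and shape ``beta``, correlated across
the two dimensions with Pearson correlation ``rho``.  Because mutations are
deleterious and partially recessive (h < 1/2), dominance is directional and
the trait shows inbreeding depression.

The population is represented as a (2N, S) uint8 haplotype matrix over the
currently segregating sites, with parallel per-site arrays of positions and
effects.  Fixed and lost sites are swept out every generation (fixed trait
effects only shift the phenotypic mean, which no downstream regression uses;
a counter records how many were dropped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterator

import numpy as np
from scipy import optimize, stats

from ._kernels import assemble_compact, count_alleles, fill_row_nonzero

__all__ = [
    "SimulationConfig",
    "MutationRecord",
    "PopulationState",
    "SimulationError",
    "default_scenario",
    "scenario_preset",
    "SCENARIO_PRESETS",
    "draw_mutation_effects",
    "dominance_rate_for_mean_h",
    "variable_dominance",
    "make_gamete",
    "fitness",
    "phenotype",
    "next_generation",
    "advance",
    "run_replicate",
    "calibrate_rates",
]

H_MODELS = ("constant", "variable_ck")

# Default scenario constants.  U was obtained with ``calibrate_rates`` (see
# docs/methods.md): Watterson initialisation for ~30,000 neutral SNPs at the
# final generation, refined by pilot replicates to absorb the diversity lost
# to background selection.  trait_scale makes the mean inbreeding load
# (sum of 2dpq over QTLs) approximately one lethal equivalent at N=100.
DEFAULT_U_N100 = 13.87
DEFAULT_TRAIT_SCALE_N100 = 0.875


class SimulationError(RuntimeError):
    """A replicate reached a state it cannot continue from."""


@dataclass
class SimulationConfig:
    """Parameters of one simulation scenario.

    Attributes
    ----------
    N : population size (diploid individuals, constant).
    L : genome length in base pairs.
    c : recombination rate between adjacent base pairs, in Morgans.
    U : mutation rate per haploid genome per generation.
    prop_causal : fraction of new mutations that are pleiotropic QTLs.
    mean_s : mean homozygous fitness effect of QTLs (negative).
    beta : gamma shape of the |s| (and |a|) distribution.
    h_model : "constant" or "variable_ck" (uniform on [0, exp(-k|s|)] with
        k solved so that the mean dominance coefficient is ``h_value``).
    h_value : dominance coefficient (constant model) or its target mean
        (variable model).
    rho : Pearson correlation between |a| and |s| for QTLs.
    trait_scale : multiplier applied to a (a = trait_scale * s at rho = 1).
    id_target : desired true inbreeding-depression rate, used by calibration.
    generations : run length; defaults to 10N (5N when N = 10,000).
    drop_fixed : sweep fixed sites out of the state (disable to measure
        inbreeding against a stored reference generation).
    seed : RNG seed for :func:`run_replicate`.
    """

    N: int
    L: int = 100_000_000
    c: float = 1e-8
    U: float = DEFAULT_U_N100
    prop_causal: float = 0.05
    mean_s: float = -0.03
    beta: float = 1.0
    h_model: str = "constant"
    h_value: float = 0.2
    rho: float = 1.0
    trait_scale: float = 1.0
    id_target: float = 1.0
    generations: int | None = None
    drop_fixed: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not (0.0 <= self.prop_causal <= 1.0):
            raise ValueError("prop_causal must be in [0, 1]")
        if self.mean_s >= 0:
            raise ValueError("mean_s must be negative")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must be in (0, 1]")
        if self.h_model not in H_MODELS:
            raise ValueError(f"h_model must be one of {H_MODELS}")
        if self.generations is None:
            self.generations = 5 * self.N if self.N >= 10_000 else 10 * self.N
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    @property
    def crossover_rate(self) -> float:
        """Expected crossovers per gamete (map length in Morgans)."""
        return self.c * (self.L - 1)


@dataclass(frozen=True)
class MutationRecord:
    """One mutation: genomic position, class, and effects."""

    position: int
    is_qtl: bool
    s: float
    a: float
    h: float
    origin_gen: int = 0


@dataclass
class PopulationState:
    """Haplotypes over the currently segregating sites plus their registry."""

    haplotypes: np.ndarray          # (2N, S) uint8
    positions: np.ndarray           # (S,) int64, sorted ascending
    is_qtl: np.ndarray              # (S,) bool
    s: np.ndarray                   # (S,) float64, 0 for neutral sites
    a: np.ndarray                   # (S,) float64, 0 for neutral sites
    h: np.ndarray                   # (S,) float64
    origin_gen: np.ndarray          # (S,) int32
    generation: int = 0
    n_fixed_dropped: int = 0
    n_fixed_qtl_dropped: int = 0

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    @property
    def n_neutral(self) -> int:
        return self.n_sites - self.n_qtl

    def genotypes(self, cols: np.ndarray | None = None) -> np.ndarray:
        """Derived-allele dosage matrix (N, S) for the selected columns."""
        hap = self.haplotypes if cols is None else self.haplotypes[:, cols]
        return (hap[0::2, :] + hap[1::2, :]).astype(np.int8)

    def site_records(self) -> Iterator[MutationRecord]:
        for k in range(self.n_sites):
            yield MutationRecord(
                position=int(self.positions[k]),
                is_qtl=bool(self.is_qtl[k]),
                s=float(self.s[k]),
                a=float(self.a[k]),
                h=float(self.h[k]),
                origin_gen=int(self.origin_gen[k]),
            )


def founding_population(config: SimulationConfig) -> PopulationState:
    """A population devoid of variation (all-ancestral genome)."""
    return PopulationState(
        haplotypes=np.zeros((2 * config.N, 0), dtype=np.uint8),
        positions=np.empty(0, dtype=np.int64),
        is_qtl=np.empty(0, dtype=bool),
        s=np.empty(0, dtype=np.float64),
        a=np.empty(0, dtype=np.float64),
        h=np.empty(0, dtype=np.float64),
        origin_gen=np.empty(0, dtype=np.int32),
    )


# ---------------------------------------------------------------------------
# Mutation effects
# ---------------------------------------------------------------------------

def dominance_rate_for_mean_h(mean_s: float, beta: float,
                              mean_h: float = 0.2) -> float:
    """Decay rate k of the variable-dominance model, h ~ U[0, exp(-k|s|)].

    With |s| ~ Gamma(beta, scale=|mean_s|/beta) the mean dominance is
    E[h] = 0.5 * E[exp(-k|s|)] = 0.5 * (1 + k*scale)^(-beta), so k has the
    closed form below.  Requires mean_h < 0.5.
    """
    if not (0.0 < mean_h < 0.5):
        raise ValueError("mean_h must be in (0, 0.5)")
    scale = abs(mean_s) / beta
    return ((0.5 / mean_h) ** (1.0 / beta) - 1.0) / scale


def variable_dominance(s, rng: np.random.Generator, k: float):
    """Draw h ~ Uniform[0, exp(-k*|s|)]: strong mutations tend recessive."""
    s = np.asarray(s, dtype=np.float64)
    upper = np.exp(-k * np.abs(s))
    return rng.uniform(0.0, 1.0, size=s.shape) * upper


@lru_cache(maxsize=32)
def _copula_correlation(beta: float, rho: float) -> float:
    """Gaussian-copula correlation giving Pearson rho between two gamma
    marginals of shape ``beta`` (solved numerically on a fixed lattice)."""
    z = np.random.default_rng(20200923).standard_normal((2, 200_000))

    def pearson(r: float) -> float:
        z2 = r * z[0] + math.sqrt(1.0 - r * r) * z[1]
        g1 = stats.gamma.ppf(stats.norm.cdf(z[0]), beta)
        g2 = stats.gamma.ppf(stats.norm.cdf(z2), beta)
        return float(np.corrcoef(g1, g2)[0, 1])

    return float(optimize.brentq(lambda r: pearson(r) - rho,
                                 1e-6, 1.0 - 1e-9, xtol=1e-4))


def _draw_effect_arrays(rng: np.random.Generator, config: SimulationConfig,
                        n: int) -> tuple[np.ndarray, ...]:
    """Vectorised effect sampling for ``n`` new mutations.

    Returns (is_qtl, s, a, h) arrays; neutral rows have s = a = 0 and carry
    the dominance coefficient only as a placeholder.
    """
    is_qtl = rng.uniform(size=n) < config.prop_causal
    s = np.zeros(n)
    a = np.zeros(n)
    nq = int(is_qtl.sum())
    if nq:
        scale = abs(config.mean_s) / config.beta
        if config.rho >= 1.0:
            mag_s = rng.gamma(config.beta, scale, size=nq)
            mag_a = mag_s.copy()
        else:
            r = _copula_correlation(config.beta, config.rho)
            z1 = rng.standard_normal(nq)
            z2 = r * z1 + math.sqrt(1.0 - r * r) * rng.standard_normal(nq)
            mag_s = stats.gamma.ppf(stats.norm.cdf(z1), config.beta) * scale
            mag_a = stats.gamma.ppf(stats.norm.cdf(z2), config.beta) * scale
        s[is_qtl] = -mag_s
        a[is_qtl] = -mag_a * config.trait_scale
    if config.h_model == "constant":
        h = np.full(n, config.h_value)
    else:
        k = dominance_rate_for_mean_h(config.mean_s, config.beta,
                                      config.h_value)
        h = np.where(is_qtl, variable_dominance(s, rng, k),
                     rng.uniform(0.0, 0.5, size=n))
    return is_qtl, s, a, h


def draw_mutation_effects(rng: np.random.Generator, config: SimulationConfig,
                          size: int | None = None):
    """Sample mutation classes and effects.

    With ``size=None`` returns a single :class:`MutationRecord` (position 0,
    to be filled by the caller); otherwise returns the tuple of arrays
    ``(is_qtl, s, a, h)`` of length ``size``.
    """
    if size is not None:
        return _draw_effect_arrays(rng, config, size)
    is_qtl, s, a, h = _draw_effect_arrays(rng, config, 1)
    return MutationRecord(position=0, is_qtl=bool(is_qtl[0]), s=float(s[0]),
                          a=float(a[0]), h=float(h[0]))


# ---------------------------------------------------------------------------
# Genotype -> fitness / phenotype maps
# ---------------------------------------------------------------------------

def fitness(qtl_genotypes: np.ndarray, s: np.ndarray,
            h: np.ndarray) -> np.ndarray:
    """Multiplicative fitness over QTLs: 1, 1+sh, 1+s by dosage, floored at 0.

    Parameters are per-QTL arrays; ``qtl_genotypes`` is (N, n_qtl) dosage of
    the mutant allele.  Per-locus values below zero are treated as lethal.
    """
    g = np.asarray(qtl_genotypes)
    if g.size == 0:
        return np.ones(g.shape[0] if g.ndim == 2 else 1)
    v = 1.0 + (g == 1) * (s * h) + (g == 2) * s
    np.clip(v, 0.0, None, out=v)
    return v.prod(axis=-1)


def phenotype(qtl_genotypes: np.ndarray, a: np.ndarray,
              h: np.ndarray) -> np.ndarray:
    """Additive trait value over QTLs: 0, ah, a by dosage (no noise)."""
    g = np.asarray(qtl_genotypes)
    if g.size == 0:
        return np.zeros(g.shape[0] if g.ndim == 2 else 1)
    return (g == 1) @ (a * h) + (g == 2) @ a


def population_phenotypes(pop: PopulationState) -> np.ndarray:
    """Trait values of every individual in the population."""
    qcols = np.flatnonzero(pop.is_qtl)
    return phenotype(pop.genotypes(qcols), pop.a[qcols], pop.h[qcols])


def population_fitness(pop: PopulationState) -> np.ndarray:
    """Fitness of every individual in the population."""
    qcols = np.flatnonzero(pop.is_qtl)
    return fitness(pop.genotypes(qcols), pop.s[qcols], pop.h[qcols])


# ---------------------------------------------------------------------------
# Gametogenesis
# ---------------------------------------------------------------------------

def _draw_mutation_positions(rng: np.random.Generator, n: int,
                             existing: np.ndarray, L: int) -> np.ndarray:
    """Uniform integer positions on [0, L), unique and collision-free.

    Infinite-sites on a discrete lattice: a proposal colliding with a
    currently segregating site (or with another proposal) is redrawn.
    """
    pos = rng.integers(0, L, size=n, dtype=np.int64)
    for _ in range(100):
        dup = np.zeros(n, dtype=bool)
        order = np.argsort(pos, kind="stable")
        sorted_pos = pos[order]
        dup[order[1:]] = sorted_pos[1:] == sorted_pos[:-1]
        # membership against the (sorted) segregating positions
        ins = np.searchsorted(existing, pos)
        hit = ins < existing.size
        hit[hit] = existing[ins[hit]] == pos[hit]
        bad = dup | hit
        nbad = int(bad.sum())
        if nbad == 0:
            return pos
        pos[bad] = rng.integers(0, L, size=nbad, dtype=np.int64)
    raise SimulationError("could not place mutations without collision")


def make_gamete(parent_hap_pair: np.ndarray, positions: np.ndarray,
                rng: np.random.Generator, config: SimulationConfig,
                origin_gen: int = 0):
    """Form one gamete from a pair of parental haplotypes.

    Crossovers are Poisson(c*(L-1)) with uniform positions and no
    interference; the gamete starts on a fair-coin strand and alternates at
    each crossover.  New mutations (count Poisson(U)) get uniform positions
    avoiding segregating sites and effects from :func:`draw_mutation_effects`.

    Returns ``(gamete, new_records)`` where ``gamete`` is a uint8 vector over
    the parental site index and ``new_records`` a list of MutationRecord.
    """
    parent_hap_pair = np.asarray(parent_hap_pair, dtype=np.uint8)
    n_cx = rng.poisson(config.crossover_rate)
    cuts = np.sort(rng.uniform(0.0, config.L, size=n_cx))
    start = int(rng.integers(0, 2))
    strand = (start + np.searchsorted(cuts, positions, side="right")) % 2
    gamete = np.where(strand == 0, parent_hap_pair[0], parent_hap_pair[1])
    n_mut = rng.poisson(config.U)
    records: list[MutationRecord] = []
    if n_mut:
        mpos = _draw_mutation_positions(rng, n_mut, positions, config.L)
        is_qtl, s, a, h = _draw_effect_arrays(rng, config, n_mut)
        for j in range(n_mut):
            records.append(MutationRecord(int(mpos[j]), bool(is_qtl[j]),
                                          float(s[j]), float(a[j]),
                                          float(h[j]), origin_gen))
    return gamete.astype(np.uint8), records


# ---------------------------------------------------------------------------
# Generation step
# ---------------------------------------------------------------------------

def next_generation(pop: PopulationState, rng: np.random.Generator,
                    config: SimulationConfig) -> PopulationState:
    """Produce the next Wright-Fisher generation.

    Each of the N offspring draws two parents independently, with replacement
    and probability proportional to fitness (monoecious random mating, so the
    two parents may coincide: selfing is permitted).  Each parent contributes
    one recombinant, mutated gamete.  Lost sites are always swept from the
    state; fixed sites are swept unless ``config.drop_fixed`` is False.
    """
    N = config.N
    n_gam = 2 * N
    S = pop.n_sites

    w = population_fitness(pop)
    wsum = w.sum()
    if wsum <= 0.0:
        raise SimulationError(
            f"all {N} individuals have zero fitness at generation "
            f"{pop.generation}; replicate aborted")
    parents = rng.choice(N, size=n_gam, p=w / wsum)

    # Crossover breakpoints as site indices, flattened across gametes.
    n_cx = rng.poisson(config.crossover_rate, size=n_gam)
    offsets = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(n_cx, out=offsets[1:])
    xpos = rng.uniform(0.0, config.L, size=int(offsets[-1]))
    cut_sites = np.searchsorted(pop.positions, xpos).astype(np.int64)
    for g in np.flatnonzero(n_cx > 1):
        cut_sites[offsets[g]:offsets[g + 1]].sort()
    start = rng.integers(0, 2, size=n_gam).astype(np.uint8)

    # New mutations, drawn jointly for all gametes.
    n_mut = rng.poisson(config.U, size=n_gam)
    total_mut = int(n_mut.sum())
    if total_mut:
        mpos = _draw_mutation_positions(rng, total_mut, pop.positions,
                                        config.L)
        m_qtl, m_s, m_a, m_h = _draw_effect_arrays(rng, config, total_mut)
        carrier = np.repeat(np.arange(n_gam), n_mut)
    else:
        mpos = np.empty(0, dtype=np.int64)
        m_qtl = np.empty(0, dtype=bool)
        m_s = m_a = m_h = np.empty(0)
        carrier = np.empty(0, dtype=np.int64)

    # Sparse index of the parental derived alleles, then pass 1: allele
    # counts of the prospective offspring, to decide which parental sites
    # survive (new mutations are singletons, always kept).
    row_a = (2 * parents).astype(np.int64)
    row_b = row_a + 1
    colsum = np.zeros(S, dtype=np.int64)
    row_counts = pop.haplotypes.sum(axis=1, dtype=np.int64)
    nz_off = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(row_counts, out=nz_off[1:])
    nz_idx = np.empty(int(nz_off[-1]) + 1, dtype=np.int64)
    if S:
        fill_row_nonzero(pop.haplotypes, nz_off, nz_idx)
        count_alleles(nz_idx, nz_off, row_a, row_b, start, cut_sites,
                      offsets, colsum)
    fixed = colsum == n_gam
    keep = colsum > 0
    if config.drop_fixed:
        keep &= ~fixed

    # Destination layout: surviving parental sites and new mutations,
    # merged in position order.
    positions = np.concatenate([pop.positions[keep], mpos])
    order = np.argsort(positions, kind="stable")
    n_total = positions.size
    dest_of = np.empty(n_total, dtype=np.int64)
    dest_of[order] = np.arange(n_total)
    colmap = np.full(S, -1, dtype=np.int64)
    colmap[keep] = dest_of[:int(keep.sum())]

    # Pass 2: write gametes directly into the compacted layout.
    haps = np.zeros((n_gam, n_total), dtype=np.uint8)
    if S:
        assemble_compact(nz_idx, nz_off, row_a, row_b, start, cut_sites,
                         offsets, colmap, haps)
    if total_mut:
        haps[carrier, dest_of[int(keep.sum()):]] = 1

    def _merge(old: np.ndarray, new: np.ndarray) -> np.ndarray:
        return np.concatenate([old[keep], new])[order]

    n_fixed = int(fixed.sum()) if config.drop_fixed else 0
    n_fixed_qtl = int((fixed & pop.is_qtl).sum()) if config.drop_fixed else 0
    return PopulationState(
        haplotypes=haps,
        positions=positions[order],
        is_qtl=_merge(pop.is_qtl, m_qtl),
        s=_merge(pop.s, m_s),
        a=_merge(pop.a, m_a),
        h=_merge(pop.h, m_h),
        origin_gen=_merge(pop.origin_gen,
                          np.full(total_mut, pop.generation + 1,
                                  dtype=np.int32)),
        generation=pop.generation + 1,
        n_fixed_dropped=pop.n_fixed_dropped + n_fixed,
        n_fixed_qtl_dropped=pop.n_fixed_qtl_dropped + n_fixed_qtl,
    )


def advance(pop: PopulationState, generations: int,
            rng: np.random.Generator,
            config: SimulationConfig) -> PopulationState:
    """Run ``generations`` successive generation steps."""
    for _ in range(generations):
        pop = next_generation(pop, rng, config)
    return pop


@dataclass
class ReplicateSummary:
    """Headline numbers of one finished replicate."""

    n_neutral_snps: int
    n_qtl: int
    true_id: float
    n_fixed_dropped: int


def run_replicate(config: SimulationConfig,
                  seed: int | None = None) -> tuple[PopulationState,
                                                    ReplicateSummary]:
    """Run one full replicate from a variation-free founder population.

    Deterministic given ``seed`` (falls back to ``config.seed``).  Returns
    the final-generation population and a summary with the segregating
    neutral-SNP count, QTL count and realised true inbreeding-depression
    rate (sum of 2dpq over segregating QTLs).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    pop = advance(founding_population(config), config.generations, rng,
                  config)
    from .truth import true_id_2dpq
    summary = ReplicateSummary(
        n_neutral_snps=pop.n_neutral,
        n_qtl=pop.n_qtl,
        true_id=true_id_2dpq(pop) if pop.n_qtl else 0.0,
        n_fixed_dropped=pop.n_fixed_dropped,
    )
    return pop, summary


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def watterson_u(N: int, target_snps: float, neutral_fraction: float) -> float:
    """Initial mutation rate from the neutral Watterson expectation.

    Solves E[S] = 4N * (neutral_fraction * U) * sum_{i=1}^{2N-1} 1/i for U,
    treating only the neutral fraction of mutations as contributing to the
    marker panel.
    """
    harmonic = np.sum(1.0 / np.arange(1, 2 * N))
    return target_snps / (4.0 * N * neutral_fraction * harmonic)


@dataclass
class CalibrationResult:
    U: float
    trait_scale: float
    realized_snps: float | None = None
    realized_id: float | None = None
    converged: bool = True


def calibrate_rates(config: SimulationConfig, target_snps: float = 30_000,
                    pilot_reps: int = 2, max_rounds: int = 3,
                    tol: float = 0.05, seed: int = 0) -> CalibrationResult:
    """Tune (U, trait_scale) so a replicate segregates ~``target_snps``
    neutral SNPs and its expected inbreeding load matches ``id_target``.

    U starts at the Watterson solution and is refined multiplicatively from
    short pilot replicates (selection and linkage depress diversity below
    the neutral expectation).  Because the trait does not feed back on
    fitness, trait_scale is solved exactly from the pilots' unscaled loads:
    scale = id_target / mean(sum 2 d p q with trait_scale = 1).
    """
    from .truth import true_id_2dpq

    if config.id_target == 0:
        return CalibrationResult(U=config.U, trait_scale=0.0)

    U = watterson_u(config.N, target_snps, 1.0 - config.prop_causal)
    ss = np.random.SeedSequence(seed)
    realized_s = realized_b = None
    converged = False
    for _ in range(max_rounds):
        pilot_cfg = replace(config, U=U, trait_scale=1.0)
        counts, loads = [], []
        for child in ss.spawn(pilot_reps):
            pilot_seed = int(child.generate_state(1)[0] % (2 ** 31))
            pop, summ = run_replicate(pilot_cfg, seed=pilot_seed)
            counts.append(summ.n_neutral_snps)
            loads.append(true_id_2dpq(pop))
        realized_s = float(np.mean(counts))
        realized_b = float(np.mean(loads))
        if abs(realized_s - target_snps) <= tol * target_snps:
            converged = True
            break
        U *= target_snps / realized_s
    scale = config.id_target / realized_b if realized_b else 0.0
    return CalibrationResult(U=U, trait_scale=scale,
                             realized_snps=realized_s,
                             realized_id=realized_b * scale,
                             converged=converged)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def default_scenario(N: int = 100, **overrides) -> SimulationConfig:
    """The default benchmark scenario at population size ``N``.

    Mutation rate and trait scale default to the calibrated N=100 values;
    other population sizes should recalibrate via :func:`calibrate_rates`.
    """
    params = dict(N=N, U=DEFAULT_U_N100,
                  trait_scale=DEFAULT_TRAIT_SCALE_N100)
    params.update(overrides)
    return SimulationConfig(**params)


# Variant scenarios (single-parameter departures from the default).
SCENARIO_PRESETS: dict[str, dict] = {
    "default": {},
    "c_high": {"c": 1e-7},
    "c_low": {"c": 1e-9},
    "quarter_density": {"U": DEFAULT_U_N100 / 4.0},
    "pc10": {"prop_causal": 0.10},
    "s01": {"mean_s": -0.1},
    "beta01": {"beta": 0.1},
    "beta2": {"beta": 2.0},
    "h0": {"h_value": 0.0},
    "rho05": {"rho": 0.5},
    "variable_h": {"h_model": "variable_ck"},
}


def scenario_preset(name: str, N: int = 100, **overrides) -> SimulationConfig:
    """Named variant scenario (one parameter changed from the default)."""
    if name not in SCENARIO_PRESETS:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"choose from {sorted(SCENARIO_PRESETS)}")
    params = dict(SCENARIO_PRESETS[name])
    params.update(overrides)
    return default_scenario(N=params.pop("N", N), **params)
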