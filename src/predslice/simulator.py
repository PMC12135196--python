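"""Forward-in-time genomic-selection simulator.

Emulates a breeding program with three traits:

* trait 1 ("production"): polygenic, initial h2 = 0.4, under truncation
  selection on its GEBV every generation;
* trait 2 ("scaffold"): polygenic, h2 = 0.1, genetically independent of
  trait 1, never selected — it only exists to build trait 3;
* trait 3 ("fitness"): the engineered composite
      u3 = alpha_j * [ u2 - beta * u1 * (u1 - mean(u1, generation 0)) ]
  with alpha_j rescaling var(u3) to 1 within each generation.  Because the
  centering constant is frozen at the generation-0 mean, directional selection
  on trait 1 shifts the u1 distribution and drags corr(u1, u3) downward —
  by about 0.1 per generation once beta is calibrated.

Founders carry haplotypes drawn per locus from uniform allele frequencies and
then go through a few generations of random mating (burn-in) to build linkage
disequilibrium between markers and QTN.  Breeding values are always recomputed
from QTN genotypes, never drawn from a normal, so the genetic covariance
structure is the one implied by the realized genomic relationships.  Meiosis
follows the Haldane model: crossover counts per chromosome are Poisson in map
length, positions uniform, no interference, no mutation.

Default scale (used throughout the test suite): 10 chromosomes x 100 cM,
500 markers + 30 QTN per chromosome, 2,000 offspring per generation, top 13
sires and 500 dams selected on trait-1 GEBV (Ne = 4*13*500/513 ~ 50, the same
effective size and 50% dam selected fraction as an industrial nucleus), 7
generations (0-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import CalibrationError, DegenerateInputError, InvalidInputError
from .gblup import GenotypeMatrix, build_grm, solve_gblup

__all__ = ["GenomeSpec", "TraitArchitecture", "SelectionScheme", "SimConfig",
           "SimPopulation", "RealizedParameters", "simulate_founders",
           "sample_qtn_effects", "composite_trait", "calibrate_beta",
           "select_and_mate", "run_generations", "realized_parameters",
           "effective_population_size"]

# output of calibrate_beta at the default scale (seed 0): realized
# corr(u1, u3) declines by ~0.1 per generation
DEFAULT_BETA = 0.115


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    n_chromosomes: int = 10
    chromosome_length_cm: float = 100.0
    markers_per_chromosome: int = 500
    qtn_per_chromosome: int = 30
    founder_maf_range: Tuple[float, float] = (0.05, 0.5)

    def __post_init__(self):
        if min(self.n_chromosomes, self.markers_per_chromosome,
               self.qtn_per_chromosome) < 1 or self.chromosome_length_cm <= 0:
            raise InvalidInputError("genome counts must be >= 1 and length > 0")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidInputError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")

    @property
    def genome_length_morgans(self) -> float:
        return self.n_chromosomes * self.chromosome_length_cm / 100.0

    @property
    def loci_per_chromosome(self) -> int:
        return self.markers_per_chromosome + self.qtn_per_chromosome

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome


@dataclass(frozen=True)
class TraitArchitecture:
    """Trait model: gamma-magnitude random-sign QTN effects for traits 1 and 2
    (scaled so generation-0 var(u) = 1), residual variances per observed trait,
    and the composite-trait coefficient beta."""

    residual_variances: Tuple[float, float, float] = (1.5, 9.0, 9.0)
    gamma_shape: float = 0.4
    beta: float = DEFAULT_BETA

    def __post_init__(self):
        if any(v <= 0 for v in self.residual_variances):
            raise InvalidInputError("residual variances must be > 0")
        if self.gamma_shape <= 0:
            raise InvalidInputError("gamma_shape must be > 0")


@dataclass(frozen=True)
class SelectionScheme:
    n_sires: int = 13
    n_dams: int = 500
    offspring_per_generation: int = 2000
    select: bool = True              # False: parents drawn at random (control)

    def __post_init__(self):
        if min(self.n_sires, self.n_dams, self.offspring_per_generation) < 1:
            raise InvalidInputError("scheme counts must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    traits: TraitArchitecture = field(default_factory=TraitArchitecture)
    scheme: SelectionScheme = field(default_factory=SelectionScheme)
    n_generations: int = 6           # selection cycles after generation 0
    burn_in_generations: int = 10
    burn_in_size: int = 200          # recent effective size of the founder history
    h2_gblup: float = 0.4            # assumed h2 for the selection GBLUP
    blend_alpha: float = 0.05


def effective_population_size(n_sires: int, n_dams: int) -> float:
    """Ne = 4 Nm Nf / (Nm + Nf)."""
    return 4.0 * n_sires * n_dams / (n_sires + n_dams)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class SimPopulation:
    """All generations 0..J of a simulated program."""

    individuals: pd.DataFrame        # id, generation, sex, sire, dam, u1..u3, y1..y3
    genotypes: GenotypeMatrix        # marker dosages, generations 0..J
    qtn_dosages: np.ndarray = field(repr=False, default=None)
    qtn_effects: np.ndarray = field(repr=False, default=None)   # (n_qtn, 2)
    beta: float = None
    u1_ref_mean: float = None        # mean of u1 in generation 0 (frozen)
    alphas: dict = field(default_factory=dict)                  # generation -> alpha_j
    config: SimConfig = None

    @property
    def generations(self) -> list:
        return sorted(self.individuals["generation"].unique())

    def phenotype_table(self) -> pd.DataFrame:
        cols = ["id", "generation", "sex", "y1", "y2", "y3"]
        return self.individuals[cols].copy()


@dataclass
class RealizedParameters:
    """Per-generation parameters computed from true breeding values."""

    table: pd.DataFrame              # generation, h2_1..h2_3, corr_u1_u3, mean_u1..

    def h2(self, trait: int, generation: int) -> float:
        row = self.table.loc[self.table["generation"] == generation]
        return float(row[f"h2_{trait}"].iloc[0])

    def corr_u1_u3(self, generation: int) -> float:
        row = self.table.loc[self.table["generation"] == generation]
        return float(row["corr_u1_u3"].iloc[0])

    def mean_decline_corr_u1_u3(self) -> float:
        c = self.table.sort_values("generation")["corr_u1_u3"].to_numpy()
        return float((c[-1] - c[0]) / (len(c) - 1))


# ---------------------------------------------------------------------------
# Genome and meiosis
# ---------------------------------------------------------------------------


def _genome_layout(genome: GenomeSpec, rng: np.random.Generator):
    """Locus positions (Morgans, per chromosome), chromosome starts, QTN mask.

    Markers sit on an even grid; QTN at uniform random positions (distinct from
    markers with probability one).
    """
    length_m = genome.chromosome_length_cm / 100.0
    positions, qtn_mask = [], []
    for _ in range(genome.n_chromosomes):
        mk = (np.arange(genome.markers_per_chromosome) + 0.5) \
            * length_m / genome.markers_per_chromosome
        qt = rng.uniform(0.0, length_m, size=genome.qtn_per_chromosome)
        pos = np.concatenate([mk, qt])
        mask = np.concatenate([np.zeros(mk.size, bool), np.ones(qt.size, bool)])
        order = np.argsort(pos)
        positions.append(pos[order])
        qtn_mask.append(mask[order])
    return positions, np.concatenate(qtn_mask)


def _meiosis(haps: np.ndarray, parent_idx: np.ndarray, positions: list,
             chrom_lengths: list, rng: np.random.Generator) -> np.ndarray:
    """One gamete per requested parent.

    haps: (n_parents, 2, n_loci) phased haplotypes; parent_idx: (n_gametes,)
    rows of haps to draw gametes from.  Haldane model per chromosome: the
    crossover count is Poisson in the chromosome map length (Morgans),
    positions uniform, no interference.
    """
    n_g = parent_idx.size
    n_loci = haps.shape[2]
    gametes = np.empty((n_g, n_loci), dtype=np.uint8)
    start = 0
    for pos, length_m in zip(positions, chrom_lengths):
        ln = pos.size
        k = rng.poisson(lam=max(length_m, 1e-12), size=n_g)
        phase = rng.integers(0, 2, size=n_g)
        sl = slice(start, start + ln)
        chrom = haps[:, :, sl]
        for g in range(n_g):
            p = parent_idx[g]
            if k[g] == 0:
                gametes[g, sl] = chrom[p, phase[g]]
            else:
                xo = np.sort(rng.uniform(0.0, length_m, size=k[g]))
                src = (phase[g] + np.searchsorted(xo, pos)) % 2
                gametes[g, sl] = chrom[p, src, np.arange(ln)]
        start += ln
    return gametes


# ---------------------------------------------------------------------------
# Founders and effects
# ---------------------------------------------------------------------------


def simulate_founders(genome: GenomeSpec, n: int, seed) -> Tuple[np.ndarray, list, np.ndarray]:
    """Founder haplotypes: per-locus Bernoulli draws at frequencies uniform in
    the configured minor-allele range (random orientation), followed by
    burn-in random mating elsewhere (see run_generations).

    Returns (haplotypes (n, 2, n_loci), positions per chromosome, qtn_mask).
    """
    if n < 2:
        raise InvalidInputError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    positions, qtn_mask = _genome_layout(genome, rng)
    lo, hi = genome.founder_maf_range
    maf = rng.uniform(lo, hi, size=genome.n_loci)
    flip = rng.integers(0, 2, size=genome.n_loci).astype(bool)
    p = np.where(flip, 1.0 - maf, maf)
    haps = (rng.random((n, 2, genome.n_loci)) < p).astype(np.uint8)
    return haps, positions, qtn_mask


def sample_qtn_effects(n_qtn: int, gamma_shape: float, rng: np.random.Generator,
                       n_traits: int = 2) -> np.ndarray:
    """Additive QTN effects: gamma(shape) magnitudes with random sign, drawn
    independently per trait.  Returned unscaled; run_generations rescales each
    trait so generation-0 var(u) = 1."""
    if gamma_shape <= 0:
        raise InvalidInputError("gamma_shape must be > 0")
    mags = rng.gamma(gamma_shape, 1.0, size=(n_qtn, n_traits))
    signs = rng.choice((-1.0, 1.0), size=(n_qtn, n_traits))
    return mags * signs


def composite_trait(u1: np.ndarray, u2: np.ndarray, beta: float,
                    ref_mean_u1: float) -> Tuple[np.ndarray, float]:
    """u3 = alpha * [u2 - beta * u1 * (u1 - ref_mean_u1)], alpha = 1/sd(raw),
    so var(u3) = 1 exactly on the given vector."""
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if u1.shape != u2.shape or u1.size < 2:
        raise InvalidInputError("u1 and u2 must be equal-length vectors, length >= 2")
    raw = u2 - beta * u1 * (u1 - ref_mean_u1)
    sd = float(np.std(raw, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("composite trait has zero variance")
    alpha = 1.0 / sd
    return alpha * raw, alpha


# ---------------------------------------------------------------------------
# Selection and mating
# ---------------------------------------------------------------------------


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly even sex split (shuffled); keeps the burn-in Ne at its census size."""
    sex = np.array(["M"] * (n // 2) + ["F"] * (n - n // 2))
    rng.shuffle(sex)
    return sex


def _pick_parents(candidates: pd.DataFrame, gebv: Optional[pd.Series],
                  scheme: SelectionScheme, rng: np.random.Generator):
    males = candidates.index[candidates["sex"] == "M"]
    females = candidates.index[candidates["sex"] == "F"]
    if len(males) < scheme.n_sires or len(females) < scheme.n_dams:
        raise InvalidInputError(
            f"not enough candidates: {len(males)} males / {len(females)} females "
            f"for {scheme.n_sires} sires / {scheme.n_dams} dams")
    if scheme.select:
        if gebv is None:
            raise InvalidInputError("selection requested but no GEBVs supplied")
        sires = gebv.loc[males].nlargest(scheme.n_sires).index.to_list()
        dams = gebv.loc[females].nlargest(scheme.n_dams).index.to_list()
    else:
        sires = list(rng.choice(males, size=scheme.n_sires, replace=False))
        dams = list(rng.choice(females, size=scheme.n_dams, replace=False))
    return sires, dams


def select_and_mate(candidates: pd.DataFrame, haps: np.ndarray,
                    gebv: Optional[pd.Series], scheme: SelectionScheme,
                    positions: list, chrom_lengths: list,
                    rng: np.random.Generator, id_prefix: str = "G1"):
    """Truncation selection on GEBV within each sex, then random mating.

    ``candidates`` is indexed by id with columns sex; ``haps`` holds their
    haplotypes in the same row order.  Each selected dam contributes an equal
    number of offspring (offspring_per_generation // n_dams); the sire of each
    offspring is drawn uniformly with replacement from the selected sires.
    Offspring sexes are assigned with equal probability.

    Returns (offspring DataFrame [id, sex, sire, dam], offspring haplotypes).
    """
    sires, dams = _pick_parents(candidates, gebv, scheme, rng)
    per_dam = scheme.offspring_per_generation // scheme.n_dams
    if per_dam < 1:
        raise InvalidInputError("offspring_per_generation must be >= n_dams")
    dam_ids = np.repeat(dams, per_dam)
    n_off = dam_ids.size
    sire_ids = np.asarray(sires)[rng.integers(0, len(sires), size=n_off)]

    row = {iid: k for k, iid in enumerate(candidates.index)}
    sire_rows = np.asarray([row[i] for i in sire_ids])
    dam_rows = np.asarray([row[i] for i in dam_ids])
    paternal = _meiosis(haps, sire_rows, positions, chrom_lengths, rng)
    maternal = _meiosis(haps, dam_rows, positions, chrom_lengths, rng)
    off_haps = np.stack([paternal, maternal], axis=1)

    ids = [f"{id_prefix}_{k:05d}" for k in range(n_off)]
    sex = np.where(rng.integers(0, 2, size=n_off) == 0, "M", "F")
    off = pd.DataFrame({"sex": sex, "sire": sire_ids, "dam": dam_ids}, index=ids)
    return off, off_haps


# ---------------------------------------------------------------------------
# The full program
# ---------------------------------------------------------------------------


def _gen_gblup_gebv(marker_dosages: np.ndarray, ids: list, y: np.ndarray,
                    h2: float, blend_alpha: float) -> pd.Series:
    """Within-generation mean-only GBLUP used as the selection criterion."""
    gm = GenotypeMatrix(marker_dosages, ids, [f"m{k}" for k in range(marker_dosages.shape[1])])
    grm = build_grm(gm, blend_alpha=blend_alpha)
    res = solve_gblup(pd.Series(y, index=ids), None, grm, h2, ids)
    return res.gebv


def run_generations(config: SimConfig, seed) -> Tuple[SimPopulation, RealizedParameters]:
    """Simulate generations 0..J of the breeding program.

    Generation 0 is the product of burn-in random mating; its u1/u2 variances
    define the QTN-effect scale (var = 1) and its u1 mean is the frozen
    centering constant of the composite trait.  Every later generation is bred
    from parents truncation-selected on a within-generation trait-1 GBLUP run
    with the assumed heritability ``config.h2_gblup`` (selection always uses
    these initial parameters, not re-estimated ones).
    """
    rng = np.random.default_rng(seed)
    genome, traits, scheme = config.genome, config.traits, config.scheme
    n_off = scheme.offspring_per_generation
    chrom_lengths = [genome.chromosome_length_cm / 100.0] * genome.n_chromosomes

    # Burn-in happens in a bottleneck population of config.burn_in_size:
    # random mating at the nucleus's effective size builds the small-Ne
    # linkage disequilibrium a livestock founder genome carries (the drift-
    # recombination structure behind Me ~ 4 Ne L).  The last round expands
    # the population to full generation size.
    n_burn = max(config.burn_in_size, 4)
    haps, positions, qtn_mask = simulate_founders(genome, n_burn, rng)
    sex = _balanced_sexes(n_burn, rng)
    for b in range(config.burn_in_generations + 1):
        expand = b == config.burn_in_generations
        n_next = n_off if expand else n_burn
        males = np.flatnonzero(sex == "M")
        females = np.flatnonzero(sex == "F")
        if males.size == 0 or females.size == 0:
            raise InvalidInputError("burn-in generation lost one sex entirely")
        sire_rows = males[rng.integers(0, males.size, size=n_next)]
        dam_rows = females[rng.integers(0, females.size, size=n_next)]
        haps = np.stack([_meiosis(haps, sire_rows, positions, chrom_lengths, rng),
                         _meiosis(haps, dam_rows, positions, chrom_lengths, rng)],
                        axis=1)
        sex = _balanced_sexes(n_next, rng)
    cur = pd.DataFrame({"sex": sex, "sire": "", "dam": ""},
                       index=[f"B_{k:05d}" for k in range(n_off)])

    effects = sample_qtn_effects(int(qtn_mask.sum()), traits.gamma_shape, rng)

    marker_idx = np.flatnonzero(~qtn_mask)
    qtn_idx = np.flatnonzero(qtn_mask)
    sve = np.asarray(traits.residual_variances, dtype=float)

    all_rows, all_markers, all_qtn = [], [], []
    u1_ref_mean = None
    alphas = {}

    for j in range(config.n_generations + 1):
        if j > 0:
            gebv = None
            if scheme.select:
                gebv = _gen_gblup_gebv(prev_markers, list(prev.index), prev_y1,
                                       config.h2_gblup, config.blend_alpha)
            cur, haps = select_and_mate(prev, prev_haps, gebv, scheme, positions,
                                        chrom_lengths, rng, id_prefix=f"G{j}")
        else:
            cur = cur.copy()
            cur.index = [f"G0_{k:05d}" for k in range(len(cur))]

        dose = (haps[:, 0, :] + haps[:, 1, :]).astype(np.int8)
        markers = dose[:, marker_idx]
        qtn = dose[:, qtn_idx]

        if j == 0:
            # scale QTN effects so generation-0 var(u) = 1 per trait, and
            # express breeding values as deviations from the generation-0 mean
            u_raw = qtn.astype(float) @ effects
            sds = u_raw.std(axis=0, ddof=1)
            if np.any(sds == 0.0):
                raise DegenerateInputError("a trait has zero genetic variance at generation 0")
            effects = effects / sds
            u_offset = (qtn.astype(float) @ effects).mean(axis=0)
        u = qtn.astype(float) @ effects - u_offset
        u1, u2 = u[:, 0], u[:, 1]
        if j == 0:
            u1_ref_mean = float(u1.mean())   # 0 by construction; kept explicit
        u3, alphas[j] = composite_trait(u1, u2, traits.beta, u1_ref_mean)

        e = rng.normal(0.0, np.sqrt(sve), size=(len(cur), 3))
        y1 = u1 + e[:, 0]
        gen = cur.copy()
        gen["generation"] = j
        gen["u1"], gen["u2"], gen["u3"] = u1, u2, u3
        gen["y1"], gen["y2"], gen["y3"] = y1, u2 + e[:, 1], u3 + e[:, 2]
        all_rows.append(gen)
        all_markers.append(markers)
        all_qtn.append(qtn)

        prev, prev_haps, prev_markers, prev_y1 = gen, haps, markers, y1

    individuals = pd.concat(all_rows)
    individuals.index.name = "id"
    individuals = individuals.reset_index()
    gm = GenotypeMatrix(np.vstack(all_markers), individuals["id"].to_list(),
                        [f"m{k}" for k in range(marker_idx.size)])
    pop = SimPopulation(individuals=individuals, genotypes=gm,
                        qtn_dosages=np.vstack(all_qtn), qtn_effects=effects,
                        beta=traits.beta, u1_ref_mean=u1_ref_mean,
                        alphas=alphas, config=config)
    return pop, realized_parameters(pop, traits.residual_variances)


def realized_parameters(pop: SimPopulation, residual_variances) -> RealizedParameters:
    """Per-generation heritabilities var(u)/(var(u)+sigma_e^2) and corr(u1, u3)
    computed from true breeding values."""
    sve = np.asarray(residual_variances, dtype=float)
    rows = []
    for j, grp in pop.individuals.groupby("generation"):
        if len(grp) < 2:
            raise DegenerateInputError(f"generation {j} has fewer than 2 individuals")
        rec = {"generation": j, "n": len(grp)}
        for t in (1, 2, 3):
            vu = float(grp[f"u{t}"].var(ddof=1))
            rec[f"var_u{t}"] = vu
            rec[f"h2_{t}"] = vu / (vu + sve[t - 1])
            rec[f"mean_u{t}"] = float(grp[f"u{t}"].mean())
        rec["corr_u1_u3"] = float(np.corrcoef(grp["u1"], grp["u3"])[0, 1])
        rows.append(rec)
    return RealizedParameters(table=pd.DataFrame(rows).sort_values("generation")
                              .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Beta calibration
# ---------------------------------------------------------------------------


def calibrate_beta(config: SimConfig, target_decline: float = -0.1, seed=0,
                   bracket: Tuple[float, float] = (0.01, 0.5),
                   max_evals: int = 6, tol: float = 0.01) -> Tuple[float, list]:
    """Choose beta so realized corr(u1, u3) declines by ``target_decline`` per
    generation, by bisection on pilot simulations (one replicate per beta).

    The mean decline is monotone (more negative) in beta over the bracket, so
    bisection on decline(beta) - target converges; ``tol`` is on the decline.
    Returns (beta, evaluation log).
    """
    if target_decline >= 0:
        raise InvalidInputError("target_decline must be negative")
    ss = np.random.SeedSequence(seed)
    log = []

    def decline(beta: float) -> float:
        cfg = replace(config, traits=replace(config.traits, beta=beta))
        # same child seed for every beta: common random numbers sharpen the search
        _, realized = run_generations(cfg, np.random.SeedSequence(seed).spawn(1)[0])
        d = realized.mean_decline_corr_u1_u3()
        log.append({"beta": beta, "mean_decline": d})
        return d

    lo, hi = bracket
    d_lo, d_hi = decline(lo), decline(hi)
    if not (d_lo > target_decline > d_hi):
        raise CalibrationError(
            f"target decline {target_decline} not bracketed: "
            f"decline({lo})={d_lo:.4f}, decline({hi})={d_hi:.4f}")
    beta = 0.5 * (lo + hi)
    for _ in range(max_evals - 2):
        d = decline(beta)
        if abs(d - target_decline) <= tol:
            break
        if d > target_decline:
            lo = beta
        else:
            hi = beta
        beta = 0.5 * (lo + hi)
    return beta, log
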