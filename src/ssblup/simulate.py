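"""Breeding-scheme simulator for the two-trait selection study.

One replicate emulates a closed livestock population:

* founder haplotypes from a neutral coalescent (msprime) with a
  bottleneck history ending at Ne = 280, 30 chromosomes of 1 Morgan;
* 900 pleiotropic QTL (30 per chromosome) with gamma(0.4, 1.0) effect
  magnitudes for two traits, signs and cross-trait dependence from a
  Gaussian copula calibrated so the founder genetic correlation is −0.3;
  effects are rescaled so founder heritabilities are 0.3 (production)
  and 0.1 (adaptation) on phenotypic variance 1;
* a base population of 2800 males and 2800 females mated randomly, then
  10 generations in which the best 200 males and 2800 females — ranked
  by an equally weighted index of within-cohort standardized own
  phenotypes — form the breeding population; each of the 2800 matings
  produces one offspring, sexes exactly balanced; meiosis draws a
  Poisson number of crossovers per Morgan without interference;
* evaluation data: phenotypes of all females except the last
  generation; genotypes for sires of phenotyped females and all animals
  of the last three generations; a 54,000-SNP panel, optionally
  augmented with the largest QTL until they explain 5% or 20% of
  genetic variance.

``scale`` multiplies every population count and panel size so that a
structurally identical study can run at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genomic import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "SimConfig",
    "FounderGenomes",
    "TraitArchitecture",
    "SimulatedStudy",
    "simulate_founders",
    "assign_loci_and_effects",
    "breed_generations",
    "extract_study_data",
    "run_study",
    "run_replicates",
]


@dataclass
class SimConfig:
    n_chr: int = 30
    chr_length_morgans: float = 1.0
    ne_recent: int = 280
    ne_ancient: int = 10_000
    ancient_time: float = 1_000.0
    base_males: int = 2800
    base_females: int = 2800
    sel_males: int = 200
    sel_females: int = 2800
    generations: int = 10
    qtl_per_chr: int = 30
    snp_panel: int = 54_000
    gamma_shape: float = 0.4
    gamma_scale: float = 1.0
    h2: tuple[float, float] = (0.3, 0.1)
    genetic_corr: float = -0.3
    residual_corr: float = 0.0
    qtl_variance_fractions: tuple[float, ...] = (0.05, 0.20)
    replicates: int = 10
    scale: float = 1.0
    seed: int = 1

    # -- scaled counts ---------------------------------------------------
    def _n(self, x: float) -> int:
        return max(1, int(round(x * self.scale)))

    @property
    def n_base_males(self) -> int:
        return self._n(self.base_males)

    @property
    def n_base_females(self) -> int:
        return self._n(self.base_females)

    @property
    def n_sel_males(self) -> int:
        return self._n(self.sel_males)

    @property
    def n_sel_females(self) -> int:
        return self._n(self.sel_females)

    @property
    def n_qtl_per_chr(self) -> int:
        return self._n(self.qtl_per_chr)

    @property
    def n_snp_per_chr(self) -> int:
        if (self.snp_panel % self.n_chr) != 0:
            raise ValueError("snp_panel must be divisible by n_chr")
        return self._n(self.snp_panel / self.n_chr)

    @property
    def n_traits(self) -> int:
        return len(self.h2)

    def g0_true(self) -> np.ndarray:
        sd = np.sqrt(np.asarray(self.h2))
        corr = np.array([[1.0, self.genetic_corr], [self.genetic_corr, 1.0]])
        return corr * np.outer(sd, sd)

    def r0_true(self) -> np.ndarray:
        rv = 1.0 - np.asarray(self.h2)
        sd = np.sqrt(rv)
        corr = np.array([[1.0, self.residual_corr], [self.residual_corr, 1.0]])
        return corr * np.outer(sd, sd)


@dataclass
class FounderGenomes:
    """Per-chromosome founder haplotypes at segregating sites."""

    haplotypes: list[np.ndarray]       # each (2N, L_c) int8
    positions_morgans: list[np.ndarray]
    n_founders: int


@dataclass
class TraitArchitecture:
    """Selected loci (QTL + panel SNPs), effects and founder truth."""

    founder_haps: np.ndarray           # (N, 2, L) int8, loci concatenated over chromosomes
    chr_index: np.ndarray              # (L,) chromosome of each locus
    positions: np.ndarray              # (L,) Morgans within chromosome
    is_qtl: np.ndarray                 # (L,) bool
    qtl_effects: np.ndarray            # (n_qtl, T) rescaled allele substitution effects
    base_freq: np.ndarray              # (L,) founder allele frequencies
    copula_rho: float


@dataclass
class SimulatedStudy:
    """One replicate's evaluation dataset plus the simulation truth."""

    ped: Pedigree
    genotypes: dict[str, GenotypeMatrix]      # panel name -> genotyped-animal counts
    base_freq: dict[str, np.ndarray]          # panel name -> true base frequencies
    panel_loci: dict[str, np.ndarray]         # panel name -> locus indices
    phenotypes: pd.DataFrame                  # animal + trait columns (females, not last gen)
    tbv: np.ndarray                           # (n_animals, T), pedigree order
    qtl_effects: np.ndarray
    validation: np.ndarray                    # pedigree positions of validation animals
    config: SimConfig
    qtl_genotypes: np.ndarray | None = None   # (n_animals, n_qtl) allele counts

    @property
    def trait_names(self) -> list[str]:
        return ["production", "adaptation"]


def simulate_founders(config: SimConfig) -> FounderGenomes:
    """Coalescent founder haplotypes on every chromosome.

    Piecewise-constant history: Ne = ``ne_recent`` up to ``ancient_time``
    generations ago, ``ne_ancient`` before that.  1 Morgan = 1e8 bp with
    uniform recombination and mutation at 1e-8 per bp.
    """
    n_founders = config.n_base_males + config.n_base_females
    demog = msprime.Demography()
    demog.add_population(initial_size=config.ne_recent)
    demog.add_population_parameters_change(
        time=config.ancient_time, initial_size=config.ne_ancient
    )
    # Down-scaled runs simulate a proportionally shorter founder map per
    # chromosome (SNP density per unit map is scale-invariant) and stretch
    # the positions onto the full meiosis map afterwards.
    length = config.chr_length_morgans * 1e8 * config.scale
    haps: list[np.ndarray] = []
    pos: list[np.ndarray] = []
    needed = config.n_qtl_per_chr + config.n_snp_per_chr
    for c in range(config.n_chr):
        seed_c = config.seed * 1000 + c + 1
        ts = msprime.sim_ancestry(
            samples=n_founders,
            demography=demog,
            sequence_length=length,
            recombination_rate=1e-8,
            random_seed=seed_c,
        )
        ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=seed_c, model="binary")
        gm = ts.genotype_matrix().astype(np.int8)  # (sites, 2N)
        p = np.array([s.position for s in ts.sites()])
        seg = (gm.sum(axis=1) > 0) & (gm.sum(axis=1) < gm.shape[1])
        gm, p = gm[seg], p[seg]
        if gm.shape[0] < needed:
            raise RuntimeError(
                f"chromosome {c}: only {gm.shape[0]} segregating sites, need {needed}"
            )
        haps.append(np.ascontiguousarray(gm.T))  # (2N, L_c)
        pos.append(p * 1e-8 / config.scale)      # Morgans, stretched to full map
    return FounderGenomes(haplotypes=haps, positions_morgans=pos, n_founders=n_founders)


def _copula_effects(z: np.ndarray, eps: np.ndarray, rho: float,
                    shape: float, scale: float) -> np.ndarray:
    """Signed gamma effect pairs from a Gaussian copula draw.

    Magnitudes come from the gamma quantile of |z| (folded-normal
    probability), the sign from z itself, so the cross-trait dependence
    is monotone in the copula correlation ``rho``.
    """
    z2 = rho * z + np.sqrt(max(1.0 - rho * rho, 0.0)) * eps
    out = np.empty((z.shape[0], 2))
    for t, zt in enumerate((z, z2)):
        u = 2.0 * stats.norm.cdf(np.abs(zt)) - 1.0
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        out[:, t] = np.sign(zt) * stats.gamma.ppf(u, shape, scale=scale)
    return out


def assign_loci_and_effects(
    founders: FounderGenomes, config: SimConfig, rng: np.random.Generator,
    corr_tol: float = 0.05,
) -> TraitArchitecture:
    """Choose QTL and panel loci; draw and calibrate QTL effects.

    QTL are sampled uniformly from segregating sites; the panel takes
    evenly spaced non-QTL sites.  The copula correlation is solved so
    the realized founder genetic correlation hits the configured target,
    then effects are rescaled so founder genetic variances equal the
    heritabilities (phenotypic variance 1).
    """
    sel_haps, sel_pos, sel_chr, sel_qtl = [], [], [], []
    for c in range(config.n_chr):
        hap = founders.haplotypes[c]
        pos = founders.positions_morgans[c]
        n_sites = hap.shape[1]
        qtl_idx = np.sort(rng.choice(n_sites, size=config.n_qtl_per_chr, replace=False))
        rest = np.setdiff1d(np.arange(n_sites), qtl_idx)
        take = np.linspace(0, rest.size - 1, config.n_snp_per_chr).round().astype(int)
        snp_idx = rest[np.unique(take)]
        if snp_idx.size < config.n_snp_per_chr:
            extra = np.setdiff1d(rest, snp_idx)[: config.n_snp_per_chr - snp_idx.size]
            snp_idx = np.sort(np.concatenate([snp_idx, extra]))
        keep = np.sort(np.concatenate([qtl_idx, snp_idx]))
        sel_haps.append(hap[:, keep])
        sel_pos.append(pos[keep])
        sel_chr.append(np.full(keep.size, c))
        sel_qtl.append(np.isin(keep, qtl_idx))

    hap_flat = np.concatenate(sel_haps, axis=1)       # (2N, L)
    n = founders.n_founders
    founder_haps = hap_flat.reshape(n, 2, -1)
    positions = np.concatenate(sel_pos)
    chr_index = np.concatenate(sel_chr)
    is_qtl = np.concatenate(sel_qtl)
    base_freq = founder_haps.sum(axis=1).mean(axis=0) / 2.0

    q_geno = founder_haps.sum(axis=1)[:, is_qtl].astype(float)
    n_qtl = int(is_qtl.sum())
    z = rng.standard_normal(n_qtl)
    eps = rng.standard_normal(n_qtl)

    def realized_corr(rho: float) -> float:
        eff = _copula_effects(z, eps, rho, config.gamma_shape, config.gamma_scale)
        tbv = q_geno @ eff
        return float(np.corrcoef(tbv.T)[0, 1])

    target = config.genetic_corr
    if abs(realized_corr(target) - target) <= corr_tol:
        rho = target  # a good starting guess at full scale
    else:
        try:
            rho = optimize.brentq(lambda r: realized_corr(r) - target, -0.999, 0.999, xtol=1e-3)
        except ValueError as exc:
            raise RuntimeError("copula calibration failed to bracket the target correlation") from exc
    effects = _copula_effects(z, eps, rho, config.gamma_shape, config.gamma_scale)
    tbv = q_geno @ effects
    sd = tbv.std(axis=0, ddof=0)
    effects *= np.sqrt(np.asarray(config.h2)) / sd
    return TraitArchitecture(
        founder_haps=founder_haps, chr_index=chr_index, positions=positions,
        is_qtl=is_qtl, qtl_effects=effects, base_freq=base_freq, copula_rho=float(rho),
    )


def _gamete(hap: np.ndarray, arch: TraitArchitecture, config: SimConfig,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a (2, L) parent genome."""
    out = np.empty(hap.shape[1], dtype=np.int8)
    for c in range(config.n_chr):
        sel = arch.chr_index == c
        pos = arch.positions[sel]
        n_cx = rng.poisson(config.chr_length_morgans)
        start = rng.integers(2)
        if n_cx == 0:
            out[sel] = hap[start, sel]
            continue
        breaks = np.sort(rng.uniform(0.0, config.chr_length_morgans, size=n_cx))
        seg = np.searchsorted(breaks, pos)
        choice = (start + seg) % 2
        out[sel] = hap[choice, sel]
    return out


def _chr_slices(arch: TraitArchitecture, config: SimConfig) -> list[np.ndarray]:
    return [np.flatnonzero(arch.chr_index == c) for c in range(config.n_chr)]


@dataclass
class _Population:
    """Full simulated population across all generations."""

    haps: np.ndarray          # (n, 2, L)
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    tbv: np.ndarray           # (n, T)
    phen: np.ndarray          # (n, T)


def _tbv_and_phen(haps: np.ndarray, arch: TraitArchitecture, config: SimConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    geno = haps.sum(axis=1)[:, arch.is_qtl].astype(float)
    tbv = geno @ arch.qtl_effects
    resid_sd = np.sqrt(1.0 - np.asarray(config.h2))
    phen = tbv + rng.standard_normal(tbv.shape) * resid_sd
    return tbv, phen


def _selection_index(phen: np.ndarray) -> np.ndarray:
    std = phen.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    return ((phen - phen.mean(axis=0)) / std).sum(axis=1)


def breed_generations(arch: TraitArchitecture, config: SimConfig,
                      rng: np.random.Generator) -> _Population:
    """Random base mating then index selection for ``generations`` rounds."""
    n0 = arch.founder_haps.shape[0]
    nm, nf = config.n_base_males, config.n_base_females
    sexes = [np.array(["M"] * nm + ["F"] * nf, dtype=object)]
    haps = [arch.founder_haps]
    sire = [np.full(n0, UNKNOWN, dtype=np.int64)]
    dam = [np.full(n0, UNKNOWN, dtype=np.int64)]
    gen = [np.zeros(n0, dtype=np.int64)]
    tbv0, phen0 = _tbv_and_phen(arch.founder_haps, arch, config, rng)
    tbv, phen = [tbv0], [phen0]

    all_haps = arch.founder_haps
    all_sex = sexes[0]
    all_phen = phen0
    # breeding pool starts as the whole base population (random mating)
    pool = np.arange(n0)
    next_id = n0
    n_matings = config.n_sel_females

    for g in range(1, config.generations + 1):
        pool_males = pool[all_sex[pool] == "M"]
        pool_females = pool[all_sex[pool] == "F"]
        if g == 1:
            sires_pool, dams_pool = pool_males, pool_females
            n_mat = min(dams_pool.size, config.n_base_females)
        else:
            sires_pool, dams_pool = pool_males, pool_females
            n_mat = n_matings
        dams_g = rng.permutation(dams_pool)[:n_mat]
        sires_g = rng.choice(sires_pool, size=n_mat, replace=True)

        child_haps = np.empty((n_mat, 2, all_haps.shape[2]), dtype=np.int8)
        for j in range(n_mat):
            child_haps[j, 0] = _gamete(all_haps[sires_g[j]], arch, config, rng)
            child_haps[j, 1] = _gamete(all_haps[dams_g[j]], arch, config, rng)
        child_sex = np.array(["M", "F"] * ((n_mat + 1) // 2), dtype=object)[:n_mat]
        tbv_g, phen_g = _tbv_and_phen(child_haps, arch, config, rng)

        haps.append(child_haps)
        sire.append(sires_g)
        dam.append(dams_g)
        sexes.append(child_sex)
        gen.append(np.full(n_mat, g, dtype=np.int64))
        tbv.append(tbv_g)
        phen.append(phen_g)

        child_ids = np.arange(next_id, next_id + n_mat)
        next_id += n_mat
        all_haps = np.concatenate([all_haps, child_haps], axis=0)
        all_sex = np.concatenate([all_sex, child_sex])
        all_phen = np.concatenate([all_phen, phen_g], axis=0)

        # next breeding population: best among current pool + new offspring
        cand = np.concatenate([pool, child_ids])
        index = _selection_index(all_phen[cand])
        males = cand[all_sex[cand] == "M"]
        females = cand[all_sex[cand] == "F"]
        idx_rank = {a: s for a, s in zip(cand, index)}
        males = males[np.argsort([-idx_rank[a] for a in males], kind="stable")]
        females = females[np.argsort([-idx_rank[a] for a in females], kind="stable")]
        pool = np.concatenate([males[: config.n_sel_males], females[: config.n_sel_females]])

    return _Population(
        haps=all_haps,
        sire=np.concatenate(sire),
        dam=np.concatenate(dam),
        sex=np.concatenate(sexes),
        generation=np.concatenate(gen),
        tbv=np.concatenate(tbv, axis=0),
        phen=np.concatenate(phen, axis=0),
    )


def extract_study_data(pop: _Population, arch: TraitArchitecture,
                       config: SimConfig) -> SimulatedStudy:
    """Carve the evaluation dataset out of one simulated population."""
    n = pop.haps.shape[0]
    last = config.generations
    is_female = pop.sex == "F"
    phenotyped = is_female & (pop.generation < last)

    # genotyped: sires of phenotyped females + all animals of last 3 generations
    genotyped = pop.generation >= last - 2
    sires_of_phen = np.unique(pop.sire[phenotyped & (pop.sire != UNKNOWN)])
    genotyped[sires_of_phen] = True

    labels = np.arange(1, n + 1)
    ped = Pedigree(
        labels=labels, sire=pop.sire, dam=pop.dam, sex=pop.sex,
        generation=pop.generation, genotyped=genotyped, phenotyped=phenotyped,
    )
    validation = np.flatnonzero(genotyped & (pop.generation == last))
    if validation.size == 0:
        raise RuntimeError("empty validation set")

    trait_names = ["production", "adaptation"]
    pidx = np.flatnonzero(phenotyped)
    phen_df = pd.DataFrame({"animal": labels[pidx]})
    for t, name in enumerate(trait_names):
        phen_df[name] = pop.phen[pidx, t]

    # marker panels
    snp_loci = np.flatnonzero(~arch.is_qtl)
    qtl_loci = np.flatnonzero(arch.is_qtl)
    p_q = arch.base_freq[qtl_loci]
    h2 = np.asarray(config.h2)
    frac = 2.0 * p_q * (1.0 - p_q) * (arch.qtl_effects ** 2 / h2).mean(axis=1)
    order = np.argsort(-frac)
    cum = np.cumsum(frac[order])

    panels: dict[str, np.ndarray] = {"qtl0": snp_loci}
    for f in config.qtl_variance_fractions:
        n_add = int(np.searchsorted(cum, f) + 1)
        n_add = min(n_add, qtl_loci.size)
        add = np.sort(qtl_loci[order[:n_add]])
        panels[f"qtl{int(round(f * 100))}"] = np.sort(np.concatenate([snp_loci, add]))

    gidx = np.flatnonzero(genotyped)
    counts_all = pop.haps[gidx].sum(axis=1)
    genotypes = {}
    base_freq = {}
    for name, loci in panels.items():
        genotypes[name] = GenotypeMatrix(ids=labels[gidx], counts=counts_all[:, loci])
        base_freq[name] = arch.base_freq[loci]

    return SimulatedStudy(
        ped=ped, genotypes=genotypes, base_freq=base_freq, panel_loci=panels,
        phenotypes=phen_df, tbv=pop.tbv, qtl_effects=arch.qtl_effects,
        validation=validation, config=config,
        qtl_genotypes=pop.haps.sum(axis=1)[:, qtl_loci],
    )


def run_study(config: SimConfig) -> SimulatedStudy:
    """Simulate one full replicate and extract its evaluation dataset."""
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config)
    arch = assign_loci_and_effects(founders, config, rng)
    pop = breed_generations(arch, config, rng)
    return extract_study_data(pop, arch, config)


def run_replicates(config: SimConfig, n: int | None = None) -> list[SimulatedStudy]:
    """Independent replicates r = 0..n−1 with seeds ``seed + r``."""
    n = config.replicates if n is None else n
    return [run_study(replace(config, seed=config.seed + r)) for r in range(n)]
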