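"""Three-phase population process: historical, expansion, recent selection.

The historical phase builds linkage disequilibrium and a mutation–drift
allele-frequency spectrum by random union of gametes over thousands of
discrete generations (constant size, then linear growth).  The expansion
phase multiplies the population with a fixed litter size and no selection.
The recent phase mimics a production nucleus: overlapping parent use across
seasons, one or two progeny per dam per year, pedigree-BLUP EBV selection
with sex-specific replacement rates, and age culling.  Only recent-phase
animals are recorded (pedigree, TBV, phenotype, EBV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import genome, quantgen
from .genome import GenomeMap

__all__ = [
    "MALE",
    "FEMALE",
    "SimConfig",
    "Population",
    "RecentResult",
    "init_founders",
    "random_mating_cohort",
    "run_historical",
    "run_expansion",
    "run_recent",
    "finalize_marker_panel",
]

MALE = 0
FEMALE = 1


@dataclass
class SimConfig:
    """All simulator parameters (see the methods note for defaults).

    Defaults reproduce the full-scale study design; the desk-scale profile
    in :mod:`caprigen.io` overrides sizes for minute-scale runs.
    """

    # historical phase
    hist_gens_phase1: int = 5000
    hist_size_phase1: int = 1000
    hist_gens_phase2: int = 500
    hist_final_males: int = 400
    hist_final_females: int = 2600
    # expansion phase
    exp_founder_males: int = 400
    exp_founder_females: int = 2600
    exp_gens: int = 10
    exp_offspring_per_dam: int = 5
    exp_pop_cap: int = 15000
    # recent phase
    rec_founder_males: int = 40
    rec_founder_females: int = 400
    rec_gens: int = 10
    litter_min: int = 1
    litter_max: int = 2
    male_prop: float = 0.5
    repl_sires: float = 0.8
    repl_dams: float = 0.3
    max_breeding_age: int = 5
    # genome / trait
    n_markers: int = 45000
    n_qtl: int = 100
    candidate_factor: float = 3.0
    mutation_rate: float = 9.4e-6
    interference: float = 5.0
    maf_min: float = 0.05
    h2: float = 0.11
    sigma2_p: float = 1.0
    direction: int = 1  # +1 select high (LBW), -1 select low (FD)

    def __post_init__(self) -> None:
        for name in ("male_prop", "repl_sires", "repl_dams", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "hist_size_phase1", "hist_final_males", "hist_final_females",
            "exp_founder_males", "exp_founder_females", "exp_pop_cap",
            "rec_founder_males", "rec_founder_females", "n_markers", "n_qtl",
            "litter_min", "litter_max", "max_breeding_age",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.litter_min > self.litter_max:
            raise ValueError("litter_min must not exceed litter_max")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")
        if self.interference <= 0:
            raise ValueError("interference must be > 0")
        if self.exp_pop_cap < self.exp_founder_males + self.exp_founder_females:
            raise ValueError("population cap below founder count")

    @property
    def hist_final_size(self) -> int:
        return self.hist_final_males + self.hist_final_females

    @property
    def chrom_lengths(self) -> np.ndarray:
        """29 autosomes totalling 2,922 cM (equal lengths by default)."""
        return np.full(29, 2922.0 / 29.0)


@dataclass
class Population:
    """A cohort (or multi-generation record) of diploid individuals."""

    ids: np.ndarray          # int64
    sire: np.ndarray         # int64, 0 = unknown
    dam: np.ndarray          # int64, 0 = unknown
    sex: np.ndarray          # int8, MALE/FEMALE
    generation: np.ndarray   # int32
    haplotypes: np.ndarray   # uint8 (n, 2, L)

    @property
    def size(self) -> int:
        return self.ids.size

    def genotypes(self, locus_idx=None) -> np.ndarray:
        g = self.haplotypes.sum(axis=1, dtype=np.int64)
        return g if locus_idx is None else g[:, locus_idx]

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def subset(self, idx: np.ndarray) -> "Population":
        idx = np.asarray(idx, dtype=np.int64)
        return Population(
            ids=self.ids[idx], sire=self.sire[idx], dam=self.dam[idx],
            sex=self.sex[idx], generation=self.generation[idx],
            haplotypes=self.haplotypes[idx],
        )

    def pedigree_frame(self, alive: np.ndarray | None = None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": self.sire,
                "dam": self.dam,
                "sex": np.where(self.sex == MALE, "M", "F"),
                "generation": self.generation,
                "alive": (np.ones(self.size, dtype=bool) if alive is None else alive),
            }
        )


def _sex_vector(n: int, n_males: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly ``n_males`` males among n, in random order."""
    sex = np.full(n, FEMALE, dtype=np.int8)
    sex[:n_males] = MALE
    rng.shuffle(sex)
    return sex


def init_founders(gmap: GenomeMap, n_males: int, n_females: int,
                  rng: np.random.Generator) -> Population:
    """Unrelated founders with allele frequency 1/2 at every locus."""
    n = n_males + n_females
    haps = rng.integers(0, 2, size=(n, 2, gmap.n_loci), dtype=np.uint8)
    return Population(
        ids=np.arange(1, n + 1, dtype=np.int64),
        sire=np.zeros(n, dtype=np.int64),
        dam=np.zeros(n, dtype=np.int64),
        sex=_sex_vector(n, n_males, rng),
        generation=np.zeros(n, dtype=np.int32),
        haplotypes=haps,
    )


def _random_union(
    pop: Population,
    n_offspring: int,
    n_males_next: int,
    config: SimConfig,
    gmap: GenomeMap,
    rng: np.random.Generator,
    generation: int,
) -> Population:
    """One generation of random union of gametes (no selection)."""
    males, females = pop.males(), pop.females()
    if males.size == 0 or females.size == 0:
        raise ValueError("population lost one sex; cannot continue mating")
    sires = males[rng.integers(0, males.size, size=n_offspring)]
    dams = females[rng.integers(0, females.size, size=n_offspring)]
    h0 = genome.sample_gametes(pop.haplotypes, sires, gmap, config.interference, rng)
    h1 = genome.sample_gametes(pop.haplotypes, dams, gmap, config.interference, rng)
    haps = np.stack([h0, h1], axis=1)
    genome.apply_mutation(haps, config.mutation_rate, rng)
    return Population(
        ids=np.arange(1, n_offspring + 1, dtype=np.int64),
        sire=pop.ids[sires],
        dam=pop.ids[dams],
        sex=_sex_vector(n_offspring, n_males_next, rng),
        generation=np.full(n_offspring, generation, dtype=np.int32),
        haplotypes=haps,
    )


def random_mating_cohort(
    pop: Population,
    n_offspring: int,
    config: SimConfig,
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> Population:
    """One unselected cohort bred by random union of gametes from ``pop``."""
    return _random_union(pop, n_offspring, n_offspring // 2, config, gmap, rng,
                         generation=int(pop.generation.max()) + 1)


def run_historical(config: SimConfig, gmap: GenomeMap,
                   rng: np.random.Generator) -> Population:
    """Historical phase: constant size, then linear growth to the final size.

    Discrete non-overlapping generations, random union of gametes, no
    selection.  Intermediate generations keep an even sex split; the final
    generation carries the configured terminal split.
    """
    n1 = config.hist_size_phase1
    pop = init_founders(gmap, n1 // 2, n1 - n1 // 2, rng)
    gen = 0
    for _ in range(config.hist_gens_phase1):
        gen += 1
        pop = _random_union(pop, n1, n1 // 2, config, gmap, rng, gen)
    if config.hist_gens_phase2 > 0:
        sizes = np.linspace(n1, config.hist_final_size,
                            config.hist_gens_phase2 + 1)[1:]
        sizes = np.rint(sizes).astype(int)
        for t, n in enumerate(sizes):
            gen += 1
            last = t == sizes.size - 1
            n_m = config.hist_final_males if last else n // 2
            pop = _random_union(pop, int(n), int(n_m), config, gmap, rng, gen)
    return pop


def run_expansion(founders: Population, config: SimConfig, gmap: GenomeMap,
                  rng: np.random.Generator) -> Population:
    """Expansion: every dam leaves a fixed litter, random sires, no selection.

    The configured numbers of founder males and females are sampled at
    random from the input population.  If a generation would exceed
    ``exp_pop_cap`` the offspring are culled at random to the cap,
    preserving the realised sex ratio.
    """
    males, females = founders.males(), founders.females()
    if males.size < config.exp_founder_males or females.size < config.exp_founder_females:
        raise ValueError("historical population too small for expansion founders")
    pop = founders.subset(np.concatenate([
        rng.choice(males, size=config.exp_founder_males, replace=False),
        rng.choice(females, size=config.exp_founder_females, replace=False),
    ]))
    for g in range(1, config.exp_gens + 1):
        males, females = pop.males(), pop.females()
        if males.size == 0 or females.size == 0:
            raise ValueError("population lost one sex during expansion")
        k = config.exp_offspring_per_dam
        dams = np.repeat(females, k)
        sires = males[rng.integers(0, males.size, size=dams.size)]
        n = dams.size
        h0 = genome.sample_gametes(pop.haplotypes, sires, gmap, config.interference, rng)
        h1 = genome.sample_gametes(pop.haplotypes, dams, gmap, config.interference, rng)
        haps = np.stack([h0, h1], axis=1)
        genome.apply_mutation(haps, config.mutation_rate, rng)
        sex = (rng.random(n) >= config.male_prop).astype(np.int8)  # 0 = male
        keep = np.arange(n)
        if n > config.exp_pop_cap:
            n_m = int(np.rint(config.exp_pop_cap * (sex == MALE).sum() / n))
            m_idx = np.flatnonzero(sex == MALE)
            f_idx = np.flatnonzero(sex == FEMALE)
            keep = np.concatenate([
                rng.choice(m_idx, size=min(n_m, m_idx.size), replace=False),
                rng.choice(f_idx, size=min(config.exp_pop_cap - n_m, f_idx.size),
                           replace=False),
            ])
        pop = Population(
            ids=np.arange(1, keep.size + 1, dtype=np.int64),
            sire=pop.ids[sires[keep]],
            dam=pop.ids[dams[keep]],
            sex=sex[keep],
            generation=np.full(keep.size, g, dtype=np.int32),
            haplotypes=haps[keep],
        )
    return pop


@dataclass
class RecentResult:
    """Recorded recent-phase animals with trait records and pedigree."""

    population: Population          # all recorded animals, founders first
    records: pd.DataFrame           # id, generation, sex, phenotype, tbv, ebv
    pedigree: pd.DataFrame          # id, sire, dam, sex, generation, alive
    trait: quantgen.TraitModel
    gmap: GenomeMap


def _select_parents(
    current: np.ndarray,
    ages: np.ndarray,
    young: np.ndarray,
    ebv: np.ndarray,
    n_slots: int,
    repl: float,
    max_age: int,
    direction: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace ``floor(repl * n_slots)`` parents with top-ranked young animals.

    ``current``/``young`` are row indices into the recorded population;
    ranking is by EBV in the selection direction.  Age-culled parents are
    removed first; any shortfall is filled with additional young animals.
    Returns (new parent rows, their ages).
    """
    score = ebv * direction
    ok = ages <= max_age
    current, ages = current[ok], ages[ok]
    n_replace = int(np.floor(repl * n_slots))
    n_keep = min(n_slots - n_replace, current.size)
    if n_keep > 0:
        order = np.argsort(-score[current], kind="stable")[:n_keep]
        kept, kept_ages = current[order], ages[order]
    else:
        kept = np.empty(0, dtype=np.int64)
        kept_ages = np.empty(0, dtype=np.int64)
    n_young = n_slots - kept.size
    if young.size < n_young:
        raise ValueError("insufficient candidates to fill replacement slots")
    order = np.argsort(-score[young], kind="stable")[:n_young]
    new = np.concatenate([kept, young[order]])
    new_ages = np.concatenate([kept_ages, np.ones(n_young, dtype=np.int64)])
    return new, new_ages


def run_recent(
    expanded: Population,
    config: SimConfig,
    gmap: GenomeMap,
    raw_effects: np.ndarray,
    rng: np.random.Generator,
) -> RecentResult:
    """Recent phase: EBV selection, replacement, age culling, 1–2 progeny/dam.

    Founders are sampled from the expanded population and form the pedigree
    base (unknown parents).  QTL effects are rescaled on the founder cohort
    so base Var(TBV) = h²·sigma2_p.  Each season all new progeny are
    phenotyped, a pedigree-BLUP evaluation is run on every record to date,
    and parents are replaced by top-EBV young animals at the configured
    sex-specific rates.
    """
    males, females = expanded.males(), expanded.females()
    if males.size < config.rec_founder_males or females.size < config.rec_founder_females:
        raise ValueError("expanded population too small for recent founders")
    pick = np.concatenate([
        rng.choice(males, size=config.rec_founder_males, replace=False),
        rng.choice(females, size=config.rec_founder_females, replace=False),
    ])
    base = expanded.subset(pick)
    n0 = base.size

    trait = quantgen.scale_to_heritability(
        raw_effects, base.genotypes(gmap.qtl_index),
        config.h2, config.sigma2_p, config.direction,
    )

    # growing arrays of recorded animals; founders get fresh ids 1..n0
    ids = [np.arange(1, n0 + 1, dtype=np.int64)]
    sire = [np.zeros(n0, dtype=np.int64)]
    dam = [np.zeros(n0, dtype=np.int64)]
    sex = [base.sex.copy()]
    generation = [np.zeros(n0, dtype=np.int32)]
    haps = [base.haplotypes]
    tbv = [quantgen.compute_tbv(base.genotypes(gmap.qtl_index), trait)]
    phen = [quantgen.simulate_phenotype(tbv[0], trait, rng)]

    all_sex = base.sex.copy()
    sires_now = np.flatnonzero(all_sex == MALE)
    dams_now = np.flatnonzero(all_sex == FEMALE)
    sire_ages = np.ones(sires_now.size, dtype=np.int64)
    dam_ages = np.ones(dams_now.size, dtype=np.int64)
    next_id = n0 + 1
    total = n0

    def stacked_haps() -> np.ndarray:
        return haps[0] if len(haps) == 1 else np.concatenate(haps, axis=0)

    ebv = np.zeros(total)
    for g in range(1, config.rec_gens + 1):
        litters = rng.integers(config.litter_min, config.litter_max + 1,
                               size=dams_now.size)
        dam_rows = np.repeat(dams_now, litters)
        sire_of_dam = sires_now[rng.integers(0, sires_now.size, size=dams_now.size)]
        sire_rows = np.repeat(sire_of_dam, litters)
        n_new = dam_rows.size
        block = stacked_haps()
        h0 = genome.sample_gametes(block, sire_rows, gmap, config.interference, rng)
        h1 = genome.sample_gametes(block, dam_rows, gmap, config.interference, rng)
        new_haps = np.stack([h0, h1], axis=1)
        genome.apply_mutation(new_haps, config.mutation_rate, rng)
        new_sex = (rng.random(n_new) >= config.male_prop).astype(np.int8)
        new_tbv = quantgen.compute_tbv(new_haps.sum(axis=1)[:, gmap.qtl_index], trait)
        all_ids = np.concatenate(ids)
        ids.append(np.arange(next_id, next_id + n_new, dtype=np.int64))
        sire.append(all_ids[sire_rows])
        dam.append(all_ids[dam_rows])
        sex.append(new_sex)
        generation.append(np.full(n_new, g, dtype=np.int32))
        haps.append(new_haps)
        tbv.append(new_tbv)
        phen.append(quantgen.simulate_phenotype(new_tbv, trait, rng))
        young_start = total
        total += n_new
        next_id += n_new
        all_sex = np.concatenate([all_sex, new_sex])

        ped = pd.DataFrame({
            "id": np.concatenate(ids),
            "sire": np.concatenate(sire),
            "dam": np.concatenate(dam),
        })
        ebv, _ = quantgen.pedigree_blup(np.concatenate(phen), ped, config.h2)

        young = np.arange(young_start, total)
        young_m = young[new_sex == MALE]
        young_f = young[new_sex == FEMALE]
        sires_now, sire_ages = _select_parents(
            sires_now, sire_ages + 1, young_m, ebv, config.rec_founder_males,
            config.repl_sires, config.max_breeding_age, trait.direction)
        dams_now, dam_ages = _select_parents(
            dams_now, dam_ages + 1, young_f, ebv, config.rec_founder_females,
            config.repl_dams, config.max_breeding_age, trait.direction)

    recorded = Population(
        ids=np.concatenate(ids),
        sire=np.concatenate(sire),
        dam=np.concatenate(dam),
        sex=np.concatenate(sex),
        generation=np.concatenate(generation),
        haplotypes=stacked_haps(),
    )
    alive = np.zeros(total, dtype=bool)
    alive[sires_now] = True
    alive[dams_now] = True
    records = pd.DataFrame({
        "id": recorded.ids,
        "generation": recorded.generation,
        "sex": np.where(recorded.sex == MALE, "M", "F"),
        "phenotype": np.concatenate(phen),
        "tbv": np.concatenate(tbv),
        "ebv": ebv,
    })
    return RecentResult(
        population=recorded,
        records=records,
        pedigree=recorded.pedigree_frame(alive),
        trait=trait,
        gmap=gmap,
    )


def finalize_marker_panel(
    pop: Population,
    gmap: GenomeMap,
    n_markers: int,
    n_qtl: int,
    maf_min: float,
    rng: np.random.Generator,
) -> tuple[GenomeMap, Population]:
    """Keep exactly the requested number of segregating markers and QTLs.

    Markers must segregate with minor allele frequency >= ``maf_min`` in the
    supplied population (typically the last historical generation); QTLs
    must segregate.  Qualifying loci beyond the target counts are dropped by
    random subsampling, and all haplotypes are re-indexed consistently.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    p = pop.haplotypes.mean(axis=(0, 1))
    maf = np.minimum(p, 1.0 - p)
    if np.all(maf == 0):
        raise ValueError("all loci are monomorphic")
    ok_marker = np.flatnonzero((~gmap.is_qtl) & (maf >= max(maf_min, np.nextafter(0, 1))))
    ok_qtl = np.flatnonzero(gmap.is_qtl & (maf > 0))
    if ok_marker.size < n_markers:
        raise ValueError(
            f"only {ok_marker.size} markers qualify (requested {n_markers})")
    if ok_qtl.size < n_qtl:
        raise ValueError(f"only {ok_qtl.size} QTLs qualify (requested {n_qtl})")
    keep = np.sort(np.concatenate([
        rng.choice(ok_marker, size=n_markers, replace=False),
        rng.choice(ok_qtl, size=n_qtl, replace=False),
    ]))
    new_map = gmap.subset(keep)
    new_pop = replace(pop, haplotypes=np.ascontiguousarray(pop.haplotypes[:, :, keep]))
    return new_map, new_pop
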