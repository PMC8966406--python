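"""File I/O, run configuration, and the end-to-end pipeline.

Canonical on-disk formats are plain text: PLINK PED/MAP for genotypes
(alleles coded 1/2, 1 = the 0-allele; MAP bp = round(cM x 1e6)), CSV for
pedigree and trait records, aligned text for the ANOVA/Duncan reports.  A
minimal phased VCF export is provided for interoperability.

Every pipeline artifact is stamped with the configuration hash and the
master seed; re-running with the same configuration reproduces all
stochastic outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, genome, population, quantgen
from .evaluation import ExperimentDesign
from .genome import GenomeMap
from .population import Population, RecentResult, SimConfig

__all__ = [
    "RunConfig",
    "desk_scale",
    "paper_scale",
    "write_map",
    "write_genotypes",
    "read_genotypes",
    "write_vcf",
    "write_pedigree",
    "write_records",
    "simulate_population",
    "simulate_unselected_cohort",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# configuration and profiles
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Simulation + experiment configuration with a master seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    chain: dict = field(default_factory=lambda: {
        "n_iter": 20000, "burn_in": 5000, "thin": 10})
    seed: int = 1
    realized: str = "tbv"

    def to_dict(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "design": dataclasses.asdict(self.design),
            "chain": dict(self.chain),
            "seed": self.seed,
            "realized": self.realized,
        }

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = SimConfig(**raw.get("sim", {}))
        draw = raw.get("design", {})
        for key in ("marker_densities", "qtl_numbers", "ref_sizes", "methods"):
            if key in draw:
                draw[key] = tuple(draw[key])
        if "sex_compositions" in draw:
            draw["sex_compositions"] = tuple(tuple(x) for x in draw["sex_compositions"])
        design = ExperimentDesign(**draw)
        return cls(sim=sim, design=design, chain=raw.get("chain", {}),
                   seed=raw.get("seed", 1), realized=raw.get("realized", "tbv"))


def paper_scale(trait: str = "FD") -> RunConfig:
    """Full-scale profile: the complete study design (hours of runtime)."""
    if trait == "FD":
        sim = SimConfig(h2=0.34, direction=-1, n_markers=60000, n_qtl=150)
        design = ExperimentDesign.baseline_fd()
    elif trait == "LBW":
        sim = SimConfig(h2=0.11, direction=1, n_markers=45000, n_qtl=100)
        design = ExperimentDesign.baseline_lbw()
    else:
        raise ValueError("trait must be 'FD' or 'LBW'")
    return RunConfig(sim=sim, design=design)


def desk_scale(trait: str = "FD") -> RunConfig:
    """Minute-scale profile: shrunken history and panels, same machinery."""
    h2, direction = (0.34, -1) if trait == "FD" else (0.11, 1)
    sim = SimConfig(
        hist_gens_phase1=300, hist_size_phase1=200,
        hist_gens_phase2=50, hist_final_males=100, hist_final_females=500,
        exp_founder_males=100, exp_founder_females=500,
        exp_gens=3, exp_offspring_per_dam=3, exp_pop_cap=3000,
        rec_founder_males=40, rec_founder_females=400,
        n_markers=3000, n_qtl=50, candidate_factor=2.0,
        h2=h2, direction=direction,
    )
    design = ExperimentDesign(
        marker_densities=(3000,), qtl_numbers=(50,),
        ref_sizes=(300, 500), replicates=2, val_size=500,
        baseline={"marker_density": 3000, "n_qtl": 50, "ref_size": 500},
    )
    return RunConfig(sim=sim, design=design,
                     chain={"n_iter": 1500, "burn_in": 500, "thin": 5})


# ---------------------------------------------------------------------------
# PLINK PED/MAP and friends
# ---------------------------------------------------------------------------

def write_map(gmap: GenomeMap, path, include_qtl: bool = False) -> None:
    """PLINK MAP dialect: chrom, locus id, genetic position (cM), bp."""
    ids = gmap.locus_ids()
    keep = np.arange(gmap.n_loci) if include_qtl else gmap.marker_index
    with open(path, "w") as fh:
        for i in keep:
            bp = int(round(gmap.pos_cM[i] * 1e6))
            fh.write(f"{gmap.chrom[i] + 1}\t{ids[i]}\t{gmap.pos_cM[i]:.6f}\t{bp}\n")


def write_genotypes(pop: Population, gmap: GenomeMap, prefix,
                    include_qtl: bool = False,
                    phenotypes: np.ndarray | None = None) -> None:
    """Write <prefix>.ped and <prefix>.map (alleles 1/2; 1 = the 0-allele)."""
    prefix = Path(prefix)
    write_map(gmap, prefix.with_suffix(".map"), include_qtl=include_qtl)
    keep = np.arange(gmap.n_loci) if include_qtl else gmap.marker_index
    haps = pop.haplotypes[:, :, keep].astype(np.int64) + 1
    sex_code = np.where(pop.sex == population.MALE, 1, 2)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(pop.size):
            phe = -9 if phenotypes is None else phenotypes[i]
            fields = [str(pop.ids[i]), str(pop.ids[i]), str(pop.sire[i]),
                      str(pop.dam[i]), str(sex_code[i]), str(phe)]
            pair = np.empty(2 * keep.size, dtype=np.int64)
            pair[0::2] = haps[i, 0]
            pair[1::2] = haps[i, 1]
            fields.extend(map(str, pair))
            fh.write(" ".join(fields) + "\n")


def read_genotypes(prefix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read PED/MAP back into (allele-count matrix, map frame).

    The count matrix counts copies of the 1-allele (PED code 2), matching
    the simulator's internal genotype coding.
    """
    prefix = Path(prefix)
    map_df = pd.read_csv(prefix.with_suffix(".map"), sep="\t", header=None,
                         names=["chrom", "locus", "cM", "bp"])
    m = len(map_df)
    ids, rows, meta = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError("PED line has wrong number of fields")
            ids.append(int(parts[1]))
            meta.append((int(parts[2]), int(parts[3]), int(parts[4])))
            alleles = np.array(parts[6:], dtype=np.int64)
            rows.append((alleles.reshape(-1, 2) - 1).sum(axis=1))
    counts = pd.DataFrame(np.array(rows, dtype=np.int64),
                          index=pd.Index(ids, name="id"),
                          columns=map_df["locus"])
    return counts, map_df


def write_vcf(pop: Population, gmap: GenomeMap, path,
              include_qtl: bool = False) -> None:
    """Minimal phased VCF (GT only); PED/MAP remains canonical."""
    keep = np.arange(gmap.n_loci) if include_qtl else gmap.marker_index
    ids = gmap.locus_ids()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=caprigen\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(str(i) for i in pop.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in keep:
            pos = int(round(gmap.pos_cM[j] * 1e6))
            gts = "\t".join(f"{pop.haplotypes[i, 0, j]}|{pop.haplotypes[i, 1, j]}"
                            for i in range(pop.size))
            fh.write(f"{gmap.chrom[j] + 1}\t{pos}\t{ids[j]}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n")


def write_pedigree(pedigree: pd.DataFrame, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pedigree.to_csv(fh, index=False)


def write_records(records: pd.DataFrame, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        records.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def simulate_population(sim: SimConfig, seed) -> RecentResult:
    """One full simulation: map -> historical -> panel -> expansion -> recent.

    ``seed`` may be an int or a ``SeedSequence``.  The candidate map is
    oversampled by ``candidate_factor`` so the exact marker/QTL targets
    survive the post-historical MAF filter.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_cand_m = int(np.ceil(sim.n_markers * sim.candidate_factor))
    n_cand_q = max(int(np.ceil(sim.n_qtl * sim.candidate_factor)), sim.n_qtl + 10)
    gmap = genome.build_genome_map(sim.chrom_lengths, n_cand_m, n_cand_q, rng)
    hist = population.run_historical(sim, gmap, rng)
    gmap, hist = population.finalize_marker_panel(
        hist, gmap, sim.n_markers, sim.n_qtl, sim.maf_min, rng)
    expanded = population.run_expansion(hist, sim, gmap, rng)
    raw = quantgen.sample_qtl_effects(sim.n_qtl, rng)
    return population.run_recent(expanded, sim, gmap, raw, rng)


def simulate_unselected_cohort(sim: SimConfig, n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """TBV and phenotypes of ``n`` unselected individuals.

    Runs the historical phase and marker-panel finalisation, breeds one
    random-mating cohort of size ``n``, rescales the gamma QTL effects on
    that cohort (the heritability-scaling operation), and phenotypes it.
    Used to measure the realised narrow-sense heritability
    Var(TBV)/Var(phenotype) of a trait configuration.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_cand_m = int(np.ceil(sim.n_markers * sim.candidate_factor))
    n_cand_q = max(int(np.ceil(sim.n_qtl * sim.candidate_factor)), sim.n_qtl + 10)
    gmap = genome.build_genome_map(sim.chrom_lengths, n_cand_m, n_cand_q, rng)
    hist = population.run_historical(sim, gmap, rng)
    gmap, hist = population.finalize_marker_panel(
        hist, gmap, sim.n_markers, sim.n_qtl, sim.maf_min, rng)
    cohort = population.random_mating_cohort(hist, n, sim, gmap, rng)
    raw = quantgen.sample_qtl_effects(sim.n_qtl, rng)
    trait = quantgen.scale_to_heritability(
        raw, cohort.genotypes(gmap.qtl_index), sim.h2, sim.sigma2_p, sim.direction)
    tbv = quantgen.compute_tbv(cohort.genotypes(gmap.qtl_index), trait)
    phen = quantgen.simulate_phenotype(tbv, trait, rng)
    return tbv, phen


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run the whole study for one configuration and write all artifacts.

    Writes genotypes (PED/MAP) and pedigree/trait records of the baseline
    replicate, the accuracy record CSV, and ANOVA + Duncan reports for
    every factor with at least two levels.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"config={config.config_hash()} seed={config.seed}"
    master = np.random.SeedSequence(config.seed)
    sim_cache: dict[tuple, RecentResult] = {}

    def scenario_fn(cell: dict, replicate: int, rng: np.random.Generator):
        key = (cell["marker_density"], cell["n_qtl"], replicate)
        if key not in sim_cache:
            sim = replace(config.sim, n_markers=cell["marker_density"],
                          n_qtl=cell["n_qtl"])
            sim_cache[key] = simulate_population(sim, master.spawn(1)[0])
        recent = sim_cache[key]
        comp = cell.get("sex_composition")
        return evaluation.make_scenario(
            recent, cell["ref_size"], config.design.val_size, rng,
            sex_composition=comp)

    # baseline artifacts from one dedicated replicate
    base_seed = master.spawn(1)[0]
    base = simulate_population(
        replace(config.sim,
                n_markers=config.design.baseline["marker_density"],
                n_qtl=config.design.baseline["n_qtl"]),
        base_seed)
    write_genotypes(base.population, base.gmap, outdir / "genotypes",
                    phenotypes=base.records["phenotype"].to_numpy())
    write_pedigree(base.pedigree, outdir / "pedigree.csv", header=stamp)
    write_records(base.records, outdir / "records.csv", header=stamp)

    acc = evaluation.run_factorial(
        config.design, scenario_fn,
        seed=int(master.spawn(1)[0].generate_state(1)[0] % (2**31 - 1)),
        realized=config.realized, chain_kwargs=dict(config.chain))
    write_records(acc, outdir / "accuracy.csv", header=stamp)

    factors = [f for f in ("marker_density", "n_qtl", "ref_size", "method")
               if acc[f].nunique() > 1]
    reports = [stamp]
    if len(factors) >= 1 and acc["r"].size > len(factors) + 1:
        try:
            tab = evaluation.anova_glm(acc, factors)
            reports.append(evaluation.format_anova(tab, "ANOVA of GEBV accuracy"))
            err = tab.loc[tab["Source"] == "Error"].iloc[0]
            for f in factors:
                means = acc.groupby(f)["r"].mean()
                counts = acc.groupby(f)["r"].count()
                dt = evaluation.duncan_mrt(means, counts, err["MS"], int(err["DF"]))
                reports.append(evaluation.format_duncan(dt, f"Duncan groups: {f}"))
        except ValueError:
            reports.append("ANOVA skipped: design too small")
    (outdir / "report.txt").write_text("\n\n".join(reports) + "\n")
    (outdir / "run.json").write_text(json.dumps(
        {"config_hash": config.config_hash(), "seed": config.seed}, indent=2))
    config.to_yaml(outdir / "config.yaml")
    return outdir
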