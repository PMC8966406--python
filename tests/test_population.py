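"""Population process tests: historical, expansion, recent selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from caprigen import genome, population as pop, quantgen
from .conftest import micro_sim_config


@pytest.fixture
def small_map(rng):
    return genome.build_genome_map([60.0, 40.0], 150, 15, rng)


def small_config(**kw):
    base = dict(
        hist_gens_phase1=5, hist_size_phase1=40, hist_gens_phase2=5,
        hist_final_males=30, hist_final_females=50,
        exp_founder_males=10, exp_founder_females=30,
        exp_gens=2, exp_offspring_per_dam=4, exp_pop_cap=200,
        rec_founder_males=8, rec_founder_females=40, rec_gens=3,
        n_markers=150, n_qtl=15, h2=0.34, direction=-1,
    )
    base.update(kw)
    return pop.SimConfig(**base)


class TestHistorical:
    def test_zero_generations_returns_founders(self, small_map, rng):
        cfg = small_config(hist_gens_phase1=0, hist_gens_phase2=0)
        p = pop.run_historical(cfg, small_map, rng)
        assert p.size == cfg.hist_size_phase1
        assert np.all(p.generation == 0)
        assert np.all(p.sire == 0) and np.all(p.dam == 0)

    def test_terminal_size_and_sex_split(self, small_map, rng):
        cfg = small_config()
        p = pop.run_historical(cfg, small_map, rng)
        assert p.size == cfg.hist_final_size == 80
        assert p.males().size == cfg.hist_final_males
        assert p.females().size == cfg.hist_final_females

    def test_founder_allele_frequency_half(self, small_map, rng):
        p = pop.init_founders(small_map, 200, 200, rng)
        freq = p.haplotypes.mean(axis=(0, 1))
        assert abs(freq.mean() - 0.5) < 0.01


class TestExpansion:
    def test_offspring_arithmetic_below_cap(self, small_map, rng):
        cfg = small_config(exp_gens=1, exp_founder_females=30,
                           exp_offspring_per_dam=4, exp_pop_cap=10000)
        founders = pop.init_founders(small_map, 10, 30, rng)
        out = pop.run_expansion(founders, cfg, small_map, rng)
        assert out.size == 30 * 4

    def test_zero_generations_returns_founders(self, small_map, rng):
        cfg = small_config(exp_gens=0)
        founders = pop.init_founders(small_map, 10, 30, rng)
        out = pop.run_expansion(founders, cfg, small_map, rng)
        assert out.size == cfg.exp_founder_males + cfg.exp_founder_females

    def test_sex_ratio_binomial(self, small_map, rng):
        cfg = small_config(exp_gens=1, exp_founder_females=300,
                           exp_founder_males=20, exp_offspring_per_dam=5,
                           exp_pop_cap=10000)
        founders = pop.init_founders(small_map, 20, 300, rng)
        out = pop.run_expansion(founders, cfg, small_map, rng)
        n_m = out.males().size
        p = stats.binomtest(n_m, out.size, 0.5).pvalue
        assert p > 1e-3

    def test_cap_enforced_preserving_sex_ratio(self, small_map, rng):
        cfg = small_config(exp_gens=1, exp_founder_males=10,
                           exp_founder_females=100, exp_offspring_per_dam=5,
                           exp_pop_cap=200)
        founders = pop.init_founders(small_map, 10, 100, rng)
        out = pop.run_expansion(founders, cfg, small_map, rng)
        assert out.size == 200
        assert 0.35 < out.males().size / out.size < 0.65

    def test_cap_below_founders_rejected(self):
        with pytest.raises(ValueError):
            small_config(exp_founder_males=100, exp_founder_females=200,
                         exp_pop_cap=150)


class TestRecentSelection:
    def test_replacement_count(self):
        """40 sire slots at replacement 0.8 -> 32 young sires enter."""
        ebv = np.concatenate([np.linspace(0, 1, 40), np.linspace(2, 3, 50)])
        current = np.arange(40)
        young = np.arange(40, 90)
        new, ages = pop._select_parents(
            current, np.ones(40, dtype=np.int64) + 1, young, ebv,
            n_slots=40, repl=0.8, max_age=5, direction=1)
        assert new.size == 40
        assert np.intersect1d(new, young).size == 32
        kept = np.intersect1d(new, current)
        assert kept.size == 8
        # the kept parents are the top-EBV incumbents
        assert set(kept) == set(np.argsort(-ebv[:40])[:8])

    def test_zero_replacement_keeps_parents(self):
        ebv = np.linspace(0, 1, 60)
        current = np.arange(20)
        new, _ = pop._select_parents(
            current, np.ones(20, dtype=np.int64), np.arange(20, 60), ebv,
            n_slots=20, repl=0.0, max_age=5, direction=1)
        assert set(new) == set(current)

    def test_insufficient_candidates_raise(self):
        ebv = np.zeros(10)
        with pytest.raises(ValueError):
            pop._select_parents(np.arange(2), np.ones(2, dtype=np.int64),
                                np.arange(2, 4), ebv, n_slots=10, repl=0.9,
                                max_age=5, direction=1)

    def test_recent_run_structure_and_mendelian_consistency(self, micro_recent):
        rec = micro_recent
        p = rec.population
        # unique ids, parents precede offspring
        assert np.unique(p.ids).size == p.size
        order = {int(a): i for i, a in enumerate(p.ids)}
        for col in (p.sire, p.dam):
            known = col > 0
            assert all(order[int(a)] < i for i, a in zip(np.flatnonzero(known),
                                                         col[known]))
        # sire male, dam female
        sex = dict(zip(p.ids.tolist(), p.sex.tolist()))
        assert all(sex[int(s)] == pop.MALE for s in p.sire[p.sire > 0])
        assert all(sex[int(d)] == pop.FEMALE for d in p.dam[p.dam > 0])
        # Mendelian consistency, exhaustive on a sample of offspring
        idx = np.flatnonzero(p.sire > 0)[:25]
        for i in idx:
            si, di = order[int(p.sire[i])], order[int(p.dam[i])]
            assert np.all((p.haplotypes[i, 0] == p.haplotypes[si, 0])
                          | (p.haplotypes[i, 0] == p.haplotypes[si, 1]))
            assert np.all((p.haplotypes[i, 1] == p.haplotypes[di, 0])
                          | (p.haplotypes[i, 1] == p.haplotypes[di, 1]))

    def test_tbv_reproducible_from_genotypes(self, micro_recent):
        rec = micro_recent
        tbv = quantgen.compute_tbv(
            rec.population.genotypes(rec.gmap.qtl_index), rec.trait)
        assert np.allclose(tbv, rec.records["tbv"].to_numpy())

    def test_selection_differential_sign(self, micro_recent):
        """Selected parents beat the candidate mean EBV in the goal direction."""
        rec = micro_recent
        r = rec.records
        d = rec.trait.direction
        parents = set(rec.pedigree.loc[rec.pedigree["alive"], "id"])
        last = r[r["generation"] >= r["generation"].max() - 1]
        sel = last["id"].isin(parents)
        assert sel.any()
        diff = d * (last.loc[sel, "ebv"].mean() - last["ebv"].mean())
        assert diff > 0

    def test_base_generation_variance_matches_h2(self, micro_recent):
        rec = micro_recent
        base = rec.records[rec.records["generation"] == 0]
        assert np.var(base["tbv"]) == pytest.approx(rec.trait.h2, rel=0.02)


class TestMarkerPanel:
    def _population(self, rng, n=60):
        gmap = genome.build_genome_map([50.0, 50.0], 200, 30, rng)
        return gmap, pop.init_founders(gmap, n // 2, n - n // 2, rng)

    def test_exact_counts_retained(self, rng):
        gmap, p = self._population(rng)
        new_map, new_pop = pop.finalize_marker_panel(p, gmap, 150, 20, 0.05, rng)
        assert new_map.n_markers == 150
        assert new_map.n_qtl == 20
        assert new_pop.haplotypes.shape[2] == 170

    def test_reindexing_consistent(self, rng):
        gmap, p = self._population(rng)
        new_map, new_pop = pop.finalize_marker_panel(p, gmap, 100, 10, 0.05, rng)
        # allele frequencies of retained markers match the original loci
        freq = new_pop.haplotypes.mean(axis=(0, 1))
        maf = np.minimum(freq, 1 - freq)
        assert np.all(maf[~new_map.is_qtl] >= 0.05)

    def test_impossible_threshold_rejected(self, rng):
        gmap, p = self._population(rng)
        with pytest.raises(ValueError):
            pop.finalize_marker_panel(p, gmap, 10, 2, 0.5, rng)

    def test_monomorphic_population_rejected(self, rng):
        gmap = genome.build_genome_map([50.0], 40, 4, rng)
        p = pop.init_founders(gmap, 5, 5, rng)
        p.haplotypes[:] = 0
        with pytest.raises(ValueError):
            pop.finalize_marker_panel(p, gmap, 10, 2, 0.0, rng)

    def test_insufficient_qualifying_markers_rejected(self, rng):
        gmap, p = self._population(rng)
        with pytest.raises(ValueError):
            pop.finalize_marker_panel(p, gmap, 201, 5, 0.05, rng)
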