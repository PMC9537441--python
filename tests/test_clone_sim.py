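"""Simulator: transduction, expansion, treatment dynamics and sequencing."""

import numpy as np
import pandas as pd
import pytest

from capture_kit import amplicon_io, clonal_stats
from capture_kit.clone_sim import (
    ORIGIN_ACQ,
    ORIGIN_PRE,
    SimConfig,
    barcode_founders,
    evaluate_pipeline,
    expand,
    sequence,
    simulate,
    treat,
)

SMALL = dict(
    n_founders=2_000,
    library_size=20_000,
    expansion_coverage=60,
    depth=20_000,
    seq_error=0.0,
)


class TestFounders:
    def test_multi_barcode_fraction_matches_poisson(self):
        """At MOI 0.3 the conditional multi-integration fraction is
        (1 - e^-m - m e^-m) / (1 - e^-m) ~ 0.1392."""
        cfg = SimConfig(n_founders=100_000, library_size=10**6, moi=0.3, seed=2)
        rng = np.random.default_rng(cfg.seed)
        pool = barcode_founders(cfg, rng)
        m = 0.3
        expected = (1 - np.exp(-m) - m * np.exp(-m)) / (1 - np.exp(-m))
        n = pool.n_clones
        tol = 4 * np.sqrt(expected * (1 - expected) / n)
        assert pool.multi_barcode_fraction == pytest.approx(expected, abs=tol)

    def test_low_moi_limit_single_barcodes(self):
        cfg = SimConfig(n_founders=5_000, library_size=10**6, moi=0.001, seed=3)
        pool = barcode_founders(cfg, np.random.default_rng(3))
        assert pool.multi_barcode_fraction < 0.01

    def test_pigeonhole_small_library(self):
        cfg = SimConfig(n_founders=10_000, library_size=10, seed=4)
        with pytest.warns(UserWarning, match="collisions"):
            pool = barcode_founders(cfg, np.random.default_rng(4))
        assert len(pool.barcode_keys) == 10
        counts = pd.Series(
            [b for bcs in pool.clone_barcodes for b in bcs]
        ).value_counts()
        # every barcode is used and shared by multiple founders (the skewed
        # weights make the rarest barcode much less frequent than the median)
        assert len(counts) == 10
        assert (counts > 1).all()
        assert counts.median() > 100

    def test_invalid_moi(self):
        with pytest.raises(ValueError):
            SimConfig(moi=0.0)

    def test_keys_are_valid_40mers(self):
        cfg = SimConfig(n_founders=500, library_size=5_000, seed=5)
        pool = barcode_founders(cfg, np.random.default_rng(5))
        keys = list(pool.barcode_keys.values())
        assert len(set(keys)) == len(keys)
        assert all(len(k) == 40 and set(k) <= set("ACGT") for k in keys)


class TestExpand:
    def test_deterministic_doubling_without_death(self):
        cfg = SimConfig(**{**SMALL, "expansion_death_prob": 0.0}, seed=6)
        rng = np.random.default_rng(6)
        pool = barcode_founders(cfg, rng)
        expand(pool, cfg, rng)
        # pure doubling: every clone has the same power-of-two size
        sizes = set(pool.cells.tolist())
        assert len(sizes) == 1
        assert not pool.dropout.any()
        assert pool.cells.mean() >= cfg.expansion_coverage * (cfg.n_replicates + 1)

    def test_critical_branching_reports_dropout(self):
        cfg = SimConfig(**{**SMALL, "expansion_death_prob": 0.5}, seed=7)
        rng = np.random.default_rng(7)
        pool = barcode_founders(cfg, rng)
        expand(pool, cfg, rng)
        # p_death = 0.5 is critical: most lineages go extinct
        assert pool.dropout.mean() > 0.5


class TestTreat:
    def test_pure_preexisting_shared_across_replicates(self):
        cfg = SimConfig(**SMALL, rho_pre=0.02, mu_acq=0.0, seed=8)
        rng = np.random.default_rng(cfg.seed)
        pool = barcode_founders(cfg, rng)
        expand(pool, cfg, rng)
        result = treat(pool, cfg, rng)
        assert (result.acquired_day == -1).all()
        resistant_any = result.final_resistant > 0
        for rep in range(cfg.n_replicates):
            assert set(np.nonzero(resistant_any[rep])[0]) <= set(
                np.nonzero(pool.preexisting)[0]
            )

    def test_total_kill_extinction_by_day_two(self):
        cfg = SimConfig(
            **SMALL, rho_pre=0.0, mu_acq=0.0, persister_fraction=0.0,
            kill_prob_sensitive=1.0, seed=9,
        )
        rng = np.random.default_rng(cfg.seed)
        pool = barcode_founders(cfg, rng)
        expand(pool, cfg, rng)
        result = treat(pool, cfg, rng)
        assert len(result.extinct_replicates) == cfg.n_replicates
        assert (result.trajectories[1:, 2:, :] == 0).all()

    def test_conservation_audit(self):
        cfg = SimConfig(**SMALL, seed=10)
        rng = np.random.default_rng(cfg.seed)
        pool = barcode_founders(cfg, rng)
        expand(pool, cfg, rng)
        result = treat(pool, cfg, rng)
        audit = result.audit
        # daily totals evolve exactly by births - deaths
        assert (
            audit.total == audit.total_prev + audit.births - audit.deaths
        ).all()
        assert (result.trajectories >= 0).all()


class TestSequence:
    def test_counts_mode_exact_multinomial(self):
        cfg = SimConfig(**SMALL, seed=11)
        sim = simulate(cfg)
        totals = sim.table.totals
        assert (totals == cfg.depth).all()
        # control fractions track the (uniform-ish) baseline cell fractions
        truth_cells = sim.truth.groupby("barcode_key")["cells_control"].sum()
        top_key = truth_cells.idxmax()
        frac = sim.table.fractions()["control"]
        cell_frac = truth_cells[top_key] / truth_cells.sum()
        assert frac.get(top_key, 0.0) == pytest.approx(
            cell_frac, abs=4 * np.sqrt(cell_frac / cfg.depth) + 1e-4
        )

    def test_seq_error_thinning_matches_survival_probability(self):
        cfg = SimConfig(**{**SMALL, "seq_error": 0.001}, seed=12)
        sim = simulate(cfg)
        p = (1 - 0.001) ** 67
        for s in sim.table.sample_ids:
            assigned = int(sim.table.totals[s])
            frac = assigned / cfg.depth
            assert frac == pytest.approx(p, abs=4 * np.sqrt(p * (1 - p) / cfg.depth))

    def test_fastq_mode_recount_matches_intent(self, tmp_path):
        cfg = SimConfig(
            **{**SMALL, "depth": 5_000, "seq_error": 0.0}, seed=13
        )
        sim = simulate(cfg, as_fastq=True, out_dir=tmp_path)
        assert set(sim.fastq_paths) == set(cfg.sample_ids)
        reads = {
            s: amplicon_io.read_fastq(p) for s, p in sim.fastq_paths.items()
        }
        table = amplicon_io.count_barcodes(
            reads, list(sim.pool.barcode_keys.values())
        )
        # error-free reads must reproduce the intended counts exactly
        common = table.counts.reindex(
            index=sim.table.counts.index, columns=sim.table.counts.columns,
            fill_value=0,
        )
        pd.testing.assert_frame_equal(common, sim.table.counts)

    def test_seed_determinism(self):
        cfg = SimConfig(**SMALL, seed=14)
        a = simulate(cfg)
        b = simulate(cfg)
        pd.testing.assert_frame_equal(a.table.counts, b.table.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestEvaluate:
    def _run(self, cfg):
        sim = simulate(cfg)
        summary = clonal_stats.call_enriched(
            sim.table, "control", cfg.sample_ids[1:]
        )
        return sim, summary

    def test_no_acquired_clones_no_false_preexisting(self):
        """With mu_acq = 0 every enriched barcode traces to a planted
        preexisting clone and the acquired row of the confusion is empty."""
        cfg = SimConfig(**SMALL, rho_pre=0.01, mu_acq=0.0, seed=15)
        sim, summary = self._run(cfg)
        ev = evaluate_pipeline(sim, summary)
        assert ev.confusion.loc[ORIGIN_ACQ].sum() == 0
        assert ev.confusion.loc["never_resistant"].sum() == 0
        # every all-replicate candidate is truly planted
        assert ev.confusion.loc[ORIGIN_PRE, "all_replicates"] >= 0

    def test_perfect_separation(self):
        cfg = SimConfig(
            **{**SMALL, "depth": 50_000}, rho_pre=0.01, mu_acq=0.0,
            resistant_fitness_sd=0.01, seed=16,
        )
        sim, summary = self._run(cfg)
        ev = evaluate_pipeline(sim, summary)
        assert ev.precision == 1.0 and ev.recall == 1.0


def test_empty_pool_sequencing_errors():
    cfg = SimConfig(
        **SMALL, rho_pre=0.0, mu_acq=0.0, persister_fraction=0.0,
        kill_prob_sensitive=1.0, seed=17,
    )
    rng = np.random.default_rng(cfg.seed)
    pool = barcode_founders(cfg, rng)
    expand(pool, cfg, rng)
    result = treat(pool, cfg, rng)
    # control group still has cells, so sequencing succeeds and treated
    # samples are empty
    sim = sequence(pool, result, cfg, rng)
    assert (sim.table.counts[cfg.sample_ids[1:]].sum() == 0).all()
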