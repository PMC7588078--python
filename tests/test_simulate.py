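import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from sortscreen import (
    CellPopulation,
    ConfigurationError,
    EffectSpec,
    GeneEffectMap,
    LibraryDesign,
    ScreenSimConfig,
    assign_gene_effects,
    build_library,
    gate_cells,
    normalize_counts,
    sequence_fractions,
    simulate_cells,
    simulate_screen,
)


class TestBuildLibrary:
    def test_sizes_and_composition(self):
        lib = build_library(20, sgrnas_per_gene=5, n_ntc=10, seed=3)
        assert len(lib) == 110
        assert lib.n_ntc == 10
        assert len(lib.targets()) == 20
        assert lib.entries["spacer"].is_unique

    def test_single_entry_library(self):
        lib = build_library(1, sgrnas_per_gene=1, n_ntc=0, seed=0)
        assert len(lib) == 1 and lib.n_ntc == 0

    def test_same_seed_reproduces_library(self):
        a = build_library(5, n_ntc=4, seed=9)
        b = build_library(5, n_ntc=4, seed=9)
        pd.testing.assert_frame_equal(a.entries, b.entries)

    def test_spacer_space_exhaustion_rejected(self):
        with pytest.raises(ConfigurationError):
            build_library(10, sgrnas_per_gene=5, n_ntc=0, seed=0, spacer_length=2)


class TestAssignGeneEffects:
    def test_null_spec_gives_zero_betas(self):
        lib = build_library(10, n_ntc=5, seed=0)
        effects = assign_gene_effects(lib, EffectSpec(), seed=1)
        assert (effects.beta == 0).all()
        assert effects.activity.between(0, 1).all()
        assert len(effects.activity) == 50

    def test_all_positive_point_mass_sign_convention(self):
        lib = build_library(6, n_ntc=2, seed=0)
        effects = assign_gene_effects(
            lib, EffectSpec(fraction_positive=1.0, beta_magnitude=0.7), seed=1
        )
        # positive regulators lower the reporter when silenced: beta = -m
        assert (effects.beta == -0.7).all()

    def test_regulator_counts_are_exact(self):
        lib = build_library(1000, sgrnas_per_gene=1, n_ntc=2, seed=0)
        effects = assign_gene_effects(
            lib, EffectSpec(fraction_positive=0.02, fraction_negative=0.01), seed=4
        )
        assert int((effects.beta < 0).sum()) == 20
        assert int((effects.beta > 0).sum()) == 10

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            EffectSpec(fraction_positive=0.7, fraction_negative=0.5)


class TestSimulateCells:
    def test_null_mean_matches_mu_induced(self):
        cfg = ScreenSimConfig(n_genes=20, n_ntc=10, coverage=30, depth=1000,
                              pi_off=0.0, seed=5)
        lib = build_library(cfg.n_genes, n_ntc=cfg.n_ntc, seed=5)
        effects = assign_gene_effects(lib, EffectSpec(), seed=5)
        pop = simulate_cells(lib, effects, cfg)
        log10f = np.log10(pop.fluorescence)
        se = cfg.sigma / np.sqrt(len(pop))
        assert abs(log10f.mean() - cfg.mu_induced) < 3 * se

    def test_full_block_gene_sits_at_off_peak(self):
        cfg = ScreenSimConfig(n_genes=10, n_ntc=5, coverage=200, depth=1000,
                              pi_off=0.0, seed=6)
        lib = build_library(cfg.n_genes, n_ntc=cfg.n_ntc, seed=6)
        effects = assign_gene_effects(lib, EffectSpec(), seed=6)
        gene = effects.beta.index[0]
        beta = effects.beta.copy()
        beta[gene] = cfg.mu_off - cfg.mu_induced
        activity = effects.activity.copy()
        sgids = lib.entries.loc[lib.entries["target"] == gene, "sgrna_id"]
        activity[sgids] = 1.0
        pop = simulate_cells(lib, GeneEffectMap(beta, activity), cfg)
        mask = np.isin(pop.sgrna_ids[pop.sgrna_index], sgids)
        mean = np.log10(pop.fluorescence[mask]).mean()
        se = cfg.sigma / np.sqrt(mask.sum())
        assert abs(mean - cfg.mu_off) < 4 * se

    def test_empty_library_gives_empty_population(self):
        cfg = ScreenSimConfig(n_genes=5, n_ntc=0, coverage=10, depth=100, seed=0)
        empty = LibraryDesign(
            pd.DataFrame(
                columns=["sgrna_id", "target", "tss_id", "spacer", "library_id"]
            )
        )
        effects = GeneEffectMap(
            beta=pd.Series(dtype=float), activity=pd.Series(dtype=float)
        )
        pop = simulate_cells(empty, effects, cfg)
        assert len(pop) == 0


class TestGateCells:
    @staticmethod
    def _population(values):
        values = np.asarray(values, dtype=float)
        return CellPopulation(
            sgrna_index=np.zeros(len(values), dtype=np.int64),
            fluorescence=values,
            sgrna_ids=np.array(["sg1"]),
        )

    def test_bimodal_mixture_low_weight_recovered(self):
        rng = np.random.default_rng(2)
        n = 20_000
        off = rng.random(n) < 0.10
        log10f = np.where(off, 1.5, 3.0) + 0.2 * rng.standard_normal(n)
        fractions = gate_cells(self._population(10.0**log10f))
        low_share = len(fractions.low) / n
        assert abs(low_share - 0.10) < 0.02
        assert abs(len(fractions.medium) - len(fractions.high)) <= 1
        assert not fractions.used_fallback

    def test_partition_is_exact(self):
        rng = np.random.default_rng(3)
        pop = self._population(10.0 ** rng.normal(2.5, 0.5, size=5000))
        fr = gate_cells(pop)
        combined = np.concatenate([fr.low, fr.medium, fr.high])
        assert len(combined) == 5000
        assert len(np.unique(combined)) == 5000

    def test_identical_values_fall_back_to_quantile_gate(self):
        fr = gate_cells(self._population(np.full(100, 50.0)))
        assert fr.used_fallback
        assert len(fr.low) + len(fr.medium) + len(fr.high) == 100
        assert abs(len(fr.medium) - len(fr.high)) <= 1

    def test_multiplicative_rescaling_preserves_memberships(self):
        rng = np.random.default_rng(4)
        off = rng.random(4000) < 0.15
        values = 10.0 ** (np.where(off, 1.0, 3.0) + 0.2 * rng.standard_normal(4000))
        a = gate_cells(self._population(values))
        b = gate_cells(self._population(values * 37.5))
        for fa, fb in zip((a.low, a.medium, a.high), (b.low, b.medium, b.high)):
            assert np.array_equal(fa, fb)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ConfigurationError):
            gate_cells(self._population(np.ones(5)))


class TestSequenceFractions:
    def _screen_parts(self, seed=7):
        cfg = ScreenSimConfig(n_genes=30, n_ntc=10, coverage=50, depth=50_000,
                              seed=seed)
        lib = build_library(cfg.n_genes, n_ntc=cfg.n_ntc, seed=seed)
        effects = assign_gene_effects(lib, EffectSpec(), seed=seed)
        pop = simulate_cells(lib, effects, cfg)
        return cfg, lib, pop, gate_cells(pop)

    def test_columns_sum_to_depth(self):
        cfg, lib, pop, fractions = self._screen_parts()
        counts = sequence_fractions(fractions, pop, cfg.depth, seed=1)
        assert (counts.counts.sum(axis=0) == cfg.depth).all()

    def test_single_sgrna_fraction_takes_all_reads(self):
        pop = CellPopulation(
            sgrna_index=np.array([0] * 30 + [1] * 30, dtype=np.int64),
            fluorescence=np.concatenate([np.full(30, 10.0), np.full(30, 1000.0)]),
            sgrna_ids=np.array(["sgA", "sgB"]),
        )
        fractions = gate_cells(pop)
        counts = sequence_fractions(fractions, pop, depth=500, seed=0)
        assert counts.counts.loc["sgA", "low"] == 500
        assert counts.counts.loc["sgB", "high"] == 500

    def test_counts_track_cell_tallies_within_binomial_noise(self):
        cfg, lib, pop, fractions = self._screen_parts()
        tally = np.bincount(pop.sgrna_index[fractions.high], minlength=len(lib))
        p = tally / tally.sum()
        counts = sequence_fractions(fractions, pop, cfg.depth, seed=3)
        observed = counts.counts["high"].to_numpy()
        expected = cfg.depth * p
        sd = np.sqrt(cfg.depth * p * (1 - p))
        assert (np.abs(observed - expected) <= 4 * np.maximum(sd, 1)).all()


class TestSimulateScreen:
    def test_fixed_seed_is_deterministic(self):
        cfg = ScreenSimConfig(n_genes=25, n_ntc=10, coverage=20, depth=20_000, seed=13)
        a = simulate_screen(cfg)
        b = simulate_screen(cfg)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.library.entries, b.library.entries)

    def test_null_screen_gene_and_ntc_counts_indistinguishable(self):
        ok = 0
        for seed in range(10):
            cfg = ScreenSimConfig(n_genes=100, n_ntc=100, coverage=30,
                                  depth=100_000, seed=seed)
            screen = simulate_screen(cfg, EffectSpec())
            is_ntc = (screen.library.entries["target"] == "NTC").to_numpy()
            col = screen.counts.counts["high"].to_numpy()
            ok += ks_2samp(col[is_ntc], col[~is_ntc]).pvalue > 0.01
        assert ok >= 9

    def test_full_block_gene_enriches_in_low_fraction(self):
        cfg = ScreenSimConfig(n_genes=40, n_ntc=20, coverage=50, depth=100_000, seed=21)
        lib = build_library(cfg.n_genes, n_ntc=cfg.n_ntc, seed=21)
        effects = assign_gene_effects(lib, EffectSpec(), seed=21)
        gene = effects.beta.index[0]
        beta = effects.beta.copy()
        beta[gene] = cfg.mu_off - cfg.mu_induced
        activity = effects.activity.copy()
        sgids = lib.entries.loc[lib.entries["target"] == gene, "sgrna_id"]
        activity[sgids] = 1.0
        screen = simulate_screen(cfg, library=lib,
                                 effects=GeneEffectMap(beta, activity))
        freqs = normalize_counts(screen.counts, screen.library)
        pooled = freqs.loc[sgids].sum(axis=0)
        assert pooled["low"] > pooled["high"]

    def test_stronger_effects_do_not_weaken_enrichment(self):
        """Expected |low-vs-high log-ratio| is monotone in |beta| over seeds."""
        means = []
        for magnitude in (0.2, 0.8):
            ratios = []
            for seed in range(3):
                cfg = ScreenSimConfig(n_genes=30, n_ntc=15, coverage=50,
                                      depth=100_000, seed=seed)
                lib = build_library(cfg.n_genes, n_ntc=cfg.n_ntc, seed=seed)
                effects = assign_gene_effects(lib, EffectSpec(), seed=seed)
                gene = effects.beta.index[0]
                beta = effects.beta.copy()
                beta[gene] = -magnitude
                screen = simulate_screen(cfg, library=lib,
                                         effects=GeneEffectMap(beta, effects.activity))
                sgids = lib.entries.loc[lib.entries["target"] == gene, "sgrna_id"]
                freqs = normalize_counts(screen.counts, screen.library)
                pooled = freqs.loc[sgids].sum(axis=0)
                ratios.append(abs(np.log(pooled["low"] / pooled["high"])))
            means.append(np.mean(ratios))
        assert means[1] >= means[0]

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            ScreenSimConfig(n_genes=0)
        with pytest.raises(ConfigurationError):
            ScreenSimConfig(n_genes=10, mu_off=3.0, mu_induced=1.5)
        with pytest.raises(ConfigurationError):
            ScreenSimConfig(n_genes=10, pi_off=0.6)
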