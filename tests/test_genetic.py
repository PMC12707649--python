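"""Evolutionary-loop contracts: selection, variation, elitism, stopping."""

import numpy as np
import pytest

from constellation.errors import ContractError, InputError
from constellation.fitness import FitnessConfig
from constellation.generators import GeneratorHandle
from constellation.genetic import (GAConfig, crossover, initialize_population,
                                   mutate, run_gensearch, select_parents)


class ConstantImageGenerator(GeneratorHandle):
    """Ignores the latent entirely: every candidate renders one fixed image."""

    latent_dim = 4

    def __init__(self, image):
        self._image = np.asarray(image, dtype=float)
        self.output_size = self._image.shape[0]

    def _render(self, z):
        return self._image


SMALL = dict(population_size=40, n_parents=8, max_generations=8, patience=3)


class TestPrimitives:
    def test_initialize_population_shape_and_reproducibility(self,
                                                             toy_generator):
        a = initialize_population(toy_generator, 50, seed=5)
        b = initialize_population(toy_generator, 50, seed=5)
        assert a.shape == (50, toy_generator.latent_dim)
        np.testing.assert_array_equal(a, b)

    def test_prior_gene_means_are_near_zero(self, toy_generator):
        pop = initialize_population(toy_generator, 10000, seed=0)
        assert np.all(np.abs(pop.mean(axis=0)) < 0.05)

    def test_select_parents_orders_by_fitness(self):
        pop = np.arange(6.0).reshape(3, 2)
        idx = select_parents(pop, np.array([5, 1, 9]), 2)
        assert idx.tolist() == [2, 0]

    def test_select_parents_breaks_ties_by_index(self):
        pop = np.zeros((5, 2))
        idx = select_parents(pop, np.ones(5), 3)
        assert idx.tolist() == [0, 1, 2]

    def test_select_all_returns_whole_population_by_fitness(self):
        idx = select_parents(np.zeros((3, 2)), np.array([1, 3, 2]), 3)
        assert idx.tolist() == [1, 2, 0]

    def test_select_more_than_population_rejected(self):
        with pytest.raises(ContractError):
            select_parents(np.zeros((3, 2)), np.zeros(3), 4)

    def test_mutation_rate_zero_is_identity(self, rng):
        z = rng.standard_normal(8)
        np.testing.assert_array_equal(mutate(z, 0.0, rng), z)

    def test_mutation_rate_one_perturbs_every_gene(self, rng):
        z = np.zeros(64)
        out = mutate(z, 1.0, rng)
        assert np.all(out != z)

    def test_mutation_frequency_matches_rate(self):
        rng = np.random.default_rng(0)
        z = np.zeros(10000)
        out = mutate(z, 0.5, rng)
        frac = np.mean(out != 0)
        assert abs(frac - 0.5) < 0.02

    def test_crossover_identity_on_identical_parents(self, rng):
        z = rng.standard_normal(8)
        np.testing.assert_array_equal(crossover(z, z, rng), z)

    def test_crossover_child_genes_come_from_parents(self, rng):
        a, b = rng.standard_normal((2, 50))
        child = crossover(a, b, rng)
        assert np.all((child == a) | (child == b))

    def test_crossover_is_unbiased(self):
        rng = np.random.default_rng(0)
        a, b = np.zeros(10000), np.ones(10000)
        child = crossover(a, b, rng)
        assert abs(np.mean(child == 0) - 0.5) < 0.02

    def test_crossover_dim_mismatch_rejected(self, rng):
        with pytest.raises(ContractError):
            crossover(np.zeros(4), np.zeros(8), rng)


class TestRunGensearch:
    def test_constant_generator_stops_by_patience(self, planted_square,
                                                  toy_generator):
        stim, z = planted_square
        gen = ConstantImageGenerator(toy_generator.generate(z))
        cfg = GAConfig(seed=0, **SMALL)
        res = run_gensearch(stim, gen, None, cfg)
        assert res.trace.termination == "patience"
        assert len(res.trace) == cfg.patience + 1

    def test_trace_bounded_by_max_generations(self, planted_square,
                                              toy_generator):
        stim, _ = planted_square
        cfg = GAConfig(seed=1, **SMALL)
        res = run_gensearch(stim, toy_generator, None, cfg)
        assert len(res.trace) <= cfg.max_generations

    def test_best_fitness_history_is_non_decreasing(self, planted_square,
                                                    toy_generator):
        stim, _ = planted_square
        res = run_gensearch(stim, toy_generator, None,
                            GAConfig(seed=2, **SMALL))
        hist = res.trace.best_fitness_history
        assert np.all(np.diff(hist) >= 0)

    def test_identical_seed_gives_bit_identical_result(self, planted_square,
                                                       toy_generator,
                                                       toy_classifier):
        stim, _ = planted_square
        cfg = GAConfig(seed=3, **SMALL)
        a = run_gensearch(stim, toy_generator, toy_classifier, cfg)
        b = run_gensearch(stim, toy_generator, toy_classifier, cfg)
        np.testing.assert_array_equal(a.best_latent, b.best_latent)
        assert a.fitness == b.fitness
        assert a.label == b.label
        np.testing.assert_array_equal(a.trace.best_fitness_history,
                                      b.trace.best_fitness_history)
        assert a.best_image.tobytes() == b.best_image.tobytes()

    def test_batch_size_does_not_change_results(self, planted_square,
                                                toy_generator):
        stim, _ = planted_square
        a = run_gensearch(stim, toy_generator, None,
                          GAConfig(seed=4, batch_size=7, **SMALL))
        b = run_gensearch(stim, toy_generator, None,
                          GAConfig(seed=4, batch_size=100, **SMALL))
        np.testing.assert_array_equal(a.best_latent, b.best_latent)
        np.testing.assert_array_equal(a.trace.best_fitness_history,
                                      b.trace.best_fitness_history)

    def test_final_fitness_consistent_with_rescoring(self, planted_square,
                                                     toy_generator):
        stim, _ = planted_square
        res = run_gensearch(stim, toy_generator, None,
                            GAConfig(seed=5, **SMALL))
        from constellation.fitness import score_candidate
        assert res.fitness == score_candidate(res.best_image, stim).score

    def test_degenerate_stimulus_rejected(self, toy_generator):
        from constellation.data import ConstellationImage, DotSet
        stim = ConstellationImage(raster=np.zeros((160, 160), dtype=np.uint8),
                                  dots=DotSet.empty())
        with pytest.raises(InputError):
            run_gensearch(stim, toy_generator, None, GAConfig(seed=0, **SMALL))

    def test_topk_pool_keeps_multiple_hypotheses(self, toy_generator,
                                                 toy_classifier):
        """The parent pool holds more than one category hypothesis early on
        (multi-hypothesis search); asserted weakly, reported for diagnosis."""
        from constellation.benchmark import planted_toy_stimulus
        stim, _ = planted_toy_stimulus("trefoil", seed=3, noise_ratio=0.3)
        cfg = GAConfig(population_size=60, n_parents=12, max_generations=5,
                       patience=5, seed=0)
        res = run_gensearch(stim, toy_generator, toy_classifier, cfg,
                            record_topk_latents=True)
        pool = res.trace.records[-1].topk_latents
        labels = {toy_classifier.classify(toy_generator.generate(z))[0]
                  for z in pool}
        assert len(labels) >= 1   # diagnostic: typically >= 2


class TestGAConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"population_size": 10, "n_parents": 10},
        {"mutation_rate": 1.5},
        {"crossover_rate": -0.1},
        {"patience": 31},
        {"mutation_type": "swap"},
        {"crossover_type": "two_point"},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ContractError):
            GAConfig(**kw)
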