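"""Synthetic generators: determinism, texture calibration, trees, BM traits."""

import numpy as np
import pytest

from conftest import brute_force_band_energies
from mottle.granularity import luminance_channel, pattern_metrics
from mottle.phylo import read_newick, simulate_bm_tips
from mottle.synth import (
    SpeciesGeneratorSpec,
    default_strategy_specs,
    generate_dataset,
    generate_phylogeny,
    generate_wing_image,
    simulate_bm_traits,
)

SMALL = (12.0, 8.0)  # small frame keeps per-image cost low


class TestWingImages:
    def test_same_seed_tuple_gives_bit_identical_images(self):
        spec = SpeciesGeneratorSpec(species_id="det", image_size_mm=SMALL)
        a, ra = generate_wing_image(spec, 3, 77)
        b, rb = generate_wing_image(spec, 3, 77)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(ra.mask, rb.mask)
        c, _ = generate_wing_image(spec, 4, 77)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_zero_amplitude_image_is_uniform_with_zero_contrast(self):
        spec = SpeciesGeneratorSpec(
            species_id="flat", mean_contrast_amp=0.0, image_size_mm=SMALL
        )
        img, roi = generate_wing_image(spec, 0, 5)
        for c in range(3):  # spatially uniform in every channel
            assert np.ptp(img.pixels[..., c]) == 0.0
        summary = pattern_metrics(img, roi)
        assert summary.contrast == 0.0
        assert summary.degenerate

    def test_marking_scale_outside_band_range_rejected(self):
        with pytest.raises(ValueError, match="band range"):
            SpeciesGeneratorSpec(species_id="bad", mean_marking_scale=0.05)

    def test_single_specimen_species_rejected(self):
        with pytest.raises(ValueError, match="n_specimens"):
            SpeciesGeneratorSpec(species_id="solo", n_specimens=1)

    def test_roi_ellipse_covers_most_of_the_frame(self):
        spec = SpeciesGeneratorSpec(species_id="roi", image_size_mm=SMALL)
        img, roi = generate_wing_image(spec, 0, 1)
        assert roi.mask.mean() >= 0.60
        assert roi.mask.shape == img.shape

    def test_larger_marking_scale_raises_downstream_max_freq(self):
        # oracle: marking size recomputed with the independent annulus binning
        def oracle_max_freq(img, roi):
            lum, _ = luminance_channel(img, roi)
            energies = brute_force_band_energies(lum)
            return (np.argmax(energies) + 1) / 10.0

        medians = []
        for scale in (0.5, 2.0):
            spec = SpeciesGeneratorSpec(
                species_id=f"s{scale}", mean_marking_scale=scale,
                cv_marking_scale=0.1, image_size_mm=SMALL,
            )
            vals = [
                oracle_max_freq(*generate_wing_image(spec, i, 13)) for i in range(20)
            ]
            medians.append(np.median(vals))
        assert medians[1] > medians[0]

    def test_median_max_freq_increases_across_scale_grid(self):
        medians = []
        for scale in (0.3, 1.0, 3.0):
            spec = SpeciesGeneratorSpec(
                species_id=f"g{scale}", mean_marking_scale=scale,
                cv_marking_scale=0.1, image_size_mm=(20.0, 14.0),
            )
            vals = [
                pattern_metrics(*generate_wing_image(spec, i, 29)).marking_size
                for i in range(20)
            ]
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]

    def test_median_contrast_increases_with_amplitude(self):
        medians = []
        for amp in (0.05, 0.15, 0.3):
            spec = SpeciesGeneratorSpec(
                species_id=f"a{amp}", mean_contrast_amp=amp,
                cv_contrast_amp=0.1, image_size_mm=SMALL,
            )
            vals = [
                pattern_metrics(*generate_wing_image(spec, i, 31)).contrast
                for i in range(20)
            ]
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]


class TestPhylogenySimulation:
    def test_two_tips_make_a_unit_depth_cherry(self):
        tree = generate_phylogeny(2, seed=3)
        depths = tree.tip_depths()
        assert len(depths) == 2
        assert all(d == pytest.approx(1.0, abs=1e-12) for d in depths.values())

    def test_forty_tips_ultrametric_to_nano(self):
        tree = generate_phylogeny(40, seed=8)
        depths = np.array(list(tree.tip_depths().values()))
        assert np.abs(depths - 1.0).max() < 1e-9
        assert sorted(tree.tip_labels) == sorted(
            f"species_{i + 1}" for i in range(40)
        )

    def test_same_seed_gives_identical_newick(self):
        assert generate_phylogeny(15, seed=4).newick() == generate_phylogeny(15, seed=4).newick()
        assert generate_phylogeny(15, seed=4).newick() != generate_phylogeny(15, seed=5).newick()

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError, match="n_tips"):
            generate_phylogeny(1, seed=0)

    def test_terminal_branches_are_positive(self):
        tree = generate_phylogeny(25, seed=11)
        for leaf in tree.tree.leaf_node_iter():
            assert leaf.edge.length > 0


class TestBrownianTraits:
    def test_zero_rate_gives_identical_tips(self):
        tree = generate_phylogeny(6, seed=2)
        traits = simulate_bm_traits(tree, 0.0, seed=1)
        assert len(set(traits.values())) == 1

    def test_cherry_variance_and_covariance_match_closed_form(self):
        # root cherry: shared path 0, so var = 1 and cov = 0
        tree = read_newick("(A:1,B:1);")
        _, C = tree.vcv()
        draws = simulate_bm_tips(C, 1.0, 10_000, np.random.default_rng(2026))
        emp = np.cov(draws.T)
        assert emp[0, 0] == pytest.approx(1.0, abs=0.05)
        assert emp[1, 1] == pytest.approx(1.0, abs=0.05)
        assert emp[0, 1] == pytest.approx(0.0, abs=0.05)

    def test_clustered_tree_within_clade_correlation(self):
        clade = lambda tag: ",".join(f"{tag}{i}:0.1" for i in range(5))
        tree = read_newick(f"(({clade('a')}):0.9,({clade('b')}):0.9);")
        labels, C = tree.vcv()
        draws = simulate_bm_tips(C, 1.0, 10_000, np.random.default_rng(99))
        corr = np.corrcoef(draws.T)
        i = {lab: k for k, lab in enumerate(labels)}
        within = [corr[i[f"a{p}"], i[f"a{q}"]] for p in range(5) for q in range(p + 1, 5)]
        assert np.mean(within) == pytest.approx(0.9, abs=0.05)

    def test_covariance_recovery_within_three_standard_errors(self):
        tree = generate_phylogeny(8, seed=6)
        _, C = tree.vcv()
        n = 10_000
        draws = simulate_bm_tips(C, 1.0, n, np.random.default_rng(2026))
        emp = (draws.T @ draws) / n  # mean is known to be 0
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / n)
        assert (np.abs(emp - C) / se).max() < 3.0

    def test_negative_rate_rejected(self):
        tree = generate_phylogeny(4, seed=1)
        with pytest.raises(ValueError, match="sigma2"):
            simulate_bm_traits(tree, -0.5, seed=0)


class TestDatasetAssembly:
    def test_every_species_is_a_tip_and_truth_is_verbatim(self):
        specs = default_strategy_specs(3, 2, seed=5)
        ds = generate_dataset(specs, seed=5, wings=("forewing",))
        assert sorted(ds.tree.tip_labels) == sorted(s.species_id for s in specs)
        assert list(ds.generator_truth["cv_marking_scale"]) == [
            s.cv_marking_scale for s in specs
        ]
        assert len(ds.images) == sum(s.n_specimens for s in specs)
        assert set(ds.factors) == {"strategy", "activity", "diet"}

    def test_duplicate_species_ids_rejected(self):
        spec = SpeciesGeneratorSpec(species_id="dup", image_size_mm=SMALL)
        with pytest.raises(ValueError, match="unique"):
            generate_dataset([spec, spec], seed=0)
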