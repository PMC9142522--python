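import numpy as np
import pytest

from debleed.containers import SlideCounts
from debleed.kernels import MixingModel, kernel_value
from debleed.simulate import (
    SpeciesAnnotation,
    annotate_computational_mixtures,
    background_distance_profile,
    background_umi_proportion,
    compute_lpss,
    matched_nonsv_genes,
    mse,
    simI_preprocess,
    simulate_contamination,
    synth_slide,
)


class TestSynthSlide:
    def test_fixed_seed_is_reproducible(self):
        t1, g1 = synth_slide(10, 10, 20, seed=4)
        t2, g2 = synth_slide(10, 10, 20, seed=4)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(g1.barcode, g2.barcode)

    def test_truth_defined_on_tissue_only(self):
        truth, geom = synth_slide(10, 10, 20, tissue_fraction=0.4, seed=1)
        assert truth.shape == (20, geom.n_tissue)
        assert geom.n_tissue < geom.n_spots

    def test_requested_mean_spot_total_is_hit(self):
        truth, _ = synth_slide(12, 12, 30, target_spot_total=2500.0, seed=2)
        realized = truth.sum(axis=0).mean()
        assert realized == pytest.approx(2500.0, rel=0.01)

    def test_excess_tissue_fraction_warns(self):
        with pytest.warns(UserWarning, match="background"):
            synth_slide(10, 10, 5, tissue_fraction=0.9, seed=0)

    def test_tissue_region_is_contiguous_rectangle(self):
        _, geom = synth_slide(10, 10, 5, tissue_fraction=0.5, seed=0)
        rows = geom.array_row[geom.tissue_indices]
        cols = geom.array_col[geom.tissue_indices]
        height = rows.max() - rows.min() + 1
        width = cols.max() - cols.min() + 1
        assert height * width == geom.n_tissue


class TestSimulateContamination:
    def test_zero_bleed_leaves_background_empty(self):
        truth, geom = synth_slide(8, 8, 10, seed=3, target_spot_total=500)
        sim = simulate_contamination(truth, geom, "gaussian", 0.0, 0.0, 150.0, seed=3)
        np.testing.assert_array_equal(
            sim.observed.counts[:, ~geom.in_tissue], 0
        )

    def test_positive_bleed_reaches_background(self):
        truth, geom = synth_slide(8, 8, 10, seed=3, target_spot_total=500)
        sim = simulate_contamination(truth, geom, "gaussian", 0.3, 0.1, 150.0, seed=3)
        assert sim.observed.counts[:, ~geom.in_tissue].sum() > 0

    def test_per_gene_totals_within_poisson_error(self):
        truth, geom = synth_slide(10, 10, 15, seed=6, target_spot_total=2000)
        sim = simulate_contamination(truth, geom, "gaussian", 0.3, 0.1, 200.0, seed=6)
        expected = truth.sum(axis=1)
        observed = sim.observed.counts.sum(axis=1)
        # each gene's total is a Poisson sum with variance = its expectation
        se = np.sqrt(expected)
        assert (np.abs(observed - expected) <= 4 * se + 1).all()

    def test_eta_matches_naive_triple_loop(self):
        truth, geom = synth_slide(4, 4, 3, tissue_fraction=0.5, seed=8,
                                  target_spot_total=100)
        r_beta, r_gamma, sigma = 0.4, 0.2, 150.0
        sim = simulate_contamination(truth, geom, "gaussian", r_beta, r_gamma,
                                     sigma, seed=8)
        model = MixingModel.from_geometry(geom, sigma, "gaussian")
        w = model.weights
        k = geom.n_spots
        cols = geom.tissue_indices
        eta = np.zeros((3, k))
        for g in range(3):
            for j in range(k):
                for t in range(geom.n_tissue):
                    eta[g, j] += truth[g, t] * r_beta * (
                        (1 - r_gamma) * w[t, j] + r_gamma / k
                    )
                    if cols[t] == j:
                        eta[g, j] += truth[g, t] * (1 - r_beta)
        np.testing.assert_allclose(sim.eta, eta, atol=1e-10)

    def test_background_bleed_decays_with_distance_from_tissue(self):
        truth, geom = synth_slide(14, 14, 40, tissue_fraction=0.35, seed=9)
        sim = simulate_contamination(truth, geom, "gaussian", 0.4, 0.05, 120.0, seed=9)
        assert background_distance_profile(sim.observed, geom) < 0.0


class TestSimIPreprocess:
    def make_slide(self, n_genes, seed=0):
        truth, geom = synth_slide(8, 8, n_genes, seed=seed, target_spot_total=800)
        sim = simulate_contamination(truth, geom, "gaussian", 0.2, 0.1, 150.0,
                                     seed=seed)
        return sim.observed, geom

    def test_gene_cap_applied(self):
        slide, geom = self.make_slide(40)
        truth, genes, _ = simI_preprocess(slide, geom, n_genes=30)
        assert truth.shape[0] == 30 and len(genes) == 30

    def test_fewer_genes_than_cap_warns_and_keeps_all(self):
        slide, geom = self.make_slide(10)
        with pytest.warns(UserWarning, match="using all"):
            truth, genes, _ = simI_preprocess(slide, geom, n_genes=30)
        assert truth.shape[0] == 10

    def test_default_sigma_is_ten_pixels(self):
        slide, geom = self.make_slide(10)
        _, _, (_, _, sigma) = simI_preprocess(slide, geom, n_genes=10)
        assert sigma == 10.0

    def test_rates_delegate_to_initial_value_rules(self):
        from debleed.fitting import initial_bleed_rate
        slide, geom = self.make_slide(40)
        _, genes, (r_beta, _, _) = simI_preprocess(slide, geom, n_genes=30)
        mask = np.isin(slide.gene_ids, genes)
        totals = slide.counts[mask].sum(axis=0).astype(float)
        assert r_beta == pytest.approx(initial_bleed_rate(totals, geom))


class TestMatchedNonSvGenes:
    def test_zero_mean_gives_all_zero_row(self):
        out = matched_nonsv_genes(np.array([0.0, 2.0]), n_spots=50, seed=1)
        np.testing.assert_array_equal(out[0], 0)

    def test_empirical_mean_within_poisson_error(self):
        means = np.array([3.0, 10.0, 0.5])
        out = matched_nonsv_genes(means, n_spots=2000, seed=2)
        se = np.sqrt(means / 2000)
        assert (np.abs(out.mean(axis=1) - means) <= 4 * se).all()

    def test_seed_reproducible(self):
        a = matched_nonsv_genes(np.array([5.0]), 30, seed=7)
        b = matched_nonsv_genes(np.array([5.0]), 30, seed=7)
        np.testing.assert_array_equal(a, b)


class TestMse:
    def test_perfect_estimate(self, rng):
        truth = rng.uniform(0, 10, size=(4, 6))
        per_gene, overall = mse(truth, truth)
        assert overall == 0.0
        np.testing.assert_array_equal(per_gene, 0.0)

    def test_unit_offset(self, rng):
        truth = rng.uniform(0, 10, size=(4, 6))
        _, overall = mse(truth, truth + 1.0)
        assert overall == pytest.approx(1.0)

    def test_matches_naive_loop(self, rng):
        truth = rng.uniform(0, 10, size=(3, 5))
        est = rng.uniform(0, 10, size=(3, 5))
        per_gene, overall = mse(truth, est)
        for g in range(3):
            manual = sum((truth[g, j] - est[g, j]) ** 2 for j in range(5)) / 5
            assert per_gene[g] == pytest.approx(manual)
        assert overall == pytest.approx(np.mean(per_gene))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            mse(np.zeros((2, 3)), np.zeros((2, 4)))


class TestBackgroundUmiProportion:
    def test_examples(self, line_geometry):
        ids = np.array(["g"], dtype=object)
        clean = SlideCounts(ids, np.array([[5, 5, 5, 0, 0]]))
        assert background_umi_proportion(clean, line_geometry) == 0.0
        split = SlideCounts(ids, np.array([[5, 5, 0, 4, 6]]))
        assert background_umi_proportion(split, line_geometry) == pytest.approx(0.5)
        empty = SlideCounts(ids, np.zeros((1, 5), dtype=int))
        with pytest.raises(ValueError, match="zero total"):
            background_umi_proportion(empty, line_geometry)


def species_fixture():
    """2 human + 2 mouse + 1 background spot; 2 human + 1 mouse gene."""
    counts = np.array([
        [10, 8, 1, 0, 0],   # human gene
        [6, 9, 0, 2, 0],    # human gene
        [1, 0, 7, 9, 0],    # mouse gene
    ])
    slide = SlideCounts(np.array(["hA", "hB", "mA"], dtype=object), counts)
    ann = SpeciesAnnotation(
        spot_labels=np.array(
            ["human", "human", "mouse", "mouse", "background"], dtype=object
        ),
        gene_species=np.array(["human", "human", "mouse"], dtype=object),
    )
    return slide, ann


class TestLpss:
    def test_no_swapped_reads(self):
        slide, ann = species_fixture()
        counts = slide.counts.copy()
        counts[2, :2] = 0
        counts[:2, 2:4] = 0
        clean = SlideCounts(slide.gene_ids, counts)
        assert compute_lpss(clean, ann) == 0.0

    def test_all_reads_swapped(self):
        slide, ann = species_fixture()
        counts = np.array([[0, 0, 3, 4, 0], [0, 0, 2, 1, 0], [5, 6, 0, 0, 0]])
        assert compute_lpss(SlideCounts(slide.gene_ids, counts), ann) == 1.0

    def test_hand_computed_toy(self):
        slide, ann = species_fixture()
        # mouse reads in human spots: 1; human reads in mouse spots: 1+2=3
        # total reads in pure spots: 10+8+1 + 6+9+2 + 1+7+9 = 53
        assert compute_lpss(slide, ann) == pytest.approx(4 / 53)

    def test_no_pure_spots_is_an_error(self):
        slide, ann = species_fixture()
        bad = SpeciesAnnotation(
            spot_labels=np.array(["mixture"] * 4 + ["background"], dtype=object),
            gene_species=ann.gene_species,
        )
        with pytest.raises(ValueError, match="pure"):
            compute_lpss(slide, bad)


class TestComputationalMixtures:
    def test_clean_human_spot_stays_human(self):
        slide, ann = species_fixture()
        counts = slide.counts.copy()
        counts[2, :2] = 0  # no mouse reads in human spots
        out, _ = annotate_computational_mixtures(
            SlideCounts(slide.gene_ids, counts), ann
        )
        assert out.spot_labels[0] == "human" and out.spot_labels[1] == "human"

    def test_contaminated_spot_relabeled(self):
        slide, ann = species_fixture()
        counts = slide.counts.copy()
        counts[2, 0] = 50  # mouse reads exceeding mouse-spot median totals
        out, _ = annotate_computational_mixtures(
            SlideCounts(slide.gene_ids, counts), ann
        )
        assert out.spot_labels[0] == "mixture"

    def test_matches_direct_rule_evaluation_and_is_idempotent(self, rng):
        n_spots, n_genes = 6, 4
        counts = rng.poisson(8.0, size=(n_genes, n_spots))
        labels = np.array(
            ["human", "human", "human", "mouse", "mouse", "mouse"], dtype=object
        )
        species = np.array(["human", "human", "mouse", "mouse"], dtype=object)
        slide = SlideCounts(
            np.array([f"g{i}" for i in range(n_genes)], dtype=object), counts
        )
        ann = SpeciesAnnotation(labels, species)
        out, medians = annotate_computational_mixtures(slide, ann)

        spot_totals = counts.sum(axis=0)
        mouse_median = np.median(spot_totals[3:])
        human_median = np.median(spot_totals[:3])
        mouse_in = counts[species == "mouse"].sum(axis=0)
        human_in = counts[species == "human"].sum(axis=0)
        for i in range(3):
            expected = "mixture" if mouse_in[i] > mouse_median else "human"
            assert out.spot_labels[i] == expected
        for i in range(3, 6):
            expected = "mixture" if human_in[i] > human_median else "mouse"
            assert out.spot_labels[i] == expected

        # medians frozen from the first pass: second pass is a no-op
        again, _ = annotate_computational_mixtures(slide, out, medians=medians)
        np.testing.assert_array_equal(again.spot_labels, out.spot_labels)
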