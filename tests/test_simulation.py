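import numpy as np
import pytest

import nbid


class TestGenerateNbMatrix:
    def test_seed_determinism(self):
        m1, _ = nbid.generate_nb_matrix(100, 50, seed=9)
        m2, _ = nbid.generate_nb_matrix(100, 50, seed=9)
        np.testing.assert_array_equal(m1.counts, m2.counts)

    def test_zero_depth_variation_concentrates_totals(self):
        mat, _ = nbid.generate_nb_matrix(
            500, 200, depth_variation=0.0, median_depth=2000, seed=3
        )
        totals = mat.counts.sum(axis=0)
        assert abs(totals.mean() - 2000) / 2000 < 0.05
        assert totals.std() / totals.mean() < 0.1

    def test_moment_structure(self):
        # var - mean should scale as phi * mean^2 across cells
        mat, params = nbid.generate_nb_matrix(
            300, 2000, depth_variation=0.0, median_depth=2000, seed=4
        )
        mean = mat.counts.mean(axis=1)
        var = mat.counts.var(axis=1, ddof=1)
        keep = mean > 1
        phi_hat = (var[keep] - mean[keep]) / mean[keep] ** 2
        # regression through the origin of phi_hat on true phi
        slope = (phi_hat * params["dispersions"][keep]).sum() / (
            params["dispersions"][keep] ** 2
        ).sum()
        assert slope == pytest.approx(1.0, rel=0.1)


class TestSwapDe:
    @pytest.fixture
    def base(self):
        mat, _ = nbid.generate_nb_matrix(800, 300, seed=5)
        return mat

    def test_fc_of_one_rejected(self, base):
        with pytest.raises(ValueError):
            nbid.simulate_swap_de(base, 150, 150, t=0.5, fc=1.0, seed=0)

    def test_cell_totals_conserved(self, base):
        sim, truth = nbid.simulate_swap_de(base, 150, 150, t=0.5, fc=4.0, seed=1)
        kept = truth.extra["cells"]
        np.testing.assert_array_equal(
            sim.counts.sum(axis=0), base.counts[:, kept].sum(axis=0)
        )

    def test_realized_fold_changes(self, base):
        sim, truth = nbid.simulate_swap_de(base, 150, 150, t=0.5, fc=4.0, seed=2)
        pre = base.subset_cells(truth.extra["cells"])
        g2 = truth.group_assignment == 1
        ratios_low, ratios_high = [], []
        for low, high in truth.swap_pairs:
            il, ih = pre.gene_ids.index(low), pre.gene_ids.index(high)
            ratios_low.append(sim.counts[il, g2].mean() / pre.counts[il, g2].mean())
            ratios_high.append(sim.counts[ih, g2].mean() / pre.counts[ih, g2].mean())
        # low-expression genes gained ~fc, high-expression genes lost ~1/fc
        assert np.median(ratios_low) == pytest.approx(4.0, rel=0.35)
        assert np.median(ratios_high) == pytest.approx(0.25, rel=0.35)

    def test_insufficient_genes_error_names_shortfall(self, base):
        with pytest.raises(ValueError, match="not enough genes"):
            nbid.simulate_swap_de(base, 150, 150, t=1e6, fc=2.0, seed=3)

    def test_truth_bookkeeping(self, base):
        sim, truth = nbid.simulate_swap_de(base, 100, 200, t=0.5, fc=3.0, n_pairs=20, seed=4)
        assert len(truth.swap_pairs) == 20
        assert len(truth.de_genes) == 40
        assert len(set(truth.de_genes)) == 40
        assert (truth.group_assignment == 0).sum() == 100
        assert (truth.group_assignment == 1).sum() == 200


class TestThinning:
    def test_identity_range(self):
        mat, _ = nbid.generate_nb_matrix(100, 40, seed=6)
        out = nbid.thin_counts(mat, np.arange(40), (1.0, 1.0), seed=0)
        np.testing.assert_array_equal(out.counts, mat.counts)

    def test_retention_within_range_and_monotone(self):
        mat, _ = nbid.generate_nb_matrix(200, 60, seed=7)
        cells = np.arange(30)
        out = nbid.thin_counts(mat, cells, (0.5, 0.6), seed=1)
        assert (out.counts <= mat.counts).all()
        before = mat.counts.sum(axis=0)[cells]
        after = out.counts.sum(axis=0)[cells]
        ratio = after / before
        assert (ratio >= 0.5 - 1 / before).all()
        assert (ratio <= 0.6 + 1 / before).all()
        untouched = np.arange(30, 60)
        np.testing.assert_array_equal(
            out.counts[:, untouched], mat.counts[:, untouched]
        )

    def test_expected_retained_count(self, rng):
        mat, _ = nbid.generate_nb_matrix(50, 4, depth_variation=0.0, seed=8)
        reps = np.array(
            [
                nbid.thin_counts(mat, [0], (0.7, 0.7), seed=s).counts[:, 0]
                for s in range(300)
            ],
            dtype=float,
        )
        expected = 0.7 * mat.counts[:, 0]
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps)) + 1e-9
        # rounding of the target total adds a sub-molecule bias bound
        assert (np.abs(reps.mean(axis=0) - expected) <= 3 * se + 0.05).all()


@pytest.fixture(scope="module")
def replicates():
    return nbid.generate_replicate_pair(
        n_genes=400, n_cells=80, median_depth=3000, seed=10
    )


class TestBatchConfounded:
    def test_composition_preset(self, replicates):
        rep_a, rep_b, _ = replicates
        comp = nbid.BATCH_COMPOSITION_PRESETS["g2_18a_22b"]
        assert comp == (9, 21, 18, 22)
        sim, truth = nbid.simulate_batch_confounded(
            rep_a, rep_b, comp, t=1.0, fc=5.0, n_pairs=10, seed=11
        )
        assert (truth.group_assignment == 0).sum() == 30
        assert (truth.group_assignment == 1).sum() == 40
        assert truth.batch_assignment.shape == truth.group_assignment.shape
        # group 1 has 9 replicate-A cells, group 2 has 18
        g = truth.group_assignment
        b = truth.batch_assignment
        assert ((g == 0) & (b == 0)).sum() == 9
        assert ((g == 1) & (b == 0)).sum() == 18

    def test_de_genes_are_batch_neutral(self, replicates):
        rep_a, rep_b, _ = replicates
        sim, truth = nbid.simulate_batch_confounded(
            rep_a, rep_b, (9, 21, 18, 12), t=1.0, fc=5.0, n_pairs=10, seed=12
        )
        neutral = set(truth.extra["neutral_genes"])
        assert set(truth.de_genes) <= neutral

    def test_shifted_genes_excluded_from_truth(self):
        # adversarial check: with a strong known shift, no shifted gene
        # should survive the neutrality filter into the DE truth set
        rep_a, rep_b, shifted = nbid.generate_replicate_pair(
            n_genes=400, n_cells=100, median_depth=3000,
            shift_frac=0.25, shift_log_sd=np.log(6), seed=13
        )
        sim, truth = nbid.simulate_batch_confounded(
            rep_a, rep_b, (9, 21, 18, 12), t=1.0, fc=5.0, n_pairs=10, seed=14
        )
        shifted_ids = {f"gene{i}" for i in np.flatnonzero(shifted)}
        strong = {
            g for g in shifted_ids
            if abs(np.log(rep_b.counts[int(g[4:])].mean() + 0.1)
                   - np.log(rep_a.counts[int(g[4:])].mean() + 0.1)) > np.log(2)
        }
        assert not (set(truth.de_genes) & strong)

    def test_reproducible_under_seed(self, replicates):
        rep_a, rep_b, _ = replicates
        s1, t1 = nbid.simulate_batch_confounded(
            rep_a, rep_b, (9, 21, 18, 12), t=1.0, fc=5.0, n_pairs=10, seed=15
        )
        s2, t2 = nbid.simulate_batch_confounded(
            rep_a, rep_b, (9, 21, 18, 12), t=1.0, fc=5.0, n_pairs=10, seed=15
        )
        np.testing.assert_array_equal(s1.counts, s2.counts)
        assert t1.de_genes == t2.de_genes
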