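"""Domain statistics, signature scoring, and clustering agreement metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tissuedomains import (adjusted_rand_index, compute_domain_stats,
                           consensus_ari, domain_proportions,
                           domain_stats_table, generate_synthetic_st,
                           max_connected_component, signature_score)


def flood_fill_max_cc(labels, domain, connectivity):
    """Independent brute-force oracle for the largest connected component."""
    h, w = labels.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    seen = np.zeros((h, w), dtype=bool)
    best = 0
    for i in range(h):
        for j in range(w):
            if labels[i, j] != domain or seen[i, j]:
                continue
            stack, size = [(i, j)], 0
            seen[i, j] = True
            while stack:
                r, c = stack.pop()
                size += 1
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < h and 0 <= cc < w and not seen[rr, cc]
                            and labels[rr, cc] == domain):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            best = max(best, size)
    return best


class TestProportions:
    def test_counting(self):
        labels = np.concatenate([np.zeros(30, dtype=int), np.ones(70, dtype=int)])
        assert domain_proportions(labels) == {0: 0.3, 1: 0.7}

    def test_single_domain(self):
        assert domain_proportions(np.full((4, 4), 2)) == {2: 1.0}

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(-1, 5, size=(10, 10))
        labels[0, 0] = 0  # guarantee one foreground pixel
        assert np.isclose(sum(domain_proportions(labels).values()), 1.0)

    def test_all_background_rejected(self):
        with pytest.raises(ValueError, match="no in-mask"):
            domain_proportions(np.full((3, 3), -1))


class TestMaxConnectedComponent:
    def test_single_pixel_and_full_image(self):
        labels = np.full((4, 6), -1)
        labels[2, 3] = 1
        assert max_connected_component(labels, 1) == 1
        assert max_connected_component(np.full((4, 6), 0), 0) == 24
        assert max_connected_component(labels, 7) == 0

    def test_diagonal_blocks_depend_on_connectivity(self):
        labels = np.full((5, 5), 0)
        labels[0:2, 0:2] = 1
        labels[2:4, 2:4] = 1
        assert max_connected_component(labels, 1, connectivity=4) == 4
        assert max_connected_component(labels, 1, connectivity=8) == 8

    def test_region_mask_restriction_matches_crop(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=(12, 12))
        region = np.zeros((12, 12), dtype=bool)
        region[3:9, 2:10] = True
        masked = compute_domain_stats(labels, region_mask=region)
        cropped = compute_domain_stats(labels[3:9, 2:10])
        assert masked.proportions == cropped.proportions
        assert masked.max_cc_size == cropped.max_cc_size
        assert masked.tissue_area == cropped.tissue_area

    def test_sum_of_max_cc_bounded_by_area(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(-1, 4, size=(20, 20))
        stats = compute_domain_stats(labels)
        assert sum(stats.max_cc_size.values()) <= stats.tissue_area

    def test_stats_table_shape(self):
        stats = [compute_domain_stats(np.array([[0, 1], [1, 1]]), "img")]
        table = domain_stats_table(stats)
        assert list(table.columns) == ["slide_id", "domain", "proportion",
                                       "max_cc_size", "tissue_area"]
        assert len(table) == 2


class TestSignatureScore:
    def test_constant_matrix_scores_zero(self):
        from tissuedomains import SpotDataset
        ds = SpotDataset(matrix=np.full((5, 8), 3.0),
                         spot_ids=[f"s{i}" for i in range(5)],
                         array_row=np.zeros(5, dtype=int),
                         array_col=np.arange(0, 10, 2),
                         gene_names=[f"g{i}" for i in range(8)])
        out = signature_score(ds, {"sigA": ["g0", "g1"], "sigB": ["g4"]}, seed=0)
        assert np.allclose(out.scores.to_numpy(), 0.0)
        assert np.all(out.annotations == 0)  # tie -> first signature

    def test_all_genes_set_scores_zero(self):
        from tissuedomains import SpotDataset
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        ds = SpotDataset(matrix=rng.poisson(8.0, (10, 30)) + 1.0,
                         spot_ids=[f"s{i}" for i in range(10)],
                         array_row=np.zeros(10, dtype=int),
                         array_col=np.arange(0, 20, 2), gene_names=genes)
        out = signature_score(ds, {"all": genes}, n_reference=50, seed=0)
        assert np.allclose(out.scores.to_numpy(), 0.0, atol=1e-12)

    def test_recovers_planted_domains(self):
        datasets, truths = generate_synthetic_st(n_slides=1, lattice=(20, 20),
                                                 k_true=2, seed=8)
        ds, truth = datasets[0], truths[0]
        sets = {"dom0": [f"gene{i}" for i in range(8)],
                "dom1": [f"gene{i}" for i in range(8, 16)]}
        # 40-gene fixture: use wide bins so each control pool mixes both
        # domains' markers instead of reducing to the signature set itself
        out = signature_score(ds, sets, n_bins=2, seed=0)
        assert adjusted_rand_index(out.annotations, truth.labels) >= 0.9

    def test_disjoint_gene_set_rejected(self):
        from tissuedomains import SpotDataset
        ds = SpotDataset(matrix=np.ones((3, 4)), spot_ids=["a", "b", "c"],
                         array_row=[0, 0, 0], array_col=[0, 2, 4],
                         gene_names=["g0", "g1", "g2", "g3"])
        with pytest.raises(ValueError, match="no genes"):
            signature_score(ds, {"bad": ["zz"]}, seed=0)


class TestARI:
    def test_identical_and_permuted(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert adjusted_rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_closed_form_value(self):
        # crossed partition of 4 elements: Hubert-Arabie ARI = -0.5
        assert np.isclose(adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]), -0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            adjusted_rand_index([0, 1], [0, 1, 2])

    def test_max_cc_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            labels = rng.integers(-1, 3, size=rng.integers(2, 12, size=2))
            for conn in (4, 8):
                for d in range(3):
                    assert (max_connected_component(labels, d, conn)
                            == flood_fill_max_cc(labels, d, conn))


class TestConsensusARI:
    def test_single_sample_reduces_to_plain_ari(self):
        a, b = [0, 0, 1, 2], [2, 2, 0, 1]
        assert np.isclose(consensus_ari([a], [b]), adjusted_rand_index(a, b))

    def test_label_swap_across_samples_penalized(self):
        truth = [np.array([0, 0, 1, 1]), np.array([0, 0, 1, 1])]
        pred = [np.array([0, 0, 1, 1]), np.array([1, 1, 0, 0])]
        per_sample = [adjusted_rand_index(t, p) for t, p in zip(truth, pred)]
        assert per_sample == [1.0, 1.0]
        assert consensus_ari(truth, pred) < 1.0

    def test_perfect_consensus(self):
        truth = [np.array([0, 1, 2]), np.array([2, 2, 0])]
        assert consensus_ari(truth, [t.copy() for t in truth]) == 1.0

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            consensus_ari([[0, 1]], [[0, 1], [1, 0]])
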