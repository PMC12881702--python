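import numpy as np
import pandas as pd
import pytest

from defrac import (DistanceMatrix, ValidationError, aitchison_distance,
                    bray_curtis, clr_transform, paired_distances, pairwise_permanova,
                    pcoa, permanova, phase_contrast, select_extreme_pairs,
                    to_relative)

from conftest import make_table


class TestClr:
    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.integers(0, 100, size=(5, 8)))
        clr = clr_transform(table)
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-9)

    def test_two_part_limit(self):
        # counts [80, 20] at vanishing pseudocount: clr -> (ln 4 / 2, -ln 4 / 2)
        clr = clr_transform(make_table([[80, 20]]), pseudocount=1e-9)
        np.testing.assert_allclose(clr.to_numpy()[0],
                                   [np.log(4) / 2, -np.log(4) / 2], atol=1e-6)

    def test_uniform_row_is_zero(self):
        clr = clr_transform(make_table([[5, 5, 5]]))
        np.testing.assert_allclose(clr.to_numpy()[0], 0.0, atol=1e-12)

    def test_scale_invariance(self):
        a = clr_transform(make_table([[10, 20, 30]]), pseudocount=1e-9)
        b = clr_transform(make_table([[100, 200, 300]]), pseudocount=1e-9)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)

    def test_matches_skbio(self):
        from skbio.stats.composition import clr as skbio_clr

        rng = np.random.default_rng(5)
        counts = rng.integers(0, 50, size=(4, 6)).astype(float)
        ours = clr_transform(make_table(counts), pseudocount=1.0)
        x = counts + 1.0
        theirs = skbio_clr(x / x.sum(axis=1, keepdims=True))
        np.testing.assert_allclose(ours.to_numpy(), theirs, atol=1e-10)

    def test_requires_counts_and_positive_pseudocount(self):
        rel = to_relative(make_table([[1, 1]]))
        with pytest.raises(ValidationError):
            clr_transform(rel)
        with pytest.raises(ValidationError):
            clr_transform(make_table([[1, 1]]), pseudocount=0)


class TestAitchison:
    def test_identical_rows_zero(self):
        dm = aitchison_distance(make_table([[3, 7], [3, 7]]))
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_part_worked_example(self):
        # CLR([80,20]) - CLR([20,80]) = (ln4, -ln4); norm = sqrt(2) ln 4
        dm = aitchison_distance(make_table([[80, 20], [20, 80]]), pseudocount=1e-9)
        assert dm.values[0, 1] == pytest.approx(np.sqrt(2) * np.log(4), abs=1e-6)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(2)
        dm = aitchison_distance(make_table(rng.integers(0, 200, size=(6, 10))))
        v = dm.values
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-9


class TestBrayCurtis:
    def test_identical_rows(self):
        dm = bray_curtis(make_table([[0.5, 0.5], [0.5, 0.5]], mode="relative"))
        assert dm.values[0, 1] == 0.0

    def test_disjoint_supports(self):
        dm = bray_curtis(make_table([[1.0, 0.0], [0.0, 1.0]], mode="relative"))
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_half_overlap(self):
        dm = bray_curtis(make_table([[1.0, 0.0], [0.5, 0.5]], mode="relative"))
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_counts_autonormalized_with_warning(self):
        with pytest.warns(UserWarning, match="auto-normalized"):
            dm = bray_curtis(make_table([[10, 0], [5, 5]]))
        assert dm.values[0, 1] == pytest.approx(0.5)


class TestPcoa:
    def test_collinear_points(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(ids, d, "aitchison"), k=1)
        coords = res.coordinates.to_numpy()[:, 0]
        for i in range(3):
            for j in range(3):
                assert abs(abs(coords[i] - coords[j]) - d[i, j]) < 1e-9

    def test_euclidean_exactness(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d, "aitchison"), k=2)
        emb = res.coordinates.to_numpy()
        d_emb = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
        np.testing.assert_allclose(d_emb, d, atol=1e-6)

    def test_duplicated_sample_identical_coords(self):
        table = make_table([[5, 5, 1], [5, 5, 1], [1, 9, 3]])
        res = pcoa(aitchison_distance(table), k=1)
        np.testing.assert_allclose(res.coordinates.iloc[0], res.coordinates.iloc[1],
                                   atol=1e-9)

    def test_k_truncated_with_warning(self):
        d = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="truncating"):
            res = pcoa(DistanceMatrix(["a", "b"], d, "aitchison"), k=5)
        assert res.coordinates.shape[1] == 1


def two_group_dm(seed=0, n_per=6, shift=0.0, dim=5):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(2 * n_per, dim))
    pts[n_per:] += shift
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    ids = [f"s{i}" for i in range(2 * n_per)]
    groups = {ids[i]: ("A" if i < n_per else "B") for i in range(2 * n_per)}
    return DistanceMatrix(ids, d, "aitchison"), groups


class TestPermanova:
    def test_perfect_separation(self):
        # within-group distances 0, between-group 1; groups large enough that
        # no label permutation recreates the split among the 99 draws
        n, half = 16, 8
        d = np.ones((n, n))
        d[:half, :half] = 0
        d[half:, half:] = 0
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(n)]
        groups = {ids[i]: "A" if i < half else "B" for i in range(n)}
        res = permanova(DistanceMatrix(ids, d, "bray_curtis"), groups,
                        n_permutations=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_sample_order_invariance(self):
        dm, groups = two_group_dm(seed=1, shift=1.0)
        perm = np.random.default_rng(0).permutation(len(dm.sample_ids))
        ids2 = [dm.sample_ids[i] for i in perm]
        res1 = permanova(dm, groups, 99, seed=3)
        res2 = permanova(dm.subset(ids2), groups, 99, seed=3)
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f)
        assert res1.r_squared == pytest.approx(res2.r_squared)

    def test_matches_skbio_statistic(self):
        import skbio

        dm, groups = two_group_dm(seed=7, shift=0.8)
        ours = permanova(dm, groups, 999, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, ids=dm.sample_ids),
            [groups[s] for s in dm.sample_ids], permutations=999, seed=0)
        assert ours.pseudo_f == pytest.approx(float(sk["test statistic"]), rel=1e-9)
        assert abs(ours.p_value - float(sk["p-value"])) < 0.05

    def test_group_of_one_rejected(self):
        dm, groups = two_group_dm(n_per=3)
        groups[dm.sample_ids[0]] = "C"
        with pytest.raises(ValidationError):
            permanova(dm, groups, 9, seed=0)

    def test_pairwise_runs_each_pair(self):
        dm, groups = two_group_dm(seed=2, n_per=4, shift=0.5)
        groups = dict(groups)
        for s in dm.sample_ids[:2]:
            groups[s] = "C"
        table = pairwise_permanova(dm, groups, 49, seed=0)
        assert len(table) == 3
        assert set(table["group_a"]) | set(table["group_b"]) == {"A", "B", "C"}

    def test_p_floor(self):
        dm, groups = two_group_dm(seed=3, shift=5.0)
        res = permanova(dm, groups, 199, seed=0)
        assert res.p_value >= 1 / 200


class TestPhaseContrast:
    def pairs_frame(self, rows):
        return pd.DataFrame(rows, columns=["week", "depth", "phase",
                                           "sample_a", "sample_b", "distance"])

    def test_constant_distances(self):
        rows = [(w, 5.0, "pre_bloom" if w <= 2 else "bloom", "a", "b", 0.4)
                for w in range(1, 5)]
        pc = phase_contrast(self.pairs_frame(rows))
        row = pc.table.iloc[0]
        assert row["delta"] == pytest.approx(0.0)
        assert row["ci95_prebloom"] == 0.0

    def test_forced_delta(self):
        rows = [(1, 5.0, "pre_bloom", "a", "b", 0.1),
                (2, 5.0, "pre_bloom", "a", "b", 0.1),
                (3, 5.0, "bloom", "a", "b", 0.3),
                (4, 5.0, "bloom", "a", "b", 0.3)]
        pc = phase_contrast(self.pairs_frame(rows))
        assert pc.table.iloc[0]["delta"] == pytest.approx(0.2)

    def test_t_interval_closed_form(self):
        from scipy import stats

        values = [0.1, 0.2, 0.3, 0.4]
        rows = [(w, 5.0, "pre_bloom", "a", "b", v) for w, v in enumerate(values, 1)]
        rows += [(9, 5.0, "bloom", "a", "b", 0.5), (10, 5.0, "bloom", "a", "b", 0.5)]
        pc = phase_contrast(self.pairs_frame(rows))
        expected = stats.sem(values) * stats.t.ppf(0.975, 3)
        assert pc.table.iloc[0]["ci95_prebloom"] == pytest.approx(expected)

    def test_depth_missing_phase_omitted(self):
        rows = [(1, 5.0, "pre_bloom", "a", "b", 0.1)]
        with pytest.warns(UserWarning, match="omitted"):
            pc = phase_contrast(self.pairs_frame(rows))
        assert pc.omitted_depths == [5.0]
        assert pc.table.empty


class TestPairedDistances:
    def test_matched_contexts_only(self, small_sim):
        from defrac import (defractionate_all, pair_fractions)

        rel = to_relative(small_sim.table)
        pairs, _ = pair_fractions(rel, small_sim.metadata)
        sl, sl_meta, _ = defractionate_all(pairs)
        asvs = rel.data.columns
        both = pd.concat([rel.data, sl.data.reindex(columns=asvs, fill_value=0.0)])
        from defrac import AsvTable
        dm = bray_curtis(AsvTable(both, mode="relative"))
        meta = {**small_sim.metadata, **sl_meta}
        out = paired_distances(dm, meta, "SL", "W")
        assert len(out) == len(pairs)
        assert (out["distance"] >= 0).all()


class TestSelectExtremePairs:
    def frame(self, distances):
        return pd.DataFrame([
            {"week": i + 1, "depth": 5.0, "phase": "pre_bloom",
             "sample_a": f"a{i}", "sample_b": f"b{i}", "distance": d}
            for i, d in enumerate(distances)
        ])

    def test_argmin_argmax(self):
        out = select_extreme_pairs(self.frame([0.1, 0.5, 0.9]), 1, 1)
        assert list(out["distance"]) == [0.1, 0.9]
        assert list(out["tail"]) == ["low", "high"]

    def test_only_high_tail(self):
        out = select_extreme_pairs(self.frame([0.3, 0.2, 0.8]), 0, 2)
        assert list(out["tail"]) == ["high", "high"]
        assert out["distance"].iloc[0] == 0.8

    def test_eighteen_from_seventy_nine(self):
        rng = np.random.default_rng(0)
        out = select_extreme_pairs(self.frame(rng.random(79)), 9, 9)
        assert len(out) == 18
        assert (out["tail"] == "low").sum() == 9

    def test_tie_broken_by_week(self):
        out = select_extreme_pairs(self.frame([0.5, 0.5, 0.9]), 1, 1)
        assert out.iloc[0]["week"] == 1  # lexicographically first at the tie

    def test_overdraw_rejected(self):
        with pytest.raises(ValidationError):
            select_extreme_pairs(self.frame([0.1]), 1, 1)
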