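import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import tfcrkit as tk

from conftest import make_tfcr
from oracles import brute_interval_intersection, brute_overlap_pairs


def stage(name, intervals, links=None):
    tfcrs = [
        make_tfcr(f"{name}_t{i}", "chr1", s, e) for i, (s, e) in enumerate(intervals)
    ]
    return tk.StageData(name=name, tfcrs=tfcrs, links=links or [])


class TestOverlapPairs:
    def test_basic_overlap_reported(self):
        a = [make_tfcr("a0", "chr1", 100, 200)]
        b = [make_tfcr("b0", "chr1", 150, 250)]
        assert tk.overlap_pairs(a, b) == {("a0", "b0")}

    def test_half_open_adjacency_is_no_overlap(self):
        a = [make_tfcr("a0", "chr1", 100, 200)]
        b = [make_tfcr("b0", "chr1", 200, 300)]
        assert tk.overlap_pairs(a, b) == set()

    def test_min_overlap_threshold(self):
        a = [make_tfcr("a0", "chr1", 100, 200)]
        b = [make_tfcr("b0", "chr1", 195, 300)]
        assert tk.overlap_pairs(a, b, min_overlap_bp=5) == {("a0", "b0")}
        assert tk.overlap_pairs(a, b, min_overlap_bp=6) == set()

    def test_matches_quadratic_brute_force(self, rng):
        def random_intervals(n):
            starts = rng.integers(0, 20_000, size=n)
            lengths = rng.integers(1, 500, size=n)
            return [(int(s), int(s + l)) for s, l in zip(starts, lengths)]

        ia, ib = random_intervals(500), random_intervals(500)
        a = [make_tfcr(f"a{i}", "chr1", s, e) for i, (s, e) in enumerate(ia)]
        b = [make_tfcr(f"b{i}", "chr1", s, e) for i, (s, e) in enumerate(ib)]
        got = tk.overlap_pairs(a, b)
        expected = {(f"a{i}", f"b{j}") for i, j in brute_overlap_pairs(ia, ib)}
        assert got == expected

    def test_symmetry(self, rng):
        a = [make_tfcr(f"a{i}", "chr1", int(s), int(s) + 100) for i, s in
             enumerate(rng.integers(0, 5_000, 20))]
        b = [make_tfcr(f"b{i}", "chr1", int(s), int(s) + 100) for i, s in
             enumerate(rng.integers(0, 5_000, 20))]
        assert tk.overlap_pairs(a, b) == {(y, x) for x, y in tk.overlap_pairs(b, a)}


class TestGainedLost:
    def test_new_tfcr_is_gained(self):
        col = tk.StageCollection([stage("s1", [(100, 200)]), stage("s2", [(100, 200), (5_000, 5_100)])])
        res = tk.gained_lost(col)
        assert res["s2"]["gained"] == {"s2_t1"}
        assert res["s2"]["kept"] == {"s2_t0"}

    def test_identical_stages_all_kept(self):
        col = tk.StageCollection([stage("s1", [(100, 200), (400, 500)]),
                                  stage("s2", [(100, 200), (400, 500)])])
        res = tk.gained_lost(col)
        for s in ("s1", "s2"):
            assert res[s]["gained"] == set() and res[s]["lost"] == set()
            assert res[s]["gained"].isdisjoint(res[s]["kept"])

    def test_first_stage_gained_and_last_stage_lost_empty(self):
        col = tk.StageCollection([stage("s1", [(0, 10)]), stage("s2", [(5_000, 5_010)])])
        res = tk.gained_lost(col)
        assert res["s1"]["gained"] == set()
        assert res["s2"]["lost"] == set()
        assert res["s1"]["lost"] == {"s1_t0"}
        assert res["s2"]["gained"] == {"s2_t0"}

    def test_three_stage_panel_matches_brute_force(self, rng):
        def random_stage(name, n):
            starts = rng.integers(0, 10_000, size=n)
            return stage(name, [(int(s), int(s) + int(rng.integers(50, 400))) for s in starts])

        stages = [random_stage(f"s{k}", 30) for k in range(3)]
        col = tk.StageCollection(stages)
        res = tk.gained_lost(col)
        for k, st in enumerate(stages):
            for t in st.tfcrs:
                iv = (t.interval.start, t.interval.end)
                if k > 0:
                    prev = [(o.interval.start, o.interval.end) for o in stages[k - 1].tfcrs]
                    gained = all(min(iv[1], e) - max(iv[0], s) < 1 for s, e in prev)
                    assert (t.tfcr_id in res[st.name]["gained"]) == gained
                if k < 2:
                    nxt = [(o.interval.start, o.interval.end) for o in stages[k + 1].tfcrs]
                    lost = all(min(iv[1], e) - max(iv[0], s) < 1 for s, e in nxt)
                    assert (t.tfcr_id in res[st.name]["lost"]) == lost

    def test_single_stage_is_error(self):
        with pytest.raises(ValueError):
            tk.gained_lost(tk.StageCollection([stage("s1", [(0, 10)])]))


class TestStableRegions:
    def test_worked_three_interval_chain(self):
        col = tk.StageCollection([
            stage("s1", [(100, 200)]),
            stage("s2", [(150, 250)]),
            stage("s3", [(180, 300)]),
        ])
        regions = tk.stable_regions(col)
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (180, 200)
        assert regions[0].tfcr_ids_per_stage == (("s1_t0",), ("s2_t0",), ("s3_t0",))

    def test_disjoint_stages_give_nothing(self):
        col = tk.StageCollection([stage("s1", [(0, 100)]), stage("s2", [(500, 600)])])
        assert tk.stable_regions(col) == []

    def test_empty_stage_gives_empty_result(self):
        col = tk.StageCollection([stage("s1", [(0, 100)]), stage("s2", [])])
        assert tk.stable_regions(col) == []

    def test_five_stage_random_panel_matches_mask_oracle(self, rng):
        interval_lists = []
        stages = []
        for k in range(5):
            starts = rng.integers(0, 4_000, size=25)
            ivs = [(int(s), int(s) + int(rng.integers(20, 300))) for s in starts]
            interval_lists.append(ivs)
            stages.append(stage(f"s{k}", ivs))
        col = tk.StageCollection(stages)
        got = sorted((r.interval.start, r.interval.end) for r in tk.stable_regions(col))
        expected = brute_interval_intersection(interval_lists, 0, 5_000)
        assert got == sorted(expected)

    def test_stage_order_invariance(self, rng):
        interval_lists = []
        for _ in range(4):
            starts = rng.integers(0, 3_000, size=15)
            interval_lists.append([(int(s), int(s) + int(rng.integers(20, 200))) for s in starts])
        forward = tk.StageCollection([stage(f"s{k}", ivs) for k, ivs in enumerate(interval_lists)])
        backward = tk.StageCollection(
            [stage(f"s{k}", ivs) for k, ivs in enumerate(reversed(interval_lists))]
        )
        f = [(r.interval.start, r.interval.end) for r in tk.stable_regions(forward)]
        b = [(r.interval.start, r.interval.end) for r in tk.stable_regions(backward)]
        assert f == b


class TestLrBins:
    def _link(self, d, region="R4"):
        return tk.TFCRGeneLink(
            tfcr_id="t", gene_id="g", chrom="chr1", peak_pos=0, tss=d,
            distance=d, direction="tfcr_to_gene", region=region,
        )

    @pytest.mark.parametrize(
        "distance, bin_label",
        [(50_001, "50-100k"), (100_000, "50-100k"), (150_000, "100-150k"),
         (200_000, "150-200k"), (200_001, ">200k")],
    )
    def test_bin_membership(self, distance, bin_label):
        counts = tk.lr_distance_bins([self._link(distance)])
        assert counts[bin_label] == 1

    def test_counts_conserved(self, rng):
        links = [self._link(int(d)) for d in rng.integers(50_001, 400_000, size=200)]
        counts = tk.lr_distance_bins(links)
        assert sum(counts.values()) == 200

    def test_non_r4_link_is_error(self):
        with pytest.raises(ValueError):
            tk.lr_distance_bins([self._link(1_000, region="R1")])


class TestTrajectories:
    def _collection(self):
        """5 genes x 3 stages with hand-assembled nearest-TFCR complexities."""
        stages = []
        tc_table = {
            "gA": (1.0, 2.0, 3.0),
            "gB": (5.0, 5.0, 1.0),
            "gC": (2.0, 4.0, 8.0),
        }
        for k in range(3):
            tfcrs = []
            links = []
            for i, (g, tcs) in enumerate(sorted(tc_table.items())):
                t = make_tfcr(f"s{k}_{g}", "chr1", 1_000 * i, 1_000 * i + 100, tc=tcs[k])
                tfcrs.append(t)
                links.append(
                    tk.TFCRGeneLink(
                        tfcr_id=t.tfcr_id, gene_id=g, chrom="chr1",
                        peak_pos=t.peak_pos, tss=1_000 * i, distance=50,
                        direction="gene_to_tfcr",
                    )
                )
            stages.append(tk.StageData(name=f"s{k}", tfcrs=tfcrs, links=links))
        return tk.StageCollection(stages), tc_table

    def test_matrix_matches_hand_assembly(self):
        col, tc_table = self._collection()
        ids, matrix = tk.tc_trajectories(col)
        assert ids == sorted(tc_table)
        for row, g in zip(matrix, ids):
            raw = np.asarray(tc_table[g])
            expected = (raw - raw.mean()) / raw.std()
            assert np.allclose(row, expected)
            assert row.mean() == pytest.approx(0.0, abs=1e-12)
            assert row.std() == pytest.approx(1.0, abs=1e-12)

    def test_gene_missing_a_stage_excluded(self):
        col, _ = self._collection()
        col.stages[1].links = [l for l in col.stages[1].links if l.gene_id != "gB"]
        ids, matrix = tk.tc_trajectories(col)
        assert "gB" not in ids and len(ids) == 2

    def test_max_tc_wins_on_distance_ties(self):
        col, _ = self._collection()
        extra = make_tfcr("s0_extra", "chr1", 0, 100, tc=99.0)
        col.stages[0].tfcrs.append(extra)
        col.stages[0].links.append(
            tk.TFCRGeneLink(
                tfcr_id="s0_extra", gene_id="gA", chrom="chr1", peak_pos=50,
                tss=0, distance=50, direction="gene_to_tfcr",
            )
        )
        ids, matrix = tk.tc_trajectories(col)
        row = matrix[ids.index("gA")]
        raw = np.asarray([99.0, 2.0, 3.0])
        assert np.allclose(row, (raw - raw.mean()) / raw.std())


class TestFuzzyCMeans:
    def _planted(self, rng, n_per=40):
        up = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        down = -up
        rows = [up + rng.normal(0, 0.1, 5) for _ in range(n_per)]
        rows += [down + rng.normal(0, 0.1, 5) for _ in range(n_per)]
        labels = [0] * n_per + [1] * n_per
        return np.asarray(rows), labels

    def test_memberships_sum_to_one(self, rng):
        X, _ = self._planted(rng)
        res = tk.fuzzy_cmeans(X, c=3, seed=1)
        assert np.allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_planted_partition(self, rng):
        X, labels = self._planted(rng)
        res = tk.fuzzy_cmeans(X, c=2, seed=1)
        assert adjusted_rand_score(labels, res.hard_labels) == 1.0

    def test_same_seed_reproduces_memberships(self, rng):
        X, _ = self._planted(rng)
        a = tk.fuzzy_cmeans(X, c=4, seed=5)
        b = tk.fuzzy_cmeans(X, c=4, seed=5)
        assert np.array_equal(a.memberships, b.memberships)

    def test_point_on_center_gets_full_membership(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
        res = tk.fuzzy_cmeans(X, c=2, seed=0)
        d2 = ((X[:, None, :] - res.centers[None]) ** 2).sum(axis=2)
        hits = d2 <= 1e-300
        for i in range(len(X)):
            if hits[i].any():
                assert res.memberships[i][hits[i]].sum() == pytest.approx(1.0)

    def test_too_few_rows_is_error(self):
        with pytest.raises(ValueError):
            tk.fuzzy_cmeans(np.zeros((3, 5)), c=6)

    def test_bad_fuzzifier_is_error(self):
        with pytest.raises(ValueError):
            tk.fuzzy_cmeans(np.zeros((10, 5)), c=2, m=1.0)
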