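import numpy as np
import pytest

import tfcrkit as tk

from conftest import make_tfcr
from oracles import brute_nearest


def gene(gene_id, chrom, tss, strand="+"):
    return tk.GeneRecord(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand)


DEFAULTS = tk.RegionThresholds(*tk.DEFAULT_THRESHOLDS)


class TestLinkNearest:
    def test_tfcr_links_to_closer_gene(self):
        t = make_tfcr("t1", "chr1", 9_900, 10_100, peak_pos=10_000)
        links = tk.link_nearest(
            [t], [gene("gA", "chr1", 9_000), gene("gB", "chr1", 12_000)],
            direction="tfcr_to_gene",
        )
        assert [(l.gene_id, l.distance) for l in links] == [("gA", 1000)]

    def test_exact_distance_ties_all_retained(self):
        t = make_tfcr("t1", "chr1", 9_950, 10_050, peak_pos=10_000)
        links = tk.link_nearest(
            [t], [gene("gA", "chr1", 9_000), gene("gB", "chr1", 11_000)],
            direction="tfcr_to_gene",
        )
        assert sorted(l.gene_id for l in links) == ["gA", "gB"]
        assert all(l.distance == 1000 for l in links)

    def test_tss_inside_tfcr_gives_distance_zero(self):
        t = make_tfcr("t1", "chr1", 9_000, 11_000, peak_pos=10_500)
        (l,) = tk.link_nearest([t], [gene("gA", "chr1", 9_100)], direction="gene_to_tfcr")
        assert l.distance == 0

    def test_gene_on_tfcr_free_chromosome_yields_placeholder(self):
        t = make_tfcr("t1", "chr1", 100, 200)
        links = tk.link_nearest(
            [t], [gene("gA", "chr1", 500), gene("gB", "chr9", 500)],
            direction="gene_to_tfcr",
        )
        by_gene = {l.gene_id: l for l in links}
        assert by_gene["gB"].is_no_tfcr and by_gene["gB"].distance is None
        assert not by_gene["gA"].is_no_tfcr

    def test_empty_gene_list_is_error(self):
        with pytest.raises(ValueError, match="empty gene list"):
            tk.link_nearest([make_tfcr("t", "chr1", 0, 10)], [], direction="gene_to_tfcr")

    def test_matches_brute_force_on_random_fixture(self, rng):
        """50 x 50 random layout equals the exhaustive O(N*M) minimum,
        including all-ties-retained behaviour."""
        peaks = sorted(rng.choice(100_000, size=50, replace=False).tolist())
        tsss = sorted(rng.choice(100_000, size=50, replace=False).tolist())
        tfcrs = [
            make_tfcr(f"t{i}", "chr1", p, p + 10, peak_pos=p) for i, p in enumerate(peaks)
        ]
        genes = [gene(f"g{i}", "chr1", s) for i, s in enumerate(tsss)]
        links = tk.link_nearest(tfcrs, genes, direction="gene_to_tfcr")
        got = {}
        for l in links:
            got.setdefault(l.gene_id, set()).add(l.tfcr_id)
        # narrow intervals here never contain a foreign TSS, so the
        # point-distance oracle applies exactly
        for (best_d, idxs), g in zip(brute_nearest(tsss, peaks), genes):
            assert got[g.gene_id] == {f"t{i}" for i in idxs}
        links_t = tk.link_nearest(tfcrs, genes, direction="tfcr_to_gene")
        got_t = {}
        for l in links_t:
            got_t.setdefault(l.tfcr_id, set()).add(l.gene_id)
        for (best_d, idxs), t in zip(brute_nearest(peaks, tsss), tfcrs):
            assert got_t[t.tfcr_id] == {f"g{i}" for i in idxs}

    def test_nearest_of_nearest_inequality(self, rng):
        """If gene g's nearest TFCR is t at distance d, then t's own nearest
        gene is at distance <= d."""
        peaks = sorted(rng.choice(50_000, size=20, replace=False).tolist())
        tsss = sorted(rng.choice(50_000, size=20, replace=False).tolist())
        tfcrs = [make_tfcr(f"t{i}", "chr1", p, p + 10, peak_pos=p) for i, p in enumerate(peaks)]
        genes = [gene(f"g{i}", "chr1", s) for i, s in enumerate(tsss)]
        g2t = tk.link_nearest(tfcrs, genes, direction="gene_to_tfcr")
        t2g = tk.link_nearest(tfcrs, genes, direction="tfcr_to_gene")
        min_t2g = {}
        for l in t2g:
            min_t2g[l.tfcr_id] = min(min_t2g.get(l.tfcr_id, np.inf), l.distance)
        for l in g2t:
            assert min_t2g[l.tfcr_id] <= l.distance


class TestThresholds:
    def _mixture_links(self, rng, n=600):
        distances = []
        for _ in range(n):
            u = rng.random()
            if u < 0.45:
                d = abs(rng.normal(500, 300))
            elif u < 0.80:
                d = 0
                while d <= 2000:
                    d = rng.normal(27_000, 8_000)
            else:
                d = rng.integers(50_001, 300_000)
            distances.append(max(1, int(d)))
        return [
            tk.TFCRGeneLink(
                tfcr_id=f"t{i}", gene_id=f"g{i}", chrom="chr1", peak_pos=0,
                tss=d, distance=d, direction="tfcr_to_gene",
            )
            for i, d in enumerate(distances)
        ]

    def test_bimodal_mixture_recovers_planted_cuts(self, rng):
        th = tk.derive_thresholds(self._mixture_links(rng))
        assert th.provenance == "derived"
        assert 1_000 <= th.t1 <= 5_000
        assert 20_000 <= th.t2 <= 35_000
        assert th.t3 == 50_000

    def test_unimodal_distances_fall_back_to_defaults(self, rng):
        links = [
            tk.TFCRGeneLink(
                tfcr_id=f"t{i}", gene_id=f"g{i}", chrom="chr1", peak_pos=0,
                tss=d, distance=d, direction="tfcr_to_gene",
            )
            for i, d in enumerate(np.maximum(1, rng.normal(5_000, 500, 500)).astype(int))
        ]
        th = tk.derive_thresholds(links)
        assert th.provenance == "default"
        assert (th.t1, th.t2, th.t3) == tk.DEFAULT_THRESHOLDS

    def test_too_few_links_fall_back_to_defaults(self):
        links = [
            tk.TFCRGeneLink(
                tfcr_id="t", gene_id="g", chrom="chr1", peak_pos=0,
                tss=100, distance=100, direction="tfcr_to_gene",
            )
        ] * 10
        th = tk.derive_thresholds(links)
        assert th.provenance == "default"

    def test_defaults_are_the_published_cuts(self):
        assert tk.DEFAULT_THRESHOLDS == (2_000, 27_000, 50_000)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            tk.RegionThresholds(5_000, 2_000, 50_000)


class TestClassifyRegions:
    @pytest.mark.parametrize(
        "distance, region",
        [
            (0, "R1"),
            (2_000, "R1"),
            (2_001, "R2"),
            (27_000, "R2"),
            (27_001, "R3"),
            (50_000, "R3"),
            (50_001, "R4"),
        ],
    )
    def test_boundary_memberships(self, distance, region):
        link = tk.TFCRGeneLink(
            tfcr_id="t", gene_id="g", chrom="chr1", peak_pos=0,
            tss=distance, distance=distance, direction="gene_to_tfcr",
        )
        (out,) = tk.classify_regions([link], DEFAULTS)
        assert out.region == region

    def test_partition_total_and_exclusive(self, rng):
        links = [
            tk.TFCRGeneLink(
                tfcr_id=f"t{i}", gene_id=f"g{i}", chrom="chr1", peak_pos=0,
                tss=int(d), distance=int(d), direction="gene_to_tfcr",
            )
            for i, d in enumerate(rng.integers(0, 200_000, size=2_000))
        ]
        out = tk.classify_regions(links, DEFAULTS)
        assert all(l.region in tk.gene_linking.REGIONS for l in out)
        props = tk.region_proportions(out)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_classification_is_idempotent(self, rng):
        links = [
            tk.TFCRGeneLink(
                tfcr_id=f"t{i}", gene_id=f"g{i}", chrom="chr1", peak_pos=0,
                tss=int(d), distance=int(d), direction="gene_to_tfcr",
            )
            for i, d in enumerate(rng.integers(1, 100_000, size=300))
        ]
        once = tk.classify_regions(links, DEFAULTS)
        twice = tk.classify_regions(once, DEFAULTS)
        assert [l.region for l in once] == [l.region for l in twice]


class TestRegionProportions:
    def test_hand_counted_fixture(self):
        spec = {"R1": 10, "R2": 5, "R3": 4, "R4": 1}
        links = []
        i = 0
        for region, count in spec.items():
            for _ in range(count):
                links.append(
                    tk.TFCRGeneLink(
                        tfcr_id=f"t{i}", gene_id=f"g{i}", chrom="chr1", peak_pos=0,
                        tss=0, distance=0, direction="gene_to_tfcr", region=region,
                    )
                )
                i += 1
        props = tk.region_proportions(links)
        assert props == {"R1": 0.5, "R2": 0.25, "R3": 0.2, "R4": 0.05}

    def test_all_one_region(self):
        links = [
            tk.TFCRGeneLink(
                tfcr_id="t", gene_id=f"g{i}", chrom="chr1", peak_pos=0,
                tss=0, distance=0, direction="gene_to_tfcr", region="R1",
            )
            for i in range(4)
        ]
        assert tk.region_proportions(links) == {"R1": 1.0, "R2": 0.0, "R3": 0.0, "R4": 0.0}

    def test_no_classified_links_is_error(self):
        with pytest.raises(ValueError):
            tk.region_proportions([])


class TestExpressionGroups:
    def test_high_low_cut_is_strict(self):
        expr = tk.ExpressionTable({"a": 1.0, "b": 1.01, "c": 0.0})
        groups = tk.expression_groups(expr, scheme="HL")
        assert groups == {"a": "L", "b": "H", "c": "L"}

    def test_e6_distinct_values_equal_bins(self, rng):
        values = rng.permutation(600).astype(float)
        expr = tk.ExpressionTable({f"g{i}": v for i, v in enumerate(values)})
        groups = tk.expression_groups(expr, scheme="E6")
        from collections import Counter

        assert Counter(groups.values()) == {f"E{k}": 100 for k in range(1, 7)}

    def test_q100_matches_rank_binning_oracle(self, rng):
        values = rng.normal(size=1_000)
        expr = tk.ExpressionTable({f"g{i:04d}": float(abs(v)) for i, v in enumerate(values)})
        groups = tk.expression_groups(expr, scheme="Q100")
        # oracle: sort genes by value, chunk into 100 rank groups
        genes = sorted(expr, key=lambda g: expr.get(g))
        for b, chunk in enumerate(np.array_split(genes, 100)):
            for g in chunk:
                assert groups[g] == f"Q{b + 1}"

    def test_unknown_scheme_is_error(self):
        with pytest.raises(ValueError):
            tk.expression_groups(tk.ExpressionTable({"a": 1.0}), scheme="X")
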