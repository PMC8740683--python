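"""Regulatory-network construction: loop parsing, anchor tiling,
promoters, gene categories, expression quantiles, silencer statistics."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retgnet.intervals import GenomicInterval, Loop, RegulatoryElement, ValidationError
from retgnet.network import (
    ParseError,
    RETGNetwork,
    build_network,
    expression_quantiles,
    make_promoters,
    read_loops,
    silencer_stats,
    tile_and_classify,
    write_loops,
)


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


class TestReadLoops:
    def test_q_threshold_filters(self, tmp_path):
        path = tmp_path / "loops.bedpe"
        path.write_text(
            "chr1\t0\t5000\tchr1\t10000\t15000\t0.005\n"
            "chr1\t0\t5000\tchr1\t20000\t25000\t0.02\n"
        )
        loops = read_loops(path, q_threshold=0.01)
        assert len(loops) == 1
        assert loops[0].q_value == 0.005

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bedpe"
        path.write_text("")
        assert read_loops(path) == []

    def test_malformed_line_names_lineno(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        path.write_text("chr1\t0\t5000\tchr1\t10000\t15000\t0.005\nchr1\t0\tnope\n")
        with pytest.raises(ParseError, match="line 2"):
            read_loops(path)

    def test_inverted_interval_rejected(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        path.write_text("chr1\t5000\t0\tchr1\t10000\t15000\t0.005\n")
        with pytest.raises(ValidationError):
            read_loops(path)

    def test_round_trip(self, tmp_path):
        loops = [Loop(iv(0, 5000), iv(10_000, 15_000), 0.004)]
        path = tmp_path / "rt.bedpe"
        write_loops(loops, path)
        assert read_loops(path) == loops


class TestTiling:
    def test_five_kb_anchor_gives_five_tiles(self):
        loops = [Loop(iv(0, 5000), iv(100_000, 105_000), 1e-3)]
        res = tile_and_classify(loops, [])
        starts = sorted(e.interval.start for e in res
                        if e.interval.start < 50_000)
        assert starts == [0, 1000, 2000, 3000, 4000]

    def test_final_tile_truncated(self):
        loops = [Loop(iv(0, 1500), iv(100_000, 101_000), 1e-3)]
        res = tile_and_classify(loops, [])
        widths = sorted(e.interval.width for e in res if e.interval.start < 2000)
        assert widths == [500, 1000]

    def test_half_open_boundary_classification(self):
        loops = [Loop(iv(0, 1000), iv(100_000, 101_000), 1e-3)]
        open_res = tile_and_classify(loops, [iv(999, 1200)])
        closed_res = tile_and_classify(loops, [iv(1000, 1200)])
        by_start = lambda rs, s: next(e for e in rs if e.interval.start == s)
        assert by_start(open_res, 0).openness_class == "open"
        assert by_start(closed_res, 0).openness_class == "nonopen"

    @settings(max_examples=50, derandomize=True)
    @given(
        start=st.integers(0, 10_000),
        width=st.integers(1, 12_000),
    )
    def test_tiling_conserves_coverage(self, start, width):
        """Tiles are disjoint and their union equals the anchor."""
        anchor = iv(start, start + width)
        loops = [Loop(anchor, iv(10 ** 6, 10 ** 6 + 1000), 1e-3)]
        res = [e for e in tile_and_classify(loops, [])
               if e.interval.start < 10 ** 6]
        tiles = sorted((e.interval.start, e.interval.end) for e in res)
        assert tiles[0][0] == anchor.start
        assert tiles[-1][1] == anchor.end
        for (s1, e1), (s2, e2) in zip(tiles, tiles[1:]):
            assert e1 == s2  # contiguous, disjoint
        assert all(e - s <= 1000 for s, e in tiles)

    def test_adding_peaks_is_monotone(self):
        loops = [Loop(iv(0, 5000), iv(100_000, 105_000), 1e-3)]
        few = tile_and_classify(loops, [iv(500, 600)])
        more = tile_and_classify(loops, [iv(500, 600), iv(3500, 3600)])
        open_few = {e.re_id for e in few if e.openness_class == "open"}
        open_more = {e.re_id for e in more if e.openness_class == "open"}
        assert open_few <= open_more


class TestPromoters:
    def test_plus_strand(self):
        genes = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "tss": [10_000], "strand": ["+"]}
        )
        assert make_promoters(genes)["g"] == iv(8000, 10_000)

    def test_minus_strand(self):
        genes = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "tss": [10_000], "strand": ["-"]}
        )
        assert make_promoters(genes)["g"] == iv(10_000, 12_000)

    def test_clipped_at_chromosome_start(self):
        genes = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "tss": [500], "strand": ["+"]}
        )
        assert make_promoters(genes)["g"] == iv(0, 500)

    def test_missing_strand_rejected(self):
        genes = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "tss": [500], "strand": ["."]}
        )
        with pytest.raises(ValidationError):
            make_promoters(genes)


class TestBuildNetwork:
    def test_open_loop_gene(self, tiny_network):
        net, _ = tiny_network
        assert net.gene_category["g1"] == "OpenLoop"
        # g1's REs include the distal anchor tiles
        res = net.res_of_gene("g1")
        assert any("100000" in r for r in res)

    def test_nonopen_loop_gene(self, tiny_network):
        net, _ = tiny_network
        assert net.gene_category["g2"] == "NonOpenLoop"

    def test_no_loop_gene(self):
        genes = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "tss": [10_000], "strand": ["+"]}
        )
        net = build_network([], make_promoters(genes), [])
        assert net.gene_category["g"] == "NoLoop"

    def test_any_open_wins(self):
        genes = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "tss": [10_000], "strand": ["+"]}
        )
        loops = [
            Loop(iv(8000, 13_000), iv(100_000, 105_000), 1e-4),
            Loop(iv(8000, 13_000), iv(200_000, 205_000), 1e-4),
        ]
        peaks = [iv(100_100, 100_200)]  # only the first distal anchor is open
        res = tile_and_classify(loops, peaks)
        net = build_network(loops, make_promoters(genes), res)
        assert net.gene_category["g"] == "OpenLoop"

    def test_categories_partition_universe(self, default_study):
        net = default_study.network
        counts = {c: 0 for c in ("OpenLoop", "NonOpenLoop", "NoLoop")}
        for g in net.genes:
            counts[net.gene_category[g]] += 1
        assert sum(counts.values()) == len(net.genes)

    def test_promoter_re_present_but_does_not_set_category(self, tiny_network):
        net, _ = tiny_network
        prom_res = [r for r in net.res_of_gene("g2") if r.startswith("promoter")]
        assert prom_res  # promoter RE linked
        assert net.gene_category["g2"] == "NonOpenLoop"

    def test_json_round_trip(self, tiny_network, tmp_path):
        net, _ = tiny_network
        net.to_json(tmp_path / "net.json")
        back = RETGNetwork.from_json(tmp_path / "net.json")
        assert back.edges == net.edges
        assert back.gene_category == net.gene_category
        assert set(back.elements) == set(net.elements)


class TestExpressionQuantiles:
    def _net(self, categories):
        net = RETGNetwork()
        net.genes = set(categories)
        net.gene_category = categories
        return net

    def test_median_of_mostly_zero(self):
        net = self._net({"a": "OpenLoop", "b": "OpenLoop", "c": "OpenLoop"})
        out = expression_quantiles(net, {"c": 10.0}, [0.5])
        assert out.loc["OpenLoop", 0.5] == 0.0

    def test_all_zero(self):
        net = self._net({"a": "NoLoop", "b": "NoLoop"})
        out = expression_quantiles(net, {}, [0.25, 0.75])
        assert (out.loc["NoLoop"] == 0).all()

    def test_empty_category_flagged_nan(self):
        net = self._net({"a": "OpenLoop"})
        out = expression_quantiles(net, {"a": 1.0}, [0.5])
        assert math.isnan(out.loc["NonOpenLoop", 0.5])

    def test_quantiles_monotone_in_probability(self, default_study):
        probs = [0.05, 0.25, 0.5, 0.75, 0.95]
        out = expression_quantiles(
            default_study.network, default_study.landscape.fpkm, probs
        )
        row = out.loc["OpenLoop"].to_numpy(dtype=float)
        assert np.all(np.diff(row) >= 0)

    def test_planted_ordering_openloop_above_nonopenloop(self, default_study):
        out = expression_quantiles(
            default_study.network, default_study.landscape.fpkm, [0.5]
        )
        assert out.loc["OpenLoop", 0.5] > out.loc["NonOpenLoop", 0.5]


class TestSilencerStats:
    def test_no_silencers(self, tiny_network):
        net, _ = tiny_network
        out = silencer_stats(net, net, [], category="OpenLoop")
        assert out["p_value"] == 1.0
        assert all(
            f == 0 or math.isnan(f)
            for side in out["fractions"].values()
            for f in side.values()
        )

    def test_identical_networks_p_one(self, tiny_network):
        net, _ = tiny_network
        out = silencer_stats(
            net, net, [iv(100_000, 100_500)], category="OpenLoop"
        )
        assert out["p_value"] == pytest.approx(1.0)

    def test_two_sided_fisher_matches_enumeration(self):
        """scipy's two-sided Fisher exact on [[3,7],[0,10]] equals the sum
        of hypergeometric point probabilities <= the observed table's."""
        from scipy.stats import fisher_exact, hypergeom

        table = [[3, 7], [0, 10]]
        p_scipy = fisher_exact(table, alternative="two-sided")[1]
        # enumerate tables with the same margins: a in 0..3
        pmf = [hypergeom.pmf(a, 20, 3, 10) for a in range(4)]
        p_enum = sum(p for p in pmf if p <= pmf[3] + 1e-12)
        assert p_scipy == pytest.approx(p_enum, abs=1e-12)
        # one-sided tail for reference: 120/1140
        assert hypergeom.sf(2, 20, 3, 10) == pytest.approx(120 / 1140, abs=1e-12)

    def test_empty_category_rejected(self, tiny_network):
        net, _ = tiny_network
        with pytest.raises(ValidationError):
            silencer_stats(net, net, [], category="NoLoop")

    def test_direct_silencer_linkage_detected(self, tiny_network):
        net, _ = tiny_network
        out = silencer_stats(
            net, net, [iv(100_000, 100_500)], category="OpenLoop"
        )
        assert out["fractions"]["A"]["OpenLoop"] == 1.0  # g1 linked
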