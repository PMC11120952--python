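"""Size spectrum, context classification, window counting and hotspots."""

import numpy as np
import pandas as pd
import pytest

from pavscape.core import GeneAnnotation, GeneModel, GenotypeMatrix
from pavscape.landscape import (
    ContextClassifier,
    WindowCounts,
    count_breakpoints_in_windows,
    detect_hotspots,
    mean_per_chromosome,
    size_spectrum,
    summarize_context,
)
from pavscape.simulate import SimulationConfig, simulate_gene_annotation, simulate_pav_truth


class TestSizeSpectrum:
    def test_half_open_bins_and_short_fraction(self):
        out = size_spectrum([60, 500, 1500], bin_edges=[50, 1000, 10_000])
        assert out["counts"] == [2, 1]
        assert out["short_fraction"] == pytest.approx(2 / 3)

    def test_empty_input_reports_missing_fraction(self):
        out = size_spectrum([], bin_edges=[50, 1000])
        assert out["counts"] == [0]
        assert out["short_fraction"] is None

    def test_undersized_pav_rejected(self):
        with pytest.raises(ValueError, match="50"):
            size_spectrum([40, 100])


def _toy_annotation():
    """One gene [10000, 20000]: exon1 [10000,11999] (UTR head), intron
    [12000,12499], exon2 [12500,20000]."""
    gene = GeneModel(
        gene_id="g1", chrom="chr1", start=10_000, end=20_000, strand="+",
        exons=[(10_000, 11_999), (12_500, 20_000)],
        cds=[(10_500, 11_999), (12_500, 19_500)],
        utrs=[(10_000, 10_499), (19_501, 20_000)])
    return GeneAnnotation(genes=[gene])


class TestContextClassification:
    @pytest.mark.parametrize("start,end,expected", [
        (6_500, 6_900, {"intergenic"}),            # flank begins at 7000
        (6_500, 7_100, {"intergenic", "flank_3kb"}),
        (12_100, 12_400, {"intron"}),              # fully inside the intron
        (10_600, 10_800, {"CDS"}),
        (10_400, 10_600, {"UTR", "CDS"}),
        (11_900, 12_600, {"CDS", "intron"}),
        (22_000, 30_000, {"flank_3kb", "intergenic"}),
    ])
    def test_overlap_classes(self, start, end, expected):
        clf = ContextClassifier(_toy_annotation())
        assert clf.classify("chr1", start, end, "DEL") == expected

    def test_insertion_classified_as_point(self):
        clf = ContextClassifier(_toy_annotation())
        # INS anchored in the intron, nominal end irrelevant
        assert clf.classify("chr1", 12_100, 12_100, "INS") == {"intron"}

    def test_unknown_chromosome_warns_intergenic(self):
        clf = ContextClassifier(_toy_annotation())
        with pytest.warns(UserWarning, match="chrUn"):
            assert clf.classify("chrUn", 5, 50, "DEL") == {"intergenic"}

    def test_summary_enumeration(self):
        """4 loci: {intergenic}, {flank}, {flank+intergenic}, {CDS} ->
        intergenic 50%, flank 50%, CDS 25%, genic 75%."""
        loci = pd.DataFrame({
            "locus_id": ["l1", "l2", "l3", "l4"],
            "chrom": "chr1",
            "start": [2_000, 8_000, 6_500, 10_600],
            "end": [2_100, 8_100, 7_100, 10_800],
            "svtype": "DEL", "size": 100, "callers": "c", "n_members": 1})
        m = GenotypeMatrix(samples=["s1"], loci=loci,
                           genotypes=np.ones((1, 4), dtype=np.int8))
        out = summarize_context(m, _toy_annotation())
        assert out["pct_intergenic"] == pytest.approx(50.0)
        assert out["pct_flank_3kb"] == pytest.approx(50.0)
        assert out["pct_CDS"] == pytest.approx(25.0)
        assert out["pct_genic"] == pytest.approx(75.0)
        assert out["pct_flank_within_genic"] == pytest.approx(200 / 3)

    def test_all_intergenic_zero_genic(self):
        loci = pd.DataFrame({
            "locus_id": ["l1"], "chrom": "chr1", "start": [1_000],
            "end": [1_100], "svtype": "DEL", "size": 100,
            "callers": "c", "n_members": 1})
        m = GenotypeMatrix(samples=["s1"], loci=loci,
                           genotypes=np.ones((1, 1), dtype=np.int8))
        out = summarize_context(m, _toy_annotation())
        assert out["pct_genic"] == 0.0
        assert out["pct_flank_within_genic"] is None

    def test_classifier_matches_per_base_oracle(self):
        """Class sets agree with a brute-force per-base boolean-mask recount
        on a small simulated genome."""
        cfg = SimulationConfig(seed=17, n_chromosomes=1,
                               chromosome_length_bp=400_000, n_genes=25,
                               n_true_pavs=300, max_pav_size_bp=5_000,
                               n_samples=5)
        ann = simulate_gene_annotation(cfg)
        truth = simulate_pav_truth(cfg, ann)
        clf = ContextClassifier(ann, flank_bp=3000)
        L = cfg.chromosome_length_bp
        pad = 10_000
        masks = {c: np.zeros(L + pad + 2, dtype=bool)
                 for c in ("flank", "cds", "utr", "intron", "body")}

        def fill(mask, s, e):
            mask[max(s, 1):e + 1] = True

        from pavscape._intervals import subtract
        for g in ann.genes:
            fill(masks["body"], g.start, g.end)
            for s, e in subtract([(max(1, g.start - 3000), g.start - 1),
                                  (g.end + 1, g.end + 3000)],
                                 [(gg.start, gg.end) for gg in ann.genes]):
                fill(masks["flank"], s, e)
            for s, e in g.utrs:
                fill(masks["utr"], s, e)
            for s, e in g.introns:
                fill(masks["intron"], s, e)
            for s, e in subtract(g.exons, g.utrs):
                fill(masks["cds"], s, e)
        nongenic_ok = ~(masks["body"] | masks["flank"])
        for r in truth.loci.itertuples():
            s, e = int(r.start), int(r.start if r.svtype == "INS" else r.end)
            expected = set()
            if masks["flank"][s:e + 1].any():
                expected.add("flank_3kb")
            if masks["cds"][s:e + 1].any():
                expected.add("CDS")
            if masks["utr"][s:e + 1].any():
                expected.add("UTR")
            if masks["intron"][s:e + 1].any():
                expected.add("intron")
            if nongenic_ok[s:min(e, L + pad) + 1].any():
                expected.add("intergenic")
            assert clf.classify(r.chrom, r.start, r.end, r.svtype) == expected


class TestWindows:
    def test_window_arithmetic(self):
        counts = count_breakpoints_in_windows(
            pd.DataFrame(columns=["chrom", "start"]), {"chr1": 3_000_000})
        df = counts.windows["chr1"]
        assert list(df["start"]) == [0, 500_000, 1_000_000, 1_500_000,
                                     2_000_000, 2_500_000]
        assert df["end"].iloc[-1] == 3_000_000

    def test_breakpoint_counted_in_both_covering_windows(self):
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [750_000]})
        df = count_breakpoints_in_windows(loci, {"chr1": 3_000_000}).windows["chr1"]
        assert list(df["count"]) == [1, 1, 0, 0, 0, 0]

    def test_counts_match_bruteforce_membership(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(1, 3_000_001, size=500)
        loci = pd.DataFrame({"chrom": "chr1", "start": starts})
        df = count_breakpoints_in_windows(loci, {"chr1": 3_000_000}).windows["chr1"]
        for w_start, _, count in df[["start", "end", "count"]].to_numpy():
            members = ((starts - 1 >= w_start)
                       & (starts - 1 < w_start + 1_000_000)).sum()
            assert count == members

    def test_mass_conservation_under_double_counting(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(1, 2_000_001, size=300)
        loci = pd.DataFrame({"chrom": "chr1", "start": starts})
        counts = count_breakpoints_in_windows(loci, {"chr1": 2_000_000})
        per_locus = np.array(
            [((starts[i] - 1 >= counts.windows["chr1"]["start"].to_numpy())
              & (starts[i] - 1 < counts.windows["chr1"]["start"].to_numpy()
                 + 1_000_000)).sum() for i in range(len(starts))])
        assert counts.windows["chr1"]["count"].sum() == per_locus.sum()

    def test_locus_beyond_chromosome_rejected(self):
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [5_000_000]})
        with pytest.raises(ValueError, match="outside"):
            count_breakpoints_in_windows(loci, {"chr1": 1_000_000})


def _wc(counts_by_chrom, window=1_000_000, step=500_000, length=None):
    windows = {}
    for chrom, counts in counts_by_chrom.items():
        n = len(counts)
        L = length or (n * step + (window - step))
        starts = np.arange(n) * step
        windows[chrom] = pd.DataFrame({
            "start": starts, "end": np.minimum(starts + window, L),
            "count": np.asarray(counts)})
    return WindowCounts(windows=windows, window_size=window, step=step)


class TestHotspots:
    def test_tied_top_windows_merge_into_one_region(self):
        wc = _wc({"chr1": [9, 9, 1, 1, 1, 1, 1, 1, 1, 1]})
        regions = detect_hotspots(wc, top_frac=0.10)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (1, 1_500_000)  # union of both 9-count windows
        assert r.n_windows == 2 and r.max_window_count == 9

    def test_all_zero_counts_no_hotspots(self):
        assert detect_hotspots(_wc({"chr1": [0] * 10})) == []

    def test_single_nonzero_window(self):
        counts = [0] * 20
        counts[7] = 3
        regions = detect_hotspots(_wc({"chr1": counts}))
        assert len(regions) == 1
        assert regions[0].start == 7 * 500_000 + 1
        assert regions[0].n_windows == 1

    def test_regions_are_disjoint_unions_of_hot_windows(self):
        rng = np.random.default_rng(8)
        wc = _wc({"chr1": rng.poisson(3, 40), "chr2": rng.poisson(3, 40)})
        regions = detect_hotspots(wc, top_frac=0.10)
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_invalid_top_frac(self):
        with pytest.raises(ValueError, match="top_frac"):
            detect_hotspots(_wc({"chr1": [1, 2]}), top_frac=0.0)


def test_mean_per_chromosome_rounds_half_down():
    assert mean_per_chromosome(33_220, 12) == 2768
    assert mean_per_chromosome(25, 10) == 2  # 2.5 rounds down
    assert mean_per_chromosome(26, 10) == 3
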