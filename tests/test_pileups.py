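"""Anchor selection, PE-SCAn pile-ups and domain-scaled aggregation."""

import numpy as np
import pytest

from hcdscan import (BinnedTrack, GenomeLayout, GenomicInterval,
                     aggregate_over_domains, compute_oe, peak_signals,
                     pescan, select_anchorpoints, standard_scenario)
from hcdscan.pileups import PeakSignal
from hcdscan.pipeline import simulate_scenario
from hcdscan.simulate import plant_truth, simulate_contact_matrix, \
    simulate_tracks


def make_peaks(n, declines, chrom="a", spacing=10_000):
    out = []
    for i in range(n):
        iv = GenomicInterval(chrom, i * spacing, i * spacing + 500)
        out.append(PeakSignal(iv, wt_signal=100.0,
                              mut_signal=100.0 * (1 - declines[i])))
    return out


class TestSelectAnchorpoints:
    def test_ceil_rule_two_of_twenty(self):
        declines = np.linspace(0, 0.95, 20)
        peaks = make_peaks(20, declines)
        sel = select_anchorpoints(peaks, peaks, q=0.10)
        # top ceil(2) = 2 peaks per factor, identical sets -> 2 anchors
        assert len(sel) == 2
        tops = sorted(p.interval.start for p in peaks[-2:])
        assert sorted(iv.start for iv in sel) == tops

    def test_monotone_in_q(self):
        rng = np.random.default_rng(0)
        declines = rng.random(50)
        peaks = make_peaks(50, declines)
        prev: set = set()
        for q in (0.05, 0.1, 0.2, 0.4):
            sel = {(iv.start, iv.end) for iv in
                   select_anchorpoints(peaks, peaks, q=q)}
            assert prev <= sel
            prev = sel

    def test_disjoint_factors_warn_and_return_empty(self):
        a = make_peaks(10, np.linspace(0, 0.9, 10))
        b = [PeakSignal(GenomicInterval("b", p.interval.start,
                                        p.interval.end),
                        p.wt_signal, p.mut_signal) for p in a]
        with pytest.warns(UserWarning, match="no overlapping"):
            assert select_anchorpoints(a, b) == []

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_declining_anchors_fall_in_domains(self, seed):
        """With mutant peak decline confined to domains, >= 80% of selected
        anchorpoints land inside truth domain regions."""
        layout = GenomeLayout([("a", "a", 40_000_000)], bin_size=20_000)
        p = standard_scenario(layout=layout, seed=seed, peak_count=200)
        truth = plant_truth(p)
        wt = simulate_tracks(p, truth, "wt")
        mut = simulate_tracks(p, truth, "mut")
        peaks = [GenomicInterval("a", max(0, c - 500), c + 500)
                 for c in truth["a"].peak_positions]
        ctcf = peak_signals(peaks, wt["CTCF"], mut["CTCF"], layout)
        scc1 = peak_signals(peaks, wt["SCC1"], mut["SCC1"], layout)
        anchors = select_anchorpoints(ctcf, scc1)
        assert anchors
        doms = truth["a"].domain_regions
        inside = sum(any(d.start <= a.midpoint < d.end for d in doms)
                     for a in anchors)
        assert inside / len(anchors) >= 0.8


class TestPescan:
    def _oe(self, layout, seed, **kw):
        p = standard_scenario(layout=layout, seed=seed, **kw)
        cms, truth = simulate_contact_matrix(p, "wt")
        return {a: compute_oe(cm) for a, cm in cms.items()}, truth, p

    def test_min_sep_guard(self):
        layout = GenomeLayout([("a", "a", 40_000_000)], bin_size=20_000)
        oes, truth, p = self._oe(layout, 0)
        anchors = [GenomicInterval("a", 1_000_000, 1_020_000),
                   GenomicInterval("a", 3_000_000, 3_020_000)]
        with pytest.raises(ValueError, match="min_sep"):
            pescan(oes, anchors, layout, m=10, min_sep=100_000)

    def test_single_pair_equals_submatrix(self):
        layout = GenomeLayout([("a", "a", 40_000_000)], bin_size=20_000)
        oes, truth, p = self._oe(layout, 1)
        a, b = 500, 600  # bins
        anchors = [GenomicInterval("a", a * 20_000, (a + 1) * 20_000),
                   GenomicInterval("a", b * 20_000, (b + 1) * 20_000)]
        res = pescan(oes, anchors, layout, m=3, min_sep=200_000, max_sep=10e6)
        assert res.n_pairs == 1
        sub = oes["a"].values[a - 3:a + 4, b - 3:b + 4]
        assert np.allclose(res.matrix, sub, equal_nan=True)

    def test_anchor_order_invariance(self):
        layout = GenomeLayout([("a", "a", 40_000_000)], bin_size=20_000)
        oes, truth, p = self._oe(layout, 2)
        anchors = [GenomicInterval("a", s, s + 20_000)
                   for s in (2_000_000, 5_000_000, 9_000_000, 15_000_000)]
        r1 = pescan(oes, anchors, layout)
        r2 = pescan(oes, anchors[::-1], layout)
        assert np.allclose(r1.matrix, r2.matrix, equal_nan=True)
        assert r1.n_pairs == r2.n_pairs

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_null_pileup_flat(self, seed):
        """k=0, no TADs, no loops: pile-up ~ 1, center enrichment in [0.9, 1.1]."""
        layout = GenomeLayout([("a", "a", 40_000_000)], bin_size=20_000)
        oes, truth, p = self._oe(layout, seed, k_comp=0.0,
                                 tad_insulation_factor=1.0, loop_strength=1.0)
        rng = np.random.default_rng(seed)
        starts = rng.choice(np.arange(1_000_000, 39_000_000, 20_000), 30,
                            replace=False)
        anchors = [GenomicInterval("a", int(s), int(s) + 20_000)
                   for s in starts]
        res = pescan(oes, anchors, layout)
        assert 0.9 <= res.center_enrichment <= 1.1

    def test_planted_loops_enrich_center(self):
        layout = GenomeLayout([("a", "a", 40_000_000)], bin_size=20_000)
        oes, truth, p = self._oe(layout, 5, loop_strength=3.0, loop_anchors=20)
        anchors = truth["a"].loop_anchors
        res = pescan(oes, anchors, layout, min_sep=1e6, max_sep=10e6)
        assert res.center_enrichment > 1.5

    def test_pair_list_apa_matches_planted_loops(self, tmp_path):
        """APA on the explicit planted pair list (BEDPE round trip) is also
        center-enriched."""
        from hcdscan.io import read_bedpe
        from hcdscan.pileups import pescan_pairs

        layout = GenomeLayout([("a", "a", 40_000_000)], bin_size=20_000)
        oes, truth, p = self._oe(layout, 6, loop_strength=3.0,
                                 loop_anchors=20)
        pairs = truth["a"].loop_anchor_pairs
        bedpe = tmp_path / "loops.bedpe"
        with open(bedpe, "w") as fh:
            for a, b in pairs:
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t"
                         f"{b.chrom}\t{b.start}\t{b.end}\n")
        res = pescan_pairs(oes, read_bedpe(bedpe), layout)
        assert res.n_pairs == len(pairs)
        assert res.center_enrichment > 1.5


class TestAggregateOverDomains:
    def test_constant_track_gives_constant_profile(self):
        layout = GenomeLayout([("a", "a", 1_000_000)], bin_size=1000)
        tr = BinnedTrack("a", 1000, np.full(1000, 3.0))
        domains = [GenomicInterval("a", 100_000, 200_000),
                   GenomicInterval("a", 400_000, 700_000)]
        agg = aggregate_over_domains({"a": tr}, domains, layout, k=10)
        assert np.allclose(agg.profile, 3.0)
        assert agg.matrix.shape == (2, 50)

    def test_body_mean_conserved_by_rescaling(self, rng):
        layout = GenomeLayout([("a", "a", 1_000_000)], bin_size=1000)
        vals = rng.random(1000) * 10
        tr = BinnedTrack("a", 1000, vals)
        d = GenomicInterval("a", 200_000, 505_000)  # not bin-aligned
        agg = aggregate_over_domains({"a": tr}, [d], layout, k=20)
        body = agg.matrix[0, 20:80]
        # length-weighted mean over the domain bp range
        base = np.repeat(vals, 1000)[200_000:505_000].mean()
        assert body.mean() == pytest.approx(base, abs=1e-9)

    def test_flanks_clipped_at_arm_ends_are_missing(self):
        layout = GenomeLayout([("a", "a", 100_000)], bin_size=1000)
        tr = BinnedTrack("a", 1000, np.ones(100))
        d = GenomicInterval("a", 0, 40_000)  # left flank entirely off-arm
        agg = aggregate_over_domains({"a": tr}, [d], layout, k=10)
        assert np.isnan(agg.matrix[0, :10]).all()
        assert np.allclose(agg.matrix[0, 10:40], 1.0)

    def test_domain_flank_ratio_on_synthetic_h3k9me3(self):
        p = standard_scenario(seed=12, track_noise=0.01)
        truth = plant_truth(p)
        tracks = simulate_tracks(p, truth, "wt")
        domains = [iv for t in truth.values() for iv in t.domain_regions]
        # flanks of B domains are mostly A (baseline); body is 5x elevated
        agg = aggregate_over_domains(tracks["H3K9me3"], domains,
                                     p.layout, k=10)
        body = np.nanmean(agg.profile[10:40])
        flank = np.nanmean(np.r_[agg.profile[:5], agg.profile[-5:]])
        assert body / flank == pytest.approx(5.0, rel=0.25)

    def test_empty_domain_list_rejected(self, tiny_layout):
        tr = BinnedTrack("chr1p", 1000, np.ones(5))
        with pytest.raises(ValueError):
            aggregate_over_domains({"chr1p": tr}, [], tiny_layout)
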