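"""Declining-anchor selection, PE-SCAn Hi-C pile-ups and domain-scaled
signal aggregation.

PE-SCAn averages the O/E sub-matrix around every eligible pairwise
combination of a set of anchor loci; a loop shows up as central enrichment
of the mean pile-up. Anchors are "virtual loop anchorpoints": CTCF/SCC1
co-bound sites in the top decile of relative ChIP-signal decline between
conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .compartments import OEMatrix
from .core import BinnedTrack, GenomeLayout, GenomicInterval
from .intervals import merge_intervals

__all__ = [
    "PeakSignal",
    "PileupResult",
    "DomainAggregate",
    "peak_signals",
    "select_anchorpoints",
    "pescan",
    "pescan_pairs",
    "aggregate_over_domains",
]


@dataclass
class PeakSignal:
    interval: GenomicInterval
    wt_signal: float
    mut_signal: float

    @property
    def rel_decline(self) -> float:
        return (self.wt_signal - self.mut_signal) / self.wt_signal


@dataclass
class PileupResult:
    matrix: np.ndarray       # (2m+1, 2m+1) mean O/E
    n_pairs: int

    @property
    def center_enrichment(self) -> float:
        """Mean of the central 3x3 over the mean of the four corner 3x3s."""
        m = self.matrix
        c = m.shape[0] // 2
        center = np.nanmean(m[c - 1:c + 2, c - 1:c + 2])
        corners = np.nanmean([m[:3, :3], m[:3, -3:], m[-3:, :3], m[-3:, -3:]])
        return float(center / corners)


@dataclass
class DomainAggregate:
    profile: np.ndarray      # (5k,) column means
    matrix: np.ndarray       # (n_domains, 5k) per-domain rows
    k: int


def peak_signals(peaks: list[GenomicInterval],
                 wt_track: dict[str, BinnedTrack],
                 mut_track: dict[str, BinnedTrack],
                 layout: GenomeLayout) -> list[PeakSignal]:
    """Summed depth-normalized coverage over each peak footprint, per condition.

    Depth normalization: each condition's track values are scaled by the
    ratio of the mean of the two totals to that condition's total, so a
    global efficiency difference does not masquerade as decline.
    """
    tot_wt = sum(np.nansum(t.values) for t in wt_track.values())
    tot_mut = sum(np.nansum(t.values) for t in mut_track.values())
    mean_tot = 0.5 * (tot_wt + tot_mut)
    out: list[PeakSignal] = []
    for p in peaks:
        arm_id, s, e = layout.interval_arm(p)
        wt, mut = wt_track[arm_id], mut_track[arm_id]
        b0, b1 = s // wt.bin_size, -(-e // wt.bin_size)

        def footprint_sum(tr: BinnedTrack) -> float:
            vals = tr.values[b0:b1]
            return float(np.nansum(vals))

        out.append(PeakSignal(p,
                              wt_signal=footprint_sum(wt) * mean_tot / tot_wt,
                              mut_signal=footprint_sum(mut) * mean_tot / tot_mut))
    return out


def select_anchorpoints(ctcf: list[PeakSignal], scc1: list[PeakSignal],
                        q: float = 0.10) -> list[GenomicInterval]:
    """Intersect the top-``q`` declining CTCF and SCC1 peaks.

    For each factor the ceil(q*n) peaks with the largest relative decline are
    taken (ties by coordinate); returned anchors are the union spans of
    selected CTCF/SCC1 peak pairs overlapping by >= 1 bp.
    """
    if not ctcf or not scc1:
        raise ValueError("both peak lists must be nonempty")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")

    def top(peaks: list[PeakSignal]) -> list[GenomicInterval]:
        k = math.ceil(q * len(peaks))
        ranked = sorted(peaks,
                        key=lambda p: (-p.rel_decline, p.interval.sort_key()))
        return [p.interval for p in ranked[:k]]

    sel_c, sel_s = top(ctcf), top(scc1)
    anchors: list[GenomicInterval] = []
    for c in sel_c:
        for s in sel_s:
            if c.chrom == s.chrom and c.start < s.end and s.start < c.end:
                anchors.append(GenomicInterval(c.chrom, min(c.start, s.start),
                                               max(c.end, s.end)))
    anchors = merge_intervals(anchors) if anchors else []
    if not anchors:
        warnings.warn("no overlapping selected CTCF/SCC1 peaks", stacklevel=2)
    return anchors


def pescan(oes: dict[str, OEMatrix], anchors: list[GenomicInterval],
           layout: GenomeLayout, m: int = 10,
           min_sep: float = 1e6, max_sep: float = 10e6) -> PileupResult:
    """Mean (2m+1)^2 O/E sub-matrix over same-arm anchor pairs.

    For each pair (a, b) with a left of b and midpoint separation in
    [min_sep, max_sep], the window centered on (bin_a, bin_b) is accumulated
    with rows following the left anchor. NaN/masked cells are ignored
    per-cell. ``min_sep`` must clear the window off the diagonal.
    """
    some_oe = next(iter(oes.values()))
    bs = some_oe.bin_size
    if min_sep < (2 * m + 1) * bs:
        raise ValueError("min_sep must be at least (2m+1) * bin_size")
    size = 2 * m + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    n_pairs = 0
    by_arm: dict[str, list[int]] = {}
    for a in anchors:
        arm_id, s, e = layout.interval_arm(a)
        by_arm.setdefault(arm_id, []).append((s + e) // 2)
    for arm_id, mids in by_arm.items():
        oe = oes[arm_id]
        n = oe.n_bins
        mids = sorted(mids)
        for i in range(len(mids)):
            for j in range(i + 1, len(mids)):
                sep = abs(mids[j] - mids[i])
                if not (min_sep <= sep <= max_sep):
                    continue
                ba, bb = mids[i] // bs, mids[j] // bs
                if ba - m < 0 or bb + m >= n or ba + m >= n or bb - m < 0:
                    continue
                sub = oe.values[ba - m:ba + m + 1, bb - m:bb + m + 1]
                ok = np.isfinite(sub)
                acc[ok] += sub[ok]
                cnt[ok] += 1
                n_pairs += 1
    if n_pairs == 0:
        raise ValueError(
            f"no eligible anchor pair with separation in [{min_sep}, {max_sep}]")
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return PileupResult(matrix=mean, n_pairs=n_pairs)


def pescan_pairs(oes: dict[str, OEMatrix],
                 pairs: list[tuple[GenomicInterval, GenomicInterval]],
                 layout: GenomeLayout, m: int = 10) -> PileupResult:
    """Aggregate pile-up over explicitly listed anchor pairs (APA on a loop
    list, e.g. BEDPE calls) instead of all pairwise combinations."""
    some_oe = next(iter(oes.values()))
    bs = some_oe.bin_size
    size = 2 * m + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    n_pairs = 0
    for a, b in pairs:
        arm_a, sa, ea = layout.interval_arm(a)
        arm_b, sb, eb = layout.interval_arm(b)
        if arm_a != arm_b:
            continue
        oe = oes[arm_a]
        ba, bb = ((sa + ea) // 2) // bs, ((sb + eb) // 2) // bs
        if ba > bb:
            ba, bb = bb, ba
        if ba - m < 0 or bb + m >= oe.n_bins:
            continue
        sub = oe.values[ba - m:ba + m + 1, bb - m:bb + m + 1]
        ok = np.isfinite(sub)
        acc[ok] += sub[ok]
        cnt[ok] += 1
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no usable anchor pair on any single arm")
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return PileupResult(matrix=mean, n_pairs=n_pairs)


def _resample_bp(track: BinnedTrack, bp_start: float, bp_end: float,
                 n_out: int, arm_length: int) -> np.ndarray:
    """Length-weighted resampling of a piecewise-constant binned track.

    The bp range is cut into ``n_out`` equal segments; each output value is
    the coverage-weighted mean of the track over its segment. Segments
    falling outside the arm, or covered only by masked bins, are NaN.
    """
    bs = track.bin_size
    edges = np.linspace(bp_start, bp_end, n_out + 1)
    vals = np.where(track.mask, 0.0, track.values)
    wts = (~track.mask).astype(float)
    # cumulative integrals at arbitrary bp positions
    cum_v = np.concatenate([[0.0], np.cumsum(vals * bs)])
    cum_w = np.concatenate([[0.0], np.cumsum(wts * bs)])

    def integral(cum: np.ndarray, x: float) -> float:
        x = min(max(x, 0.0), min(track.n_bins * bs, arm_length))
        b = int(x // bs)
        b = min(b, track.n_bins - 1)
        frac = x - b * bs
        per_bp = (cum[b + 1] - cum[b]) / bs
        return cum[b] + per_bp * frac

    out = np.empty(n_out)
    for i in range(n_out):
        lo, hi = edges[i], edges[i + 1]
        if hi <= 0 or lo >= arm_length:
            out[i] = np.nan
            continue
        w = integral(cum_w, hi) - integral(cum_w, lo)
        v = integral(cum_v, hi) - integral(cum_v, lo)
        out[i] = v / w if w > 1e-9 else np.nan
    return out


def aggregate_over_domains(tracks: dict[str, BinnedTrack],
                           domains: list[GenomicInterval],
                           layout: GenomeLayout, k: int = 30) -> DomainAggregate:
    """Scale every domain to 3k positions plus k-position flanks of half the
    domain length on each side; rows are per-domain, the profile is the
    column mean (NaN-skipping)."""
    if not domains:
        raise ValueError("empty domain list")
    rows = []
    for d in domains:
        arm_id, s, e = layout.interval_arm(d)
        tr = tracks[arm_id]
        if e - s < 2 * tr.bin_size:
            raise ValueError(f"domain {d.chrom}:{d.start}-{d.end} shorter than 2 bins")
        arm_len = layout.arm_length(arm_id)
        flank = 0.5 * (e - s)
        left = _resample_bp(tr, s - flank, s, k, arm_len)
        body = _resample_bp(tr, s, e, 3 * k, arm_len)
        right = _resample_bp(tr, e, e + flank, k, arm_len)
        rows.append(np.concatenate([left, body, right]))
    matrix = np.vstack(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(matrix, axis=0)
    return DomainAggregate(profile=profile, matrix=matrix, k=k)
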