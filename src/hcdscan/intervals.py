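"""Interval arithmetic: merging, intersection, coverage, binning.

Small numpy sweep-line implementations; every operation is tested against a
per-base brute-force oracle on toy arms.
"""

from __future__ import annotations

import numpy as np

from .core import BinnedTrack, GenomeLayout, GenomicInterval

__all__ = [
    "merge_intervals",
    "intersect_intervals",
    "total_coverage",
    "coverage_to_track",
    "midpoint_in_any",
]


def _as_arrays(intervals: list[GenomicInterval]) -> dict[str, np.ndarray]:
    """Group intervals by chromosome into sorted (n, 2) start/end arrays."""
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals per chromosome."""
    merged: list[GenomicInterval] = []
    for chrom, arr in sorted(_as_arrays(intervals).items()):
        cur_s, cur_e = arr[0]
        for s, e in arr[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
    return merged


def intersect_intervals(a: list[GenomicInterval],
                        b: list[GenomicInterval]) -> list[GenomicInterval]:
    """Base-pair intersection of two interval sets (each merged first)."""
    am = _as_arrays(merge_intervals(a)) if a else {}
    bm = _as_arrays(merge_intervals(b)) if b else {}
    out: list[GenomicInterval] = []
    for chrom in sorted(set(am) & set(bm)):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i, 0], ys[j, 0])
            e = min(xs[i, 1], ys[j, 1])
            if s < e:
                out.append(GenomicInterval(chrom, int(s), int(e)))
            if xs[i, 1] < ys[j, 1]:
                i += 1
            else:
                j += 1
    return out


def total_coverage(intervals: list[GenomicInterval]) -> int:
    """Total bp covered after merging."""
    if not intervals:
        return 0
    return sum(iv.length for iv in merge_intervals(intervals))


def midpoint_in_any(points: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean membership of points in a sorted, merged (n,2) interval array."""
    if intervals.size == 0:
        return np.zeros(points.shape, dtype=bool)
    idx = np.searchsorted(intervals[:, 0], points, side="right") - 1
    ok = idx >= 0
    res = np.zeros(points.shape, dtype=bool)
    res[ok] = points[ok] < intervals[idx[ok], 1]
    return res


def coverage_to_track(intervals: list[GenomicInterval], layout: GenomeLayout,
                      bin_size: int, reducer: str = "mean") -> dict[str, BinnedTrack]:
    """Bin scored (bedGraph-style) intervals into per-arm tracks.

    Per-base semantics: every covered base carries the reducer-combined score
    of the intervals covering it (mean / sum / max across overlapping
    intervals). A bin's value is then the mean over its *covered* bases for
    ``reducer='mean'``, the sum over bases for ``'sum'``, and the max for
    ``'max'``. Bins with no covered base are masked.
    """
    if reducer not in {"mean", "sum", "max"}:
        raise ValueError(f"unknown reducer {reducer!r}")

    per_arm: dict[str, list[tuple[int, int, float]]] = {a: [] for a in layout.arm_ids}
    for iv in intervals:
        if iv.score is None:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} has no score")
        arm_id, s, e = layout.interval_arm(iv)
        per_arm[arm_id].append((s, e, float(iv.score)))

    tracks: dict[str, BinnedTrack] = {}
    for arm_id in layout.arm_ids:
        n = layout.n_bins(arm_id, bin_size)
        length = layout.arm_length(arm_id)
        ivs = per_arm[arm_id]
        # breakpoint sweep: piecewise-constant per-base profile
        bps = sorted({0, length} | {s for s, _, _ in ivs} | {e for _, e, _ in ivs})
        starts = np.array(bps[:-1], dtype=np.int64)
        ends = np.array(bps[1:], dtype=np.int64)
        seg_sum = np.zeros(len(starts))
        seg_cnt = np.zeros(len(starts))
        seg_max = np.full(len(starts), -np.inf)
        for s, e, sc in ivs:
            i0 = np.searchsorted(starts, s)
            i1 = np.searchsorted(starts, e)
            seg_sum[i0:i1] += sc
            seg_cnt[i0:i1] += 1
            seg_max[i0:i1] = np.maximum(seg_max[i0:i1], sc)
        covered = seg_cnt > 0
        if reducer == "mean":
            base_val = np.where(covered, seg_sum / np.maximum(seg_cnt, 1), 0.0)
        elif reducer == "sum":
            base_val = seg_sum
        else:
            base_val = np.where(covered, seg_max, 0.0)

        values = np.zeros(n)
        weight = np.zeros(n)
        maxes = np.full(n, -np.inf)
        for s0, e0, v, cov in zip(starts, ends, base_val, covered):
            if not cov:
                continue
            b0, b1 = int(s0 // bin_size), int((e0 - 1) // bin_size)
            for b in range(b0, b1 + 1):
                lo = max(int(s0), b * bin_size)
                hi = min(int(e0), (b + 1) * bin_size)
                w = hi - lo
                if w <= 0:
                    continue
                values[b] += v * w
                weight[b] += w
                maxes[b] = max(maxes[b], v)
        mask = weight == 0
        with np.errstate(invalid="ignore"):
            if reducer == "mean":
                out = np.where(mask, np.nan, values / np.maximum(weight, 1))
            elif reducer == "sum":
                out = np.where(mask, np.nan, values)
            else:
                out = np.where(mask, np.nan, maxes)
        tracks[arm_id] = BinnedTrack(arm_id, bin_size, out, mask)
    return tracks
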