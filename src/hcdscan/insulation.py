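"""Insulation scores, TAD-border stratification and HCD-relative position.

The insulation score of bin i is the mean contact count in the w x w square
upstream-by-downstream of the bin (rows i-w..i-1, columns i+1..i+w),
log2-normalized to the arm mean. Low insulation marks a boundary: few
contacts cross it. Higher insulation in the mutant therefore means a
*weakened* border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ContactMatrix, GenomeLayout, GenomicInterval

__all__ = [
    "InsulationProfile",
    "TadBorder",
    "insulation_score",
    "relative_position",
    "stratify_borders",
]


@dataclass
class InsulationProfile:
    arm_id: str
    bin_size: int
    window_bins: int
    raw: np.ndarray          # NaN where masked
    normalized: np.ndarray   # log2(raw / arm mean raw)
    mask: np.ndarray


@dataclass
class TadBorder:
    interval: GenomicInterval
    delta: float                  # mut normalized - wt normalized
    in_hcd: bool
    category: str | None = None   # 'weaker' | 'unchanged' | 'stronger'
    rel_pos: float | None = None  # in [0, 0.5], defined iff in_hcd


def insulation_score(cm: ContactMatrix, w: int = 10) -> InsulationProfile:
    """Sliding-square insulation with window ``w`` bins.

    raw_i = mean of unmasked counts in rows (i-w..i-1) x cols (i+1..i+w);
    bins within ``w`` of either arm end are masked, as are bins whose square
    contains no unmasked cell.
    """
    if w < 2:
        raise ValueError("window must be >= 2 bins")
    n = cm.n_bins
    if n < 3 * w:
        raise ValueError("arm too short for the insulation window")
    counts = cm.counts
    cell_ok = np.outer(~cm.bin_mask, ~cm.bin_mask)
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        sq = counts[i - w:i, i + 1:i + w + 1]
        ok = cell_ok[i - w:i, i + 1:i + w + 1]
        if ok.any():
            raw[i] = sq[ok].mean()
    mask = ~np.isfinite(raw) | cm.bin_mask
    raw[mask] = np.nan
    mean_raw = np.nanmean(raw)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(raw > 0, np.log2(raw / mean_raw), np.nan)
    mask = mask | ~np.isfinite(normalized)
    return InsulationProfile(cm.arm_id, cm.bin_size, w, raw, normalized, mask)


def relative_position(border: GenomicInterval, hcd: GenomicInterval) -> float:
    """min(distance of border midpoint to either HCD edge) / HCD length."""
    m = border.midpoint
    if not (hcd.start <= m < hcd.end) or border.chrom != hcd.chrom:
        raise ValueError("border midpoint not inside the HCD")
    return min(m - hcd.start, hcd.end - m) / hcd.length


def _split_thirds(n: int) -> tuple[int, int, int]:
    """Category sizes (stronger, unchanged, weaker), differing by <= 1.

    Remainders go to 'unchanged' first, then 'weaker'.
    """
    base, rem = divmod(n, 3)
    stronger = unchanged = weaker = base
    if rem >= 1:
        unchanged += 1
    if rem == 2:
        weaker += 1
    return stronger, unchanged, weaker


def stratify_borders(borders: list[GenomicInterval],
                     ins_wt: dict[str, InsulationProfile],
                     ins_mut: dict[str, InsulationProfile],
                     hcds: list[GenomicInterval],
                     layout: GenomeLayout) -> list[TadBorder]:
    """Delta-insulation stratification of TAD borders inside HCDs.

    Borders inside an HCD are ordered by delta = mutant minus wild-type
    normalized insulation at the border's bin (midpoint bin for multi-bin
    borders) and split into three near-equal categories: the highest-delta
    third is 'weaker' (separation lost), the lowest 'stronger', the middle
    'unchanged'. Ties are broken by coordinate. Borders whose bin is masked
    in either profile are dropped with a warning.
    """
    annotated: list[TadBorder] = []
    for b in borders:
        arm_id, s, e = layout.interval_arm(b)
        wt, mut = ins_wt[arm_id], ins_mut[arm_id]
        if wt.bin_size != mut.bin_size:
            raise ValueError("insulation profiles disagree on bin size")
        bin_i = ((s + e) // 2) // wt.bin_size
        if wt.mask[bin_i] or mut.mask[bin_i]:
            warnings.warn(f"border {b.chrom}:{b.start}-{b.end} masked; dropped",
                          stacklevel=2)
            continue
        delta = float(mut.normalized[bin_i] - wt.normalized[bin_i])
        host = next((h for h in hcds
                     if h.chrom == b.chrom and h.start <= b.midpoint < h.end),
                    None)
        tb = TadBorder(interval=b, delta=delta, in_hcd=host is not None)
        if host is not None:
            tb.rel_pos = relative_position(b, host)
        annotated.append(tb)

    inside = [tb for tb in annotated if tb.in_hcd]
    inside.sort(key=lambda tb: (tb.delta, tb.interval.sort_key()))
    n_strong, n_unch, n_weak = _split_thirds(len(inside))
    for tb in inside[:n_strong]:
        tb.category = "stronger"
    for tb in inside[n_strong:n_strong + n_unch]:
        tb.category = "unchanged"
    for tb in inside[n_strong + n_unch:]:
        tb.category = "weaker"
    return annotated
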