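"""Core data containers shared by every pipeline stage.

Coordinates are 0-based half-open throughout (BED convention). All Hi-C and
track computations operate per chromosome arm, never across a centromere;
a :class:`GenomeLayout` defines the arms and how chromosome coordinates
resolve onto them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "BinnedTrack",
    "ContactMatrix",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with optional score and name."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class GenomeLayout:
    """Ordered chromosome-arm decomposition of a genome.

    Parameters
    ----------
    chrom_arms
        Ordered ``(arm_id, chrom_name, length_bp)`` triples. Arms sharing a
        chromosome name are laid out consecutively along that chromosome in
        the order given (p arm then q arm, typically).
    bin_size
        Default bin size in bp for binned representations.
    """

    def __init__(self, chrom_arms: list[tuple[str, str, int]], bin_size: int = 100_000):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        ids = [a[0] for a in chrom_arms]
        if len(set(ids)) != len(ids):
            raise ValueError("arm_ids must be unique")
        for arm_id, chrom, length in chrom_arms:
            if length <= 0:
                raise ValueError(f"arm {arm_id}: length must be positive")
        self.chrom_arms = list(chrom_arms)
        self.bin_size = int(bin_size)
        self._by_id = {a[0]: a for a in chrom_arms}
        # cumulative offset of each arm on its chromosome
        self._offsets: dict[str, int] = {}
        running: dict[str, int] = {}
        for arm_id, chrom, length in chrom_arms:
            self._offsets[arm_id] = running.get(chrom, 0)
            running[chrom] = running.get(chrom, 0) + length

    @property
    def arm_ids(self) -> list[str]:
        return [a[0] for a in self.chrom_arms]

    def arm_length(self, arm_id: str) -> int:
        return self._by_id[arm_id][2]

    def arm_chrom(self, arm_id: str) -> str:
        return self._by_id[arm_id][1]

    def arm_offset(self, arm_id: str) -> int:
        """Start of the arm on its chromosome, in bp."""
        return self._offsets[arm_id]

    def n_bins(self, arm_id: str, bin_size: int | None = None) -> int:
        bs = bin_size or self.bin_size
        return -(-self.arm_length(arm_id) // bs)

    def resolve(self, chrom: str, pos: int) -> tuple[str, int]:
        """Map a chromosome coordinate to ``(arm_id, position_on_arm)``."""
        for arm_id, c, length in self.chrom_arms:
            if c != chrom:
                continue
            off = self._offsets[arm_id]
            if off <= pos < off + length:
                return arm_id, pos - off
        raise KeyError(f"coordinate {chrom}:{pos} resolves to no arm")

    def interval_arm(self, iv: GenomicInterval) -> tuple[str, int, int]:
        """Map an interval to ``(arm_id, start_on_arm, end_on_arm)``.

        The interval must lie entirely within one arm.
        """
        arm_id, s = self.resolve(iv.chrom, iv.start)
        arm_id2, e = self.resolve(iv.chrom, iv.end - 1)
        if arm_id != arm_id2:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} spans arms")
        return arm_id, s, e + 1

    def to_chrom(self, arm_id: str, start: int, end: int,
                 score: float | None = None, name: str | None = None) -> GenomicInterval:
        """Build a chromosome-coordinate interval from arm coordinates."""
        off = self.arm_offset(arm_id)
        return GenomicInterval(self.arm_chrom(arm_id), off + start, off + end,
                               score=score, name=name)


@dataclass
class BinnedTrack:
    """Per-bin values on one arm; ``mask`` marks missing/blacklisted bins."""

    arm_id: str
    bin_size: int
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have equal length")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]


@dataclass
class ContactMatrix:
    """Symmetric binned intra-arm contact counts with a valid-bin mask."""

    arm_id: str
    bin_size: int
    counts: np.ndarray
    bin_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square")
        if not np.allclose(self.counts, self.counts.T, equal_nan=True):
            raise ValueError("counts must be symmetric")
        if np.nanmin(self.counts) < 0:
            raise ValueError("counts must be nonnegative")
        if self.bin_mask is None:
            self.bin_mask = np.zeros(n, dtype=bool)
        self.bin_mask = np.asarray(self.bin_mask, dtype=bool)
        if self.bin_mask.shape != (n,):
            raise ValueError("bin_mask length must match matrix size")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]
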