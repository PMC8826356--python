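"""Plain-text readers and writers: BED, bedGraph, sparse triplet matrices.

Sparse matrices travel as two files, cooler-dump style: a bin table
(``chrom  start  end  bin_index``) and a triplet file
(``bin_index_1  bin_index_2  value``) holding the upper triangle (or any
mix; entries are symmetrized on read). Only intra-arm contacts are kept.
"""

from __future__ import annotations

import os

import numpy as np

from .core import BinnedTrack, ContactMatrix, GenomeLayout, GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph_track",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_dense_matrix",
    "write_dense_matrix",
]


class ParseError(ValueError):
    pass


def read_bed(path: str | os.PathLike, layout: GenomeLayout | None = None,
             sort: bool = True) -> list[GenomicInterval]:
    """Read BED3+ (tab-separated; col 4 name, col 5 score)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 tab-separated fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            if start >= end:
                raise ParseError(f"{path}:{ln}: start >= end")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] != ".":
                score = float(parts[4])
            iv = GenomicInterval(chrom, start, end, score=score, name=name)
            if layout is not None:
                layout.interval_arm(iv)  # raises on unknown chrom / off-arm
            out.append(iv)
    if sort:
        out.sort(key=GenomicInterval.sort_key)
    return out


def write_bed(intervals: list[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=GenomicInterval.sort_key):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read bedGraph: ``chrom start end value`` -> scored intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: bedGraph needs 4 fields")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                       score=float(parts[3])))
    out.sort(key=GenomicInterval.sort_key)
    return out


def write_bedgraph_track(track: BinnedTrack, layout: GenomeLayout,
                         path: str | os.PathLike, mode: str = "w") -> None:
    """Write one arm's binned track as bedGraph (masked bins omitted)."""
    chrom = layout.arm_chrom(track.arm_id)
    off = layout.arm_offset(track.arm_id)
    length = layout.arm_length(track.arm_id)
    with open(path, mode) as fh:
        for i, (v, m) in enumerate(zip(track.values, track.mask)):
            if m:
                continue
            s = off + i * track.bin_size
            e = min(off + (i + 1) * track.bin_size, off + length)
            fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def read_bedpe(path: str | os.PathLike) -> list[tuple[GenomicInterval,
                                                      GenomicInterval]]:
    """Read BEDPE pairs (chrom1 start1 end1 chrom2 start2 end2 ...)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{ln}: BEDPE needs 6 fields")
            out.append((GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                        GenomicInterval(parts[3], int(parts[4]), int(parts[5]))))
    return out


# ---------------------------------------------------------------------------
# sparse triplet contact matrices

def read_contact_matrix(path_triplet: str | os.PathLike,
                        path_bins: str | os.PathLike,
                        layout: GenomeLayout) -> list[ContactMatrix]:
    """Read a bin table + triplet file into one symmetric matrix per arm.

    A bin whose marginal sum is zero is auto-masked (stand-in for
    unmappable/blacklisted bins).
    """
    bins: dict[int, tuple[str, int]] = {}  # bin_index -> (arm_id, arm_bin)
    bin_size = None
    with open(path_bins) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path_bins}:{ln}: expected chrom start end index")
            chrom, start, end, idx = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
            if start >= end:
                raise ParseError(f"{path_bins}:{ln}: start >= end")
            arm_id, s = layout.resolve(chrom, start)
            if bin_size is None:
                bin_size = end - start
            if s % bin_size != 0:
                raise ParseError(f"{path_bins}:{ln}: bin not aligned to bin grid")
            bins[idx] = (arm_id, s // bin_size)
    if bin_size is None:
        raise ParseError(f"{path_bins}: empty bin table")

    mats = {a: np.zeros((layout.n_bins(a, bin_size),) * 2) for a in layout.arm_ids}
    with open(path_triplet) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path_triplet}:{ln}: expected 3 fields")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path_triplet}:{ln}: {exc}") from exc
            if i not in bins or j not in bins:
                raise ParseError(f"{path_triplet}:{ln}: bin index out of range")
            if v < 0:
                raise ParseError(f"{path_triplet}:{ln}: negative count")
            (arm_i, bi), (arm_j, bj) = bins[i], bins[j]
            if arm_i != arm_j:
                continue  # inter-arm contacts discarded
            mats[arm_i][bi, bj] += v
            if bi != bj:
                mats[arm_i][bj, bi] += v

    out = []
    for arm_id in layout.arm_ids:
        m = mats[arm_id]
        mask = m.sum(axis=0) == 0
        out.append(ContactMatrix(arm_id, bin_size, m, mask))
    return out


def write_contact_matrix(cms: list[ContactMatrix], layout: GenomeLayout,
                         path_triplet: str | os.PathLike,
                         path_bins: str | os.PathLike) -> None:
    """Write matrices as a genome-wide bin table + upper-triangle triplets."""
    idx = 0
    index_of: dict[tuple[str, int], int] = {}
    with open(path_bins, "w") as fh:
        for cm in cms:
            chrom = layout.arm_chrom(cm.arm_id)
            off = layout.arm_offset(cm.arm_id)
            length = layout.arm_length(cm.arm_id)
            for b in range(cm.n_bins):
                s = off + b * cm.bin_size
                e = min(off + (b + 1) * cm.bin_size, off + length)
                fh.write(f"{chrom}\t{s}\t{e}\t{idx}\n")
                index_of[(cm.arm_id, b)] = idx
                idx += 1
    with open(path_triplet, "w") as fh:
        for cm in cms:
            iu, ju = np.nonzero(np.triu(cm.counts))
            for bi, bj in zip(iu, ju):
                v = cm.counts[bi, bj]
                fh.write(f"{index_of[(cm.arm_id, bi)]}\t"
                         f"{index_of[(cm.arm_id, bj)]}\t{float(v)!r}\n")


def read_dense_matrix(path: str | os.PathLike, arm_id: str,
                      bin_size: int) -> ContactMatrix:
    m = np.loadtxt(path)
    mask = m.sum(axis=0) == 0
    return ContactMatrix(arm_id, bin_size, m, mask)


def write_dense_matrix(cm: ContactMatrix, path: str | os.PathLike) -> None:
    np.savetxt(path, cm.counts, fmt="%.10g")
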