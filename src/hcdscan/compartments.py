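"""Observed-over-expected normalization, compartment score and strength.

Per chromosome arm: the O/E matrix divides observed counts by the mean count
at each genomic distance (diagonal mean over unmasked bins). The compartment
score is the leading eigenvector of (O/E - 1) scaled by the square root of
its eigenvalue, oriented so that it correlates positively with H3K4me1
(active chromatin). Compartment strength contrasts homotypic and heterotypic
mean O/E among the top/bottom 20% scoring bins::

    strength = log2( (AA * BB) / AB**2 )

Larger strength means stronger A/B segregation of the arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .core import BinnedTrack, ContactMatrix

__all__ = [
    "OEMatrix",
    "CompartmentProfile",
    "CompartmentStrength",
    "compute_oe",
    "compartment_score",
    "compartment_strength",
    "compartment_score_delta",
]


@dataclass
class OEMatrix:
    arm_id: str
    bin_size: int
    values: np.ndarray      # NaN where masked / undefined
    bin_mask: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class CompartmentProfile:
    arm_id: str
    bin_size: int
    score: np.ndarray       # NaN at masked bins
    mask: np.ndarray
    eigenvalue: float
    oriented: bool = False
    orientation_corr: float = float("nan")


@dataclass
class CompartmentStrength:
    arm_id: str
    AA: float
    BB: float
    AB: float

    @property
    def strength(self) -> float:
        return float(np.log2(self.AA * self.BB / self.AB**2))


def compute_oe(cm: ContactMatrix) -> OEMatrix:
    """Observed/expected with expected = per-diagonal mean over unmasked bins.

    Entries on diagonals whose expected value is zero, and all entries
    touching a masked bin, are NaN.
    """
    n = cm.n_bins
    valid = ~cm.bin_mask
    if valid.sum() < 10:
        raise ValueError("need at least 10 unmasked bins")
    counts = cm.counts
    oe = np.full((n, n), np.nan)
    vv = np.outer(valid, valid)
    for d in range(n):
        idx = np.arange(n - d)
        obs = counts[idx, idx + d]
        ok = vv[idx, idx + d]
        if not ok.any():
            continue
        expected = obs[ok].mean()
        if expected <= 0:
            continue
        vals = np.where(ok, obs / expected, np.nan)
        oe[idx, idx + d] = vals
        oe[idx + d, idx] = vals
    return OEMatrix(cm.arm_id, cm.bin_size, oe, cm.bin_mask.copy())


def _leading_eigpair(sym: np.ndarray) -> tuple[float, np.ndarray]:
    """Eigenpair with largest eigenvalue >= 0, else largest |eigenvalue|."""
    w, v = linalg.eigh(sym)
    nonneg = w >= 0
    i = int(np.argmax(w)) if nonneg.any() else int(np.argmax(np.abs(w)))
    return float(w[i]), v[:, i]


def compartment_score(oe: OEMatrix,
                      orientation_track: BinnedTrack | None = None
                      ) -> CompartmentProfile:
    """Compartment score: leading eigenvector of (O/E - 1) times sqrt(|lambda|).

    If an orientation track (mean H3K4me1 per bin) is given and the Pearson
    correlation between score and track over unmasked bins is negative, the
    score is negated so positive = active (A) compartment.
    """
    valid = ~oe.bin_mask
    if valid.sum() < 10:
        raise ValueError("need at least 10 unmasked bins")
    sub = oe.values[np.ix_(valid, valid)] - 1.0
    sub = np.nan_to_num(sub, nan=0.0)  # zero-expected diagonals treated neutral
    lam, vec = _leading_eigpair(sub)
    if lam < 0:
        warnings.warn("leading eigenvalue negative; using sqrt(|lambda|)",
                      stacklevel=2)
    score = np.full(oe.n_bins, np.nan)
    score[valid] = vec * np.sqrt(abs(lam))

    oriented = False
    corr = float("nan")
    if orientation_track is not None:
        if orientation_track.bin_size != oe.bin_size:
            raise ValueError("orientation track bin size mismatch")
        both = valid & ~orientation_track.mask
        if both.sum() >= 3:
            corr, _ = stats.pearsonr(score[both], orientation_track.values[both])
            corr = float(corr)
            if corr < 0:
                score = -score
                corr = -corr
            if corr != 0:
                oriented = True
    return CompartmentProfile(oe.arm_id, oe.bin_size, score, oe.bin_mask.copy(),
                              eigenvalue=lam, oriented=oriented,
                              orientation_corr=corr)


def compartment_strength(oe: OEMatrix, profile: CompartmentProfile,
                         quantile: float = 0.20) -> CompartmentStrength:
    """Mean O/E within A-A, B-B and A-B pairs of top/bottom-quantile bins.

    A = unmasked bins in the top ``quantile`` of the compartment score,
    B = bottom ``quantile``; ties at the cutoff are broken by ascending bin
    index. Self-pairs (i = j) and NaN O/E entries are excluded.
    """
    valid = np.flatnonzero(~profile.mask & ~oe.bin_mask)
    scores = profile.score[valid]
    n = valid.size
    k = int(np.floor(quantile * n))
    if k < 5:
        raise ValueError("fewer than 5 bins per compartment class")
    order = np.lexsort((valid, scores))  # score asc, ties by bin index
    b_bins = valid[order[:k]]
    a_bins = valid[order[-k:]]

    def pair_mean(rows: np.ndarray, cols: np.ndarray, same: bool) -> float:
        sub = oe.values[np.ix_(rows, cols)]
        if same:
            iu = np.triu_indices(len(rows), k=1)
            vals = sub[iu]
        else:
            vals = sub.ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no finite O/E pairs in compartment class")
        return float(vals.mean())

    return CompartmentStrength(
        oe.arm_id,
        AA=pair_mean(a_bins, a_bins, True),
        BB=pair_mean(b_bins, b_bins, True),
        AB=pair_mean(a_bins, b_bins, False),
    )


def compartment_score_delta(wt: CompartmentProfile, mut: CompartmentProfile
                            ) -> tuple[BinnedTrack, BinnedTrack]:
    """Signed (mut - wt) and absolute compartment-score difference tracks."""
    if wt.bin_size != mut.bin_size or wt.arm_id != mut.arm_id:
        raise ValueError("profiles must share arm and bin size")
    if wt.score.size != mut.score.size:
        raise ValueError("profiles must have equal length")
    mask = wt.mask | mut.mask
    signed = np.where(mask, np.nan, mut.score - wt.score)
    return (BinnedTrack(wt.arm_id, wt.bin_size, signed, mask),
            BinnedTrack(wt.arm_id, wt.bin_size, np.abs(signed), mask))
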