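"""Hypercompartmentalized-domain (HCD) calling.

A single two-state Gaussian HMM is fitted jointly on all chromosome arms at
40 kb resolution, with two responses per bin: the mutant compartment score
and the absolute wild-type/mutant score difference. One state captures bins
with a stable score, the other bins whose score changed (the "differential"
state, identified after fitting as the state with the larger mean absolute
difference). Each arm is then decoded separately and two filters are
applied: a called region must consist of at least five consecutive
differential-state bins, and its mean mutant compartment score must be
negative (B compartment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compartments import CompartmentProfile
from .core import GenomeLayout, GenomicInterval
from .hmm import DiagGaussianHMM

__all__ = [
    "HcdObservations",
    "HcdModel",
    "HcdCall",
    "HcdCallSet",
    "build_observations",
    "fit_hcd_hmm",
    "decode_states",
    "call_hcds",
    "MIN_RUN_BINS",
]

MIN_RUN_BINS = 5  # >= 5 consecutive differential bins (200 kb at 40 kb)


@dataclass
class HcdObservations:
    """Per-arm observation matrix: columns (score_mut, |score_mut - score_wt|)."""

    arm_id: str
    bin_size: int
    obs: np.ndarray          # (n_bins, 2); NaN at masked bins
    mask: np.ndarray

    def runs(self) -> list[tuple[int, np.ndarray]]:
        """Contiguous unmasked runs as (start_bin, observation block)."""
        out = []
        n = self.obs.shape[0]
        i = 0
        while i < n:
            if self.mask[i]:
                i += 1
                continue
            j = i
            while j < n and not self.mask[j]:
                j += 1
            out.append((i, self.obs[i:j]))
            i = j
        return out


@dataclass
class HcdModel:
    hmm: DiagGaussianHMM
    differential_state: int

    @property
    def means(self) -> np.ndarray:
        return self.hmm.means_

    @property
    def variances(self) -> np.ndarray:
        return self.hmm.variances_

    @property
    def transition(self) -> np.ndarray:
        return self.hmm.transition_

    @property
    def log_likelihood(self) -> float:
        return self.hmm.log_likelihood_

    @property
    def converged(self) -> bool:
        return self.hmm.converged_


@dataclass
class HcdCall:
    interval: GenomicInterval
    mean_mut_score: float
    mean_abs_delta: float
    n_bins: int


@dataclass
class HcdCallSet:
    calls: list[HcdCall] = field(default_factory=list)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [c.interval for c in self.calls]


def build_observations(wt: CompartmentProfile, mut: CompartmentProfile
                       ) -> HcdObservations:
    """Stack mutant score and |mut - wt| into the HMM observation matrix."""
    if wt.bin_size != mut.bin_size or wt.arm_id != mut.arm_id:
        raise ValueError("profiles must share arm and bin size")
    mask = wt.mask | mut.mask | ~np.isfinite(wt.score) | ~np.isfinite(mut.score)
    obs = np.column_stack([mut.score, np.abs(mut.score - wt.score)])
    obs[mask] = np.nan
    return HcdObservations(wt.arm_id, wt.bin_size, obs, mask)


def fit_hcd_hmm(obs_all_arms: list[HcdObservations], seed: int = 0,
                n_restarts: int = 5, tol: float = 1e-6,
                max_iter: int = 500) -> HcdModel:
    """Fit one two-state model jointly across arms (arms = independent runs)."""
    sequences = [blk for o in obs_all_arms for _, blk in o.runs()]
    total = sum(len(s) for s in sequences)
    if total < 100:
        raise ValueError("need at least 100 unmasked bins to fit")
    hmm = DiagGaussianHMM(n_states=2, tol=tol, max_iter=max_iter,
                          n_restarts=n_restarts, seed=seed).fit(sequences)
    # the differential state has the larger mean |delta| response
    differential = int(np.argmax(hmm.means_[:, 1]))
    return HcdModel(hmm=hmm, differential_state=differential)


def decode_states(model: HcdModel, obs: HcdObservations,
                  method: str = "viterbi") -> np.ndarray:
    """Per-bin state labels for one arm; masked bins are -1 and break paths."""
    if method not in {"viterbi", "posterior"}:
        raise ValueError("method must be 'viterbi' or 'posterior'")
    states = np.full(obs.obs.shape[0], -1, dtype=int)
    for start, blk in obs.runs():
        if method == "viterbi":
            path = model.hmm.viterbi(blk)
        else:
            path = model.hmm.posterior(blk).argmax(axis=1)
        states[start:start + len(blk)] = path
    return states


def call_hcds(states_by_arm: dict[str, np.ndarray],
              obs_by_arm: dict[str, HcdObservations],
              model: HcdModel, layout: GenomeLayout,
              min_run: int = MIN_RUN_BINS,
              score_filter: str = "region") -> HcdCallSet:
    """Apply the run-length and negative-score filters to decoded states.

    ``score_filter='region'`` keeps a run when its *mean* mutant score is
    negative; ``'bin'`` requires every bin's mutant score to be negative.
    """
    if score_filter not in {"region", "bin"}:
        raise ValueError("score_filter must be 'region' or 'bin'")
    calls: list[HcdCall] = []
    for arm_id, states in states_by_arm.items():
        obs = obs_by_arm[arm_id]
        bs = obs.bin_size
        diff = model.differential_state
        n = states.size
        i = 0
        while i < n:
            if states[i] != diff:
                i += 1
                continue
            j = i
            while j < n and states[j] == diff:
                j += 1
            if j - i >= min_run:
                mut_scores = obs.obs[i:j, 0]
                abs_delta = obs.obs[i:j, 1]
                keep = (np.nanmean(mut_scores) < 0 if score_filter == "region"
                        else bool(np.all(mut_scores < 0)))
                if keep:
                    end_bp = min(j * bs, layout.arm_length(arm_id))
                    calls.append(HcdCall(
                        interval=layout.to_chrom(arm_id, i * bs, end_bp),
                        mean_mut_score=float(np.nanmean(mut_scores)),
                        mean_abs_delta=float(np.nanmean(abs_delta)),
                        n_bins=j - i))
            i = j
    calls.sort(key=lambda c: c.interval.sort_key())
    return HcdCallSet(calls)
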