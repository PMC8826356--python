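"""End-to-end drivers over the synthetic paired-condition scenario.

These functions wire the stages together exactly as the analysis scripts
run them: simulate wild-type and mutant contact matrices and tracks, score
compartments per arm, call HCDs from the two-response HMM, and evaluate
calls against the planted truth. They exist so the scripted analyses, the
test suite and the acceptance harness all execute one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import compartments as comp
from . import hcd
from .core import BinnedTrack, ContactMatrix, GenomeLayout, GenomicInterval
from .simulate import (SimulationParams, SimulationTruth, plant_truth,
                       simulate_contact_matrix, simulate_tracks)
from .stats import interval_overlap_stats

__all__ = [
    "ScenarioData",
    "simulate_scenario",
    "compartment_profiles",
    "run_hcd_calling",
    "truth_jaccard",
]


@dataclass
class ScenarioData:
    params: SimulationParams
    truth: dict[str, SimulationTruth]
    matrices: dict[str, dict[str, ContactMatrix]]          # condition -> arm
    tracks: dict[str, dict[str, dict[str, BinnedTrack]]]   # condition -> factor -> arm
    oes: dict[str, dict[str, comp.OEMatrix]] = field(default_factory=dict)
    profiles: dict[str, dict[str, comp.CompartmentProfile]] = field(default_factory=dict)


def simulate_scenario(params: SimulationParams,
                      with_tracks: bool = True) -> ScenarioData:
    """Simulate both conditions with shared planted truth."""
    truth = plant_truth(params)
    matrices = {}
    tracks = {}
    for cond in ("wt", "mut"):
        cms, _ = simulate_contact_matrix(params, cond, truth)
        matrices[cond] = cms
        if with_tracks:
            tracks[cond] = simulate_tracks(params, truth, cond)
    return ScenarioData(params=params, truth=truth,
                        matrices=matrices, tracks=tracks)


def compartment_profiles(data: ScenarioData) -> ScenarioData:
    """O/E + oriented compartment score for every arm and condition.

    Orientation uses the wild-type H3K4me1-like track (active chromatin)
    for both conditions, as a shared reference.
    """
    for cond in ("wt", "mut"):
        data.oes[cond] = {}
        data.profiles[cond] = {}
        for arm_id, cm in data.matrices[cond].items():
            oe = comp.compute_oe(cm)
            track = None
            if data.tracks:
                track = data.tracks["wt"]["H3K4me1"][arm_id]
            data.oes[cond][arm_id] = oe
            data.profiles[cond][arm_id] = comp.compartment_score(oe, track)
    return data


def run_hcd_calling(data: ScenarioData, seed: int = 0,
                    n_restarts: int = 3) -> tuple[hcd.HcdCallSet, hcd.HcdModel]:
    """Fit the two-state HMM jointly on all arms and call HCDs."""
    if not data.profiles:
        compartment_profiles(data)
    obs_by_arm = {
        arm_id: hcd.build_observations(data.profiles["wt"][arm_id],
                                       data.profiles["mut"][arm_id])
        for arm_id in data.params.layout.arm_ids}
    model = hcd.fit_hcd_hmm(list(obs_by_arm.values()), seed=seed,
                            n_restarts=n_restarts)
    states = {arm_id: hcd.decode_states(model, o)
              for arm_id, o in obs_by_arm.items()}
    calls = hcd.call_hcds(states, obs_by_arm, model, data.params.layout)
    return calls, model


def truth_jaccard(calls: list[GenomicInterval],
                  truth: dict[str, SimulationTruth]) -> float:
    """Base-pair Jaccard between called intervals and planted truth HCDs."""
    truth_ivs = [iv for t in truth.values() for iv in t.hcd_regions]
    if not calls and not truth_ivs:
        return 1.0
    if not calls or not truth_ivs:
        return 0.0
    return interval_overlap_stats(calls, truth_ivs).jaccard


def sign_agreement(profile: comp.CompartmentProfile,
                   truth: SimulationTruth) -> float:
    """Fraction of unmasked bins whose score sign matches the planted label."""
    valid = ~profile.mask & np.isfinite(profile.score)
    sigma = np.where(truth.ab_labels == "A", 1.0, -1.0)
    agree = np.sign(profile.score[valid]) == sigma[valid]
    return float(agree.mean())
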