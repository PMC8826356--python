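"""Paired-condition synthetic Hi-C and ChIP-like data with planted truth.

The generator emulates the contrast between a wild-type and a mutant in
which B–B compartment affinity strengthens inside designated "truth" HCD
regions: distance-decay contact matrices with alternating A/B blocks, planted
TAD boundaries and loop anchors, an H3K9me3-like track elevated in B/domain
bins, an H3K4me1-like track elevated in A bins, and CTCF/SCC1-like peak
tracks whose mutant amplitude declines preferentially inside domains.

Expected contact count between bins i and j::

    E[o_ij] = depth * Z * (1 + |i-j|)**(-alpha) * c_ij * t_ij * l_ij

with ``c_ij = 1 + k_eff * sigma_i * sigma_j`` (sigma = +1 in A, -1 in B;
``k_eff = k_comp * boost`` when both bins lie in a truth HCD and the
condition is mutant, else ``k_comp``), ``t_ij = tad_insulation_factor`` per
planted TAD border strictly between i and j, ``l_ij = loop_strength`` within
one bin of a planted anchor pair, and Z chosen so the expected total equals
``depth``. Counts are Poisson draws of the symmetric mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinnedTrack, ContactMatrix, GenomeLayout, GenomicInterval

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "standard_scenario",
    "plant_truth",
    "simulate_contact_matrix",
    "simulate_tracks",
    "simulate_expression",
]

_COND_CODE = {"wt": 0, "mut": 1}


@dataclass
class SimulationParams:
    """All knobs of the paired-condition generator (defaults = study conditions)."""

    layout: GenomeLayout
    seed: int = 0
    depth: float = 1e7                 # expected total reads per arm
    decay_exponent: float = 1.0        # alpha of (1+d)^-alpha
    k_comp: float = 0.2                # compartment checkerboard amplitude
    block_size_range: tuple[float, float] = (1e6, 3e6)   # A/B block sizes, bp
    hcd_truth_fraction: float = 1.0    # fraction of B blocks boosted in mut
    boost: float = 2.5                 # multiplier on k_comp inside truth HCDs
    tad_boundary_spacing: float = 1e6  # bp between planted TAD borders
    tad_insulation_factor: float = 0.5
    loop_anchors: int = 10             # anchor pairs per arm
    loop_strength: float = 3.0
    tad_crossing_cap: int | None = 1   # max borders counted per contact
    peak_count: int = 200              # CTCF/SCC1 peaks per arm
    decline_factor: float = 0.2        # mutant peak amplitude inside domains
    track_noise: float = 0.1           # Gamma-Poisson dispersion

    def validate(self) -> None:
        if self.depth <= 0 or self.decay_exponent <= 0:
            raise ValueError("depth and decay_exponent must be positive")
        if not 0 <= self.k_comp < 1:
            raise ValueError("k_comp must be in [0, 1)")
        if self.k_comp * self.boost >= 1:
            raise ValueError("k_comp * boost must stay below 1 "
                             "(expected contacts must remain positive)")
        if not 0 < self.tad_insulation_factor <= 1:
            raise ValueError("tad_insulation_factor must be in (0, 1]")
        if not 0 < self.decline_factor <= 1:
            raise ValueError("decline_factor must be in (0, 1]")
        if self.loop_strength < 1:
            raise ValueError("loop_strength must be >= 1")
        if self.track_noise < 0:
            raise ValueError("track_noise must be >= 0")
        lo, hi = self.block_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid block_size_range")


@dataclass
class SimulationTruth:
    """Planted ground truth for one arm (chromosome coordinates)."""

    arm_id: str
    ab_labels: np.ndarray                       # per-bin 'A'/'B'
    hcd_regions: list[GenomicInterval]
    tad_borders: list[int]                      # bin indices on the arm
    loop_anchor_pairs: list[tuple[GenomicInterval, GenomicInterval]]
    loop_anchors: list[GenomicInterval] = field(default_factory=list)
    declining_peaks: list[GenomicInterval] = field(default_factory=list)
    domain_regions: list[GenomicInterval] = field(default_factory=list)
    peak_positions: list[int] = field(default_factory=list)   # bp on arm


def standard_scenario(layout: GenomeLayout | None = None, seed: int = 0,
                      **overrides) -> SimulationParams:
    """The default paired-condition scenario used throughout the test-bench."""
    if layout is None:
        layout = GenomeLayout([("chr1p", "chr1", 40_000_000),
                               ("chr2p", "chr2", 40_000_000)], bin_size=100_000)
    p = SimulationParams(layout=layout, seed=seed)
    for k, v in overrides.items():
        setattr(p, k, v)
    p.validate()
    return p


def depth_for_min_class_reads(n_bins: int, alpha: float = 1.0,
                              min_reads: float = 100.0) -> float:
    """Total depth so the sparsest distance class averages ``min_reads``/pair.

    The farthest diagonal is the sparsest; solving
    ``depth * (1+d_max)^-alpha / S >= min_reads`` with S the decay-weight sum
    over all ordered bin pairs gives the required total.
    """
    d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    S = ((1.0 + d) ** (-alpha)).sum()
    return float(min_reads * S * n_bins**alpha)


def _truth_rng(params: SimulationParams) -> np.random.Generator:
    return np.random.default_rng([int(params.seed) % (2**31), 7])


def plant_truth(params: SimulationParams) -> dict[str, SimulationTruth]:
    """Draw the planted structure (shared by both conditions) per arm.

    Deterministic given ``(params, seed)``; the contact and track samplers
    consume this truth so wild-type and mutant share identical geometry.
    """
    params.validate()
    rng = _truth_rng(params)
    layout = params.layout
    bs = layout.bin_size
    truths: dict[str, SimulationTruth] = {}
    for arm_id in layout.arm_ids:
        n = layout.n_bins(arm_id)
        length = layout.arm_length(arm_id)

        # alternating A/B blocks with sizes uniform in block_size_range
        labels = np.empty(n, dtype="<U1")
        b_blocks: list[tuple[int, int]] = []
        pos = 0
        state = "A" if rng.random() < 0.5 else "B"
        while pos < n:
            size_bp = rng.uniform(*params.block_size_range)
            size = max(1, int(round(size_bp / bs)))
            end = min(n, pos + size)
            labels[pos:end] = state
            if state == "B":
                b_blocks.append((pos, end))
            pos = end
            state = "B" if state == "A" else "A"

        # truth HCDs: a fraction of B blocks, strengthened in the mutant
        n_hcd = max(1, int(round(params.hcd_truth_fraction * len(b_blocks))))
        chosen = sorted(rng.choice(len(b_blocks), size=min(n_hcd, len(b_blocks)),
                                   replace=False))
        hcds = [layout.to_chrom(arm_id, b_blocks[c][0] * bs,
                                min(b_blocks[c][1] * bs, length)) for c in chosen]

        # planted TAD borders at regular spacing (skipping arm ends)
        step = max(2, int(round(params.tad_boundary_spacing / bs)))
        borders = list(range(step, n - 1, step))

        # loop anchor loci (CTCF/cohesin-like sites); loops form between
        # every same-arm pair of loci 1-10 Mb apart
        anchor_bins = sorted(int(b) for b in rng.choice(
            n, size=min(params.loop_anchors, n), replace=False))
        loci = [layout.to_chrom(arm_id, a * bs, min((a + 1) * bs, length))
                for a in anchor_bins]
        lo_sep, hi_sep = max(2, int(1e6 / bs)), max(3, int(10e6 / bs))
        pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
        for i in range(len(anchor_bins)):
            for j in range(i + 1, len(anchor_bins)):
                if lo_sep <= anchor_bins[j] - anchor_bins[i] <= hi_sep:
                    pairs.append((loci[i], loci[j]))

        # H3K9me3-high domains = all B blocks
        domains = [layout.to_chrom(arm_id, s * bs, min(e * bs, length))
                   for s, e in b_blocks]

        # shared CTCF/SCC1 peak positions (bp on arm)
        peak_pos = sorted(int(p) for p in rng.uniform(500, length - 500,
                                                      params.peak_count))

        truths[arm_id] = SimulationTruth(
            arm_id=arm_id, ab_labels=labels, hcd_regions=hcds,
            tad_borders=borders, loop_anchor_pairs=pairs, loop_anchors=loci,
            domain_regions=domains, peak_positions=peak_pos)
    return truths


def expected_contact_matrix(params: SimulationParams, truth: SimulationTruth,
                            condition: str) -> np.ndarray:
    """Noise-free expected counts for one arm under one condition."""
    if condition not in _COND_CODE:
        raise ValueError(f"condition must be 'wt' or 'mut', got {condition!r}")
    layout = params.layout
    bs = layout.bin_size
    n = truth.ab_labels.size
    sigma = np.where(truth.ab_labels == "A", 1.0, -1.0)

    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mean = (1.0 + d) ** (-params.decay_exponent)

    k = np.full((n, n), params.k_comp)
    if condition == "mut":
        in_hcd = np.zeros(n, dtype=bool)
        off = layout.arm_offset(truth.arm_id)
        for iv in truth.hcd_regions:
            b0 = (iv.start - off) // bs
            b1 = -(-(iv.end - off) // bs)
            in_hcd[b0:b1] = True
        both = np.outer(in_hcd, in_hcd)
        k = np.where(both, params.k_comp * params.boost, k)
    mean *= 1.0 + k * np.outer(sigma, sigma)

    if params.tad_insulation_factor < 1 and truth.tad_borders:
        # border index b = boundary at the left edge of bin b;
        # t_ij = factor ** (#boundaries with i < b <= j), capped so TAD
        # insulation stays a local effect and does not crush long-range counts
        bord = np.asarray(truth.tad_borders)
        ss = np.searchsorted(bord, np.arange(n), side="right")
        crossings = np.abs(np.subtract.outer(ss, ss))
        if params.tad_crossing_cap is not None:
            crossings = np.minimum(crossings, params.tad_crossing_cap)
        mean *= params.tad_insulation_factor ** crossings

    if params.loop_strength > 1 and truth.loop_anchor_pairs:
        off = layout.arm_offset(truth.arm_id)
        boost = np.ones((n, n))
        for a_iv, b_iv in truth.loop_anchor_pairs:
            a = (a_iv.midpoint - off) // bs
            b = (b_iv.midpoint - off) // bs
            lo_a, hi_a = max(0, a - 1), min(n, a + 2)
            lo_b, hi_b = max(0, b - 1), min(n, b + 2)
            boost[lo_a:hi_a, lo_b:hi_b] = params.loop_strength
            boost[lo_b:hi_b, lo_a:hi_a] = params.loop_strength
        mean *= boost

    if np.any(mean <= 0):
        raise ValueError("expected contact mean non-positive; check parameters")
    mean *= params.depth / mean.sum()
    return mean


def simulate_contact_matrix(params: SimulationParams, condition: str,
                            truth: dict[str, SimulationTruth] | None = None,
                            ) -> tuple[dict[str, ContactMatrix], dict[str, SimulationTruth]]:
    """Sample Poisson contact matrices for every arm under one condition."""
    params.validate()
    if truth is None:
        truth = plant_truth(params)
    cms: dict[str, ContactMatrix] = {}
    for arm_idx, arm_id in enumerate(params.layout.arm_ids):
        mean = expected_contact_matrix(params, truth[arm_id], condition)
        rng = np.random.default_rng(
            [int(params.seed) % (2**31), _COND_CODE[condition], arm_idx])
        n = mean.shape[0]
        upper = rng.poisson(np.triu(mean))
        counts = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diag(upper))
        mask = counts.sum(axis=0) == 0
        cms[arm_id] = ContactMatrix(arm_id, params.layout.bin_size,
                                    counts.astype(float), mask)
    return cms, truth


def _gamma_poisson(rng: np.random.Generator, mean: np.ndarray,
                   dispersion: float) -> np.ndarray:
    """Negative-binomial-like draws: Poisson with Gamma-jittered mean."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion**2
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(float)


def simulate_tracks(params: SimulationParams, truth: dict[str, SimulationTruth],
                    condition: str) -> dict[str, dict[str, BinnedTrack]]:
    """ChIP-like per-bin tracks: {factor: {arm_id: BinnedTrack}}.

    H3K9me3 mean is 5x baseline inside domain regions; H3K4me1 is 5x outside
    them. CTCF/SCC1 are baseline plus Gaussian-shaped peaks at the shared
    planted positions; in the mutant, peaks inside domains have their
    amplitude multiplied by ``decline_factor``. The mutant-declining peak
    footprints are recorded in ``truth[arm].declining_peaks``.
    """
    if condition not in _COND_CODE:
        raise ValueError(f"condition must be 'wt' or 'mut', got {condition!r}")
    layout = params.layout
    bs = layout.bin_size
    baseline, high = 10.0, 50.0
    peak_amp, peak_sd_bp = 200.0, bs * 0.6
    out: dict[str, dict[str, BinnedTrack]] = {f: {} for f in
                                              ("H3K9me3", "H3K4me1", "CTCF", "SCC1")}
    for arm_idx, arm_id in enumerate(layout.arm_ids):
        t = truth[arm_id]
        n = t.ab_labels.size
        off = layout.arm_offset(arm_id)
        in_domain = np.zeros(n, dtype=bool)
        for iv in t.domain_regions:
            in_domain[(iv.start - off) // bs: -(-(iv.end - off) // bs)] = True

        rng = np.random.default_rng([int(params.seed) % (2**31),
                                     _COND_CODE[condition], arm_idx, 99])
        mean_k9 = np.where(in_domain, high, baseline)
        mean_k4 = np.where(in_domain, baseline, high)
        out["H3K9me3"][arm_id] = BinnedTrack(
            arm_id, bs, _gamma_poisson(rng, mean_k9, params.track_noise),
            np.zeros(n, dtype=bool))
        out["H3K4me1"][arm_id] = BinnedTrack(
            arm_id, bs, _gamma_poisson(rng, mean_k4, params.track_noise),
            np.zeros(n, dtype=bool))

        centers = np.asarray(t.peak_positions, dtype=float)
        peak_in_domain = in_domain[np.minimum((centers // bs).astype(int), n - 1)]
        # per-site decline severity, shared by CTCF and SCC1 (the same
        # cohesin-loss event hits both factors at a co-bound site)
        sev_rng = np.random.default_rng([int(params.seed) % (2**31), 7,
                                         arm_idx, 5])
        mut_multiplier = np.clip(
            params.decline_factor * sev_rng.lognormal(0.0, 0.3, centers.size),
            0.0, 1.0)
        if params.decline_factor >= 1.0:
            mut_multiplier = np.ones(centers.size)
        declining = [
            GenomicInterval(layout.arm_chrom(arm_id),
                            max(off, int(off + c - 2 * peak_sd_bp)),
                            min(off + layout.arm_length(arm_id),
                                int(off + c + 2 * peak_sd_bp)))
            for c, ind in zip(centers, peak_in_domain) if ind]
        if condition == "mut" and not t.declining_peaks:
            t.declining_peaks = declining

        bin_centers = (np.arange(n) + 0.5) * bs
        # amplitude-jitter is part of the truth stream so both conditions
        # share per-peak baseline amplitudes
        amp_rng = np.random.default_rng([int(params.seed) % (2**31), 7, arm_idx, 3])
        for factor in ("CTCF", "SCC1"):
            amps = peak_amp * amp_rng.lognormal(0.0, 0.25, centers.size)
            eff = amps.copy()
            if condition == "mut":
                eff[peak_in_domain] *= mut_multiplier[peak_in_domain]
            prof = np.full(n, baseline)
            for c, a in zip(centers, eff):
                lo = max(0, int((c - 4 * peak_sd_bp) // bs))
                hi = min(n, int((c + 4 * peak_sd_bp) // bs) + 1)
                prof[lo:hi] += a * np.exp(
                    -0.5 * ((bin_centers[lo:hi] - c) / peak_sd_bp) ** 2)
            out[factor][arm_id] = BinnedTrack(
                arm_id, bs, _gamma_poisson(rng, prof, params.track_noise),
                np.zeros(n, dtype=bool))
    return out


def simulate_expression(params: SimulationParams,
                        truth: dict[str, SimulationTruth],
                        n_genes: int = 120, n_samples: int = 6,
                        silenced_fraction: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy gene x sample TPM table for genes inside H3K9me3-like domains.

    Half the samples are wild-type, half mutant. A ``silenced_fraction`` of
    the domain genes is silenced in the mutant samples (TPM drawn near zero),
    mimicking a cluster of genes switched off inside heterochromatin domains.

    Returns ``(tpm, gene_table)`` where ``gene_table`` has gene coordinates
    and the planted cluster label.
    """
    rng = np.random.default_rng([int(params.seed) % (2**31), 55])
    layout = params.layout
    genes, rows, labels = [], [], []
    domains = [iv for t in truth.values() for iv in t.domain_regions]
    for g in range(n_genes):
        iv = domains[int(rng.integers(len(domains)))]
        start = int(rng.integers(iv.start, max(iv.start + 1, iv.end - 1000)))
        genes.append((f"gene{g:04d}", iv.chrom, start, start + 1000))
    n_sil = int(round(silenced_fraction * n_genes))
    sil = set(rng.choice(n_genes, n_sil, replace=False).tolist())
    cols = [f"wt_{i}" for i in range(n_samples // 2)] + \
           [f"mut_{i}" for i in range(n_samples - n_samples // 2)]
    for g in range(n_genes):
        base = rng.lognormal(3.0, 0.5)
        wt = rng.normal(base, 0.05 * base, n_samples // 2)
        if g in sil:
            mut = np.abs(rng.normal(0.05 * base, 0.02 * base,
                                    n_samples - n_samples // 2))
            labels.append("silenced")
        else:
            mut = rng.normal(base, 0.05 * base, n_samples - n_samples // 2)
            labels.append("stable")
        rows.append(np.clip(np.concatenate([wt, mut]), 0, None))
    tpm = pd.DataFrame(rows, index=[g[0] for g in genes], columns=cols)
    gene_table = pd.DataFrame(genes, columns=["gene", "chrom", "start", "end"])
    gene_table["cluster_truth"] = labels
    return tpm, gene_table
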