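"""O/E normalization, compartment score and strength against oracles."""

import numpy as np
import pytest

from hcdscan import (BinnedTrack, ContactMatrix, GenomeLayout,
                     compartment_score, compartment_score_delta,
                     compartment_strength, compute_oe, standard_scenario)
from hcdscan.compartments import OEMatrix
from hcdscan.pipeline import (compartment_profiles, sign_agreement,
                              simulate_scenario)


def brute_force_oe(counts, mask):
    """Independent double-loop O/E oracle."""
    n = counts.shape[0]
    oe = np.full((n, n), np.nan)
    for d in range(n):
        vals = [counts[i, i + d] for i in range(n - d)
                if not mask[i] and not mask[i + d]]
        if not vals:
            continue
        exp = np.mean(vals)
        if exp <= 0:
            continue
        for i in range(n - d):
            if not mask[i] and not mask[i + d]:
                oe[i, i + d] = oe[i + d, i] = counts[i, i + d] / exp
    return oe


def power_iteration(sym, n_iter=5000, seed=0):
    """Independent dominant-eigenpair oracle (largest |lambda|)."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=sym.shape[0])
    for _ in range(n_iter):
        v2 = sym @ v
        v = v2 / np.linalg.norm(v2)
    lam = float(v @ sym @ v)
    return lam, v


def random_cm(rng, n=20, n_masked=3):
    m = rng.poisson(50, (n, n)).astype(float)
    m = np.triu(m) + np.triu(m, 1).T
    mask = np.zeros(n, bool)
    mask[rng.choice(n, n_masked, replace=False)] = True
    return ContactMatrix("a", 1000, m, mask)


class TestComputeOe:
    def test_constant_diagonals_give_all_ones(self):
        n = 12
        counts = np.zeros((n, n))
        for d in range(n):
            idx = np.arange(n - d)
            counts[idx, idx + d] = counts[idx + d, idx] = n - d
        oe = compute_oe(ContactMatrix("a", 1000, counts))
        assert np.allclose(oe.values[np.isfinite(oe.values)], 1.0)

    def test_zero_expected_diagonal_masked(self):
        counts = np.array([[2., 1, 0], [1, 2, 1], [0, 1, 2]])
        n = 10  # pad to satisfy the >=10 unmasked-bin precondition
        big = np.zeros((n, n))
        big[:3, :3] = counts
        for i in range(3, n):
            big[i, i] = 2.0
            big[i, i - 1] = big[i - 1, i] = 1.0
        oe = compute_oe(ContactMatrix("a", 1000, big))
        assert np.isnan(oe.values[0, 2])  # distance-2 diagonal: expected 0
        assert oe.values[0, 0] == pytest.approx(1.0)
        assert oe.values[0, 1] == pytest.approx(1.0)

    def test_all_masked_rejected(self):
        cm = ContactMatrix("a", 1000, np.ones((12, 12)), np.ones(12, bool))
        with pytest.raises(ValueError):
            compute_oe(cm)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_with_masks(self, seed):
        rng = np.random.default_rng(seed)
        cm = random_cm(rng)
        oe = compute_oe(cm)
        oracle = brute_force_oe(cm.counts, cm.bin_mask)
        assert np.allclose(oe.values, oracle, equal_nan=True)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_diagonal_means_are_one(self, seed):
        rng = np.random.default_rng(seed)
        cm = random_cm(rng, n=30, n_masked=5)
        oe = compute_oe(cm)
        n = oe.n_bins
        for d in range(n):
            diag = np.diagonal(oe.values, d)
            diag = diag[np.isfinite(diag)]
            if diag.size:
                assert diag.mean() == pytest.approx(1.0, abs=1e-9)


class TestCompartmentScore:
    def test_checkerboard_partition_recovered(self):
        k = 0.4
        rng = np.random.default_rng(0)
        sigma = np.where(rng.random(40) < 0.5, 1.0, -1.0)
        oe_vals = 1.0 + k * np.outer(sigma, sigma)
        oe = OEMatrix("a", 1000, oe_vals, np.zeros(40, bool))
        prof = compartment_score(oe)
        signs = np.sign(prof.score)
        assert (signs == sigma).all() or (signs == -sigma).all()

    def test_orientation_idempotent_under_sign_flip(self):
        rng = np.random.default_rng(1)
        sigma = np.where(rng.random(40) < 0.5, 1.0, -1.0)
        oe = OEMatrix("a", 1000, 1.0 + 0.3 * np.outer(sigma, sigma),
                      np.zeros(40, bool))
        track = BinnedTrack("a", 1000, np.where(sigma > 0, 50.0, 10.0))
        p1 = compartment_score(oe, track)
        p2 = compartment_score(oe, track)
        assert np.allclose(p1.score, p2.score)
        assert p1.oriented and p1.orientation_corr >= 0
        assert np.sign(p1.score[sigma > 0]).mean() == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_power_iteration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(30, 30))
        sym = (a + a.T) / 2
        oe = OEMatrix("a", 1000, sym + 1.0, np.zeros(30, bool))
        prof = compartment_score(oe)
        lam, vec = power_iteration(sym, seed=seed)
        if lam < 0:
            # operation prefers the largest nonnegative eigenvalue
            w = np.linalg.eigvalsh(sym)
            lam_op = w.max() if (w >= 0).any() else lam
            assert prof.eigenvalue == pytest.approx(lam_op, abs=1e-6)
            return
        expected = vec * np.sqrt(abs(lam))
        match = min(np.abs(prof.score - expected).max(),
                    np.abs(prof.score + expected).max())
        assert match < 1e-6

    def test_sign_agreement_on_synthetic(self):
        layout = GenomeLayout([("a", "a", 50_000_000)], bin_size=100_000)
        p = standard_scenario(layout=layout, seed=1, k_comp=0.3)
        data = simulate_scenario(p)
        compartment_profiles(data)
        assert sign_agreement(data.profiles["wt"]["a"], data.truth["a"]) >= 0.95


class TestCompartmentStrength:
    def _uniform_profile(self, oe, scores):
        from hcdscan.compartments import CompartmentProfile
        return CompartmentProfile("a", 1000, np.asarray(scores, float),
                                  np.zeros(len(scores), bool), 1.0, True, 1.0)

    def test_equal_classes_give_zero(self):
        n = 30
        oe = OEMatrix("a", 1000, np.ones((n, n)), np.zeros(n, bool))
        prof = self._uniform_profile(oe, np.linspace(-1, 1, n))
        s = compartment_strength(oe, prof)
        assert s.AA == s.BB == s.AB == 1.0
        assert s.strength == 0.0

    def test_closed_form_strength(self):
        # AA = BB = 4, AB = 1 -> log2(16) = 4
        n = 30
        scores = np.linspace(-1, 1, n)
        order = np.argsort(scores)
        b_set, a_set = order[:6], order[-6:]
        vals = np.ones((n, n))
        vals[np.ix_(a_set, a_set)] = 4.0
        vals[np.ix_(b_set, b_set)] = 4.0
        oe = OEMatrix("a", 1000, vals, np.zeros(n, bool))
        s = compartment_strength(oe, self._uniform_profile(oe, scores))
        assert s.strength == pytest.approx(4.0)

    def test_matches_pair_loop_oracle_on_synthetic(self):
        layout = GenomeLayout([("a", "a", 30_000_000)], bin_size=100_000)
        p = standard_scenario(layout=layout, seed=2)
        data = simulate_scenario(p)
        compartment_profiles(data)
        oe = data.oes["wt"]["a"]
        prof = data.profiles["wt"]["a"]
        s = compartment_strength(oe, prof)

        valid = np.flatnonzero(~prof.mask & ~oe.bin_mask)
        scores = prof.score[valid]
        k = int(np.floor(0.2 * valid.size))
        order = np.lexsort((valid, scores))
        b_bins, a_bins = valid[order[:k]], valid[order[-k:]]

        def loop_mean(rows, cols, same):
            tot, cnt = 0.0, 0
            for i in rows:
                for j in cols:
                    if same and j <= i:
                        continue
                    v = oe.values[i, j]
                    if np.isfinite(v):
                        tot += v
                        cnt += 1
            return tot / cnt

        assert s.AA == pytest.approx(loop_mean(a_bins, a_bins, True), abs=1e-9)
        assert s.BB == pytest.approx(loop_mean(b_bins, b_bins, True), abs=1e-9)
        assert s.AB == pytest.approx(loop_mean(a_bins, b_bins, False), abs=1e-9)

    def test_strength_monotone_in_k_and_mut_exceeds_wt(self):
        from hcdscan.simulate import depth_for_min_class_reads

        layout = GenomeLayout([("a", "a", 40_000_000)], bin_size=100_000)
        depth = depth_for_min_class_reads(layout.n_bins("a"))
        strengths = []
        for k in (0.0, 0.1, 0.2, 0.3):
            # compartment-free null: TADs and loops off so only the planted
            # checkerboard contributes structure
            p = standard_scenario(layout=layout, seed=9, k_comp=k, depth=depth,
                                  tad_insulation_factor=1.0, loop_strength=1.0)
            data = simulate_scenario(p)
            compartment_profiles(data)
            strengths.append(compartment_strength(
                data.oes["wt"]["a"], data.profiles["wt"]["a"]).strength)
        assert abs(strengths[0]) < 0.1
        assert strengths == sorted(strengths)

        p = standard_scenario(layout=layout, seed=9)
        data = simulate_scenario(p)
        compartment_profiles(data)
        wt = compartment_strength(data.oes["wt"]["a"], data.profiles["wt"]["a"])
        mut = compartment_strength(data.oes["mut"]["a"], data.profiles["mut"]["a"])
        assert mut.strength > wt.strength


class TestScoreDelta:
    def test_identical_profiles_give_zero_and_symmetry(self):
        layout = GenomeLayout([("a", "a", 30_000_000)], bin_size=100_000)
        p = standard_scenario(layout=layout, seed=4)
        data = simulate_scenario(p)
        compartment_profiles(data)
        wt, mut = data.profiles["wt"]["a"], data.profiles["mut"]["a"]
        signed0, abs0 = compartment_score_delta(wt, wt)
        assert np.nansum(np.abs(signed0.values)) == 0
        _, abs_wm = compartment_score_delta(wt, mut)
        _, abs_mw = compartment_score_delta(mut, wt)
        assert np.allclose(abs_wm.values, abs_mw.values, equal_nan=True)
        signed, _ = compartment_score_delta(wt, mut)
        expected = mut.score - wt.score
        ok = np.isfinite(signed.values)
        assert np.allclose(signed.values[ok], expected[ok])
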