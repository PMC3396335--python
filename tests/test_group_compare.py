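"""Group frequencies, chi-square + FDR, genome-wide aberration odds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acghcall.calling import CallMatrix, UNCALLED
from acghcall.group_compare import (
    aberration_burden, genome_wide_odds_test, region_chisq_fdr, region_frequencies,
)
from acghcall.regions import reduce_regions
from acghcall.simulate import SimConfig, simulate_cohort, truth_call_matrix


def _region_calls(calls, threshold=0.0):
    calls = np.asarray(calls, dtype=np.int8)
    n, s = calls.shape
    probes = pd.DataFrame(
        {"chromosome": np.arange(n) + 1, "position": [1_000_000] * n},
        index=[f"p{i:04d}" for i in range(n)],
    )
    probs = np.zeros((n, s, 4))
    for state, col in ((-1, 0), (0, 1), (1, 2)):
        probs[..., col] = calls == state
    probs[calls == UNCALLED] = 0.25
    cm = CallMatrix(probes=probes, samples=[f"s{j}" for j in range(s)],
                    calls=calls, probs=probs)
    return reduce_regions(cm, threshold=threshold)


def _groups(n_each):
    g = {}
    for j in range(2 * n_each):
        g[f"s{j}"] = "early" if j < n_each else "advanced"
    return g


class TestFrequencies:
    def test_counting(self):
        calls = np.zeros((1, 32), dtype=int)
        calls[0, :4] = 1          # 4 of 16 early gained
        calls[0, 16:28] = 1       # 12 of 16 advanced gained
        rc = _region_calls(calls)
        f = region_frequencies(rc, _groups(16))
        assert f.gain["early"][0] == pytest.approx(0.25)
        assert f.gain["advanced"][0] == pytest.approx(0.75)
        assert f.loss["early"][0] == 0.0

    def test_all_gain_both_groups(self):
        rc = _region_calls(np.ones((3, 8), dtype=int))
        f = region_frequencies(rc, _groups(4))
        for g in ("early", "advanced"):
            assert np.allclose(f.gain[g], 1.0)
            assert np.allclose(f.loss[g], 0.0)

    def test_empty_group_errors(self):
        rc = _region_calls(np.zeros((2, 4), dtype=int))
        with pytest.raises(ValueError, match="exactly 2 groups"):
            region_frequencies(rc, {f"s{j}": "early" for j in range(4)})


class TestChisqFdr:
    def test_identical_groups_no_discoveries(self):
        rng = np.random.default_rng(0)
        half = rng.choice([-1, 0, 1], size=(10, 6))
        rc = _region_calls(np.hstack([half, half]))
        res = region_chisq_fdr(rc, _groups(6))
        assert np.all(res.statistic == 0)
        assert np.all(res.p == 1)
        assert res.discovery.sum() == 0

    def test_matches_expected_count_oracle(self):
        rng = np.random.default_rng(1)
        calls = (rng.random((12, 20)) < 0.4).astype(int)
        rc = _region_calls(calls)
        res = region_chisq_fdr(rc, _groups(10))
        for r in range(rc.n_regions):
            row = rc.calls[r]
            tab = np.array([
                [(row[:10] != 0).sum(), (row[:10] == 0).sum()],
                [(row[10:] != 0).sum(), (row[10:] == 0).sum()],
            ], dtype=float)
            if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
                assert res.degenerate[r]
                continue
            exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
            chi = ((tab - exp) ** 2 / exp).sum()
            assert res.statistic[r] == pytest.approx(chi, rel=1e-9)

    def test_bh_qvalues_closed_form(self):
        # build regions whose p-values we then check against the step-up formula
        rng = np.random.default_rng(2)
        calls = (rng.random((40, 24)) < rng.uniform(0.1, 0.7, size=(40, 1))).astype(int)
        rc = _region_calls(calls)
        res = region_chisq_fdr(rc, _groups(12))
        m = len(res.p)
        order = np.argsort(res.p, kind="mergesort")
        q_oracle = np.empty(m)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            i = m - rank_from_end  # 1-based rank
            prev = min(prev, m * res.p[idx] / i)
            q_oracle[idx] = prev
        assert res.q == pytest.approx(q_oracle, rel=1e-9)

    def test_discoveries_nested_across_levels(self):
        rng = np.random.default_rng(3)
        early = (rng.random((30, 16)) < 0.2).astype(int)
        adv = (rng.random((30, 16)) < 0.6).astype(int)
        rc = _region_calls(np.hstack([early, adv]))
        res_lo = region_chisq_fdr(rc, _groups(16), fdr_level=0.05)
        res_hi = region_chisq_fdr(rc, _groups(16), fdr_level=0.25)
        assert set(np.flatnonzero(res_lo.discovery)) <= set(
            np.flatnonzero(res_hi.discovery))

    def test_fdr_and_sensitivity_on_mixture(self):
        """20 differential regions (0.2 vs 0.7) among 200 null at FDR 15%."""
        rng = np.random.default_rng(4)
        fdp = []
        sens = []
        for _ in range(25):
            null = (rng.random((200, 60)) < 0.35).astype(int)
            sig = np.hstack([
                (rng.random((20, 30)) < 0.2).astype(int),
                (rng.random((20, 30)) < 0.7).astype(int),
            ])
            calls = np.vstack([null, sig])
            rc = _region_calls(calls)
            res = region_chisq_fdr(rc, _groups(30), fdr_level=0.15)
            disc = np.flatnonzero(res.discovery)
            if len(disc) == 0:
                sens.append(0.0)
                continue
            true = set(range(200, 220))
            fdp.append(len(set(disc) - true) / len(disc))
            sens.append(len(set(disc) & true) / 20)
        assert np.mean(fdp) <= 0.25
        assert np.mean(sens) >= 0.5


class TestGenomeWideOdds:
    def test_identical_burden_null_center(self):
        rng = np.random.default_rng(5)
        half = rng.choice([-1, 0, 0, 1], size=(50, 8))
        rc = _region_calls(np.hstack([half, half]))
        res = genome_wide_odds_test(rc, _groups(8), n_perm=400, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p > 0.4

    def test_exhaustive_sign_flip_extreme(self):
        """16 pairs, advanced higher in every pair -> p = 1/2^16 exactly."""
        rng = np.random.default_rng(6)
        early = (rng.random((60, 16)) < 0.2).astype(int)
        adv = early | (rng.random((60, 16)) < 0.5).astype(int)
        rc = _region_calls(np.hstack([early, adv]))
        burden = aberration_burden(rc)
        assert np.all(burden[16:] > burden[:16])
        pairing = {f"s{j}": f"s{j + 16}" for j in range(16)}
        res = genome_wide_odds_test(rc, _groups(16), pairing=pairing)
        assert res.exhaustive
        assert res.n_permutations == 2**16
        assert res.p == pytest.approx(1 / 2**16)

    def test_type_one_error_null_simulation(self):
        rejections = 0
        n_rep = 100
        for s in range(n_rep):
            co = simulate_cohort(SimConfig(seed=30_000 + s, odds_ratio_advanced=1.0,
                                           n_chromosomes=4, probes_per_chromosome=60,
                                           n_candidate_aberrations=20))
            rc = reduce_regions(truth_call_matrix(co))
            res = genome_wide_odds_test(rc, co.true_group, pairing=co.pairing, seed=s)
            rejections += res.p < 0.05
        assert 0.0 <= rejections / n_rep <= 0.09

    def test_power_at_odds_ratio_three(self):
        hits = 0
        for s in range(20):
            co = simulate_cohort(SimConfig(seed=40_000 + s, odds_ratio_advanced=3.0,
                                           n_chromosomes=4, probes_per_chromosome=60))
            rc = reduce_regions(truth_call_matrix(co))
            res = genome_wide_odds_test(rc, co.true_group, pairing=co.pairing, seed=s)
            hits += res.p < 0.05
        assert hits / 20 > 0.8

    def test_invariance_to_relabeling(self):
        rng = np.random.default_rng(7)
        calls = rng.choice([-1, 0, 0, 1], size=(40, 12))
        rc = _region_calls(calls)
        res1 = genome_wide_odds_test(rc, _groups(6), n_perm=300, seed=1)
        # shuffle region order
        perm = rng.permutation(rc.n_regions)
        rc2 = type(rc)(
            regions=[rc.regions[i] for i in perm], samples=rc.samples,
            calls=rc.calls[perm], probs=rc.probs[perm],
            achieved_loss=rc.achieved_loss, n_total_probes=rc.n_total_probes,
        )
        res2 = genome_wide_odds_test(rc2, _groups(6), n_perm=300, seed=1)
        assert res1.statistic == pytest.approx(res2.statistic)
        assert res1.p == res2.p

    def test_small_n_perm_rejected(self):
        rc = _region_calls(np.zeros((5, 4), dtype=int))
        with pytest.raises(ValueError, match="n_perm"):
            genome_wide_odds_test(rc, _groups(2), n_perm=10)

    def test_burden_in_open_unit_interval(self):
        calls = np.zeros((10, 4), dtype=int)
        calls[:, 1] = 1
        rc = _region_calls(calls)
        b = aberration_burden(rc)
        assert np.all((b > 0) & (b < 1))
        assert b[1] > b[0]

    def test_imperfect_pairing_rejected(self):
        rc = _region_calls(np.zeros((5, 4), dtype=int))
        with pytest.raises(ValueError, match="matching"):
            genome_wide_odds_test(rc, _groups(2), pairing={"s0": "s2"})
        with pytest.raises(ValueError, match="span"):
            genome_wide_odds_test(rc, _groups(2), pairing={"s0": "s1", "s2": "s3"})
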