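"""Mode normalization and mixture calling."""

import numpy as np
import pytest

from acghcall import SimConfig, simulate_cohort
from acghcall.calling import (
    UNCALLED, MixtureModel, call_profiles, fit_call_mixture, mode_normalize,
)
from acghcall.preprocess import median_normalize
from acghcall.segmentation import CbsParams, Segment, SegmentedProfile, segment_profileset


def _profile(levels_counts, sample="s"):
    """SegmentedProfile with given (level, n_probes) runs on one chromosome."""
    segments = []
    start = 1
    values = []
    for level, n in levels_counts:
        segments.append(Segment(1, start, start + n - 1, float(level), n))
        values.extend([float(level)] * n)
        start += n
    return SegmentedProfile(sample, segments, np.array(values))


class TestModeNormalize:
    def test_mode_subtraction(self):
        sp = _profile([(0.2, 80), (1.2, 20)])
        out = mode_normalize(sp)
        assert [s.mean for s in out.segments] == pytest.approx([0.0, 1.0])

    def test_idempotent_when_centred(self):
        sp = _profile([(0.0, 80), (1.0, 20)])
        out = mode_normalize(sp)
        assert abs(out.segments[0].mean) < 1e-3

    def test_balanced_bimodal_tie_break(self):
        # equal mass at 0 and 1: the smaller shift (0) wins
        sp = _profile([(0.0, 50), (1.0, 50)])
        out = mode_normalize(sp, bandwidth=0.1)
        assert out.segments[0].mean == pytest.approx(0.0)
        assert out.segments[1].mean == pytest.approx(1.0)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError, match="no segments"):
            mode_normalize(SegmentedProfile("s", [], np.array([])))


class TestFitCallMixture:
    def test_near_constant_cohort_called_normal(self):
        rng = np.random.default_rng(0)
        cohort = [
            _profile([(m, 30) for m in rng.normal(0, 0.01, 5)], sample=f"s{i}")
            for i in range(3)
        ]
        model = fit_call_mixture(cohort)
        cm = call_profiles(model, cohort, _probes(150))
        assert set(np.unique(cm.calls)) <= {0, UNCALLED}
        assert (cm.calls == 0).mean() > 0.95

    def test_posterior_rows_sum_to_one(self):
        cohort = [_profile([(-0.5, 20), (0.0, 60), (0.4, 20)], f"s{i}")
                  for i in range(3)]
        model = fit_call_mixture(cohort)
        post = model.posterior(np.array([-0.5, 0.0, 0.4, 1.2]))
        assert post.sum(axis=1) == pytest.approx(1.0)

    def test_objective_monotone(self):
        rng = np.random.default_rng(1)
        cohort = [
            _profile([(rng.choice([-0.6, 0, 0.4]) + rng.normal(0, 0.05), 10)
                      for _ in range(8)], f"s{i}")
            for i in range(4)
        ]
        model = fit_call_mixture(cohort)
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_degrades_below_four_levels(self):
        cohort = [_profile([(0.0, 50), (0.5, 50)], f"s{i}") for i in range(2)]
        model = fit_call_mixture(cohort)
        assert model.degraded
        assert len(model.means) == 2

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            fit_call_mixture([_profile([(0.0, 10)])])

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            MixtureModel(means=np.array([0.0, -0.1]), sds=np.array([0.1, 0.1]),
                         weights=np.array([0.5, 0.5]), component_states=(0, 1))
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureModel(means=np.array([0.0, 0.5]), sds=np.array([0.1, 0.1]),
                         weights=np.array([0.5, 0.6]), component_states=(0, 1))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(2)
    cohort = []
    for i in range(6):
        levels = [(-0.7, 25), (0.0, 80), (0.45, 30), (1.0, 15)]
        cohort.append(_profile(
            [(m + rng.normal(0, 0.02), n) for m, n in levels], f"s{i}"))
    return fit_call_mixture(cohort), cohort


class TestCallProfiles:

    def test_extreme_segment_is_confident_loss(self, fitted):
        model, cohort = fitted
        post = model.posterior(np.array([-2.0]))
        assert post[0, 0] > 0.99

    def test_amplification_merged_into_gain(self, fitted):
        model, cohort = fitted
        cm = call_profiles(model, cohort, _probes(150))
        merged = cm.merged_probs
        # wherever the amplification posterior dominates, the merged call is gain
        amp_heavy = cm.probs[..., 3] > 0.5
        assert amp_heavy.any()
        assert np.all(cm.calls[amp_heavy] == 1)
        assert merged[..., 2] == pytest.approx(cm.probs[..., 2] + cm.probs[..., 3])

    def test_uncalled_when_no_state_exceeds_half(self):
        # broad, overlapping components: a segment mean in the loss/normal
        # overlap has max merged posterior < 0.5 -> uncalled sentinel
        model = MixtureModel(
            means=np.array([-0.45, 0.0, 0.3, 0.9]),
            sds=np.array([0.3, 0.3, 0.3, 0.3]),
            weights=np.array([0.3, 0.3, 0.3, 0.1]),
            component_states=(0, 1, 2, 3),
            loglik_trace=[0.0],
        )
        ambiguous = None
        for x in np.linspace(-0.4, 0.1, 101):
            post = model.posterior(np.array([x]))[0]
            merged = np.array([post[0], post[1], post[2] + post[3]])
            if merged.max() < 0.5:
                ambiguous = x
                break
        assert ambiguous is not None
        sp = _profile([(ambiguous, 150)])
        cm = call_profiles(model, [sp], _probes(150))
        assert (cm.calls == UNCALLED).all()

    def test_sample_order_invariance(self, fitted):
        model, cohort = fitted
        cm1 = call_profiles(model, cohort, _probes(150))
        cm2 = call_profiles(model, cohort[::-1], _probes(150))
        assert np.array_equal(cm1.calls, cm2.calls[:, ::-1])

    def test_unfitted_model_errors(self, fitted):
        model, cohort = fitted
        bare = MixtureModel(means=model.means, sds=model.sds, weights=model.weights,
                            component_states=model.component_states)
        with pytest.raises(ValueError, match="not fitted"):
            call_profiles(bare, cohort, _probes(150))


def test_noise_free_calls_match_truth(clean_cohort):
    """On clean data the hard-call matrix equals the truth (amp merged)."""
    seg = segment_profileset(clean_cohort.profiles, CbsParams(seed=0))
    seg = [mode_normalize(sp) for sp in seg]
    model = fit_call_mixture(seg)
    cm = call_profiles(model, seg, clean_cohort.profiles.probes)
    truth = clean_cohort.truth_states.copy()
    truth[truth == 2] = 1
    assert np.array_equal(cm.calls, truth)


def test_call_accuracy_at_stated_separation():
    """True levels {-0.6, 0, 0.5, 1.5} at sigma 0.1: >=95% correct hard calls."""
    cfg = SimConfig(seed=3, loss_amplitude=-0.6, gain_amplitude=0.5,
                    amp_amplitude=1.5, tumor_fraction=1.0, noise_sd=0.1,
                    wave_amplitude=0.0, n_per_group=6, n_chromosomes=4,
                    n_candidate_aberrations=12)
    co = simulate_cohort(cfg)
    prof = median_normalize(co.profiles)
    seg = [mode_normalize(sp) for sp in
           segment_profileset(prof, CbsParams(seed=3))]
    model = fit_call_mixture(seg)
    cm = call_profiles(model, seg, prof.probes)
    truth = co.truth_states.copy()
    truth[truth == 2] = 1
    assert (cm.calls == truth).mean() >= 0.95


def _probes(n):
    import pandas as pd
    return pd.DataFrame(
        {"chromosome": [1] * n, "position": (np.arange(n) + 1) * 1_000_000},
        index=[f"p{i:04d}" for i in range(n)],
    )
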