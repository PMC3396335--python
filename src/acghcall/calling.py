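"""Mode normalization and mixture-model calling of segmented profiles.

Segmented log2 values are first shifted so the most common level (the
presumed copy-neutral state) sits at zero.  A four-component Gaussian
mixture — loss, normal, gain, amplification — is then fitted by EM to
the pooled segment means of the cohort, each segment weighted by its
probe count, with the component means kept strictly ordered and the
normal component anchored near zero.  Per-segment posteriors follow from
the fitted mixture; the amplification posterior is folded into gain for
the three-state view used downstream, and a hard call is only assigned
when the winning merged probability exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import AcghProfileSet
from .segmentation import SegmentedProfile

UNCALLED = -9  # sentinel hard call: no merged state reached probability > 0.5
STATE_NAMES = ("loss", "normal", "gain", "amplification")
DEFAULT_INIT_MEANS = (-0.45, 0.0, 0.3, 0.9)

_SD_FLOOR = 0.01


def mode_normalize(segmented: SegmentedProfile, bandwidth: float | None = None) -> SegmentedProfile:
    """Shift a segmented profile so its modal level is zero.

    The mode of the probe-level segmented values is located with a
    Gaussian kernel density (normal-reference bandwidth by default)
    evaluated at the distinct segment levels; density ties are broken
    toward the smallest absolute shift.
    """
    if not segmented.segments:
        raise ValueError(f"sample {segmented.sample_id!r} has no segments")
    levels = np.array([s.mean for s in segmented.segments])
    counts = np.array([s.n_probes for s in segmented.segments], dtype=float)
    uniq, inv = np.unique(levels, return_inverse=True)
    w = np.zeros(len(uniq))
    np.add.at(w, inv, counts)
    if len(uniq) == 1:
        shift = float(uniq[0])
    else:
        n = counts.sum()
        if bandwidth is None:
            mean = np.average(uniq, weights=w)
            sd = np.sqrt(np.average((uniq - mean) ** 2, weights=w))
            bandwidth = max(1.06 * sd * n ** (-1 / 5), 1e-3)
        z = (uniq[:, None] - uniq[None, :]) / bandwidth
        density = (np.exp(-0.5 * z**2) * w[None, :]).sum(axis=1)
        best = density.max()
        candidates = uniq[density >= best * (1 - 1e-9)]
        shift = float(candidates[np.argmin(np.abs(candidates))])
    segments = [
        type(s)(s.chromosome, s.start_index, s.end_index, s.mean - shift, s.n_probes)
        for s in segmented.segments
    ]
    return SegmentedProfile(
        sample_id=segmented.sample_id,
        segments=segments,
        probe_level_values=segmented.probe_level_values - shift,
    )


@dataclass
class MixtureModel:
    """Ordered four-state Gaussian mixture on segment means."""

    means: np.ndarray            # ordered, one per active component
    sds: np.ndarray
    weights: np.ndarray          # simplex
    component_states: tuple[int, ...]  # index into STATE_NAMES per component
    loglik_trace: list[float] = field(default_factory=list)
    degraded: bool = False       # fewer than 4 components were identifiable
    converged: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("component means must be strictly ordered")
        if np.any(self.sds <= 0):
            raise ValueError("component SDs must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixing weights must sum to 1")

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Raw 4-state posterior for segment means ``x`` (rows sum to 1)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        logd = (
            -0.5 * ((x[:, None] - self.means[None, :]) / self.sds[None, :]) ** 2
            - np.log(self.sds[None, :])
            + np.log(self.weights[None, :])
        )
        logd -= logd.max(axis=1, keepdims=True)
        r = np.exp(logd)
        r /= r.sum(axis=1, keepdims=True)
        out = np.zeros((len(x), 4))
        for c, state in enumerate(self.component_states):
            out[:, state] += r[:, c]
        return out


def _weighted_pava(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted isotonic (non-decreasing) projection, pool-adjacent-violators."""
    v = values.astype(float).copy()
    w = weights.astype(float).copy()
    blocks = [[i] for i in range(len(v))]
    i = 0
    while i < len(v) - 1:
        if v[i] > v[i + 1] + 1e-15:
            tot = w[i] + w[i + 1]
            v[i] = (v[i] * w[i] + v[i + 1] * w[i + 1]) / tot
            w[i] = tot
            blocks[i].extend(blocks[i + 1])
            del blocks[i + 1]
            v = np.delete(v, i + 1)
            w = np.delete(w, i + 1)
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.empty(len(weights))
    for val, members in zip(v, blocks):
        out[list(members)] = val
    return out


def fit_call_mixture(
    segmented_cohort: list[SegmentedProfile],
    init_means: tuple[float, ...] = DEFAULT_INIT_MEANS,
    anchor_weight: float = 5.0,
    max_iter: int = 500,
    tol: float = 1e-8,
    shared_sd: bool = True,
) -> MixtureModel:
    """EM fit of the calling mixture to pooled, probe-weighted segment means.

    The normal component's mean is shrunk toward 0 by a quadratic prior
    worth ``anchor_weight`` probes; the ordering constraint is enforced
    in the M step by a precision-weighted isotonic projection of the
    means.  By default the components share one pooled SD — with free
    SDs the gain component tends to inflate into a catch-all for the
    stray intermediate segment means that segmentation leaves behind.
    The (penalized) objective is checked to be non-decreasing at every
    iteration.
    """
    if len(segmented_cohort) < 2:
        raise ValueError("need at least 2 samples to fit the calling mixture")
    x = np.array([s.mean for sp in segmented_cohort for s in sp.segments])
    w = np.array([s.n_probes for sp in segmented_cohort for s in sp.segments], dtype=float)
    if len(x) == 0:
        raise ValueError("no segments to fit")
    n_distinct = len(np.unique(np.round(x, 12)))
    K = min(4, n_distinct)
    degraded = K < 4
    if degraded:
        centers = np.sort(np.unique(np.round(x, 12)))[:K].astype(float)
        means = np.sort(centers)
        # map each component to the canonical state nearest its mean,
        # forcing the component closest to 0 to be 'normal'
        states = []
        for m in means:
            states.append(int(np.argmin(np.abs(np.array(DEFAULT_INIT_MEANS) - m))))
        closest = int(np.argmin(np.abs(means)))
        states[closest] = 1
        component_states = tuple(states)
        normal_idx = closest
    else:
        means = np.array(init_means, dtype=float)
        component_states = (0, 1, 2, 3)
        normal_idx = 1
    sds = np.full(K, 0.15)
    pis = np.full(K, 1.0 / K)

    def objective(means, sds, pis):
        logd = (
            -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :]) - 0.5 * np.log(2 * np.pi)
            + np.log(pis[None, :])
        )
        m = logd.max(axis=1, keepdims=True)
        ll = float(np.sum(w * (m[:, 0] + np.log(np.exp(logd - m).sum(axis=1)))))
        penalty = -0.5 * anchor_weight * means[normal_idx] ** 2 / max(sds[normal_idx], _SD_FLOOR) ** 2
        return ll + penalty

    trace = [objective(means, sds, pis)]
    converged = False
    for _ in range(max_iter):
        # E step
        logd = (
            -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :]) + np.log(pis[None, :])
        )
        logd -= logd.max(axis=1, keepdims=True)
        r = np.exp(logd)
        r /= r.sum(axis=1, keepdims=True)
        rw = r * w[:, None]
        nk = rw.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        # M step: means (anchored normal), ordered by precision-weighted PAVA
        new_means = (rw * x[:, None]).sum(axis=0) / nk
        new_means[normal_idx] = (rw[:, normal_idx] * x).sum() / (nk[normal_idx] + anchor_weight)
        prec = nk / np.maximum(sds, _SD_FLOOR) ** 2
        new_means = _weighted_pava(new_means, prec)
        # strictify exact ties
        for k in range(1, K):
            if new_means[k] <= new_means[k - 1]:
                new_means[k] = new_means[k - 1] + 1e-6
        if shared_sd:
            pooled = np.sqrt((rw * (x[:, None] - new_means[None, :]) ** 2).sum() / nk.sum())
            new_sds = np.full(K, max(pooled, _SD_FLOOR))
        else:
            new_sds = np.sqrt((rw * (x[:, None] - new_means[None, :]) ** 2).sum(axis=0) / nk)
            new_sds = np.maximum(new_sds, _SD_FLOOR)
        new_pis = nk / nk.sum()
        means, sds, pis = new_means, new_sds, new_pis
        obj = objective(means, sds, pis)
        if obj < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            raise RuntimeError(
                f"EM objective decreased: {trace[-1]:.10g} -> {obj:.10g}"
            )
        gain = obj - trace[-1]
        trace.append(obj)
        if abs(gain) < tol * max(1.0, abs(obj)):
            converged = True
            break
    return MixtureModel(
        means=means, sds=sds, weights=pis,
        component_states=component_states,
        loglik_trace=trace, degraded=degraded, converged=converged,
    )


@dataclass
class CallMatrix:
    """Per-probe, per-sample calls and posterior probabilities.

    ``calls`` holds the merged hard call (-1 loss, 0 normal, +1 gain,
    amplification folded into gain) or the :data:`UNCALLED` sentinel;
    ``probs`` holds the raw 4-state posterior per probe and sample.
    """

    probes: pd.DataFrame
    samples: list[str]
    calls: np.ndarray   # (n_probes, n_samples) int8
    probs: np.ndarray   # (n_probes, n_samples, 4) raw posteriors

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")

    @property
    def merged_probs(self) -> np.ndarray:
        """(n_probes, n_samples, 3): loss, normal, gain+amplification."""
        out = np.empty(self.probs.shape[:2] + (3,))
        out[..., 0] = self.probs[..., 0]
        out[..., 1] = self.probs[..., 1]
        out[..., 2] = self.probs[..., 2] + self.probs[..., 3]
        return out

    @property
    def n_probes(self) -> int:
        return len(self.probes)


def call_profiles(
    model: MixtureModel,
    segmented_cohort: list[SegmentedProfile],
    probes: pd.DataFrame,
    prob_cutoff: float = 0.5,
) -> CallMatrix:
    """Posterior state probabilities and >cutoff hard calls, per probe.

    Posteriors are computed per segment from the fitted mixture and
    broadcast to the segment's probes.  The hard call is the argmax of
    the merged three-state posterior when that posterior exceeds
    ``prob_cutoff`` (default 0.5), else the probe stays uncalled.
    """
    if not model.loglik_trace:
        raise ValueError("mixture model is not fitted")
    n_probes = len(probes)
    samples = [sp.sample_id for sp in segmented_cohort]
    calls = np.full((n_probes, len(samples)), UNCALLED, dtype=np.int8)
    probs = np.zeros((n_probes, len(samples), 4))
    chrom_arr = probes["chromosome"].to_numpy()
    chrom_offset = {c: int(np.flatnonzero(chrom_arr == c)[0]) for c in np.unique(chrom_arr)}
    hard_states = np.array([-1, 0, 1], dtype=np.int8)
    for s_idx, sp in enumerate(segmented_cohort):
        seg_means = np.array([s.mean for s in sp.segments])
        post = model.posterior(seg_means)
        merged = np.stack(
            [post[:, 0], post[:, 1], post[:, 2] + post[:, 3]], axis=1
        )
        arg = merged.argmax(axis=1)
        top = merged[np.arange(len(arg)), arg]
        hard = np.where(top > prob_cutoff, hard_states[arg], UNCALLED).astype(np.int8)
        for g_idx, seg in enumerate(sp.segments):
            off = chrom_offset[seg.chromosome]
            lo = off + seg.start_index - 1
            hi = off + seg.end_index
            probs[lo:hi, s_idx, :] = post[g_idx]
            calls[lo:hi, s_idx] = hard[g_idx]
    return CallMatrix(probes=probes, samples=samples, calls=calls, probs=probs)
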