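"""Group-level comparison of called copy-number regions.

Per-region gain/loss frequencies by group, Pearson chi-square tests of
differential aberration occurrence with Benjamini-Hochberg FDR control,
and a genome-wide test of the hypothesis that one group carries
aberrations at higher odds across the whole genome.  The genome-wide
test works on each sample's weighted aberration burden: the
region-size-weighted fraction of its called genome that is aberrant,
mapped to the logit scale; the group difference in mean log-odds is
assessed by a paired sign-flip permutation when a matching is supplied
(exhaustive up to 20 pairs) and by free label permutation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import UNCALLED
from .regions import RegionCallMatrix, region_weights


@dataclass
class RegionFrequency:
    groups: tuple[str, str]
    gain: dict[str, np.ndarray]   # group -> per-region gain frequency
    loss: dict[str, np.ndarray]


@dataclass
class RegionTestResult:
    statistic: np.ndarray
    p: np.ndarray
    q: np.ndarray
    discovery: np.ndarray
    fdr_level: float
    degenerate: np.ndarray        # regions with an all-identical table (p := 1)


@dataclass
class GenomeWideOddsResult:
    statistic: float              # mean logit burden (group2) - (group1)
    p: float                      # one-sided, H1: group2 higher
    burden: dict[str, float]
    n_permutations: int
    exhaustive: bool
    paired: bool
    seed: int | None = None
    groups: tuple[str, str] = ("early", "advanced")
    extra: dict = field(default_factory=dict)


def _group_arrays(regioncalls: RegionCallMatrix, groups: dict[str, str]) -> tuple:
    labels = [groups.get(s) for s in regioncalls.samples]
    if any(l is None for l in labels):
        missing = [s for s, l in zip(regioncalls.samples, labels) if l is None]
        raise ValueError(f"samples without group assignment: {missing}")
    names = sorted(set(labels))
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    masks = {g: np.array([l == g for l in labels]) for g in names}
    for g, m in masks.items():
        if m.sum() == 0:
            raise ValueError(f"group {g!r} has no samples")
    return names, masks


def region_frequencies(
    regioncalls: RegionCallMatrix, groups: dict[str, str]
) -> RegionFrequency:
    """Gain/loss frequency per region per group, over called samples only."""
    names, masks = _group_arrays(regioncalls, groups)
    calls = regioncalls.calls
    gain, loss = {}, {}
    for g in names:
        sub = calls[:, masks[g]]
        called = (sub != UNCALLED).sum(axis=1)
        denom = np.maximum(called, 1)
        gain[g] = (sub == 1).sum(axis=1) / denom
        loss[g] = (sub == -1).sum(axis=1) / denom
    return RegionFrequency(groups=tuple(names), gain=gain, loss=loss)


def region_chisq_fdr(
    regioncalls: RegionCallMatrix,
    groups: dict[str, str],
    fdr_level: float = 0.15,
) -> RegionTestResult:
    """Per-region 2x2 Pearson chi-square (no continuity correction) + BH.

    The table is aberrant (call != 0) vs not, by group; uncalled samples
    are excluded.  Regions whose table has a zero margin are flagged and
    assigned p = 1 by convention.
    """
    names, masks = _group_arrays(regioncalls, groups)
    calls = regioncalls.calls
    R = regioncalls.n_regions
    stat = np.zeros(R)
    p = np.ones(R)
    degenerate = np.zeros(R, dtype=bool)
    for r in range(R):
        row = calls[r]
        cells = np.zeros((2, 2))
        for gi, g in enumerate(names):
            sub = row[masks[g]]
            called = sub != UNCALLED
            ab = np.isin(sub, (-1, 1)) & called
            cells[gi, 0] = ab.sum()
            cells[gi, 1] = called.sum() - ab.sum()
        if (cells.sum(axis=0) == 0).any() or (cells.sum(axis=1) == 0).any():
            degenerate[r] = True
            continue
        n = cells.sum()
        det = cells[0, 0] * cells[1, 1] - cells[0, 1] * cells[1, 0]
        denom = cells.sum(axis=1).prod() * cells.sum(axis=0).prod()
        stat[r] = n * det**2 / denom
        p[r] = stats.chi2.sf(stat[r], df=1)
    _, q, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
    return RegionTestResult(
        statistic=stat, p=p, q=q,
        discovery=q <= fdr_level,
        fdr_level=fdr_level,
        degenerate=degenerate,
    )


def aberration_burden(regioncalls: RegionCallMatrix) -> np.ndarray:
    """Weighted fraction of each sample's called genome that is aberrant.

    Weights come from :func:`region_weights`; for each sample the weights
    of its uncalled regions are dropped and the rest renormalized.  The
    result is continuity-corrected away from {0, 1} by half a region's
    worth of probability mass, so the logit is always finite.
    """
    w = region_weights(regioncalls)
    calls = regioncalls.calls
    R = len(w)
    out = np.empty(len(regioncalls.samples))
    for s in range(len(regioncalls.samples)):
        col = calls[:, s]
        called = col != UNCALLED
        denom = w[called].sum()
        if denom == 0:
            b = 0.0
        else:
            b = w[called & np.isin(col, (-1, 1))].sum() / denom
        out[s] = (b + 0.5 / R) / (1.0 + 1.0 / R)
    return out


def genome_wide_odds_test(
    regioncalls: RegionCallMatrix,
    groups: dict[str, str],
    pairing: dict[str, str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative_group: str | None = None,
) -> GenomeWideOddsResult:
    """One-sided permutation test of genome-wide higher aberration odds.

    T = mean logit burden in the test group minus the reference group.
    With a perfect matching the null is generated by swapping labels
    within pairs (exhaustive over all 2^m assignments when m <= 20),
    otherwise by free permutation of the group labels.  The p-value is
    the fraction of null statistics >= the observed one, the observed
    assignment included.
    """
    names, masks = _group_arrays(regioncalls, groups)
    if alternative_group is None:
        # directional default: 'advanced' vs 'early' when those are the labels
        alternative_group = "advanced" if set(names) == {"early", "advanced"} else names[1]
    if alternative_group not in names:
        raise ValueError(f"alternative_group {alternative_group!r} not in {names}")
    g_test = alternative_group
    g_ref = names[0] if names[1] == g_test else names[1]
    burden = aberration_burden(regioncalls)
    logit = np.log(burden / (1.0 - burden))
    samples = regioncalls.samples
    idx = {s: k for k, s in enumerate(samples)}
    t_obs = logit[masks[g_test]].mean() - logit[masks[g_ref]].mean()

    if pairing is not None:
        pairs = _validated_pairs(pairing, samples, masks, g_ref, g_test)
        m = len(pairs)
        d = np.array([logit[idx[b]] - logit[idx[a]] for a, b in pairs]) / m
        exhaustive = m <= 20
        if exhaustive:
            signs = np.array(
                [[1 if (mask >> k) & 1 == 0 else -1 for k in range(m)]
                 for mask in range(2**m)], dtype=np.int8)
            null = signs.astype(float) @ d
            p = float((null >= t_obs - 1e-12).sum() / len(null))
            n_used = len(null)
        else:
            if n_perm < 100:
                raise ValueError("n_perm must be >= 100 when not exhaustive")
            rng = np.random.default_rng(seed)
            signs = rng.choice([-1.0, 1.0], size=(n_perm, m))
            null = signs @ d
            p = float((1 + (null >= t_obs - 1e-12).sum()) / (1 + n_perm))
            n_used = n_perm
        paired = True
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100 when not exhaustive")
        rng = np.random.default_rng(seed)
        n_test = int(masks[g_test].sum())
        n = len(samples)
        null = np.empty(n_perm)
        for b in range(n_perm):
            pick = rng.choice(n, size=n_test, replace=False)
            in_test = np.zeros(n, dtype=bool)
            in_test[pick] = True
            null[b] = logit[in_test].mean() - logit[~in_test].mean()
        p = float((1 + (null >= t_obs - 1e-12).sum()) / (1 + n_perm))
        n_used = n_perm
        exhaustive = False
        paired = False

    return GenomeWideOddsResult(
        statistic=float(t_obs),
        p=p,
        burden={s: float(b) for s, b in zip(samples, burden)},
        n_permutations=n_used,
        exhaustive=exhaustive,
        paired=paired,
        seed=seed,
        groups=(g_ref, g_test),
    )


def _validated_pairs(pairing, samples, masks, g_ref, g_test):
    sample_set = set(samples)
    seen = set()
    pairs = []
    ref_set = {s for s, m in zip(samples, masks[g_ref]) if m}
    test_set = {s for s, m in zip(samples, masks[g_test]) if m}
    for a, b in pairing.items():
        if a not in sample_set or b not in sample_set:
            raise ValueError(f"pairing names unknown sample: {a!r}/{b!r}")
        if a in test_set and b in ref_set:
            a, b = b, a
        if not (a in ref_set and b in test_set):
            raise ValueError(f"pair ({a!r}, {b!r}) does not span the two groups")
        pairs.append((a, b))
        seen.update((a, b))
    if seen != sample_set:
        raise ValueError("pairing is not a perfect matching of the samples")
    return pairs
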