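"""Circular binary segmentation (CBS) of log2-ratio profiles.

The sequence of a chromosome is joined into a circle; the arc (i..j]
maximizing a pooled-variance two-sample t statistic against its
complement is the candidate change, assessed by permutation.  Accepted
splits are recursed; a final pruning pass merges adjacent segments whose
separation is not supported by the residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import AcghProfileSet

_EPS = 1e-12


@dataclass
class Segment:
    chromosome: int
    start_index: int   # 1-based inclusive probe index within the chromosome
    end_index: int
    mean: float
    n_probes: int


@dataclass
class SegmentedProfile:
    sample_id: str
    segments: list[Segment]
    probe_level_values: np.ndarray  # segment mean broadcast to every probe


@dataclass
class CbsParams:
    alpha: float = 0.01
    n_perm: int = 10_000
    min_width: int = 2
    prune_sd: float = 1.5    # merge splits below (prune_sd)^2 x noise variance
    smooth_outliers: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


def cbs_max_statistic(values, i: int, j: int) -> float:
    """Pooled-variance t statistic of arc (i..j] vs its circular complement.

    Indices are 1-based with 1 <= i < j <= n; the arc holds elements
    i+1..j.  Both the arc and its complement must contain at least two
    points.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if not (1 <= i < j <= n):
        raise ValueError(f"need 1 <= i < j <= n, got i={i}, j={j}, n={n}")
    k = j - i
    if k < 2 or n - k < 2:
        raise ValueError("arc and complement must each contain >= 2 points")
    arc = x[i:j]
    comp = np.concatenate([x[:i], x[j:]])
    ssa = np.sum((arc - arc.mean()) ** 2)
    ssc = np.sum((comp - comp.mean()) ** 2)
    sp2 = (ssa + ssc) / (n - 2)
    diff = arc.mean() - comp.mean()
    if sp2 < _EPS:
        # zero within-variance: equal means -> no signal; unequal -> perfect split
        return 0.0 if abs(diff) < 1e-12 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(sp2 * (1.0 / k + 1.0 / (n - k))))


class _ArcIndex:
    """Precomputed (i, j) pair arrays for all admissible arcs of length n.

    Pairs are ordered lexicographically by (i, j) so that the first argmax
    is the leftmost, shortest arc (deterministic tie-break).
    """

    _cache: dict[tuple[int, int], "_ArcIndex"] = {}

    def __init__(self, n: int, min_width: int):
        i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        k = j - i
        ok = (i >= 1) & (j <= n) & (k >= max(2, min_width)) & (n - k >= max(2, min_width))
        self.i = i[ok]
        self.j = j[ok]
        self.k = k[ok].astype(float)
        self.m = (n - k[ok]).astype(float)
        self.n = n

    @classmethod
    def get(cls, n: int, min_width: int) -> "_ArcIndex":
        key = (n, min_width)
        if key not in cls._cache:
            if len(cls._cache) > 64:
                cls._cache.clear()
            cls._cache[key] = cls(n, min_width)
        return cls._cache[key]

    def max_stat(self, x: np.ndarray) -> tuple[float, int, int]:
        """(max |t|, i, j) over all admissible arcs; first argmax wins."""
        n = self.n
        S = np.concatenate(([0.0], np.cumsum(x)))
        Q = np.concatenate(([0.0], np.cumsum(x * x)))
        sum_a = S[self.j] - S[self.i]
        sum_c = S[n] - sum_a
        q_a = Q[self.j] - Q[self.i]
        q_c = Q[n] - q_a
        mean_a = sum_a / self.k
        mean_c = sum_c / self.m
        ss = (q_a - self.k * mean_a**2) + (q_c - self.m * mean_c**2)
        sp2 = np.maximum(ss / (n - 2), 0.0)
        denom = np.sqrt(sp2 * (1.0 / self.k + 1.0 / self.m))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(mean_a - mean_c) / denom
        t[np.isnan(t)] = 0.0  # 0/0: equal means at zero variance; +inf = perfect split
        best = int(np.argmax(t))
        return float(t[best]), int(self.i[best]), int(self.j[best])


def _perm_pvalue(
    x: np.ndarray, observed: float, idx: _ArcIndex, alpha: float,
    n_perm: int, rng: np.random.Generator,
) -> float:
    """Sequential permutation p-value with two-sided early stopping.

    Stops early in either direction once a +/- 2*sqrt binomial bound on
    the exceedance fraction separates it from alpha (and always once
    exceedances alone force p >= alpha).  Returns the hybrid estimate
    e/k from the permutations actually run.
    """
    e_stop = int(np.ceil(alpha * n_perm)) + 1
    e = 0
    for k in range(1, n_perm + 1):
        perm = rng.permutation(x)
        stat, _, _ = idx.max_stat(perm)
        if stat >= observed - _EPS:
            e += 1
            if e >= e_stop:
                return e / k
        if k >= 100 and k % 25 == 0:
            half = 2.0 * np.sqrt(e + 1.0)
            if (e + half) / k < alpha or (e - half) / k > alpha:
                return e / k
    return e / n_perm


def _smooth_outliers(x: np.ndarray) -> np.ndarray:
    """Clamp isolated single-probe spikes to their median of three.

    Only points more than 3 robust SDs away from both neighbours are
    touched, so ordinary noise keeps its independence (a blanket filter
    would correlate neighbours and wreck the permutation null).
    """
    if len(x) < 3:
        return x
    sigma = np.sqrt(_noise_var(x))
    if sigma <= 0:
        return x
    gap_prev = np.abs(x[1:-1] - x[:-2])
    gap_next = np.abs(x[1:-1] - x[2:])
    spike = (gap_prev > 3 * sigma) & (gap_next > 3 * sigma)
    if not spike.any():
        return x
    y = x.copy()
    med3 = np.median(np.stack([x[:-2], x[1:-1], x[2:]]), axis=0)
    y[1:-1][spike] = med3[spike]
    return y


def _rss(x: np.ndarray, bounds: list[int]) -> float:
    total = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = x[a:b]
        total += float(np.sum((seg - seg.mean()) ** 2))
    return total


def _noise_var(x: np.ndarray) -> float:
    """Robust noise variance from successive differences."""
    if len(x) < 2:
        return 0.0
    d = np.diff(x)
    sigma = np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0)
    return float(sigma**2)


def _prune(x: np.ndarray, bounds: list[int], prune_sd: float) -> list[int]:
    """Merge adjacent segments whose split is not worth (prune_sd)^2 x var."""
    tol = prune_sd**2 * _noise_var(x)
    bounds = list(bounds)
    while len(bounds) > 2:
        deltas = []
        for t in range(1, len(bounds) - 1):
            a, b, c = bounds[t - 1], bounds[t], bounds[t + 1]
            m1, m2 = x[a:b].mean(), x[b:c].mean()
            k1, k2 = b - a, c - b
            deltas.append(k1 * k2 / (k1 + k2) * (m1 - m2) ** 2)
        t_min = int(np.argmin(deltas))
        if deltas[t_min] < tol:
            del bounds[t_min + 1]
        else:
            break
    return bounds


def cbs_segment(
    values,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    min_width: int = 2,
    seed: int = 0,
    prune_sd: float = 1.5,
    smooth_outliers: bool = True,
    chromosome: int = 0,
) -> list[Segment]:
    """Segment one sequence into constant-mean pieces.

    Recursively locates the arc maximizing :func:`cbs_max_statistic`,
    keeps the split when the permutation p-value is below ``alpha``, and
    finally prunes splits not supported by the residual noise.  Segment
    means are taken from the original (unsmoothed) values.  Deterministic
    given ``seed``.
    """
    x_orig = np.asarray(values, dtype=float)
    n = len(x_orig)
    if n == 0:
        return []
    if n < max(4, 2 * min_width):
        return [Segment(chromosome, 1, n, float(x_orig.mean()), n)]
    x = _smooth_outliers(x_orig) if smooth_outliers else x_orig
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    bounds: list[int] = [0, n]

    def recurse(lo: int, hi: int) -> None:
        m = hi - lo
        if m < max(4, 2 * min_width):
            return
        seg = x[lo:hi]
        if np.ptp(seg) < _EPS:
            return
        idx = _ArcIndex.get(m, min_width)
        observed, i, j = idx.max_stat(seg)
        if observed <= 0.0:
            return
        p = _perm_pvalue(seg, observed, idx, alpha, n_perm, rng)
        if p >= alpha:
            return
        cuts = sorted({c for c in (i, j) if 0 < c < m})
        if not cuts:
            return
        for c in cuts:
            bounds.append(lo + c)
        pieces = [lo] + [lo + c for c in cuts] + [hi]
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, n)
    bounds = sorted(set(bounds))
    bounds = _prune(x, bounds, prune_sd)
    return [
        Segment(chromosome, a + 1, b, float(x_orig[a:b].mean()), b - a)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def segment_profileset(
    profiles: AcghProfileSet, params: CbsParams | None = None
) -> list[SegmentedProfile]:
    """Apply :func:`cbs_segment` per sample, per chromosome.

    Segments never span chromosome boundaries.  Each (sample,
    chromosome) pair gets its own seed stream derived from
    ``params.seed``, so partial reruns reproduce.
    """
    params = params or CbsParams()
    out: list[SegmentedProfile] = []
    chroms = profiles.chromosomes()
    for s_idx, sample in enumerate(profiles.samples):
        col = profiles.sample_values(sample)
        segments: list[Segment] = []
        levels = np.empty_like(col)
        for chrom in chroms:
            sl = profiles.chromosome_slice(chrom)
            sub_seed = int(
                np.random.SeedSequence(
                    entropy=params.seed, spawn_key=(s_idx, chrom)
                ).generate_state(1)[0] % (2**31)
            )
            try:
                segs = cbs_segment(
                    col[sl],
                    alpha=params.alpha,
                    n_perm=params.n_perm,
                    min_width=params.min_width,
                    seed=sub_seed,
                    prune_sd=params.prune_sd,
                    smooth_outliers=params.smooth_outliers,
                    chromosome=chrom,
                )
            except ValueError as exc:
                raise ValueError(
                    f"CBS failed for sample {sample!r} chromosome {chrom}: {exc}"
                ) from exc
            for seg in segs:
                levels[sl.start + seg.start_index - 1: sl.start + seg.end_index] = seg.mean
            segments.extend(segs)
        out.append(SegmentedProfile(sample_id=sample, segments=segments,
                                    probe_level_values=levels))
    return out
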