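"""Dimension reduction of probe-level calls into contiguous regions.

Adjacent probes whose call patterns across samples are (nearly)
identical carry redundant information.  A greedy left-to-right merge
within each chromosome grows a region while the fraction of probe-sample
hard calls that disagree with the region's per-sample majority call
stays within the information-loss budget (default 1%).  Uncalled entries
carry no information and count as agreeing with anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CallMatrix, UNCALLED

_CALL_CODES = (-1, 0, 1)


@dataclass
class Region:
    chromosome: int
    start_index: int   # 1-based inclusive probe index within the chromosome
    end_index: int
    n_probes: int


@dataclass
class RegionCallMatrix:
    regions: list[Region]
    samples: list[str]
    calls: np.ndarray          # (n_regions, n_samples) representative hard calls
    probs: np.ndarray          # (n_regions, n_samples, 3) mean merged posteriors
    achieved_loss: float
    n_total_probes: int
    probe_positions: pd.DataFrame | None = None  # genomic spans, for export

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def _majority(counts: np.ndarray, first_call: np.ndarray) -> np.ndarray:
    """Per-sample majority call from per-state counts; ties -> first probe's call.

    ``counts`` is (n_samples, 3) over states (-1, 0, 1); samples with no
    called probe get UNCALLED.
    """
    n_samples = counts.shape[0]
    out = np.full(n_samples, UNCALLED, dtype=np.int8)
    total = counts.sum(axis=1)
    best = counts.max(axis=1)
    for s in range(n_samples):
        if total[s] == 0:
            continue
        winners = [c for k, c in enumerate(_CALL_CODES) if counts[s, k] == best[s]]
        if len(winners) == 1:
            out[s] = winners[0]
        elif first_call[s] in winners:
            out[s] = first_call[s]
        else:
            out[s] = winners[0]
    return out


def reduce_regions(calls: CallMatrix, threshold: float = 0.01) -> RegionCallMatrix:
    """Greedy majority-merge under an information-loss budget.

    A region's loss is the fraction of (called) probe-sample entries
    whose hard call differs from the region's per-sample majority call,
    over all samples x probes of the region.  The current region is
    extended while the extended region's loss stays <= ``threshold``.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    if calls.n_probes == 0:
        raise ValueError("empty call matrix")
    n_samples = len(calls.samples)
    chrom_arr = calls.probes["chromosome"].to_numpy()
    merged = calls.merged_probs
    hard = calls.calls

    regions: list[Region] = []
    rep_calls: list[np.ndarray] = []
    rep_probs: list[np.ndarray] = []
    total_mismatch = 0.0

    for chrom in np.unique(chrom_arr):
        rows = np.flatnonzero(chrom_arr == chrom)
        start = 0
        while start < len(rows):
            # counts[s, k]: called probes of sample s in state k within region
            counts = np.zeros((n_samples, 3), dtype=np.int64)
            first_call = hard[rows[start]].copy()
            end = start
            _accumulate(counts, hard[rows[start]])
            while end + 1 < len(rows):
                cand = counts.copy()
                _accumulate(cand, hard[rows[end + 1]])
                n_p = end + 2 - start
                mism = int((cand.sum(axis=1) - cand.max(axis=1, initial=0)).sum())
                if mism / (n_samples * n_p) <= threshold:
                    counts = cand
                    end += 1
                else:
                    break
            n_p = end - start + 1
            maj = _majority(counts, first_call)
            mism = int((counts.sum(axis=1) - counts.max(axis=1, initial=0)).sum())
            total_mismatch += mism
            regions.append(Region(
                chromosome=int(chrom),
                start_index=start + 1,
                end_index=end + 1,
                n_probes=n_p,
            ))
            rep_calls.append(maj)
            rep_probs.append(merged[rows[start]:rows[end] + 1].mean(axis=0))
            start = end + 1

    pos = calls.probes["position"].to_numpy()
    spans = []
    for r in regions:
        rows = np.flatnonzero(chrom_arr == r.chromosome)
        spans.append((
            r.chromosome,
            int(pos[rows[r.start_index - 1]]),
            int(pos[rows[r.end_index - 1]]),
        ))
    probe_positions = pd.DataFrame(spans, columns=["chromosome", "start_bp", "end_bp"])
    achieved = total_mismatch / (n_samples * calls.n_probes)
    if achieved > threshold + 1e-12:
        raise AssertionError("information loss exceeded threshold")  # contract
    return RegionCallMatrix(
        regions=regions,
        samples=list(calls.samples),
        calls=np.vstack(rep_calls).astype(np.int8),
        probs=np.stack(rep_probs),
        achieved_loss=float(achieved),
        n_total_probes=calls.n_probes,
        probe_positions=probe_positions,
    )


def _accumulate(counts: np.ndarray, probe_calls: np.ndarray) -> None:
    for k, c in enumerate(_CALL_CODES):
        counts[:, k] += probe_calls == c


def region_weights(regioncalls: RegionCallMatrix) -> np.ndarray:
    """Probe-count weights per region; non-negative, sum to 1."""
    w = np.array([r.n_probes for r in regioncalls.regions], dtype=float)
    return w / regioncalls.n_total_probes
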