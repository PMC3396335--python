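"""Readers and writers for the pipeline's tab-separated and JSON artifacts.

All coordinates in TSV outputs are 1-based inclusive; chromosome 23 is
written as "X" and read back as 23.  Column orders are documented in
docs/formats.md.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import CallMatrix
from .profiles import AcghProfileSet
from .regions import RegionCallMatrix
from .segmentation import SegmentedProfile

_META_COLS = ("probe_id", "chromosome", "position")


def _chrom_to_str(c: int) -> str:
    return "X" if c == 23 else str(c)


def _chrom_from_str(s: str) -> int:
    s = str(s).strip()
    if s.upper() == "X":
        return 23
    try:
        c = int(s)
    except ValueError as exc:
        raise ValueError(f"bad chromosome {s!r}") from exc
    if not (1 <= c <= 23):
        raise ValueError(f"chromosome {c} out of range 1-23")
    return c


def read_probe_matrix(path: str | Path, stage_labels: dict[str, str] | None = None) -> AcghProfileSet:
    """Read a probe-level log2-ratio matrix TSV.

    Header: probe_id, chromosome, position, then one column per sample.
    Rows are sorted by (chromosome, position) on load; duplicate probe
    ids and non-numeric value cells are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    for col in sample_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"(row {row + 2}, column {col!r})"
            )
        df[col] = parsed
    probes = pd.DataFrame(
        {
            "chromosome": [_chrom_from_str(c) for c in df["chromosome"]],
            "position": pd.to_numeric(df["position"]).astype(int),
        },
        index=df["probe_id"].tolist(),
    )
    values = df[sample_cols].copy()
    values.index = df["probe_id"].tolist()
    return AcghProfileSet(probes, values, stage_labels or {})


def write_probe_matrix(profiles: AcghProfileSet, path: str | Path) -> None:
    out = pd.DataFrame({
        "probe_id": profiles.probes.index,
        "chromosome": [_chrom_to_str(c) for c in profiles.probes["chromosome"]],
        "position": profiles.probes["position"].to_numpy(),
    })
    out = pd.concat([out.reset_index(drop=True),
                     profiles.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_segments(
    segmented: list[SegmentedProfile], profiles: AcghProfileSet, path: str | Path
) -> None:
    """BED-like TSV: sample, chromosome, start/end genomic position, n_probes, mean."""
    pos = profiles.probes["position"].to_numpy()
    chrom_arr = profiles.probes["chromosome"].to_numpy()
    rows = []
    for sp in segmented:
        for seg in sp.segments:
            cr = np.flatnonzero(chrom_arr == seg.chromosome)
            rows.append((
                sp.sample_id, _chrom_to_str(seg.chromosome),
                int(pos[cr[seg.start_index - 1]]), int(pos[cr[seg.end_index - 1]]),
                seg.n_probes, round(seg.mean, 6),
            ))
    pd.DataFrame(
        rows, columns=["sample", "chromosome", "start", "end", "n_probes", "mean"]
    ).to_csv(path, sep="\t", index=False)


def write_calls(calls: CallMatrix, path: str | Path) -> None:
    """Calls TSV: probe metadata, then per sample the hard call and the
    three merged probabilities (loss/normal/gain)."""
    merged = calls.merged_probs
    data = {
        "probe_id": calls.probes.index,
        "chromosome": [_chrom_to_str(c) for c in calls.probes["chromosome"]],
        "position": calls.probes["position"].to_numpy(),
    }
    for j, s in enumerate(calls.samples):
        data[f"{s}.call"] = calls.calls[:, j]
        data[f"{s}.p_loss"] = np.round(merged[:, j, 0], 6)
        data[f"{s}.p_normal"] = np.round(merged[:, j, 1], 6)
        data[f"{s}.p_gain"] = np.round(merged[:, j, 2], 6)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> CallMatrix:
    """Read a calls TSV written by :func:`write_calls`.

    Raw 4-state posteriors are reconstructed with the amplification
    share folded into gain (the merged view is what the file stores).
    """
    df = pd.read_csv(Path(path), sep="\t")
    samples = [c[:-5] for c in df.columns if c.endswith(".call")]
    probes = pd.DataFrame(
        {
            "chromosome": [_chrom_from_str(c) for c in df["chromosome"]],
            "position": df["position"].astype(int).to_numpy(),
        },
        index=df["probe_id"].astype(str).tolist(),
    )
    n = len(df)
    calls = np.empty((n, len(samples)), dtype=np.int8)
    probs = np.zeros((n, len(samples), 4))
    for j, s in enumerate(samples):
        calls[:, j] = df[f"{s}.call"].to_numpy()
        probs[:, j, 0] = df[f"{s}.p_loss"]
        probs[:, j, 1] = df[f"{s}.p_normal"]
        probs[:, j, 2] = df[f"{s}.p_gain"]
    probs /= probs.sum(axis=2, keepdims=True)
    return CallMatrix(probes=probes, samples=samples, calls=calls, probs=probs)


def write_regions(regioncalls: RegionCallMatrix, path: str | Path) -> None:
    spans = regioncalls.probe_positions
    data = {
        "chromosome": [_chrom_to_str(r.chromosome) for r in regioncalls.regions],
        "start": spans["start_bp"].to_numpy() if spans is not None
        else [r.start_index for r in regioncalls.regions],
        "end": spans["end_bp"].to_numpy() if spans is not None
        else [r.end_index for r in regioncalls.regions],
        "n_probes": [r.n_probes for r in regioncalls.regions],
    }
    for j, s in enumerate(regioncalls.samples):
        data[s] = regioncalls.calls[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_truth_segments(truth_frame: pd.DataFrame, path: str | Path) -> None:
    out = truth_frame.copy()
    out["chromosome"] = [_chrom_to_str(c) for c in out["chromosome"]]
    out.to_csv(path, sep="\t", index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
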