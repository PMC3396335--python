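"""Normalization, wave removal and MAD-based array quality control.

Median normalization centres each array at log2 ratio 0.  De-waving
removes the slowly oscillating, genomic-position-dependent bias typical
of aCGH ("waves") while preserving true copy-number steps.  Array
quality is summarized by the unscaled median absolute deviation (MAD) of
a breakpoint-free chromosome arm; arrays above a MAD threshold are
excluded together with their matched partner when a pairing is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing, binary_dilation
from scipy.signal import savgol_filter

from .profiles import AcghProfileSet

# Approximate centromere coordinates (bp) used to split arms, autosomes + X.
DEFAULT_CENTROMERES_BP: dict[int, int] = {
    1: 125_000_000, 2: 93_300_000, 3: 91_000_000, 4: 50_400_000,
    5: 48_400_000, 6: 61_000_000, 7: 59_900_000, 8: 45_600_000,
    9: 49_000_000, 10: 40_200_000, 11: 53_700_000, 12: 35_800_000,
    13: 17_900_000, 14: 17_600_000, 15: 19_000_000, 16: 36_600_000,
    17: 24_000_000, 18: 17_200_000, 19: 26_500_000, 20: 27_500_000,
    21: 13_200_000, 22: 14_700_000, 23: 60_600_000,
}


def median_normalize(profiles: AcghProfileSet) -> AcghProfileSet:
    """Subtract each sample's median log2 ratio (missing values ignored)."""
    out = profiles.values.copy()
    for sample in profiles.samples:
        col = out[sample]
        if col.isna().all():
            raise ValueError(f"sample {sample!r} has no non-missing values")
        out[sample] = col - col.median(skipna=True)
    return profiles.with_values(out)


def dewave(
    profiles: AcghProfileSet,
    span: float = 0.3,
    wave_span: float | None = None,
    signal_mask_sd: float = 2.0,
) -> AcghProfileSet:
    """Remove the wave artifact per sample, per chromosome.

    Two-scale decomposition.  A running-median trend over a wide window
    (``span`` of the chromosome's probes) follows true copy-number
    plateaus exactly — a median is edge-preserving — while averaging out
    any oscillation shorter than the window.  The wave is then estimated
    from the trend residual with a narrow quadratic Savitzky-Golay
    smooth (window ``wave_span``, default span/10) and subtracted from
    the input.  Residuals more than ``signal_mask_sd`` robust SDs from
    the residual median are treated as copy-number signal the trend missed (short
    aberrations), not wave, and are interpolated over before the wave
    fit.  True steps therefore survive, noise is essentially untouched,
    and only the slow oscillatory component is removed.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if wave_span is None:
        wave_span = span / 10.0
    out = profiles.values.to_numpy(dtype=float).copy()
    for chrom in profiles.chromosomes():
        sl = profiles.chromosome_slice(chrom)
        n = sl.stop - sl.start
        if span * n < 10:
            raise ValueError(
                f"span {span} covers fewer than 10 probes on chromosome {chrom}"
            )
        wide = _odd(max(int(round(span * n)), 11))
        narrow = _odd(max(int(round(wave_span * n)), 15))
        for j in range(out.shape[1]):
            y = out[sl, j]
            ok = np.isfinite(y)
            if ok.sum() < 10:
                continue
            series = pd.Series(y)
            # full windows only; extend flat into the half-window edges so the
            # shrinking edge windows cannot drag the trend onto the wave
            win = min(wide, n)
            trend = (
                series.rolling(win, center=True, min_periods=win)
                .median().ffill().bfill().to_numpy()
            )
            if np.isnan(trend).all():  # chromosome shorter than the window
                trend = np.full(n, series.median())
            resid = y - trend
            med = np.median(resid[ok])
            scale = 1.4826 * np.median(np.abs(resid[ok] - med))
            signal = np.abs(resid - med) > signal_mask_sd * max(scale, 1e-12)
            # close gaps and pad so partially flagged aberrations are
            # masked contiguously, edges included
            signal = binary_closing(signal, structure=np.ones(5, dtype=bool))
            signal = binary_dilation(signal, structure=np.ones(5, dtype=bool))
            keep = ok & ~signal
            if keep.sum() < 10:
                keep = ok
            # Savitzky-Golay needs a gap-free series; interpolate over
            # NaNs and masked signal probes
            filled = np.interp(np.arange(n), np.flatnonzero(keep), resid[keep])
            wave = savgol_filter(filled, min(narrow, n - (n + 1) % 2), polyorder=2,
                                 mode="interp")
            y[ok] = y[ok] - wave[ok]
            out[sl, j] = y
    return profiles.with_values(out)


def _odd(k: int) -> int:
    return k if k % 2 == 1 else k + 1


@dataclass
class QcReport:
    mad: dict[str, float]
    qc_arm: tuple[int, str]
    threshold: float
    excluded: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "qc_arm": {"chromosome": self.qc_arm[0], "arm": self.qc_arm[1]},
            "threshold": self.threshold,
            "mad": {s: float(m) for s, m in self.mad.items()},
            "excluded": sorted(self.excluded),
        }


def mad_qc(
    profiles: AcghProfileSet,
    qc_arm: tuple[int, str] = (2, "q"),
    threshold: float = 0.50,
    pairing: dict[str, str] | None = None,
    centromeres: dict[int, int] | None = None,
) -> QcReport:
    """Unscaled MAD of a breakpoint-free arm; exclude noisy arrays.

    MAD = median(|x - median(x)|), not rescaled to the normal SD.
    Samples with MAD > ``threshold`` are excluded; when ``pairing`` maps
    samples to their matched partners, each excluded sample drags its
    partner out as well (matched-pairs design).
    """
    chrom, arm = qc_arm
    if arm not in ("p", "q"):
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")
    cent = (centromeres or DEFAULT_CENTROMERES_BP).get(chrom)
    if cent is None:
        raise ValueError(f"no centromere coordinate for chromosome {chrom}")
    try:
        sl = profiles.chromosome_slice(chrom)
    except KeyError as exc:
        raise ValueError(f"QC arm chromosome {chrom} absent from probe grid") from exc
    pos = profiles.probes["position"].to_numpy()[sl]
    mask = pos > cent if arm == "q" else pos <= cent
    if mask.sum() < 20:
        raise ValueError(
            f"QC arm {chrom}{arm} has {int(mask.sum())} probes, need >= 20"
        )
    arm_rows = np.flatnonzero(profiles.probes["chromosome"].to_numpy() == chrom)
    arm_rows = arm_rows[mask]
    sub = profiles.values.iloc[arm_rows]
    mads: dict[str, float] = {}
    for sample in profiles.samples:
        x = sub[sample].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        med = np.median(x)
        mads[sample] = float(np.median(np.abs(x - med)))
    excluded = {s for s, m in mads.items() if m > threshold}
    if pairing:
        partners = set()
        for s in excluded:
            if s in pairing:
                partners.add(pairing[s])
        for a, b in pairing.items():
            if b in excluded:
                partners.add(a)
        excluded |= partners
    return QcReport(mad=mads, qc_arm=(chrom, arm), threshold=threshold, excluded=excluded)


def drop_excluded(profiles: AcghProfileSet, report: QcReport) -> AcghProfileSet:
    """Profile set without the samples excluded by :func:`mad_qc`."""
    keep = [s for s in profiles.samples if s not in report.excluded]
    return AcghProfileSet(
        profiles.probes.copy(),
        profiles.values[keep].copy(),
        {s: l for s, l in profiles.stage_labels.items() if s in keep},
    )


def drop_sparse_probes(profiles: AcghProfileSet, max_missing: float = 0.2) -> AcghProfileSet:
    """Drop probes missing in more than ``max_missing`` of samples."""
    frac = profiles.values.isna().mean(axis=1)
    keep = frac <= max_missing
    return AcghProfileSet(
        profiles.probes[keep.to_numpy()].copy(),
        profiles.values[keep.to_numpy()].copy(),
        dict(profiles.stage_labels),
    )
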