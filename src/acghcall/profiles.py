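"""In-memory container for probe-level aCGH log2-ratio data.

An :class:`AcghProfileSet` couples a probe grid (probe id, chromosome,
genomic position) with a probes x samples matrix of log2 ratios and an
optional stage label per sample.  Probes are always kept sorted by
(chromosome, position); chromosome X is stored as integer 23.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGE_LABELS = ("early", "advanced", "unknown")


@dataclass
class AcghProfileSet:
    """Probe grid plus per-sample log2-ratio values.

    Parameters
    ----------
    probes
        DataFrame indexed by probe id with integer columns ``chromosome``
        (1-23) and ``position`` (base pairs, 1-based).
    values
        DataFrame indexed like ``probes`` with one float column per sample.
    stage_labels
        Mapping sample id -> {'early', 'advanced', 'unknown'}.  Samples
        absent from the mapping are 'unknown'.
    """

    probes: pd.DataFrame
    values: pd.DataFrame
    stage_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.probes.index.is_unique:
            dup = self.probes.index[self.probes.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if list(self.probes.index) != list(self.values.index):
            self.values = self.values.loc[self.probes.index]
        order = np.lexsort(
            (self.probes["position"].to_numpy(), self.probes["chromosome"].to_numpy())
        )
        if not np.array_equal(order, np.arange(len(order))):
            self.probes = self.probes.iloc[order]
            self.values = self.values.iloc[order]
        chrom = self.probes["chromosome"].to_numpy()
        if len(chrom) and (chrom.min() < 1 or chrom.max() > 23):
            raise ValueError("chromosome out of range 1-23")
        for s, lab in self.stage_labels.items():
            if lab not in STAGE_LABELS:
                raise ValueError(f"bad stage label {lab!r} for sample {s!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def stage_of(self, sample: str) -> str:
        return self.stage_labels.get(sample, "unknown")

    def chromosomes(self) -> list[int]:
        return sorted(set(self.probes["chromosome"].tolist()))

    def chromosome_slice(self, chromosome: int) -> slice:
        """Positional slice of the (sorted) probe grid for one chromosome."""
        chrom = self.probes["chromosome"].to_numpy()
        idx = np.flatnonzero(chrom == chromosome)
        if idx.size == 0:
            raise KeyError(f"chromosome {chromosome} absent from probe grid")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def sample_values(self, sample: str) -> np.ndarray:
        return self.values[sample].to_numpy(dtype=float)

    def with_values(self, new_values: np.ndarray | pd.DataFrame) -> "AcghProfileSet":
        """Copy of this set with the value matrix replaced (same grid)."""
        if isinstance(new_values, np.ndarray):
            new_values = pd.DataFrame(
                new_values, index=self.values.index, columns=self.values.columns
            )
        return AcghProfileSet(self.probes.copy(), new_values, dict(self.stage_labels))

    def copy(self) -> "AcghProfileSet":
        return self.with_values(self.values.copy())
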