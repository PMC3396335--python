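"""Clinical records for the 32-patient ovarian carcinoma cohort.

The packaged fixture transcribes the published patient table of the
matched early/advanced-stage study cohort: 16 FIGO stage I ("early") and
16 FIGO stage III-IV ("advanced") carcinomas with age, histological
subtype (clearcell C, endometrioid E, mucinous M, serous S), grade,
adjuvant chemotherapy flag, staging quality, vital status, overall and
progression-free survival in months, and the published two-cluster
label (A/B) from unsupervised clustering of the called copy-number data.

One row (T318) has PFS > OS as printed; it is transcribed verbatim,
without correction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

HISTOLOGIES = ("C", "E", "M", "S")
STAGE_GROUPS = ("early", "advanced")
CLUSTERS = ("A", "B", "unassigned")

_COLUMNS = [
    "sample_id", "age", "stage_group", "figo_stage", "histology", "grade",
    "chemo", "staging", "status", "os_months", "progression", "pfs_months",
    "cluster",
]


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    age: int
    stage_group: str          # 'early' | 'advanced'
    figo_stage: str           # FIGO stage as printed, e.g. 'Ia', 'IIIc'
    histology: str            # C | E | M | S
    grade: int                # 1 | 2 | 3
    chemo: bool               # adjuvant chemotherapy given
    staging_quality: str      # optimal | modified | minimal | incomplete | unknown
    status: str               # 'dead' | 'alive'
    os_months: float
    progression: bool
    pfs_months: float
    cluster: str = "unassigned"

    def __post_init__(self) -> None:
        if not (18 <= self.age <= 110):
            raise ValueError(f"{self.sample_id}: age {self.age} outside [18, 110]")
        if self.stage_group not in STAGE_GROUPS:
            raise ValueError(f"{self.sample_id}: bad stage_group {self.stage_group!r}")
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"{self.sample_id}: bad histology {self.histology!r}")
        if self.grade not in (1, 2, 3):
            raise ValueError(f"{self.sample_id}: bad grade {self.grade!r}")
        if self.status not in ("dead", "alive"):
            raise ValueError(f"{self.sample_id}: bad status {self.status!r}")
        if self.os_months < 0 or self.pfs_months < 0:
            raise ValueError(f"{self.sample_id}: negative survival time")
        if self.cluster not in CLUSTERS:
            raise ValueError(f"{self.sample_id}: bad cluster {self.cluster!r}")

    @property
    def dead(self) -> bool:
        return self.status == "dead"


class CohortTable:
    """Ordered collection of :class:`ClinicalRecord` with unique sample ids."""

    def __init__(self, records: list[ClinicalRecord]):
        ids = [r.sample_id for r in records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sample id {dup!r}")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> ClinicalRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def subset(self, predicate) -> "CohortTable":
        return CohortTable([r for r in self.records if predicate(r)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "sample_id": r.sample_id,
                "age": r.age,
                "stage_group": r.stage_group,
                "figo_stage": r.figo_stage,
                "histology": r.histology,
                "grade": r.grade,
                "chemo": "yes" if r.chemo else "no",
                "staging": r.staging_quality,
                "status": "Dead" if r.dead else "Alive",
                "os_months": r.os_months,
                "progression": "yes" if r.progression else "no",
                "pfs_months": r.pfs_months,
                "cluster": r.cluster,
            })
        return pd.DataFrame(rows, columns=_COLUMNS)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "<frame>") -> "CohortTable":
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{source}: missing columns {missing}")
        records = []
        for _, row in df.iterrows():
            try:
                records.append(ClinicalRecord(
                    sample_id=str(row["sample_id"]),
                    age=int(row["age"]),
                    stage_group=str(row["stage_group"]),
                    figo_stage=str(row["figo_stage"]),
                    histology=str(row["histology"]),
                    grade=int(row["grade"]),
                    chemo=str(row["chemo"]).lower() in ("yes", "true", "1"),
                    staging_quality=str(row["staging"]),
                    status=str(row["status"]).lower(),
                    os_months=float(row["os_months"]),
                    progression=str(row["progression"]).lower() in ("yes", "true", "1"),
                    pfs_months=float(row["pfs_months"]),
                    cluster=str(row["cluster"]),
                ))
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{source}: bad record {row.get('sample_id')!r}: {exc}") from exc
        return cls(records)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortTable":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except (OSError, pd.errors.ParserError) as exc:
            raise ValueError(f"cannot read clinical table {path}: {exc}") from exc
        return cls.from_frame(df, source=str(path))


def load_table1_fixture() -> CohortTable:
    """Load the packaged 32-patient clinical table.

    Returns all 32 records (16 early, 16 advanced) with the published
    two-cluster labels (19 in cluster A, 13 in cluster B).
    """
    ref = importlib.resources.files("acghcall").joinpath("data/table1.tsv")
    try:
        with importlib.resources.as_file(ref) as path:
            table = CohortTable.read_tsv(path)
    except (FileNotFoundError, ValueError) as exc:
        raise RuntimeError(f"packaged fixture data/table1.tsv unusable: {exc}") from exc
    if len(table) != 32:
        raise RuntimeError(
            f"packaged fixture data/table1.tsv corrupt: {len(table)} records, expected 32"
        )
    return table


# column order of the fixture/clinical TSV, for writers elsewhere
CLINICAL_COLUMNS = list(_COLUMNS)
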