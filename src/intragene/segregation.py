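"""Mendelian segregation testing of progeny resistance counts.

A hemizygous single dominant resistance locus segregates 3:1 (resistant :
susceptible) on selfing and 1:1 in a backcross to wild type. Observed progeny
counts are tested against the expected ratio with a Pearson chi-square
goodness-of-fit test on 1 degree of freedom, without continuity correction.
Control crosses (wild type x wild type) carry no expected ratio and pass
through untested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SegregationRecord:
    """Progeny counts for one cross, with the expected ratio when testable."""

    ovule_parent: str
    pollen_parent: str
    n_resistant: int
    n_susceptible: int
    expected_ratio: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.n_resistant < 0 or self.n_susceptible < 0:
            raise ValueError("progeny counts must be >= 0")
        if self.expected_ratio is not None:
            r, s = self.expected_ratio
            if r <= 0 or s <= 0:
                raise ValueError("expected ratio components must be positive")
            if self.n_resistant + self.n_susceptible == 0:
                raise ValueError("cannot test a ratio against zero progeny")

    @property
    def total(self) -> int:
        return self.n_resistant + self.n_susceptible


#: Chlorsulfuron-resistance segregation counts among progeny of two intragenic
#: tobacco lines (selfs, reciprocal backcrosses, and wild-type controls), used
#: as the package's worked example.
EXAMPLE_PROGENY_TABLE: list[SegregationRecord] = [
    SegregationRecord("021401-1", "021401-1", 54, 15, (3, 1)),
    SegregationRecord("021401-4", "021401-4", 67, 18, (3, 1)),
    SegregationRecord("021401-4", "021401-4", 74, 23, (3, 1)),
    SegregationRecord("Wild-type", "021401-1", 28, 26, (1, 1)),
    SegregationRecord("Wild-type", "021401-1", 60, 46, (1, 1)),
    SegregationRecord("Wild-type", "021401-4", 40, 41, (1, 1)),
    SegregationRecord("021401-1", "Wild-type", 39, 37, (1, 1)),
    SegregationRecord("021401-4", "Wild-type", 42, 37, (1, 1)),
    SegregationRecord("021401-4", "Wild-type", 58, 52, (1, 1)),
    SegregationRecord("Wild-type", "Wild-type", 0, 188, None),
    SegregationRecord("Wild-type", "Wild-type", 0, 59, None),
]


def chisq_gof(record: SegregationRecord) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit against the record's expected ratio.

    No Yates continuity correction is applied. Returns (chi2, df=1, p). The
    statistic is exact to float precision; truncate only for display.
    """
    if record.expected_ratio is None:
        raise ValueError("record has no expected ratio (control cross)")
    r, s = record.expected_ratio
    n = record.total
    if n == 0:
        raise ValueError("zero total progeny")
    exp = (n * r / (r + s), n * s / (r + s))
    if min(exp) < 1:
        raise ValueError("expected count below 1 in one class")
    chi2, p = stats.chisquare([record.n_resistant, record.n_susceptible], exp)
    return float(chi2), 1, float(p)


def truncate2(x: float) -> float:
    """Two-decimal truncation, the display convention of segregation tables."""
    return math.floor(x * 100) / 100


def assess_single_locus(records: Sequence[SegregationRecord], alpha: float = 0.05,
                        ) -> tuple[list[dict], str]:
    """Per-record and overall verdicts for single-dominant-locus inheritance.

    A testable record is consistent iff p >= alpha; the overall verdict is
    "consistent" iff every testable record is, and "untestable" when no record
    carries an expected ratio.
    """
    if not records:
        raise ValueError("no records to assess")
    rows: list[dict] = []
    testable = 0
    all_ok = True
    for rec in records:
        row = {
            "ovule_parent": rec.ovule_parent, "pollen_parent": rec.pollen_parent,
            "n_resistant": rec.n_resistant, "n_susceptible": rec.n_susceptible,
            "ratio": f"{rec.expected_ratio[0]}:{rec.expected_ratio[1]}"
                     if rec.expected_ratio else "-",
        }
        if rec.expected_ratio is None:
            row.update(chi2=None, p=None, verdict="control")
        else:
            chi2, _, p = chisq_gof(rec)
            ok = p >= alpha
            row.update(chi2=chi2, p=p, verdict="consistent" if ok else "inconsistent")
            testable += 1
            all_ok = all_ok and ok
        rows.append(row)
    if testable == 0:
        overall = "untestable"
    else:
        overall = "consistent" if all_ok else "inconsistent"
    return rows, overall


def read_records_tsv(path) -> list[SegregationRecord]:
    """Read crosses from TSV columns (ovule_parent, pollen_parent, n_resistant,
    n_susceptible, ratio) with ratio written as "3:1", "1:1" or "-"."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        ratio = None
        raw = str(row["ratio"]).strip()
        if raw not in ("-", "", "nan"):
            r, s = raw.split(":")
            ratio = (int(r), int(s))
        records.append(SegregationRecord(
            row["ovule_parent"], row["pollen_parent"],
            int(row["n_resistant"]), int(row["n_susceptible"]), ratio))
    return records


def records_frame(records: Sequence[SegregationRecord], alpha: float = 0.05,
                  ) -> pd.DataFrame:
    """Assessment as a DataFrame ready for TSV output (adds chi2, p, verdict)."""
    rows, _ = assess_single_locus(records, alpha)
    return pd.DataFrame(rows)
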