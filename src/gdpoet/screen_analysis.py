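"""Screening statistics: how well does the r1 ratio track absolute r1?

The high-throughput screen scores peptides by r1 ratio (sample slope over
peptide-free GdCl3 slope); absolute r1 is only measured for a shortlist
after dialysis. These helpers quantify the link between the two metrics
(Pearson correlation with the exact t-based two-sided p-value), rank
candidates against a chosen baseline peptide, and flag "beneficial"
peptides — those whose r1 ratio strictly exceeds 1, the level of free Gd.

A bundled eleven-row screening table (six evolved peptides, four natural
EF-hand/calcium/lanthanide-binding peptides, and the peptide-free GdCl3
reference) ships with the package as ``load_screen_fixture``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("source", "sequence", "r1_ratio")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_two_sided: float
    n: int


class ScreenTable:
    """Thin validated wrapper around a pandas DataFrame of screen rows.

    Columns: ``source`` (label), ``sequence`` (may be empty for the
    reference row), ``r1_ratio``, and optionally ``absolute_r1``,
    ``group`` (natural / poet / reference), ``engine`` (motif / regex)
    and ``epoch``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"screen table missing columns: {missing}")
        ratios = frame["r1_ratio"].dropna()
        if (ratios <= 0).any():
            raise ValueError("r1_ratio values must be positive")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def reference_mask(self) -> pd.Series:
        if "group" in self.frame.columns:
            return self.frame["group"] == "reference"
        return self.frame["sequence"].isna() | (self.frame["sequence"] == "")


def load_screen_fixture() -> ScreenTable:
    """The packaged eleven-row screening table (ratios and absolute r1)."""
    with resources.files("gdpoet.data").joinpath("table1.csv").open() as fh:
        frame = pd.read_csv(fh)
    return ScreenTable(frame)


def correlate(table: ScreenTable, include_reference: bool = False) -> CorrelationResult:
    """Pearson correlation of r1_ratio vs absolute_r1 over rows with both.

    The peptide-free GdCl3 row is excluded by default: it anchors the ratio
    scale at 1 by construction and is not a peptide observation. The p-value
    is the exact two-sided t transform r*sqrt(n-2)/sqrt(1-r^2) on n-2 df.
    """
    frame = table.frame
    if not include_reference:
        frame = frame[~table.reference_mask()]
    frame = frame.dropna(subset=["r1_ratio", "absolute_r1"])
    n = len(frame)
    if n < 3:
        raise ValueError(f"need >= 3 rows with both metrics, have {n}")
    x = frame["r1_ratio"].to_numpy(float)
    y = frame["absolute_r1"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a correlation column")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r, r * r, float(res.pvalue), n)


def percent_improvement(value: float, reference: float) -> float:
    """100 * (value - reference) / reference."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return 100.0 * (value - reference) / reference


def classify_beneficial(r1_ratio: float | None) -> bool:
    """A peptide is beneficial iff its r1 ratio strictly exceeds 1, the
    ratio of free GdCl3 itself (the reference row is never beneficial)."""
    if r1_ratio is None or (isinstance(r1_ratio, float) and np.isnan(r1_ratio)):
        raise ValueError("r1_ratio is missing")
    return r1_ratio > 1.0


def screening_baseline(table: ScreenTable, group: str = "natural") -> tuple[str, float]:
    """The screening baseline: (source, r1_ratio) of the best row in
    ``group`` — by default the best natural (non-evolved) peptide."""
    frame = table.frame
    rows = frame[frame["group"] == group] if "group" in frame.columns else frame
    rows = rows.dropna(subset=["r1_ratio"])
    if rows.empty:
        raise ValueError(f"no rows in group {group!r}")
    best = rows.loc[rows["r1_ratio"].idxmax()]
    return str(best["source"]), float(best["r1_ratio"])


def epoch_summary(table: ScreenTable, baseline_label: str) -> pd.DataFrame:
    """Per (engine, epoch) group: how many evolved peptides strictly exceed
    the baseline row's r1 ratio. Empty groups report count 0/0 with
    ``empty = True``."""
    frame = table.frame
    base_rows = frame[frame["source"] == baseline_label]
    if base_rows.empty:
        raise ValueError(f"baseline row {baseline_label!r} not found")
    baseline = float(base_rows["r1_ratio"].iloc[0])
    if "group" in frame.columns:
        evolved = frame[frame["group"] == "poet"]
    else:
        evolved = frame.dropna(subset=["epoch"])
    records = []
    for (engine, epoch), grp in evolved.groupby(["engine", "epoch"], dropna=False):
        with_ratio = grp.dropna(subset=["r1_ratio"])
        n = len(with_ratio)
        exceeding = int((with_ratio["r1_ratio"] > baseline).sum())
        records.append(
            {
                "engine": engine,
                "epoch": epoch,
                "n": n,
                "n_exceeding": exceeding,
                "fraction": exceeding / n if n else np.nan,
                "empty": n == 0,
                "baseline": baseline,
            }
        )
    return pd.DataFrame.from_records(records)
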