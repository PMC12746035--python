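"""File formats: FASTA peptide lists and the CSV dialects of the pipeline.

All CSVs are comma-separated, dot-decimal, UTF-8 with required headers:

* training:  ``sequence,r1_ratio``
* screen:    ``source,sequence,r1_ratio[,absolute_r1,group,engine,epoch]``
* dilution (long, raw):     ``sample_id,well,concentration_mM,tr_ms,signal``
* dilution (long, pre-fit): ``sample_id,concentration_mM,t1_ms``

Concentration columns must be explicitly millimolar (``concentration_mM``);
readers reject other unit spellings unless ``assume_mM`` is set.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import validate_sequence
from .poet_engine import TrainingSet
from .relaxometry import DilutionSeries, SignalCurve
from .screen_analysis import ScreenTable


class FormatError(ValueError):
    """Input file violates the documented dialect."""


def _require_nonempty(path) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path}: empty input file")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a peptide FASTA into ordered (id, sequence) pairs.

    Sequences are uppercased and alphabet-validated (errors name the record
    and position); duplicate IDs are rejected.
    """
    _require_nonempty(path)
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {record.id!r}")
        seen.add(record.id)
        entries.append((record.id, validate_sequence(str(record.seq), name=record.id)))
    if not entries:
        raise FormatError(f"{path}: no FASTA records found")
    return entries


def write_fasta(path, entries: Iterable[tuple[str, str]],
                descriptions: dict[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(seq), id=name,
                  description=(descriptions or {}).get(name, ""))
        for name, seq in entries
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# CSV dialects


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    _require_nonempty(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty input file")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: header mismatch, missing columns {missing} "
            f"(found {list(frame.columns)})"
        )
    return frame


def read_training_csv(path) -> TrainingSet:
    frame = _read_csv(path, ("sequence", "r1_ratio"))
    if frame.empty:
        raise FormatError(f"{path}: no data rows")
    ratios = pd.to_numeric(frame["r1_ratio"], errors="raise")
    return TrainingSet.from_records(
        list(zip(frame["sequence"].astype(str), ratios.astype(float)))
    )


def write_training_csv(path, data: TrainingSet) -> None:
    pd.DataFrame(
        {"sequence": data.sequences, "r1_ratio": data.labels}
    ).to_csv(path, index=False)


def read_screen_csv(path) -> ScreenTable:
    frame = _read_csv(path, ("source", "sequence", "r1_ratio"))
    if frame.empty:
        raise FormatError(f"{path}: no data rows")
    for seq in frame["sequence"].dropna():
        if seq:
            validate_sequence(str(seq))
    return ScreenTable(frame)


def write_screen_csv(path, table: ScreenTable) -> None:
    table.frame.to_csv(path, index=False)


def read_dilution_csv(path, assume_mM: bool = False) -> list[DilutionSeries]:
    """Read dilution series (raw signal curves or pre-fit T1 values).

    The concentration column must be named ``concentration_mM``; with
    ``assume_mM`` a bare ``concentration`` column is accepted as mM.
    """
    frame = _read_csv(path, ("sample_id",))
    if assume_mM and "concentration" in frame.columns:
        frame = frame.rename(columns={"concentration": "concentration_mM"})
    if "concentration_mM" not in frame.columns:
        raise FormatError(
            f"{path}: need a 'concentration_mM' column (or pass assume_mM "
            "for a bare 'concentration' column)"
        )
    if (frame["concentration_mM"] < 0).any():
        raise FormatError(f"{path}: negative concentrations")

    series: list[DilutionSeries] = []
    if {"tr_ms", "signal"} <= set(frame.columns):
        for sample_id, grp in frame.groupby("sample_id", sort=False):
            points = []
            for (conc, well), wgrp in grp.groupby(
                ["concentration_mM", "well"], sort=False
            ):
                curve = SignalCurve(
                    tuple(wgrp["tr_ms"].astype(float)),
                    tuple(wgrp["signal"].astype(float)),
                    well_id=str(well),
                )
                points.append((float(conc), curve))
            series.append(DilutionSeries(tuple(points), sample_id=str(sample_id)))
    elif "t1_ms" in frame.columns:
        for sample_id, grp in frame.groupby("sample_id", sort=False):
            points = [
                (float(c), float(t))
                for c, t in zip(grp["concentration_mM"], grp["t1_ms"])
            ]
            series.append(DilutionSeries(tuple(points), sample_id=str(sample_id)))
    else:
        raise FormatError(
            f"{path}: expected either raw columns (well,tr_ms,signal) or "
            "pre-fit column t1_ms"
        )
    return series


def write_dilution_csv(path, series_list: list[DilutionSeries]) -> None:
    """Write dilution series in long format (raw if curves, else pre-fit)."""
    rows = []
    raw = any(
        isinstance(payload, SignalCurve)
        for s in series_list for _, payload in s.points
    )
    for s in series_list:
        for conc, payload in s.points:
            if isinstance(payload, SignalCurve):
                for tr, sig in zip(payload.tr_values, payload.signals):
                    rows.append(
                        {"sample_id": s.sample_id, "well": payload.well_id,
                         "concentration_mM": conc, "tr_ms": tr, "signal": sig}
                    )
            elif raw:
                raise ValueError("cannot mix raw curves and pre-fit T1 values")
            else:
                rows.append(
                    {"sample_id": s.sample_id, "concentration_mM": conc,
                     "t1_ms": payload}
                )
    pd.DataFrame(rows).to_csv(path, index=False)
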