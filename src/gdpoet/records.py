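"""Lightweight record type shared by the designer and the screen analysis."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class PeptideRecord:
    """One peptide with whatever measurements/predictions exist for it.

    ``source`` is free-text provenance (training, epoch tag, literature
    label); ``epoch`` and ``engine`` are filled for evolved candidates.
    """

    sequence: str | None
    source: str = ""
    r1_ratio: float | None = None
    absolute_r1: float | None = None
    predicted_score: float | None = None
    engine: str | None = None
    epoch: int | None = None
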