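"""Peptide physicochemistry: net charge, isoelectric point, composition.

Net charge follows the Henderson–Hasselbalch model with free termini: each
basic group (N-terminus, K, R, H) contributes +1/(1 + 10^(pH - pKa)) and
each acidic group (C-terminus, D, E, C, Y) contributes -1/(1 + 10^(pKa - pH)).
The sum is strictly decreasing in pH, so the isoelectric point (pI) is the
unique root in (0, 14), found by bisection.

Published pKa sets differ by a few tenths of a pH unit; three common tables
(Lehninger, EMBOSS, Sillero) are bundled and the table in force is carried
on every result. Absolute charges therefore depend on the table choice, but
sign and threshold behaviour near physiological/buffer pH are robust.

Composition analysis pools residue counts over a set of sequences and also
aggregates them into the seven standard side-chain classes (acidic, basic,
aliphatic, aromatic, hydroxylic, sulfur-containing, amidic), which partition
the 20-letter alphabet. Enrichment of a target set against a reference is
reported as pseudocounted log2 ratios of fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .alphabet import AMINO_ACIDS, validate_sequence

#: Side-chain classes; together they partition the 20-letter alphabet.
AA_CLASSES: dict[str, str] = {
    "Acidic": "DE",
    "Basic": "KHR",
    "Aliphatic": "AGILPV",
    "Aromatic": "FWY",
    "Hydroxylic": "ST",
    "Sulfur-containing": "CM",
    "Amidic": "NQ",
}

_POSITIVE_SIDE = "KRH"
_NEGATIVE_SIDE = "DECY"


@dataclass(frozen=True)
class PkaTable:
    """Ionizable-group pKa values: both termini plus the seven titratable
    side chains (D, E, C, Y, H, K, R)."""

    name: str
    n_term: float
    c_term: float
    side_chains: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set("DECYHKR") - set(self.side_chains)
        if missing:
            raise ValueError(f"pKa table missing side chains: {sorted(missing)}")
        for v in (self.n_term, self.c_term, *self.side_chains.values()):
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {v} outside (0, 14)")


PKA_TABLES: dict[str, PkaTable] = {
    "lehninger": PkaTable(
        "lehninger", n_term=9.69, c_term=2.34,
        side_chains={"D": 3.65, "E": 4.25, "C": 8.33, "Y": 10.07,
                     "H": 6.00, "K": 10.53, "R": 12.48},
    ),
    "emboss": PkaTable(
        "emboss", n_term=8.6, c_term=3.6,
        side_chains={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
                     "H": 6.5, "K": 10.8, "R": 12.5},
    ),
    "sillero": PkaTable(
        "sillero", n_term=8.2, c_term=3.2,
        side_chains={"D": 4.0, "E": 4.5, "C": 9.0, "Y": 10.0,
                     "H": 6.4, "K": 10.4, "R": 12.0},
    ),
}

DEFAULT_PKA = PKA_TABLES["lehninger"]


@dataclass(frozen=True)
class ChargeProfile:
    sequence: str
    ph: float
    net_charge: float
    isoelectric_point: float
    pka_table: str = DEFAULT_PKA.name


def net_charge(sequence: str, ph: float, table: PkaTable = DEFAULT_PKA) -> float:
    """Henderson–Hasselbalch net charge (elementary charges) at ``ph``.

    Free (unmodified) termini are assumed. Strictly decreasing in pH.
    """
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH {ph} outside (0, 14)")
    seq = validate_sequence(sequence)
    q = 1.0 / (1.0 + 10.0 ** (ph - table.n_term))
    q -= 1.0 / (1.0 + 10.0 ** (table.c_term - ph))
    for ch in seq:
        if ch in _POSITIVE_SIDE:
            q += 1.0 / (1.0 + 10.0 ** (ph - table.side_chains[ch]))
        elif ch in _NEGATIVE_SIDE:
            q -= 1.0 / (1.0 + 10.0 ** (table.side_chains[ch] - ph))
    return q


def isoelectric_point(
    sequence: str, table: PkaTable = DEFAULT_PKA, xtol: float = 1e-6
) -> float:
    """pH at which the net charge is zero, by bisection on (0, 14).

    Strict monotonicity of the charge curve guarantees a unique root; a
    standard peptide always has both termini, so the curve changes sign.
    """
    seq = validate_sequence(sequence)
    lo, hi = 1e-9, 14.0 - 1e-9
    q_lo = net_charge(seq, lo, table)
    q_hi = net_charge(seq, hi, table)
    if q_lo <= 0 or q_hi >= 0:
        raise ValueError("charge curve does not change sign in (0, 14)")
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def charge_profile(
    sequence: str, ph: float, table: PkaTable = DEFAULT_PKA
) -> ChargeProfile:
    return ChargeProfile(
        sequence=validate_sequence(sequence),
        ph=ph,
        net_charge=net_charge(sequence, ph, table),
        isoelectric_point=isoelectric_point(sequence, table),
        pka_table=table.name,
    )


@dataclass(frozen=True)
class CompositionProfile:
    """Pooled residue fractions (20-vector in AMINO_ACIDS order) and class
    fractions (7-vector in AA_CLASSES order) over a set of sequences."""

    aa_fractions: np.ndarray
    class_fractions: np.ndarray
    n_residues: int

    def fraction(self, residue: str) -> float:
        return float(self.aa_fractions[AMINO_ACIDS.index(residue)])

    def class_fraction(self, name: str) -> float:
        return float(self.class_fractions[list(AA_CLASSES).index(name)])


def composition(sequences: list[str]) -> CompositionProfile:
    """Pooled amino-acid and class composition of ``sequences``."""
    if not sequences:
        raise ValueError("composition of an empty sequence list is undefined")
    counts = np.zeros(20)
    for s in sequences:
        for ch in validate_sequence(s):
            counts[AMINO_ACIDS.index(ch)] += 1
    total = int(counts.sum())
    aa_fractions = counts / total
    class_fractions = np.array(
        [sum(aa_fractions[AMINO_ACIDS.index(c)] for c in members)
         for members in AA_CLASSES.values()]
    )
    return CompositionProfile(aa_fractions, class_fractions, total)


def uniform_composition() -> CompositionProfile:
    """The uniform 1/20 background used as a null reference."""
    aa = np.full(20, 1.0 / 20.0)
    cls = np.array([len(m) / 20.0 for m in AA_CLASSES.values()])
    return CompositionProfile(aa, cls, 20)


def enrichment(
    target: CompositionProfile,
    reference: CompositionProfile,
    pseudocount: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue and per-class log2((target + p) / (reference + p)).

    ``pseudocount`` defaults to 1/n_residues of the target profile, keeping
    the ratios finite when a residue is absent from either set. Identical
    profiles give all-zero ratios.
    """
    if pseudocount is None:
        pseudocount = 1.0 / target.n_residues
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    p = pseudocount
    per_aa = np.log2((target.aa_fractions + p) / (reference.aa_fractions + p))
    per_class = np.log2(
        (target.class_fractions + p) / (reference.class_fractions + p)
    )
    return per_aa, per_class
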