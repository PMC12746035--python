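"""The 20-letter amino-acid alphabet and sequence validation."""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)

PEPTIDE_LENGTH = 12  # the screening library is built from 12-mers


class AlphabetError(ValueError):
    """A sequence contains a character outside the 20-letter alphabet."""


def validate_sequence(sequence: str, *, name: str | None = None) -> str:
    """Uppercase ``sequence`` and verify every residue is a standard amino acid.

    Returns the normalized sequence; raises :class:`AlphabetError` naming the
    offending position (1-based) otherwise.
    """
    seq = sequence.strip().upper()
    for i, ch in enumerate(seq):
        if ch not in AA_SET:
            where = f" in record {name!r}" if name else ""
            raise AlphabetError(
                f"invalid residue {ch!r} at position {i + 1}{where}: "
                f"expected one of {AMINO_ACIDS}"
            )
    return seq
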