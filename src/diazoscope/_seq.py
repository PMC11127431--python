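"""Small shared sequence utilities (reverse complement, translation, GC)."""

from __future__ import annotations

from Bio.Seq import Seq

#: IUPAC nucleotide codes mapped to the set of unambiguous bases they stand for.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-ambiguous) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str, table: int = 11) -> str:
    """Translate a CDS with the bacterial genetic code (trailing stop kept)."""
    trimmed = nt[: len(nt) - len(nt) % 3]
    return str(Seq(trimmed).translate(table=table))


def gc_fraction(seq: str) -> float | None:
    """GC over unambiguous bases only; ``None`` when no A/C/G/T base exists.

    Ambiguous (non-ACGT) characters are excluded from numerator and
    denominator alike.
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)
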