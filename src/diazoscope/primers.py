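"""In-silico evaluation of nifH universal primers.

Each primer (possibly degenerate, IUPAC codes) is compared against its
binding site on a reference multiple sequence alignment; the binding site
is an explicit MSA column range supplied with the primer, since primer
sites on curated nifH alignments are fixed by hand rather than searched de
novo.  Reverse-orientation primers are reverse-complemented before
comparison.  A gap in the template counts as a mismatch — a deleted
position cannot anneal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from diazoscope._seq import IUPAC, revcomp
from diazoscope.errors import InputError

_GAPS = "-."


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str             # 5'->3', IUPAC codes allowed
    orientation: str          # "forward" | "reverse"
    msa_start_col: int = 0    # 0-based, half-open binding-site columns
    msa_end_col: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"primer {self.name!r} has an empty sequence")
        bad = set(self.sequence.upper()) - set(IUPAC)
        if bad:
            raise InputError(f"primer {self.name!r}: invalid codes {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise InputError(f"primer {self.name!r}: bad orientation "
                             f"{self.orientation!r}")

    @property
    def site_sequence(self) -> str:
        """Primer sequence on the template (plus) strand."""
        seq = self.sequence.upper()
        return revcomp(seq) if self.orientation == "reverse" else seq


def iupac_match(primer_base: str, template_base: str) -> bool:
    """True iff the two IUPAC codes can pair (their expansions intersect)."""
    pb, tb = primer_base.upper(), template_base.upper()
    if pb not in IUPAC or tb not in IUPAC:
        raise InputError(f"invalid IUPAC code in ({primer_base!r}, {template_base!r})")
    return bool(IUPAC[pb] & IUPAC[tb])


def count_mismatches(primer: Primer, template_region: str) -> int:
    """Mismatches between a primer and its aligned binding-site region.

    ``template_region`` is the MSA slice of one reference sequence over the
    primer's binding-site columns, gaps included.  The binding site is
    contiguous in the primer, so the column count must equal the primer
    length; template gaps count as mismatches.
    """
    site = primer.site_sequence
    if len(template_region) != len(site):
        raise InputError(
            f"binding site for {primer.name!r}: {len(template_region)} "
            f"template columns aligned to a {len(site)}-base primer")
    mism = 0
    for pb, tb in zip(site, template_region.upper()):
        if tb in _GAPS:
            mism += 1        # deleted template position cannot anneal
        elif not iupac_match(pb, tb):
            mism += 1
    return mism


def mismatch_matrix(msa: dict[str, str],
                    primers: list[Primer]) -> pd.DataFrame:
    """Primers x templates mismatch counts over MSA-defined binding sites."""
    rows = {}
    for p in primers:
        if not (0 <= p.msa_start_col < p.msa_end_col):
            raise InputError(f"primer {p.name!r}: invalid column range")
        rows[p.name] = {
            name: count_mismatches(p, seq[p.msa_start_col:p.msa_end_col])
            for name, seq in sorted(msa.items())
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def load_primers(path: str | Path) -> list[Primer]:
    """Read a primer table (name, sequence, orientation, msa_start_col,
    msa_end_col)."""
    df = pd.read_csv(path, sep="\t")
    return [Primer(name=str(r.name_), sequence=str(r.sequence),
                   orientation=str(r.orientation),
                   msa_start_col=int(r.msa_start_col),
                   msa_end_col=int(r.msa_end_col))
            for r in df.rename(columns={"name": "name_"}).itertuples()]
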