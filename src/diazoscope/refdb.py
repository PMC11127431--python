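"""Marker-gene reference database.

The database holds three classes of markers extracted from annotated
reference genomes:

* nitrogenase structural genes — ``nifH`` plus the D/K subunits of the
  molybdenum (``nifD``/``nifK``), vanadium (``vnfD``/``vnfK``) and iron-only
  (``anfD``/``anfK``) nitrogenases.  The D/K set is the quantification
  marker; ``nifH`` is tracked separately because nifH-like genes occur on
  genomes that cannot fix nitrogen (pseudo-nifH).
* universal single-copy ribosomal-protein genes, the per-genome
  normalisation denominator.
* SSU rRNA (16S), used for whole-community composition and contamination
  screening.

Annotation coordinates are 1-based inclusive; strand ``-`` means the CDS is
reverse-complemented before storage and translation.  Translation uses the
bacterial genetic code (table 11).
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from diazoscope import _seq
from diazoscope.errors import (
    AbsentMarkerError,
    AnnotationError,
    ConsistencyError,
    CoordinateError,
)

logger = logging.getLogger(__name__)

#: D/K-subunit families used for quantifying nitrogen-fixing potential.
NITROGENASE_DK = frozenset({"nifD", "nifK", "vnfD", "vnfK", "anfD", "anfK"})

#: Default universal single-copy ribosomal-protein gene set (configurable).
DEFAULT_RP_GENES = (
    "rplA", "rplB", "rplC", "rplD", "rplE", "rplF", "rplM", "rplN",
    "rpsB", "rpsC", "rpsE", "rpsG", "rpsH", "rpsK", "rpsS",
)

SSU16S = "SSU16S"
NIFH = "nifH"

_ROLES = ("nitrogenase_H", "nitrogenase_DK", "ribosomal_protein", "rRNA")


def family_role(family: str, rp_genes: tuple[str, ...] = DEFAULT_RP_GENES) -> str:
    """Classify a marker-family name into its functional role."""
    if family == NIFH:
        return "nitrogenase_H"
    if family in NITROGENASE_DK:
        return "nitrogenase_DK"
    if family == SSU16S:
        return "rRNA"
    if family in rp_genes or family.startswith("rp:"):
        return "ribosomal_protein"
    raise AnnotationError(f"unknown marker family {family!r}")


@dataclass(frozen=True)
class MarkerGene:
    """One marker-gene copy on a reference genome."""

    gene_id: str
    genome_id: str
    family: str
    nt_sequence: str
    aa_sequence: str  # empty for SSU16S
    lineage: tuple[str, ...]
    contig: str = ""
    start: int = 0  # 1-based inclusive, on the forward strand of the contig
    end: int = 0
    strand: str = "+"

    @property
    def length_nt(self) -> int:
        return len(self.nt_sequence)


@dataclass
class ReferenceDB:
    """Collection of marker genes with per-family length tables."""

    genes: dict[str, MarkerGene] = field(default_factory=dict)
    rp_genes: tuple[str, ...] = DEFAULT_RP_GENES

    def __post_init__(self) -> None:
        self._by_family: dict[str, list[str]] = defaultdict(list)
        self._by_genome: dict[str, list[str]] = defaultdict(list)
        for gid, g in self.genes.items():
            self._by_family[g.family].append(gid)
            self._by_genome[g.genome_id].append(gid)

    # -- accessors ---------------------------------------------------------
    def add(self, gene: MarkerGene) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene
        self._by_family[gene.family].append(gene.gene_id)
        self._by_genome[gene.genome_id].append(gene.gene_id)

    def family(self, name: str) -> list[MarkerGene]:
        return [self.genes[g] for g in self._by_family.get(name, [])]

    def genome(self, genome_id: str) -> list[MarkerGene]:
        return [self.genes[g] for g in self._by_genome.get(genome_id, [])]

    @property
    def genome_ids(self) -> set[str]:
        return set(self._by_genome)

    @property
    def families(self) -> set[str]:
        return set(self._by_family)

    def genome_lineage(self, genome_id: str) -> tuple[str, ...]:
        genes = self.genome(genome_id)
        if not genes:
            raise ConsistencyError(f"unknown genome {genome_id!r}")
        return genes[0].lineage

    def gene_length(self, gene_id: str) -> int:
        if gene_id not in self.genes:
            raise ConsistencyError(f"no length entry for gene {gene_id!r}")
        return self.genes[gene_id].length_nt

    # -- serialization -----------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        """Write a TSV index plus per-family protein/nucleotide FASTA."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for gid in sorted(self.genes):
            g = self.genes[gid]
            rows.append(
                dict(gene_id=g.gene_id, genome_id=g.genome_id, family=g.family,
                     contig=g.contig, start=g.start, end=g.end, strand=g.strand,
                     length_nt=g.length_nt, lineage=";".join(g.lineage))
            )
        pd.DataFrame(rows).to_csv(out / "index.tsv", sep="\t", index=False)
        for fam in sorted(self._by_family):
            genes = sorted(self.family(fam), key=lambda g: g.gene_id)
            with open(out / f"{fam}.fna", "w") as fh:
                for g in genes:
                    fh.write(f">{g.gene_id}\n{g.nt_sequence}\n")
            if genes and genes[0].aa_sequence:
                with open(out / f"{fam}.faa", "w") as fh:
                    for g in genes:
                        fh.write(f">{g.gene_id}\n{g.aa_sequence}\n")

    @classmethod
    def load(cls, db_dir: str | Path,
             rp_genes: tuple[str, ...] = DEFAULT_RP_GENES) -> "ReferenceDB":
        db_dir = Path(db_dir)
        index = pd.read_csv(db_dir / "index.tsv", sep="\t")
        nt = {}
        aa = {}
        for fam in index["family"].unique():
            for rec in SeqIO.parse(db_dir / f"{fam}.fna", "fasta"):
                nt[rec.id] = str(rec.seq)
            faa = db_dir / f"{fam}.faa"
            if faa.exists():
                for rec in SeqIO.parse(faa, "fasta"):
                    aa[rec.id] = str(rec.seq)
        db = cls(rp_genes=rp_genes)
        for row in index.itertuples():
            db.add(MarkerGene(
                gene_id=row.gene_id, genome_id=row.genome_id, family=row.family,
                nt_sequence=nt[row.gene_id], aa_sequence=aa.get(row.gene_id, ""),
                lineage=tuple(str(row.lineage).split(";")),
                contig=str(row.contig), start=int(row.start), end=int(row.end),
                strand=str(row.strand),
            ))
        return db


def build_db(
    genomes: dict[str, dict[str, str]] | str | Path,
    annotations: pd.DataFrame | str | Path,
    taxonomy: dict[str, tuple[str, ...]] | pd.DataFrame | str | Path,
    rp_genes: tuple[str, ...] = DEFAULT_RP_GENES,
) -> ReferenceDB:
    """Build a :class:`ReferenceDB` from genome FASTA plus annotation tables.

    Parameters
    ----------
    genomes:
        ``{genome_id: {contig_id: sequence}}``, or a path to a nucleotide
        FASTA whose record ids are ``genome_id|contig_id`` (or plain
        ``contig_id`` doubling as the genome id).
    annotations:
        Table with columns ``genome_id, contig, start, end, strand, family,
        gene_id`` (1-based inclusive coordinates).
    taxonomy:
        ``{genome_id: lineage tuple}`` or a two-column table
        ``genome_id <tab> semicolon-delimited lineage``.
    """
    genomes = _load_genomes(genomes)
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.read_csv(annotations, sep="\t")
    taxonomy = _load_taxonomy(taxonomy)

    db = ReferenceDB(rp_genes=rp_genes)
    for row in annotations.itertuples():
        label = f"annotation row gene_id={row.gene_id!r}"
        if row.genome_id not in genomes or row.contig not in genomes[row.genome_id]:
            raise CoordinateError(f"{label}: unknown genome/contig "
                                  f"{row.genome_id!r}/{row.contig!r}")
        contig_seq = genomes[row.genome_id][row.contig]
        start, end = int(row.start), int(row.end)
        if not (1 <= start <= end <= len(contig_seq)):
            raise CoordinateError(
                f"{label}: coordinates {start}..{end} out of bounds for contig "
                f"{row.contig!r} of length {len(contig_seq)}")
        if row.strand not in "+-":
            raise AnnotationError(f"{label}: strand must be '+' or '-'")
        nt = contig_seq[start - 1:end].upper()
        if row.strand == "-":
            nt = _seq.revcomp(nt)
        fam = str(row.family)
        role = family_role(fam, rp_genes)
        aa = ""
        if role in ("nitrogenase_H", "nitrogenase_DK", "ribosomal_protein"):
            if len(nt) % 3 != 0:
                raise AnnotationError(
                    f"{label}: CDS length {len(nt)} not divisible by 3")
            aa = _seq.translate(nt)
            if aa.endswith("*"):
                aa = aa[:-1]
            if "*" in aa:
                warnings.warn(f"{label}: internal stop codon(s); stripped",
                              stacklevel=2)
                aa = aa.replace("*", "")
        db.add(MarkerGene(
            gene_id=str(row.gene_id), genome_id=str(row.genome_id), family=fam,
            nt_sequence=nt, aa_sequence=aa,
            lineage=taxonomy.get(str(row.genome_id), ("Unclassified",)),
            contig=str(row.contig), start=start, end=end, strand=str(row.strand),
        ))
    for fam in sorted(db.families):
        logger.info("refdb: family %s has %d gene(s)", fam, len(db.family(fam)))
    return db


def _load_genomes(genomes) -> dict[str, dict[str, str]]:
    if isinstance(genomes, (str, Path)):
        loaded: dict[str, dict[str, str]] = defaultdict(dict)
        for rec in SeqIO.parse(genomes, "fasta"):
            genome_id, _, contig = rec.id.partition("|")
            loaded[genome_id][contig or rec.id] = str(rec.seq)
        return dict(loaded)
    return genomes


def _load_taxonomy(taxonomy) -> dict[str, tuple[str, ...]]:
    if isinstance(taxonomy, (str, Path)):
        taxonomy = pd.read_csv(taxonomy, sep="\t", names=["genome_id", "lineage"],
                               header=None, comment="#")
    if isinstance(taxonomy, pd.DataFrame):
        return {str(r.genome_id): tuple(str(r.lineage).split(";"))
                for r in taxonomy.itertuples()}
    return taxonomy


def screen_diazotroph_genomes(db: ReferenceDB) -> set[str]:
    """Genomes carrying all three core nitrogenase genes (nifH, nifD, nifK).

    Archaeal genomes are excluded regardless of gene content.
    """
    out = set()
    for genome_id in db.genome_ids:
        lineage = db.genome_lineage(genome_id)
        if lineage and lineage[0].lower() == "archaea":
            continue
        fams = {g.family for g in db.genome(genome_id)}
        if {"nifH", "nifD", "nifK"} <= fams:
            out.add(genome_id)
    return out


def gc_content(genome_id: str, family: str, db: ReferenceDB) -> float | None:
    """GC fraction of the concatenated qualifying copies of ``family``.

    For 16S only copies of at least 1000 nt qualify.  Ambiguous bases are
    excluded from both numerator and denominator.  Returns ``None`` when the
    genome has no qualifying copy (an undefined, not a zero, result).
    """
    copies = [g for g in db.genome(genome_id) if g.family == family]
    if family == SSU16S:
        copies = [g for g in copies if g.length_nt >= 1000]
    if not copies:
        return None
    return _seq.gc_fraction("".join(g.nt_sequence for g in copies))


def select_nifh_copy(genome_id: str, db: ReferenceDB) -> str:
    """Pick the nifH copy closest to a nifD/K annotation on the same contig.

    Primer-mismatch analyses need one nifH per genome; the copy adjacent to
    nifD/K is the functional one, distinguishing it from pseudo-nifH copies
    elsewhere on the genome.  Ties (and genomes where no copy is co-located
    with nifD/K) resolve to the smaller start coordinate.
    """
    nifh = sorted((g for g in db.genome(genome_id) if g.family == NIFH),
                  key=lambda g: (g.contig, g.start))
    if not nifh:
        raise AbsentMarkerError(f"genome {genome_id!r} has no nifH")
    if len(nifh) == 1:
        return nifh[0].gene_id
    anchors = [g for g in db.genome(genome_id) if g.family in ("nifD", "nifK")]

    def distance(copy: MarkerGene) -> float:
        ds = [min(abs(copy.start - a.end), abs(a.start - copy.end))
              for a in anchors if a.contig == copy.contig]
        return min(ds) if ds else float("inf")

    return min(nifh, key=lambda g: (distance(g), g.start)).gene_id


def marker_length_table(db: ReferenceDB) -> dict[str, list[tuple[str, int]]]:
    """Family -> sorted ``(gene_id, length_nt)`` list (RPKM length input)."""
    table: dict[str, list[tuple[str, int]]] = {}
    for fam in db.families:
        table[fam] = sorted((g.gene_id, g.length_nt) for g in db.family(fam))
    return table
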