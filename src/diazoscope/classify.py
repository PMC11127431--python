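"""Read quality control and marker-gene assignment.

Protein markers (nitrogenase subunits and ribosomal proteins) are found by
translated homology search of every read against the reference database;
16S reads by nucleotide best hit on either strand.  Two routes implement
the same contract:

* :func:`assign_protein_marker` — per-read seed-and-extend: amino-acid
  k-mer seeding selects candidate genes, which are then scored with a full
  affine-gap Smith–Waterman (BLOSUM62) over all six reading frames.
* :func:`profile_sample` — a vectorised batch path for whole samples that
  seeds identically but approximates the extension score with an
  edit-distance identity check; its agreement with the alignment route is
  a tested property of the package.

One read receives at most one marker assignment; 16S assignment is only
attempted for reads left unassigned by the protein search.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from diazoscope import refdb as _refdb
from diazoscope._seq import revcomp
from diazoscope.errors import InputError, MetadataError
from diazoscope.refdb import ReferenceDB

UNASSIGNED = None

# Karlin–Altschul parameters for gapped BLOSUM62 (11/1) bit-score conversion
_KA_LAMBDA = 0.267
_KA_LNK = float(np.log(0.041))
_LN2 = float(np.log(2.0))


@dataclass
class ClassifyConfig:
    min_len: int = 100
    min_mean_q: float = 20.0
    protein_id_min: float = 0.6
    bits_min: float = 50.0
    ssu_id_min: float = 0.8
    protein_k: int = 8        # amino-acid seed length
    nt_k: int = 16            # nucleotide seed length for 16S
    min_seed_votes: int = 2   # batch path: shared k-mers required to assign
    min_aa_matches: int = 25  # batch path: identity * aligned length floor
    seed_stride_protein: int = 3   # batch path: subsample read-side seeds
    seed_stride_nt: int = 8


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    gene_id: str | None
    family: str | None
    score: float = 0.0       # bit score (alignment route) or seed votes (batch)
    identity: float = 0.0

    @property
    def assigned(self) -> bool:
        return self.gene_id is not None


@dataclass
class SampleProfile:
    """Per-sample marker counts plus 16S community composition."""

    sample_id: str
    metadata: dict
    total_reads_qc: int = 0
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    ssu_lineage_counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    #: family -> [(read_id, seq)] for families requested at profiling time
    marker_reads: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [self.sample_id]

    def family_count(self, family: str) -> int:
        return sum(self.counts.get(family, {}).values())

    @property
    def nifdk_count(self) -> int:
        return self.family_count("nifD") + self.family_count("nifK")

    @property
    def n_ssu_reads(self) -> int:
        return sum(self.ssu_lineage_counts.values())

    @property
    def ssu_composition(self) -> dict[str, dict[str, float]]:
        if self.n_ssu_reads == 0:
            return {}
        return {rank: summarize_composition(self, rank)
                for rank in ("phylum", "order")}


# ---------------------------------------------------------------------------
# FASTQ quality filtering


def _iter_fastq(reads):
    if isinstance(reads, (str, Path)):
        from Bio.SeqIO.QualityIO import FastqGeneralIterator
        record_index = 0
        with open(reads) as fh:
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    record_index += 1
                    yield title.split()[0], seq, qual
            except ValueError as exc:
                raise InputError(
                    f"malformed FASTQ record at index {record_index}: {exc}"
                ) from exc
    else:
        yield from reads


def quality_filter(reads, min_len: int = 100,
                   min_mean_q: float = 20.0) -> list[tuple[str, str, str]]:
    """Keep reads with length >= ``min_len`` and mean Phred >= ``min_mean_q``.

    ``reads`` is a FASTQ path or an iterable of ``(id, seq, qual)``; input
    order is preserved.
    """
    kept = []
    threshold_offset = min_mean_q + 33
    for rid, seq, qual in _iter_fastq(reads):
        if len(seq) != len(qual):
            raise InputError(f"read {rid!r}: sequence/quality length mismatch")
        if len(seq) < min_len:
            continue
        if sum(qual.encode()) >= threshold_offset * len(qual):
            kept.append((rid, seq, qual))
    return kept


# ---------------------------------------------------------------------------
# translation tables (vectorised six-frame translation)

_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i
    _NT_CODE[_b + 32] = _i
_NT_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"  # codes 0..19; 20 = stop, 21 = X
_AA_STOP, _AA_X = 20, 21
_AA_BASE = 22


def _build_codon_table() -> np.ndarray:
    table = np.full(125, _AA_X, dtype=np.uint8)
    bases = "ACGT"
    for i0 in range(4):
        for i1 in range(4):
            for i2 in range(4):
                codon = bases[i0] + bases[i1] + bases[i2]
                aa = str(Seq(codon).translate(table=11))
                idx = i0 * 25 + i1 * 5 + i2
                table[idx] = _AA_STOP if aa == "*" else _AA_ORDER.index(aa)
    return table


_CODON2AA = _build_codon_table()
_AA_CHAR = np.frombuffer((_AA_ORDER + "*X").encode(), dtype=np.uint8)
_AA_CODE = np.full(256, _AA_X, dtype=np.uint8)
for _i, _c in enumerate(_AA_ORDER.encode()):
    _AA_CODE[_c] = _i


def _six_frame_codes(seqs: list[str]) -> list[np.ndarray]:
    """Six (n_reads x n_codons) amino-acid code matrices (3 fwd + 3 rc)."""
    n = len(seqs)
    L = max(len(s) for s in seqs)
    mat = np.full((n, L), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, :len(s)] = _NT_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    rc = _NT_COMP[mat][:, ::-1]
    frames = []
    for source in (mat, rc):
        for f in range(3):
            n_cod = (L - f) // 3
            if n_cod <= 0:
                frames.append(np.zeros((n, 0), dtype=np.uint8))
                continue
            c0 = source[:, f:f + 3 * n_cod:3].astype(np.int32)
            c1 = source[:, f + 1:f + 1 + 3 * n_cod:3].astype(np.int32)
            c2 = source[:, f + 2:f + 2 + 3 * n_cod:3].astype(np.int32)
            frames.append(_CODON2AA[c0 * 25 + c1 * 5 + c2])
    return frames


def _frame_strings(seq: str) -> list[str]:
    """Six-frame translations of one read (Xs for ambiguity, * for stops)."""
    out = []
    for src in (seq, revcomp(seq)):
        codes = _NT_CODE[np.frombuffer(src.encode(), dtype=np.uint8)]
        for f in range(3):
            n_cod = (len(src) - f) // 3
            if n_cod <= 0:
                out.append("")
                continue
            c = codes[f:f + 3 * n_cod].reshape(-1, 3).astype(np.int32)
            aa = _CODON2AA[c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]]
            out.append(_AA_CHAR[aa].tobytes().decode())
    return out


def _kmer_hashes(codes: np.ndarray, k: int, alphabet: int, max_code: int,
                 stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer hashes and their validity mask for a code matrix.

    ``stride`` subsamples k-mer start positions (used on the read side,
    where neighbouring seeds are redundant); references index every
    position.
    """
    n, m = codes.shape
    if m < k:
        return (np.zeros((n, 0), dtype=np.int64), np.zeros((n, 0), dtype=bool))
    n_win = m - k + 1
    starts = np.arange(0, n_win, stride)
    hashes = np.zeros((n, starts.size), dtype=np.int64)
    valid = np.ones((n, starts.size), dtype=bool)
    weight = 1
    for j in range(k):
        col = codes[:, starts + j]
        hashes += col.astype(np.int64) * weight
        valid &= col <= max_code
        weight *= alphabet
    return hashes, valid


# ---------------------------------------------------------------------------
# reference index


class MarkerIndex:
    """Seed k-mer index over the reference protein and 16S sequences."""

    def __init__(self, db: ReferenceDB, config: ClassifyConfig | None = None):
        self.db = db
        self.config = config or ClassifyConfig()
        k = self.config.protein_k
        self.protein_genes: list[_refdb.MarkerGene] = sorted(
            (g for g in db.genes.values() if g.aa_sequence),
            key=lambda g: g.gene_id)
        self._protein_kmers: dict[int, list[int]] = defaultdict(list)
        for gi, g in enumerate(self.protein_genes):
            codes = _AA_CODE[np.frombuffer(g.aa_sequence.encode(), dtype=np.uint8)]
            h, v = _kmer_hashes(codes[None, :], k, _AA_BASE, 19)
            for hh in np.unique(h[0][v[0]]):
                self._protein_kmers[int(hh)].append(gi)
        self.protein_kmer_sorted = np.array(sorted(self._protein_kmers),
                                            dtype=np.int64)
        self.protein_mask = _membership_mask(self.protein_kmer_sorted)

        nk = self.config.nt_k
        self.ssu_genes: list[_refdb.MarkerGene] = sorted(
            db.family(_refdb.SSU16S), key=lambda g: g.gene_id)
        self._ssu_kmers: dict[int, list[int]] = defaultdict(list)
        for gi, g in enumerate(self.ssu_genes):
            for strand_seq in (g.nt_sequence, revcomp(g.nt_sequence)):
                codes = _NT_CODE[np.frombuffer(strand_seq.encode(), dtype=np.uint8)]
                h, v = _kmer_hashes(codes[None, :], nk, 4, 3)
                for hh in np.unique(h[0][v[0]]):
                    self._ssu_kmers[int(hh)].append(gi)
        self.ssu_kmer_sorted = np.array(sorted(self._ssu_kmers), dtype=np.int64)
        self.ssu_mask = _membership_mask(self.ssu_kmer_sorted)

    # -- seeding -----------------------------------------------------------
    def protein_candidates(self, frames: list[str]) -> Counter:
        """Seed votes per candidate gene index from six-frame translations."""
        k = self.config.protein_k
        votes: Counter = Counter()
        for aa in frames:
            codes = _AA_CODE[np.frombuffer(aa.encode(), dtype=np.uint8)]
            stops = np.frombuffer(aa.encode(), dtype=np.uint8) == ord("*")
            codes = codes.copy()
            codes[stops] = _AA_STOP
            h, v = _kmer_hashes(codes[None, :], k, _AA_BASE, 19)
            for hh in h[0][v[0]]:
                for gi in self._protein_kmers.get(int(hh), ()):
                    votes[gi] += 1
        return votes


# ---------------------------------------------------------------------------
# per-read contract route (seed + full affine-gap DP)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


_ALIGNER = _aligner()
_B62_ALPHA = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _alignment_identity(aln) -> tuple[int, int]:
    """(matches, aligned residue pairs) of a pairwise alignment."""
    q, t = aln.sequences
    matches = total = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        total += qe - qs
        matches += sum(a == b for a, b in zip(q[qs:qe], t[ts:te]))
    return matches, total


def bit_score(raw_score: float) -> float:
    return (_KA_LAMBDA * raw_score - _KA_LNK) / _LN2


def assign_protein_marker(
    read: tuple[str, str, str] | tuple[str, str],
    db_or_index: ReferenceDB | MarkerIndex,
    config: ClassifyConfig | None = None,
) -> ReadAssignment:
    """Assign one read to its best-scoring reference protein gene.

    All six reading frames are translated (segments between stop codons are
    scored independently), candidate genes are seeded by shared amino-acid
    k-mers, and candidates are scored with affine-gap local alignment under
    BLOSUM62.  The read is assigned to the top-scoring gene when the bit
    score and identity clear the configured thresholds; score ties break by
    higher identity, then lexicographically smaller gene id.
    """
    index = (db_or_index if isinstance(db_or_index, MarkerIndex)
             else MarkerIndex(db_or_index, config))
    cfg = config or index.config
    rid, seq = read[0], read[1]
    frames = _frame_strings(seq)
    segments = []
    for aa in frames:
        segments.extend(s for s in aa.split("*") if len(s) >= cfg.protein_k)
    if not segments:
        return ReadAssignment(rid, UNASSIGNED, None)
    votes = index.protein_candidates(frames)
    if not votes:
        return ReadAssignment(rid, UNASSIGNED, None)

    best = None  # (score, identity, gene)
    for gi in votes:
        gene = index.protein_genes[gi]
        for seg in segments:
            seg = "".join(c if c in _B62_ALPHA else "X" for c in seg)
            try:
                aln = _ALIGNER.align(seg, gene.aa_sequence)[0]
            except IndexError:
                continue
            matches, total = _alignment_identity(aln)
            if total == 0:
                continue
            ident = matches / total
            cand = (float(aln.score), ident, gene)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]) or (
                    (cand[0], cand[1]) == (best[0], best[1])
                    and gene.gene_id < best[2].gene_id):
                best = cand
    if best is None:
        return ReadAssignment(rid, UNASSIGNED, None)
    raw, ident, gene = best
    bits = bit_score(raw)
    if bits >= cfg.bits_min and ident >= cfg.protein_id_min:
        return ReadAssignment(rid, gene.gene_id, gene.family, bits, ident)
    return ReadAssignment(rid, UNASSIGNED, None, bits, ident)


def assign_16s(
    read: tuple[str, str, str] | tuple[str, str],
    db_or_index: ReferenceDB | MarkerIndex,
    id_min: float = 0.8,
) -> tuple[str, ...] | None:
    """Nucleotide best hit of a read against the 16S references (both strands).

    Returns the hit's lineage when the identity reaches ``id_min``, else
    ``None``.
    """
    index = (db_or_index if isinstance(db_or_index, MarkerIndex)
             else MarkerIndex(db_or_index))
    seq = read[1].upper()
    best = None  # (identity, lineage)
    for g in index.ssu_genes:
        for target in (g.nt_sequence, revcomp(g.nt_sequence)):
            res = edlib.align(seq, target, mode="HW", task="distance")
            ident = 1.0 - res["editDistance"] / len(seq)
            if best is None or ident > best[0]:
                best = (ident, g.lineage)
    if best is not None and best[0] >= id_min:
        return best[1]
    return None


# ---------------------------------------------------------------------------
# batch route


_MASK_BITS = 22


def _membership_mask(sorted_kmers: np.ndarray) -> np.ndarray:
    """Modular bitmask prefilter: False guarantees the k-mer is absent."""
    mask = np.zeros(1 << _MASK_BITS, dtype=bool)
    if sorted_kmers.size:
        mask[sorted_kmers & ((1 << _MASK_BITS) - 1)] = True
    return mask


def _batch_candidates(seqs: list[str], hashes_by_frame, index_sorted,
                      kmer_map, mask) -> dict[int, Counter]:
    """read index -> Counter(gene index -> matched seed k-mers)."""
    votes: dict[int, Counter] = defaultdict(Counter)
    for hashes, valid in hashes_by_frame:
        if hashes.size == 0 or index_sorted.size == 0:
            continue
        member = valid & mask[hashes & ((1 << _MASK_BITS) - 1)]
        if member.any():
            cand = hashes[member]
            pos = np.searchsorted(index_sorted, cand)
            ok = pos < index_sorted.size
            ok &= index_sorted[np.minimum(pos, index_sorted.size - 1)] == cand
            member[member] = ok
        ri, ci = np.nonzero(member)
        for r, h in zip(ri, hashes[ri, ci]):
            for gi in kmer_map[int(h)]:
                votes[int(r)][gi] += 1
    return votes


def _classify_batch_protein(seqs: list[str], index: MarkerIndex,
                            cfg: ClassifyConfig) -> dict[int, tuple[str, str]]:
    """read index -> (gene_id, family) for reads passing the batch filters."""
    if not seqs:
        return {}
    frames = _six_frame_codes(seqs)
    hbf = [_kmer_hashes(f, cfg.protein_k, _AA_BASE, 19,
                        stride=cfg.seed_stride_protein) for f in frames]
    votes = _batch_candidates(seqs, hbf, index.protein_kmer_sorted,
                              index._protein_kmers, index.protein_mask)
    out: dict[int, tuple[str, str]] = {}
    for r, counter in votes.items():
        top = max(counter.values())
        if top < cfg.min_seed_votes:
            continue
        cands = sorted(gi for gi, v in counter.items() if v == top)
        gene = min((index.protein_genes[gi] for gi in cands),
                   key=lambda g: g.gene_id)
        frame_strs = _frame_strings(seqs[r])
        best_ident, best_len = 0.0, 0
        for aa in frame_strs:
            if len(aa) < cfg.protein_k:
                continue
            res = edlib.align(aa, gene.aa_sequence, mode="HW", task="distance")
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(aa)
            if ident > best_ident:
                best_ident, best_len = ident, len(aa)
        if (best_ident >= cfg.protein_id_min
                and best_ident * best_len >= cfg.min_aa_matches):
            out[r] = (gene.gene_id, gene.family)
    return out


def _classify_batch_ssu(seqs: list[str], read_idx: list[int],
                        index: MarkerIndex,
                        cfg: ClassifyConfig) -> dict[int, tuple[str, ...]]:
    """read index -> lineage for 16S hits among the given reads."""
    if not seqs or not index.ssu_genes:
        return {}
    n = len(seqs)
    L = max(len(s) for s in seqs)
    mat = np.full((n, L), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, :len(s)] = _NT_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    hbf = [_kmer_hashes(mat, cfg.nt_k, 4, 3, stride=cfg.seed_stride_nt)]
    votes = _batch_candidates(seqs, hbf, index.ssu_kmer_sorted,
                              index._ssu_kmers, index.ssu_mask)
    out: dict[int, tuple[str, ...]] = {}
    for r, counter in votes.items():
        cands = sorted(counter, key=lambda gi: (-counter[gi], gi))
        gene = index.ssu_genes[cands[0]]
        seq = seqs[r]
        best = 0.0
        for target in (gene.nt_sequence, revcomp(gene.nt_sequence)):
            res = edlib.align(seq, target, mode="HW", task="distance")
            best = max(best, 1.0 - res["editDistance"] / len(seq))
        if best >= cfg.ssu_id_min:
            out[read_idx[r]] = gene.lineage
    return out


# ---------------------------------------------------------------------------
# sample profiling


def profile_sample(
    reads,
    db_or_index: ReferenceDB | MarkerIndex,
    metadata: dict,
    config: ClassifyConfig | None = None,
    collect_families: tuple[str, ...] = (),
) -> SampleProfile:
    """QC the reads of one sample and aggregate marker assignments.

    ``metadata`` must provide ``sample_id``, ``env``, ``latitude`` and
    ``longitude``.  Reads assigned to any family in ``collect_families``
    are retained on the profile (for downstream phylogenetic placement).
    """
    for key in ("sample_id", "env", "latitude", "longitude"):
        if key not in metadata or metadata[key] is None:
            raise MetadataError(f"sample metadata missing {key!r}")
    index = (db_or_index if isinstance(db_or_index, MarkerIndex)
             else MarkerIndex(db_or_index, config))
    cfg = config or index.config

    kept = quality_filter(reads, cfg.min_len, cfg.min_mean_q)
    profile = SampleProfile(sample_id=str(metadata["sample_id"]),
                            metadata=dict(metadata),
                            total_reads_qc=len(kept))
    if not kept:
        return profile
    seqs = [r[1] for r in kept]
    protein_hits = _classify_batch_protein(seqs, index, cfg)
    for r, (gene_id, family) in sorted(protein_hits.items()):
        profile.counts.setdefault(family, {})
        profile.counts[family][gene_id] = profile.counts[family].get(gene_id, 0) + 1
        if family in collect_families:
            profile.marker_reads.setdefault(family, []).append(
                (kept[r][0], kept[r][1]))
    rest_idx = [i for i in range(len(seqs)) if i not in protein_hits]
    ssu_hits = _classify_batch_ssu([seqs[i] for i in rest_idx], rest_idx,
                                   index, cfg)
    for r, lineage in ssu_hits.items():
        profile.ssu_lineage_counts[lineage] = (
            profile.ssu_lineage_counts.get(lineage, 0) + 1)
        gene_fam = _refdb.SSU16S
        profile.counts.setdefault(gene_fam, {})
        profile.counts[gene_fam]["_ssu"] = profile.counts[gene_fam].get("_ssu", 0) + 1
    return profile


_RANK_INDEX = {"domain": 0, "phylum": 1, "class": 2, "order": 3,
               "family": 4, "genus": 5}


def summarize_composition(profile: SampleProfile, rank: str) -> dict[str, float]:
    """16S community composition at a taxonomic rank (fractions sum to 1).

    At phylum rank, proteobacterial classes are split out (the convention
    of whole-community overviews in soil metagenomics).
    """
    if rank not in _RANK_INDEX:
        raise InputError(f"unknown rank {rank!r}")
    if profile.n_ssu_reads == 0:
        raise InputError(f"sample {profile.sample_id!r} has no 16S reads")
    idx = _RANK_INDEX[rank]
    counts: Counter = Counter()
    for lineage, n in profile.ssu_lineage_counts.items():
        if rank == "phylum" and len(lineage) > 2 and lineage[1] == "Proteobacteria":
            label = lineage[2]
        elif idx < len(lineage):
            label = lineage[idx]
        else:
            label = "unclassified"
        counts[label] += n
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}
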