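"""Synthetic reference sets, communities, reads and metadata with known truth.

The generator emulates the statistical structure the analysis assumes:

* multi-taxon communities with log-normal abundances;
* genomes carrying 0 or 1 copy of each marker, with nifH:nifD:nifK lengths
  near 3:5:5 (≈900:1500:1500 nt), a configurable set of universal
  single-copy ribosomal proteins, and one 16S rRNA gene;
* pseudo-nifH genomes (nifH present, nifD/K absent), which inflate
  nifH-based surveys;
* contaminant taxa (order Lactobacillales; plant-plastid/chloroplast 16S);
* taxon-specific GC content, applied to coding genes through GC-biased
  codon choice and to neutral spacer DNA directly;
* an anaerobic:aerobic fold-difference in the community fraction of
  diazotrophs;
* sampling coordinates with sub-kilometre replicates.

Marker proteins of one family are evolved from a common ancestor along a
three-level taxonomy-shaped tree (root -> class -> family -> leaf), so that
per-family reference packages (alignment + tree + leaf taxonomy) fall out
of the generative process and placement of reads onto them is meaningful.
Read errors are substitutions only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from diazoscope import refdb as _refdb
from diazoscope.errors import ConfigError, InputError

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = np.frombuffer(b"ACGT", dtype=np.uint8)

# class -> family pools used to draw taxon lineages; None = unlabelled at
# family rank (supports the "possibly Geobacteraceae/Anaeromyxobacteraceae"
# annotation category, which needs family-unlabelled deltaproteobacterial
# references).
_DIAZOTROPH_POOL = [
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfuromonadales", "Geobacteraceae"),
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Myxococcales", "Anaeromyxobacteraceae"),
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfuromonadales", None),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Nitrobacteraceae"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Rhizobiaceae"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae"),
    ("Bacteria", "Firmicutes", "Clostridia", "Eubacteriales", "Clostridiaceae"),
    ("Bacteria", "Cyanobacteria", "Cyanophyceae", "Nostocales", "Nostocaceae"),
]
_PLAIN_POOL = [
    ("Bacteria", "Acidobacteria", "Acidobacteriia", "Acidobacteriales", "Acidobacteriaceae"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Mycobacteriales", "Mycobacteriaceae"),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    ("Bacteria", "Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae"),
]
_LACTO_LINEAGE = ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae")
_CHLORO_LINEAGE = ("Eukaryota", "Streptophyta", "Magnoliopsida", "Chloroplast", "Chloroplast")

AEROBIC_ENVS = frozenset({"cropland", "forest", "grassland"})
ANAEROBIC_ENVS = frozenset({"paddy", "sediment", "tundra"})


@dataclass
class ReferenceConfig:
    """Shape of the synthetic reference set."""

    frac_diazotroph: float = 0.4
    frac_pseudo: float = 0.15
    n_contaminant: int = 2           # one Lactobacillales + one chloroplast
    nifh_len: int = 900              # nifH:nifD:nifK ~ 3:5:5
    nifdk_len: int = 1500
    len_jitter: float = 0.10         # +-10% uniform around the target length
    rp_len_range: tuple[int, int] = (300, 700)
    ssu_len: int = 1500
    gc_range: tuple[float, float] = (0.35, 0.70)
    spacer_ratio: float = 10.0       # spacer:marker nt, so most reads are non-marker
    rp_genes: tuple[str, ...] = _refdb.DEFAULT_RP_GENES
    # per-level substitution fractions of the three-level generative tree
    aa_divergence: tuple[float, float, float] = (0.40, 0.25, 0.08)
    nt_divergence: tuple[float, float, float] = (0.10, 0.05, 0.02)

    def validate(self) -> None:
        if not (0 <= self.frac_diazotroph <= 1 and 0 <= self.frac_pseudo <= 1):
            raise ConfigError("class fractions must lie in [0,1]")
        if self.frac_diazotroph + self.frac_pseudo > 1:
            raise ConfigError("diazotroph + pseudo fractions exceed 1")
        if not (0 < self.gc_range[0] <= self.gc_range[1] < 1):
            raise ConfigError(f"invalid GC range {self.gc_range}")
        if self.len_jitter < 0 or self.len_jitter >= 1:
            raise ConfigError(f"invalid length jitter {self.len_jitter}")
        if self.spacer_ratio < 0:
            raise ConfigError("spacer_ratio must be >= 0")


@dataclass
class CommunityConfig:
    """Community-level generative parameters."""

    lognorm_mu: float = 0.0
    lognorm_sigma: float = 1.0
    aerobic_diazotroph_fraction: float = 0.02
    anaerobic_fold: float = 17.6      # anaerobic:aerobic mean fold difference
    #: anaerobic communities favour deltaproteobacterial diazotrophs
    #: (Geobacteraceae/Anaeromyxobacteraceae) by this within-group weight
    anaerobic_delta_weight: float = 4.0
    pseudo_fraction: float = 0.01
    contaminant_fraction: float = 0.0
    n_reads: int = 200_000

    def diazotroph_fraction(self, env: str) -> float:
        if env in ANAEROBIC_ENVS:
            p = self.anaerobic_fold * self.aerobic_diazotroph_fraction
        elif env in AEROBIC_ENVS:
            p = self.aerobic_diazotroph_fraction
        else:
            raise ConfigError(f"unknown environment category {env!r}")
        if p + self.pseudo_fraction + self.contaminant_fraction >= 1:
            raise ConfigError("class fractions sum to >= 1 after fold scaling")
        return p


@dataclass
class SyntheticTaxon:
    taxon_id: str
    lineage: tuple[str, ...]
    gc_fraction: float
    marker_complement: frozenset[str]
    kind: str                         # diazotroph | pseudo_nifh | non_diazotroph | contaminant

    @property
    def is_contaminant(self) -> bool:
        return self.kind == "contaminant"


@dataclass
class SyntheticReferenceSet:
    """Reference genomes + the generative scaffolding behind them."""

    db: _refdb.ReferenceDB
    taxa: list[SyntheticTaxon]
    genomes: dict[str, dict[str, str]]
    annotations: pd.DataFrame
    taxonomy: dict[str, tuple[str, ...]]
    trees: dict[str, str] = field(default_factory=dict)  # family -> newick

    def taxon(self, taxon_id: str) -> SyntheticTaxon:
        return next(t for t in self.taxa if t.taxon_id == taxon_id)

    def genome_length(self, taxon_id: str) -> int:
        return sum(len(s) for s in self.genomes[taxon_id].values())


@dataclass
class SyntheticSample:
    sample_id: str
    environment: str
    latitude: float
    longitude: float
    abundances: dict[str, float]
    n_reads: int
    truth: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference set


def _random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _NT[rng.choice(4, size=length, p=p)].tobytes().decode()


def _mutate_aa(rng: np.random.Generator, seq: str, fraction: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < fraction
    repl = rng.integers(0, len(_AA), size=int(hit.sum()))
    arr[hit] = np.frombuffer(_AA.encode(), dtype=np.uint8)[repl]
    return arr.tobytes().decode()


def _mutate_nt(rng: np.random.Generator, seq: str, fraction: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.zeros(arr.size, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    hit = rng.random(arr.size) < fraction
    code[hit] = (code[hit] + 1 + rng.integers(0, 3, size=int(hit.sum()))) % 4
    return _NT[code].tobytes().decode()


def _codon_weights(gc: float) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-amino-acid synonymous codons with GC-biased selection weights."""
    table = CodonTable.unambiguous_dna_by_id[11]
    codons: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        codons.setdefault(aa, []).append(codon)
    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    out = {}
    for aa, cods in codons.items():
        w = np.array([math.prod(base_p[b] for b in c) for c in sorted(cods)])
        out[aa] = (sorted(cods), w / w.sum())
    return out


def _back_translate(rng: np.random.Generator, aa: str, gc: float) -> str:
    weights = _codon_weights(gc)
    parts = []
    for res in aa:
        cods, w = weights[res]
        parts.append(cods[rng.choice(len(cods), p=w)])
    parts.append("TAA")
    return "".join(parts)


def _draw_lineages(rng: np.random.Generator, pool, n: int) -> list[tuple]:
    idx = rng.integers(0, len(pool), size=n)
    out = []
    seen: dict[tuple, int] = {}
    for i in idx:
        base = pool[int(i)]
        seen[base] = seen.get(base, 0) + 1
        genus = f"{(base[4] or base[3])[:6]}Genus{seen[base]}"
        lineage = tuple(x for x in base if x is not None)
        out.append(lineage + (genus,))
    return out


def simulate_reference_set(
    n_taxa: int,
    seed: int,
    config: ReferenceConfig | None = None,
) -> SyntheticReferenceSet:
    """Generate ``n_taxa`` reference genomes with known marker complements.

    Deterministic under ``seed``.  Protein markers of each family descend
    from one ancestral sequence, so the per-family alignments are gap-free
    and the generative tree doubles as the placement reference tree.
    """
    if n_taxa < 1:
        raise ConfigError("n_taxa must be >= 1")
    config = config or ReferenceConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    n_diazo = max(1, round(config.frac_diazotroph * n_taxa)) if config.frac_diazotroph else 0
    n_pseudo = round(config.frac_pseudo * n_taxa)
    n_plain = max(0, n_taxa - n_diazo - n_pseudo)

    taxa: list[SyntheticTaxon] = []
    rp_set = tuple(config.rp_genes)
    base_markers = frozenset(rp_set) | {_refdb.SSU16S}
    lineages = _draw_lineages(rng, _DIAZOTROPH_POOL, n_diazo + n_pseudo)
    for i in range(n_diazo):
        taxa.append(SyntheticTaxon(
            taxon_id=f"T{len(taxa):03d}", lineage=lineages[i],
            gc_fraction=float(rng.uniform(*config.gc_range)),
            marker_complement=base_markers | {"nifH", "nifD", "nifK"},
            kind="diazotroph"))
    for i in range(n_pseudo):
        taxa.append(SyntheticTaxon(
            taxon_id=f"T{len(taxa):03d}", lineage=lineages[n_diazo + i],
            gc_fraction=float(rng.uniform(*config.gc_range)),
            marker_complement=base_markers | {"nifH"}, kind="pseudo_nifh"))
    for lineage in _draw_lineages(rng, _PLAIN_POOL, n_plain):
        taxa.append(SyntheticTaxon(
            taxon_id=f"T{len(taxa):03d}", lineage=lineage,
            gc_fraction=float(rng.uniform(*config.gc_range)),
            marker_complement=base_markers, kind="non_diazotroph"))
    for i in range(config.n_contaminant):
        lineage = (_LACTO_LINEAGE if i % 2 == 0 else _CHLORO_LINEAGE)
        taxa.append(SyntheticTaxon(
            taxon_id=f"T{len(taxa):03d}", lineage=lineage + (f"ContamGenus{i}",),
            gc_fraction=float(rng.uniform(*config.gc_range)),
            marker_complement=base_markers, kind="contaminant"))

    # family-wise ancestral sequences and per-taxon evolved copies
    def jitter_len(target: int) -> int:
        lo = int(target * (1 - config.len_jitter))
        hi = int(target * (1 + config.len_jitter))
        return int(rng.integers(lo, hi + 1))

    protein_fams = ["nifH", "nifD", "nifK", *rp_set]
    target_nt_len = {"nifH": config.nifh_len, "nifD": config.nifdk_len,
                     "nifK": config.nifdk_len}
    for rp in rp_set:
        target_nt_len[rp] = int(rng.integers(*config.rp_len_range))

    aa_ancestor = {
        fam: "M" + "".join(_AA[i] for i in rng.integers(0, 20, size=target_nt_len[fam] // 3 - 2))
        for fam in protein_fams
    }
    ssu_ancestor = _random_nt(rng, config.ssu_len, 0.5)

    # three-level evolution: class node -> family node -> leaf
    def level_keys(t: SyntheticTaxon) -> tuple[str, str]:
        cls = t.lineage[2] if len(t.lineage) > 2 else t.lineage[-1]
        fam = t.lineage[4] if len(t.lineage) > 4 else f"{cls}-unlabelled"
        return cls, fam

    taxon_aa: dict[tuple[str, str], str] = {}
    taxon_ssu: dict[str, str] = {}
    d1, d2, d3 = config.aa_divergence
    e1, e2, e3 = config.nt_divergence
    for fam_name in protein_fams + [_refdb.SSU16S]:
        class_anc: dict[str, str] = {}
        family_anc: dict[tuple[str, str], str] = {}
        for t in taxa:
            if fam_name != _refdb.SSU16S and fam_name not in t.marker_complement:
                continue
            ck, fk = level_keys(t)
            if fam_name == _refdb.SSU16S:
                if ck not in class_anc:
                    class_anc[ck] = _mutate_nt(rng, ssu_ancestor, e1)
                if (ck, fk) not in family_anc:
                    family_anc[(ck, fk)] = _mutate_nt(rng, class_anc[ck], e2)
                taxon_ssu[t.taxon_id] = _mutate_nt(rng, family_anc[(ck, fk)], e3)
            else:
                if ck not in class_anc:
                    class_anc[ck] = _mutate_aa(rng, aa_ancestor[fam_name], d1)
                if (ck, fk) not in family_anc:
                    family_anc[(ck, fk)] = _mutate_aa(rng, class_anc[ck], d2)
                taxon_aa[(fam_name, t.taxon_id)] = _mutate_aa(
                    rng, family_anc[(ck, fk)], d3)

    # assemble genomes: genes in fixed order, separated by neutral spacers
    genomes: dict[str, dict[str, str]] = {}
    ann_rows = []
    taxonomy: dict[str, tuple[str, ...]] = {}
    for t in taxa:
        taxonomy[t.taxon_id] = t.lineage
        genes: list[tuple[str, str, str]] = []  # (family, gene_id, nt on gene strand)
        for fam_name in protein_fams:
            if fam_name not in t.marker_complement:
                continue
            aa = taxon_aa[(fam_name, t.taxon_id)]
            # trim/keep to the per-taxon jittered length (multiple of 3)
            n_res = max(20, jitter_len(target_nt_len[fam_name]) // 3 - 1)
            aa = aa[:n_res]
            genes.append((fam_name, f"{t.taxon_id}_{fam_name}",
                          _back_translate(rng, aa, t.gc_fraction)))
        ssu = taxon_ssu[t.taxon_id][: jitter_len(config.ssu_len)]
        genes.append((_refdb.SSU16S, f"{t.taxon_id}_{_refdb.SSU16S}", ssu))

        marker_nt = sum(len(g[2]) for g in genes)
        n_gaps = len(genes) + 1
        gap_len = max(1, int(config.spacer_ratio * marker_nt / n_gaps))
        parts = []
        pos = 0
        contig = f"{t.taxon_id}_c1"
        for fam_name, gene_id, nt in genes:
            spacer = _random_nt(rng, gap_len, t.gc_fraction)
            parts.append(spacer)
            pos += len(spacer)
            strand = "+" if rng.random() < 0.5 else "-"
            stored = nt if strand == "+" else _revcomp(nt)
            parts.append(stored)
            ann_rows.append(dict(genome_id=t.taxon_id, contig=contig,
                                 start=pos + 1, end=pos + len(nt),
                                 strand=strand, family=fam_name, gene_id=gene_id))
            pos += len(nt)
        parts.append(_random_nt(rng, gap_len, t.gc_fraction))
        genomes[t.taxon_id] = {contig: "".join(parts)}

    annotations = pd.DataFrame(ann_rows)
    db = _refdb.build_db(genomes, annotations, taxonomy, rp_genes=rp_set)

    trees = {fam: _generative_newick(taxa, fam, (d1, d2, d3), level_keys)
             for fam in ("nifD", "nifK", "nifH")}
    return SyntheticReferenceSet(db=db, taxa=taxa, genomes=genomes,
                                 annotations=annotations, taxonomy=taxonomy,
                                 trees=trees)


def _revcomp(seq: str) -> str:
    from diazoscope._seq import revcomp
    return revcomp(seq)


def _generative_newick(taxa, family: str, div: tuple[float, float, float],
                       level_keys) -> str:
    """Newick of the root->class->family->leaf generative tree.

    Branch lengths are the expected substitutions/site of each level.
    Leaf names are gene ids (``<taxon>_<family>``).
    """
    d1, d2, d3 = div
    tree: dict[str, dict[str, list[str]]] = {}
    for t in taxa:
        if family not in t.marker_complement:
            continue
        ck, fk = level_keys(t)
        tree.setdefault(ck, {}).setdefault(fk, []).append(f"{t.taxon_id}_{family}")
    class_parts = []
    for ck in sorted(tree):
        fam_parts = []
        for fk in sorted(tree[ck]):
            leaves = ",".join(f"{leaf}:{d3}" for leaf in sorted(tree[ck][fk]))
            fam_parts.append(f"({leaves}):{d2}")
        class_parts.append(f"({','.join(fam_parts)}):{d1}")
    return f"({','.join(class_parts)});"


# ---------------------------------------------------------------------------
# communities


def simulate_community(
    taxa: list[SyntheticTaxon],
    env: str,
    params: CommunityConfig,
    seed: int,
    sample_id: str = "S0",
    latitude: float = 0.0,
    longitude: float = 0.0,
) -> SyntheticSample:
    """Draw a community abundance vector for one sample.

    Within each taxon class (diazotroph / pseudo-nifH / contaminant /
    other), relative abundances are log-normal; the class totals are pinned
    to the environment-dependent generative fractions, with the anaerobic
    diazotroph fraction equal to ``anaerobic_fold`` times the aerobic one.
    """
    rng = np.random.default_rng(seed)
    p_diazo = params.diazotroph_fraction(env)
    groups = {
        "diazotroph": p_diazo,
        "pseudo_nifh": params.pseudo_fraction,
        "contaminant": params.contaminant_fraction,
    }
    raw = np.exp(rng.normal(params.lognorm_mu, params.lognorm_sigma, size=len(taxa)))
    abundances = dict.fromkeys((t.taxon_id for t in taxa), 0.0)
    p_other = 1.0 - sum(groups.values())
    for kind, target in list(groups.items()) + [("non_diazotroph", p_other)]:
        members = [i for i, t in enumerate(taxa) if t.kind == kind]
        if target > 0 and not members:
            raise ConfigError(f"no taxa of class {kind!r} but fraction {target} requested")
        if not members or target <= 0:
            continue
        w = raw[members].copy()
        if kind == "diazotroph" and env in ANAEROBIC_ENVS:
            for j, i in enumerate(members):
                if "Deltaproteobacteria" in taxa[i].lineage:
                    w[j] *= params.anaerobic_delta_weight
        w /= w.sum()
        for i, wi in zip(members, w):
            abundances[taxa[i].taxon_id] = float(target * wi)
    total = sum(abundances.values())
    abundances = {k: v / total for k, v in abundances.items()}

    truth = recompute_truth(taxa, abundances)
    return SyntheticSample(sample_id=sample_id, environment=env,
                           latitude=latitude, longitude=longitude,
                           abundances=abundances, n_reads=params.n_reads,
                           truth=truth)


def recompute_truth(taxa: list[SyntheticTaxon],
                    abundances: dict[str, float]) -> dict[str, float]:
    """Ground-truth summaries derivable from the abundance vector."""
    by_id = {t.taxon_id: t for t in taxa}
    diazo = sum(a for tid, a in abundances.items() if by_id[tid].kind == "diazotroph")
    pseudo = sum(a for tid, a in abundances.items() if by_id[tid].kind == "pseudo_nifh")
    contam = sum(a for tid, a in abundances.items() if by_id[tid].is_contaminant)
    nifh_mass = diazo + pseudo
    return {
        "diazotroph_fraction": diazo,
        "pseudo_nifh_excess": (nifh_mass / diazo) if diazo > 0 else
                              (math.inf if pseudo > 0 else 0.0),
        "contaminant_fraction": contam,
    }


# ---------------------------------------------------------------------------
# reads

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def simulate_reads(
    sample: SyntheticSample,
    refset: SyntheticReferenceSet,
    read_len: int = 150,
    error_rate: float = 0.005,
    gc_bias_lambda: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Simulate ``sample.n_reads`` single-end reads as (id, seq, qual) tuples.

    Fragments are drawn with probability proportional to taxon abundance x
    genome length, with uniform start and strand; a fragment of GC fraction
    g is accepted with probability ``sigmoid(-gc_bias_lambda * (g - 0.5))``
    (no bias at lambda = 0).  Per-base substitution errors at
    ``error_rate``; qualities are the constant Phred of the error rate.
    Read ids embed the source taxon, start and strand as ground truth.
    """
    rng = np.random.default_rng(seed)
    taxa_ids = [t.taxon_id for t in refset.taxa if sample.abundances.get(t.taxon_id, 0) > 0]
    if sample.n_reads == 0 or not taxa_ids:
        return []
    arrs = {}
    for tid in taxa_ids:
        contig = "".join(refset.genomes[tid][c] for c in sorted(refset.genomes[tid]))
        if len(contig) < read_len:
            raise InputError(f"read_len {read_len} exceeds genome of {tid}")
        arrs[tid] = _CODE[np.frombuffer(contig.encode(), dtype=np.uint8)]
    weights = np.array([sample.abundances[tid] * arrs[tid].size for tid in taxa_ids])
    weights /= weights.sum()

    qchar = chr(33 + min(40, round(-10 * math.log10(max(error_rate, 1e-4)))))
    qual = qchar * read_len

    # one concatenated code array; per-taxon start offsets
    offsets = {}
    pos = 0
    for tid in taxa_ids:
        offsets[tid] = pos
        pos += arrs[tid].size
    big = np.concatenate([arrs[tid] for tid in taxa_ids])
    offset_arr = np.array([offsets[tid] for tid in taxa_ids])
    span_arr = np.array([arrs[tid].size - read_len + 1 for tid in taxa_ids])

    out: list[tuple[str, str, str]] = []
    need = sample.n_reads
    serial = 0
    while len(out) < need:
        batch = max(1024, int((need - len(out)) * 2.2))
        pick = rng.choice(len(taxa_ids), size=batch, p=weights)
        starts = (rng.random(batch) * span_arr[pick]).astype(np.int64)
        strands = rng.random(batch) < 0.5
        accept_u = rng.random(batch)
        frags = big[(offset_arr[pick] + starts)[:, None] + np.arange(read_len)]
        if gc_bias_lambda != 0.0:
            g = ((frags == 1) | (frags == 2)).mean(axis=1)
            p_acc = 1.0 / (1.0 + np.exp(gc_bias_lambda * (g - 0.5)))
        else:
            p_acc = np.full(batch, 0.5)
        keep = accept_u < p_acc
        frags = frags[keep]
        pick, starts, strands = pick[keep], starts[keep], strands[keep]
        rc = ~strands
        frags[rc] = _COMP[frags[rc][:, ::-1]]
        if error_rate > 0:
            n_err = rng.binomial(read_len, error_rate, size=frags.shape[0])
            total = int(n_err.sum())
            rows = np.repeat(np.arange(frags.shape[0]), n_err)
            cols = rng.integers(0, read_len, size=total)
            frags[rows, cols] = (frags[rows, cols]
                                 + rng.integers(1, 4, size=total)) % 4
        blob = _DECODE[frags].tobytes().decode()
        starts_l = starts.tolist()
        strand_l = np.where(strands, "+", "-").tolist()
        pick_l = pick.tolist()
        for j in range(frags.shape[0]):
            if len(out) >= need:
                break
            rid = (f"{sample.sample_id}_r{serial:07d}|taxon={taxa_ids[pick_l[j]]}"
                   f"|start={starts_l[j]}|strand={strand_l[j]}")
            out.append((rid, blob[j * read_len:(j + 1) * read_len], qual))
            serial += 1
    return out


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# geography


def simulate_geo_metadata(
    n_sites: int,
    replicates_per_site: int,
    jitter_km: float,
    seed: int,
    environments: list[str] | None = None,
) -> pd.DataFrame:
    """Sampling coordinates: distinct sites >= 10 km apart, replicates jittered
    within ``jitter_km`` of the site centre.

    Returns a table with columns sample_id, site, env, latitude, longitude.
    """
    if jitter_km < 0:
        raise ConfigError("jitter_km must be >= 0")
    from diazoscope.curate import haversine_km

    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    while len(centers) < n_sites:
        lat = float(rng.uniform(-55, 55))
        lon = float(rng.uniform(-175, 175))
        if all(haversine_km(lat, lon, la, lo) >= 10.0 for la, lo in centers):
            centers.append((lat, lon))
    envs = environments or ["cropland", "forest", "grassland", "paddy",
                            "sediment", "tundra"]
    rows = []
    r_earth = 6371.0088
    for s, (lat, lon) in enumerate(centers):
        env = envs[s % len(envs)]
        for r in range(replicates_per_site):
            d = float(rng.uniform(0, jitter_km))
            theta = float(rng.uniform(0, 2 * math.pi))
            dlat = math.degrees(d / r_earth) * math.cos(theta)
            dlon = (math.degrees(d / r_earth) * math.sin(theta)
                    / max(math.cos(math.radians(lat)), 1e-6))
            rows.append(dict(sample_id=f"site{s:02d}_rep{r}", site=f"site{s:02d}",
                             env=env, latitude=lat + dlat, longitude=lon + dlon))
    return pd.DataFrame(rows)


def save_truth(samples: list[SyntheticSample], path: str | Path) -> None:
    payload = {s.sample_id: asdict(s) for s in samples}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
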