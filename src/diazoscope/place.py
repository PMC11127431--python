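"""Placement-based taxonomic annotation of nitrogenase reads.

Short nifD/K read fragments carry limited phylogenetic signal, so a simple
best-hit taxonomy over-annotates them.  Instead each translated read is
compared against a per-marker reference package (protein alignment +
reference tree + leaf taxonomy): alignment scores against the reference
leaves are turned into a probability mass over the tree's pendant edges by
a softmax, and the read is annotated at the deepest taxonomy node whose
leaves hold at least ``tau`` of that mass (a confidence-weighted LCA).
Reads for which no node at or below domain rank reaches ``tau`` are
discarded as unreliable.

The softmax-over-leaf-scores mass is a deliberate, contract-preserving
simplification of maximum-likelihood evolutionary placement: it yields a
normalised per-edge mass distribution with tunable sharpness ``beta``
(default 0.5 per bit of score gap, so a 10-point score gap concentrates
>0.99 of the mass).

Deltaproteobacterial reads annotated above family rank whose confident
descendant families are all Geobacteraceae or Anaeromyxobacteraceae are
tracked as a dedicated "possibly Geobacteraceae/Anaeromyxobacteraceae"
category.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from skbio import TreeNode

from diazoscope.errors import ConfigError, InputError

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
POSSIBLY_FAMILIES = frozenset({"Geobacteraceae", "Anaeromyxobacteraceae"})
POSSIBLY_LABEL = "Possibly Geobacteraceae or Anaeromyxobacteraceae"

_MIN_QUERY_AA = 20


def _aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


_LOCAL = _aligner("local")
_GLOBAL = _aligner("global")
_B62 = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _sanitize(aa: str) -> str:
    return "".join(c if c in _B62 and c != "*" else "X" for c in aa.upper())


@dataclass
class RefPackage:
    """Per-marker reference package: protein MSA, tree and leaf taxonomy."""

    family: str
    msa: dict[str, str]                      # leaf id -> aligned (gapped) aa
    tree: TreeNode
    taxonomy: dict[str, tuple[str, ...]]
    clade_restriction: str | None = None

    def __post_init__(self) -> None:
        leaves = {t.name for t in self.tree.tips()}
        if not leaves <= set(self.msa):
            missing = sorted(leaves - set(self.msa))
            raise InputError(f"tree leaves absent from MSA: {missing[:5]}")
        for leaf in leaves:
            if leaf not in self.taxonomy:
                raise InputError(f"no lineage for tree leaf {leaf!r}")
        self.leaf_ids = sorted(leaves)
        widths = {len(s) for s in self.msa.values()}
        if len(widths) != 1:
            raise InputError("MSA rows have unequal widths")

    # -- serialization -----------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "alignment.fasta", "w") as fh:
            for name in sorted(self.msa):
                fh.write(f">{name}\n{self.msa[name]}\n")
        (out / "tree.nwk").write_text(str(self.tree) + "\n"
                                      if not str(self.tree).endswith("\n")
                                      else str(self.tree))
        with open(out / "taxonomy.tsv", "w") as fh:
            for name in sorted(self.taxonomy):
                fh.write(f"{name}\t{';'.join(self.taxonomy[name])}\n")
        (out / "meta.json").write_text(json.dumps(
            {"family": self.family, "clade_restriction": self.clade_restriction}))

    @classmethod
    def load(cls, pkg_dir: str | Path) -> "RefPackage":
        pkg_dir = Path(pkg_dir)
        msa = {rec.id: str(rec.seq)
               for rec in SeqIO.parse(pkg_dir / "alignment.fasta", "fasta")}
        tree = TreeNode.read(StringIO((pkg_dir / "tree.nwk").read_text()),
                             convert_underscores=False)
        taxonomy = {}
        for line in (pkg_dir / "taxonomy.tsv").read_text().splitlines():
            name, _, lineage = line.partition("\t")
            taxonomy[name] = tuple(lineage.split(";"))
        meta = json.loads((pkg_dir / "meta.json").read_text())
        return cls(family=meta["family"], msa=msa, tree=tree, taxonomy=taxonomy,
                   clade_restriction=meta.get("clade_restriction"))

    @classmethod
    def from_reference_set(cls, refset, family: str) -> "RefPackage":
        """Build the package of one marker from a synthetic reference set.

        Synthetic marker proteins of a family are substitution-only
        descendants of one ancestor, so the per-family alignment is the
        gap-free stack of sequences padded to equal width.
        """
        genes = [g for g in refset.db.family(family)]
        width = max(len(g.aa_sequence) for g in genes)
        msa = {g.gene_id: g.aa_sequence.ljust(width, "-") for g in genes}
        tree = TreeNode.read(StringIO(refset.trees[family]),
                             convert_underscores=False)
        taxonomy = {g.gene_id: g.lineage for g in genes}
        return cls(family=family, msa=msa, tree=tree, taxonomy=taxonomy)


@dataclass
class Placement:
    read_id: str
    weights: dict[str, float]                # pendant-edge (leaf) mass, sums to 1
    annotation: tuple[str, ...] | None = None
    rank: str | None = None
    confidence: float = 0.0
    category: str = "unreliable"             # annotated | possibly_geo_anaeromyxo | unreliable


# ---------------------------------------------------------------------------
# alignment against the reference package


def profile_align(read_aa: str, refpkg: RefPackage
                  ) -> tuple[tuple[int, int], dict[str, float]]:
    """Align a translated read into the MSA coordinate system.

    Returns the covered MSA column span and per-leaf alignment scores,
    where each leaf is scored on its residues restricted to the covered
    columns (so leaves are compared on the same homologous window).
    """
    if len(read_aa) < _MIN_QUERY_AA:
        raise InputError(f"query too short ({len(read_aa)} aa < {_MIN_QUERY_AA})")
    query = _sanitize(read_aa)

    degapped = {}
    col_of_res = {}
    for leaf in refpkg.leaf_ids:
        row = refpkg.msa[leaf]
        cols = [i for i, c in enumerate(row) if c not in "-."]
        degapped[leaf] = _sanitize("".join(row[i] for i in cols))
        col_of_res[leaf] = cols

    # pass 1: anchor the query on its best-scoring leaf
    best_leaf, best_aln, best_score = None, None, -math.inf
    for leaf in refpkg.leaf_ids:
        if not degapped[leaf]:
            continue
        try:
            aln = _LOCAL.align(query, degapped[leaf])[0]
        except IndexError:
            continue
        if len(aln.aligned[1]) and aln.score > best_score:
            best_leaf, best_aln, best_score = leaf, aln, float(aln.score)
    if best_aln is None:
        # no positive-scoring anchor anywhere (e.g. an all-X query):
        # fall back to the full alignment width with flat zero scores
        width = len(next(iter(refpkg.msa.values())))
        return (0, width), {leaf: 0.0 for leaf in refpkg.leaf_ids}
    t_blocks = best_aln.aligned[1]
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    cols = col_of_res[best_leaf]
    span = (cols[t_start], cols[t_end - 1] + 1)

    # pass 2: score every leaf on the covered window
    scores = {}
    for leaf in refpkg.leaf_ids:
        window = "".join(
            refpkg.msa[leaf][i] for i in range(span[0], span[1]))
        window = _sanitize(window.replace("-", "").replace(".", ""))
        if not window:
            scores[leaf] = 0.0
            continue
        try:
            scores[leaf] = float(_LOCAL.align(query, window)[0].score)
        except IndexError:
            scores[leaf] = 0.0
    return span, scores


def place_read(scores: dict[str, float], refpkg: RefPackage,
               beta: float = 0.5, read_id: str = "") -> Placement:
    """Distribute a read's placement mass over pendant edges.

    Pendant-edge weights are ``softmax(beta * score)`` over leaves; the
    mass descending through any internal edge is the sum of its pendant
    descendants, which is what the LCA annotation accounts against.
    ``beta -> 0`` gives uniform mass; the default concentrates >0.99 of
    the mass on a leaf whose score exceeds the rest by 10 points.
    """
    if not scores:
        raise InputError("empty score table")
    leaves = sorted(scores)
    s = np.array([scores[l] for l in leaves], dtype=float)
    if not np.all(np.isfinite(s)):
        raise InputError("non-finite alignment scores")
    z = beta * s
    z -= z.max()
    w = np.exp(z)
    w /= w.sum()
    return Placement(read_id=read_id,
                     weights={l: float(x) for l, x in zip(leaves, w)})


# ---------------------------------------------------------------------------
# LCA annotation


def _prefix_weights(placement: Placement, refpkg: RefPackage
                    ) -> dict[tuple[str, ...], float]:
    acc: dict[tuple[str, ...], float] = defaultdict(float)
    for leaf, w in placement.weights.items():
        lineage = refpkg.taxonomy[leaf]
        for d in range(1, len(lineage) + 1):
            acc[lineage[:d]] += w
    return acc


def annotate(placement: Placement, refpkg: RefPackage,
             tau: float = 0.8) -> Placement:
    """LCA-annotate a placement at the deepest node holding >= ``tau`` mass.

    Mutates and returns the placement.  Raising ``tau`` can only shorten
    (never deepen) the annotated lineage.
    """
    if not 0 < tau <= 1:
        raise ConfigError("tau must lie in (0, 1]")
    acc = _prefix_weights(placement, refpkg)
    eligible = [(len(p), w, p) for p, w in acc.items() if w >= tau - 1e-12]
    if not eligible:
        placement.annotation = None
        placement.rank = None
        placement.confidence = 0.0
        placement.category = "unreliable"
        return placement
    depth, w, prefix = max(eligible, key=lambda t: (t[0], t[1],
                                                    tuple(reversed(t[2]))))
    # deterministic tie-break at equal depth/weight: lexicographic prefix
    ties = [t for t in eligible if t[0] == depth and abs(t[1] - w) < 1e-12]
    prefix = min(t[2] for t in ties)
    w = acc[prefix]
    placement.annotation = prefix
    placement.rank = RANKS[min(depth, len(RANKS)) - 1]
    placement.confidence = float(min(w, 1.0))
    placement.category = "annotated"
    return resolve_possibly_category(placement, refpkg)


def resolve_possibly_category(placement: Placement, refpkg: RefPackage,
                              epsilon: float = 0.05) -> Placement:
    """Mark deltaproteobacterial above-family annotations whose confident
    descendant families are all Geobacteraceae/Anaeromyxobacteraceae.

    A descendant family is confident when it holds at least ``epsilon`` of
    the placement mass.
    """
    if placement.annotation is None:
        return placement
    prefix = placement.annotation
    fam_idx = RANKS.index("family")
    if len(prefix) > fam_idx:            # at or below family: plain annotation
        return placement
    if "Deltaproteobacteria" not in prefix:
        return placement
    fam_mass: Counter = Counter()
    for leaf, w in placement.weights.items():
        lineage = refpkg.taxonomy[leaf]
        if lineage[:len(prefix)] != prefix:
            continue
        if len(lineage) > fam_idx:
            fam_mass[lineage[fam_idx]] += w
    confident = {f for f, w in fam_mass.items() if w >= epsilon}
    if confident and confident <= POSSIBLY_FAMILIES:
        placement.category = "possibly_geo_anaeromyxo"
    return placement


def place_and_annotate(read_aa: str, refpkg: RefPackage, beta: float = 0.5,
                       tau: float = 0.8, read_id: str = "") -> Placement:
    """Convenience composition: profile-align, place, LCA-annotate."""
    _, scores = profile_align(read_aa, refpkg)
    placement = place_read(scores, refpkg, beta=beta, read_id=read_id)
    return annotate(placement, refpkg, tau=tau)


def family_composition(placements: list[Placement]) -> dict[str, float]:
    """Family-level composition over annotated reads of one sample.

    Reads annotated at or below family rank contribute to their family;
    the possibly-Geobacteraceae/Anaeromyxobacteraceae category is kept
    separate; other above-family annotations are pooled per deepest taxon.
    Unreliable reads are excluded; an empty dict means no usable read.
    """
    fam_idx = RANKS.index("family")
    counts: Counter = Counter()
    for p in placements:
        if p.category == "unreliable" or p.annotation is None:
            continue
        if p.category == "possibly_geo_anaeromyxo":
            counts[POSSIBLY_LABEL] += 1
        elif len(p.annotation) > fam_idx:
            counts[p.annotation[fam_idx]] += 1
        else:
            counts[f"unclassified {p.annotation[-1]}"] += 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(counts.items())}


# ---------------------------------------------------------------------------
# nearest-isolate mapping


def _global_identity(query: str, target: str) -> float:
    aln = _GLOBAL.align(_sanitize(query), _sanitize(target))[0]
    c = aln.counts()
    total = c.gaps + c.identities + c.mismatches
    return c.identities / total if total else 0.0


def map_to_nearest_isolate(
    queries: dict[str, str],
    known: dict[str, str],
    new_isolate: dict[str, str],
) -> tuple[dict[str, str], dict[str, float]]:
    """Classify each query by its globally most similar reference partition.

    Every query is aligned (Needleman–Wunsch, BLOSUM62, affine gaps)
    against every reference; the class is that of the top-identity hit,
    with exact ties between partitions reported as ``tie``.  Returns the
    per-read classes and the per-class fractions.
    """
    if not known or not new_isolate:
        raise ConfigError("both reference partitions must be non-empty")
    classes: dict[str, str] = {}
    for rid in sorted(queries):
        best_known = max(_global_identity(queries[rid], t)
                         for t in known.values())
        best_new = max(_global_identity(queries[rid], t)
                       for t in new_isolate.values())
        if best_known > best_new:
            classes[rid] = "known"
        elif best_new > best_known:
            classes[rid] = "new_isolate"
        else:
            classes[rid] = "tie"
    if not classes:
        return {}, {}
    n = len(classes)
    summary = {cls: sum(1 for c in classes.values() if c == cls) / n
               for cls in ("known", "new_isolate", "tie")}
    return classes, summary
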