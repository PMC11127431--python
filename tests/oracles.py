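"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: alignment scoring
goes through biotite (not Biopython), UniFrac through dendropy-parsed
trees with explicit per-branch leaf-set enumeration, clustering through a
boolean transitive-closure matrix, and group statistics through scipy /
scikit-bio reference implementations.
"""

from __future__ import annotations

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign
import dendropy

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()


def sw_best_gene(read_seq: str, genes: list, frame_fn) -> tuple[str | None, float]:
    """Exhaustive local-alignment oracle: best gene over all six frames.

    ``genes`` is a list of objects with ``gene_id`` and ``aa_sequence``;
    ``frame_fn`` translates a nucleotide read into six frame strings.
    Returns (gene_id of the best raw score, raw score); ties break by
    lexicographic gene id.
    """
    best_gene, best_score = None, -np.inf
    segments = []
    for aa in frame_fn(read_seq):
        segments.extend(s for s in aa.split("*") if len(s) >= 8)
    for seg in segments:
        try:
            q = bseq.ProteinSequence(seg.replace("X", "A"))
        except Exception:
            continue
        for gene in genes:
            t = bseq.ProteinSequence(gene.aa_sequence)
            alns = balign.align_optimal(q, t, _BLOSUM62,
                                        gap_penalty=(-11, -1), local=True,
                                        max_number=1)
            score = alns[0].score if alns else -np.inf
            if score > best_score or (score == best_score
                                      and best_gene is not None
                                      and gene.gene_id < best_gene):
                best_gene, best_score = gene.gene_id, float(score)
    return best_gene, best_score


def nw_identity(a: str, b: str) -> float:
    """Global-alignment identity via biotite (matches / alignment columns)."""
    qa = bseq.ProteinSequence(a.replace("X", "A"))
    qb = bseq.ProteinSequence(b.replace("X", "A"))
    aln = balign.align_optimal(qa, qb, _BLOSUM62, gap_penalty=(-11, -1),
                               local=False, max_number=1)[0]
    codes = balign.get_codes(aln)
    matches = int(np.sum((codes[0] == codes[1]) & (codes[0] != -1)))
    return matches / codes.shape[1]


def unifrac_bruteforce(masses_a: dict[str, float], masses_b: dict[str, float],
                       newick: str) -> float:
    """Branch-enumeration weighted UniFrac on a dendropy-parsed tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    ta, tb = sum(masses_a.values()), sum(masses_b.values())
    pa = {k: v / ta for k, v in masses_a.items()}
    pb = {k: v / tb for k, v in masses_b.items()}
    num = den = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        leaves = {l.taxon.label for l in edge.head_node.leaf_iter()}
        wa = sum(pa.get(l, 0.0) for l in leaves)
        wb = sum(pb.get(l, 0.0) for l in leaves)
        num += edge.length * abs(wa - wb)
        den += edge.length * (wa + wb)
    return num / den if den else 0.0


def cluster_bruteforce(coords: dict[str, tuple[float, float]],
                       radius_km: float, dist_fn) -> dict[str, int]:
    """Transitive closure of the within-radius adjacency matrix."""
    ids = sorted(coords)
    n = len(ids)
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d = dist_fn(*coords[ids[i]], *coords[ids[j]])
            adj[i, j] = adj[j, i] = d < radius_km
    closure = adj.copy()
    for _ in range(n):
        new = closure | (closure @ closure)
        if (new == closure).all():
            break
        closure = new
    labels = {}
    next_label = 0
    for i, sid in enumerate(ids):
        root = int(np.argmax(closure[i]))  # smallest connected index
        key = ids[root]
        if key not in labels:
            labels[key] = next_label
            next_label += 1
        labels[sid] = labels[key]
    return {sid: labels[sid] for sid in ids}
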