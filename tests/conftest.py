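import pandas as pd
import pytest

from diazoscope import classify, refdb, synthesize
from diazoscope.place import RefPackage
from skbio import TreeNode
from io import StringIO


@pytest.fixture(scope="session")
def refset():
    """Small synthetic reference set shared across read-level tests."""
    return synthesize.simulate_reference_set(20, seed=11)


@pytest.fixture(scope="session")
def marker_index(refset):
    return classify.MarkerIndex(refset.db)


@pytest.fixture(scope="session")
def paddy_reads(refset):
    params = synthesize.CommunityConfig(n_reads=50_000)
    sample = synthesize.simulate_community(refset.taxa, "paddy", params,
                                           seed=21, sample_id="P1")
    return sample, synthesize.simulate_reads(sample, refset, seed=22)


@pytest.fixture(scope="session")
def paddy_profile(refset, marker_index, paddy_reads):
    sample, reads = paddy_reads
    return classify.profile_sample(
        reads, marker_index,
        dict(sample_id=sample.sample_id, env="paddy", latitude=0.0,
             longitude=0.0),
        collect_families=("nifD", "nifK"))


def _spacer(n: int) -> str:
    return ("ACGT" * (n // 4 + 1))[:n]


@pytest.fixture()
def tiny_db():
    """Hand-built database: a diazotroph, a pseudo-nifH genome, an archaeon."""
    nifh = "ATGGCTGGTAAAGGTGGTATTGGTAAATCTACTACTACTCAAAATACTGCTGCTTTA"  # 57 nt
    nifd = "ATGACTGCTGAAAATATTGAAAAAGTTTTAGATGCTTATCCTGAAAAAACTCGTAAA"
    nifk = "ATGTCTCAAACTATTGATAAAATTCATTCTTGTTATCCTTTATTTGAACAAGATGAA"
    rplb = "ATGGCTATTAAAAAATATAAACCTACTACTCCTGGTCGTCGTCATATGACTACTTTA"
    ssu = "AGAGTTTGATCCTGGCTCAG" * 60                                    # 1200 nt

    def contig(genes):
        seq, rows = _spacer(50), []
        for gid, fam, g in genes:
            rows.append((len(seq) + 1, len(seq) + len(g), gid, fam))
            seq += g + _spacer(30)
        return seq, rows

    genomes, ann, tax = {}, [], {}
    layouts = {
        "G1": [("G1_nifH", "nifH", nifh), ("G1_nifD", "nifD", nifd),
               ("G1_nifK", "nifK", nifk), ("G1_rplB", "rplB", rplb),
               ("G1_16S", "SSU16S", ssu)],
        "G2": [("G2_nifH", "nifH", nifh), ("G2_rplB", "rplB", rplb),
               ("G2_16S", "SSU16S", ssu)],
        "G3": [("G3_nifH", "nifH", nifh), ("G3_nifD", "nifD", nifd),
               ("G3_nifK", "nifK", nifk)],
    }
    tax = {
        "G1": "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfuromonadales;Geobacteraceae;Geomonas",
        "G2": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus",
        "G3": "Archaea;Euryarchaeota;Methanococci;Methanococcales;Methanococcaceae;Methanococcus",
    }
    for gid, genes in layouts.items():
        seq, rows = contig(genes)
        genomes[gid] = {f"{gid}_c1": seq}
        for start, end, gene_id, fam in rows:
            ann.append(dict(genome_id=gid, contig=f"{gid}_c1", start=start,
                            end=end, strand="+", family=fam, gene_id=gene_id))
    annotations = pd.DataFrame(ann)
    taxonomy = {k: tuple(v.split(";")) for k, v in tax.items()}
    return refdb.build_db(genomes, annotations, taxonomy)


@pytest.fixture()
def toy_refpkg():
    """Six-leaf nifD package with two deltaproteobacterial families plus a
    family-unlabelled deltaproteobacterial leaf and an outgroup family."""
    base = "MKTAEINELLRQGAYEEFKSHPDVKVNRSKQCCPLGAMLAVRGIEDVIHLVHGPQGCAYD"
    def mut(s, pos, c):
        return s[:pos] + c + s[pos + 1:]

    msa = {
        "geo1": base,
        "geo2": mut(base, 10, "W"),
        "anaero1": mut(mut(base, 20, "W"), 21, "W"),
        "anaero2": mut(mut(base, 20, "W"), 25, "Y"),
        "delta_unlabelled": mut(mut(base, 30, "W"), 35, "W"),
        "delta_other": mut(mut(base, 40, "W"), 45, "W"),
        "rhizo1": "".join("W" if i % 4 == 0 else c for i, c in enumerate(base)),
        "arch1": "".join("Y" if i % 3 == 0 else c for i, c in enumerate(base)),
    }
    tree = TreeNode.read(StringIO(
        "((((geo1:0.05,geo2:0.05):0.1,(anaero1:0.05,anaero2:0.05):0.1,"
        "delta_unlabelled:0.15,delta_other:0.15):0.3,rhizo1:0.5):0.2,"
        "arch1:0.9);"), convert_underscores=False)
    tax = {
        "geo1": ("Bacteria", "Proteobacteria", "Deltaproteobacteria",
                 "Desulfuromonadales", "Geobacteraceae", "Geomonas"),
        "geo2": ("Bacteria", "Proteobacteria", "Deltaproteobacteria",
                 "Desulfuromonadales", "Geobacteraceae", "Oryzomonas"),
        "anaero1": ("Bacteria", "Proteobacteria", "Deltaproteobacteria",
                    "Myxococcales", "Anaeromyxobacteraceae", "Anaeromyxobacter"),
        "anaero2": ("Bacteria", "Proteobacteria", "Deltaproteobacteria",
                    "Myxococcales", "Anaeromyxobacteraceae", "Anaeromyxobacter"),
        "delta_unlabelled": ("Bacteria", "Proteobacteria",
                             "Deltaproteobacteria", "Desulfuromonadales"),
        "delta_other": ("Bacteria", "Proteobacteria", "Deltaproteobacteria",
                        "Desulfobacterales", "Desulfobacteraceae",
                        "Desulfobacter"),
        "rhizo1": ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                   "Hyphomicrobiales", "Rhizobiaceae", "Rhizobium"),
        "arch1": ("Archaea", "Euryarchaeota", "Methanococci",
                  "Methanococcales", "Methanococcaceae", "Methanococcus"),
    }
    return RefPackage(family="nifD", msa=msa, tree=tree, taxonomy=tax)
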