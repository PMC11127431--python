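import math

import numpy as np
import pytest

from diazoscope import classify, synthesize
from diazoscope._seq import revcomp
from diazoscope.errors import InputError, MetadataError

import oracles


def _read(seq, rid="r1", q="I"):
    return (rid, seq, q * len(seq))


class TestQualityFilter:
    def test_thresholds(self):
        reads = [_read("ACGT" * 40, "good"),
                 _read("ACGT" * 10, "short"),
                 ("lowq", "ACGT" * 40, chr(33 + 10) * 160)]
        kept = classify.quality_filter(reads, min_len=100, min_mean_q=20)
        assert [r[0] for r in kept] == ["good"]

    def test_order_preserved(self):
        reads = [_read("ACGT" * 30, f"r{i}") for i in range(5)]
        assert [r[0] for r in classify.quality_filter(reads, 100, 20)] \
            == [f"r{i}" for i in range(5)]

    def test_empty_input(self):
        assert classify.quality_filter([], 100, 20) == []

    def test_malformed_fastq_reports_index(self, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\nMISSING_PLUS\n")
        with pytest.raises(InputError, match="malformed FASTQ"):
            classify.quality_filter(str(bad), 1, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError, match="mismatch"):
            classify.quality_filter([("r", "ACGT", "II")], 1, 0)


class TestAssignProteinMarker:
    def test_error_free_read_hits_source_gene(self, refset, marker_index):
        gene = refset.db.family("nifD")[0]
        read = _read(gene.nt_sequence[30:180])
        a = classify.assign_protein_marker(read, marker_index)
        assert a.gene_id == gene.gene_id
        assert a.identity == pytest.approx(1.0)
        assert a.score >= 50

    def test_reverse_strand_read_hits_source_gene(self, refset, marker_index):
        gene = refset.db.family("nifK")[0]
        read = _read(revcomp(gene.nt_sequence[60:210]))
        a = classify.assign_protein_marker(read, marker_index)
        assert a.gene_id == gene.gene_id

    def test_random_reads_stay_unassigned(self, marker_index):
        rng = np.random.default_rng(1)
        nt = np.frombuffer(b"ACGT", dtype=np.uint8)
        hits = 0
        for i in range(10_000):
            seq = nt[rng.integers(0, 4, 150)].tobytes().decode()
            if classify.assign_protein_marker(_read(seq, f"rnd{i}"),
                                              marker_index).assigned:
                hits += 1
        assert hits / 10_000 < 0.001

    def test_tie_breaks_to_lexicographic_gene(self, refset):
        # two byte-identical nifD genes: the lexicographically smaller wins
        import pandas as pd
        from diazoscope import refdb
        gene = refset.db.family("nifD")[0]
        contig = gene.nt_sequence + "ACGT" * 10 + gene.nt_sequence
        ann = pd.DataFrame([
            dict(genome_id="G", contig="c", start=1, end=gene.length_nt,
                 strand="+", family="nifD", gene_id="dupB"),
            dict(genome_id="G", contig="c", start=gene.length_nt + 41,
                 end=2 * gene.length_nt + 40, strand="+", family="nifD",
                 gene_id="dupA"),
        ])
        db = refdb.build_db({"G": {"c": contig}}, ann, {"G": ("Bacteria",)})
        a = classify.assign_protein_marker(
            _read(gene.nt_sequence[0:150]), db)
        assert a.gene_id == "dupA"

    def test_heuristic_agrees_with_exhaustive_dp_oracle(self):
        # seeded heuristic vs full dynamic programming on 1,000 marker reads
        cfg = synthesize.ReferenceConfig(rp_genes=("rplB",))
        rs = synthesize.simulate_reference_set(3, seed=33, config=cfg)
        index = classify.MarkerIndex(rs.db)
        genes = index.protein_genes
        rng = np.random.default_rng(34)
        agree = 0
        n = 1000
        for i in range(n):
            g = genes[rng.integers(0, len(genes))]
            if g.length_nt < 160:
                agree += 1
                continue
            start = int(rng.integers(0, g.length_nt - 150))
            seq = g.nt_sequence[start:start + 150]
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            err = rng.random(arr.size) < 0.03
            nts = np.frombuffer(b"ACGT", dtype=np.uint8)
            arr[err] = nts[rng.integers(0, 4, int(err.sum()))]
            seq = arr.tobytes().decode()
            if rng.random() < 0.5:
                seq = revcomp(seq)
            mine = classify.assign_protein_marker(_read(seq), index).gene_id
            oracle, score = oracles.sw_best_gene(seq, genes,
                                                 classify._frame_strings)
            bits = (0.267 * score - math.log(0.041)) / math.log(2)
            oracle = oracle if bits >= 50 else None
            agree += mine == oracle
        assert agree / n >= 0.99


class TestAssign16S:
    def test_exact_substring_and_strand_symmetry(self, refset, marker_index):
        gene = refset.db.family("SSU16S")[0]
        frag = gene.nt_sequence[100:250]
        assert classify.assign_16s(_read(frag), marker_index) == gene.lineage
        assert classify.assign_16s(_read(revcomp(frag)), marker_index) \
            == gene.lineage

    def test_low_identity_unassigned(self, marker_index):
        rng = np.random.default_rng(2)
        nt = np.frombuffer(b"ACGT", dtype=np.uint8)
        seq = nt[rng.integers(0, 4, 150)].tobytes().decode()
        assert classify.assign_16s(_read(seq), marker_index, id_min=0.8) is None


class TestProfileSample:
    META = dict(sample_id="S", env="paddy", latitude=0.0, longitude=0.0)

    def test_missing_metadata_rejected(self, marker_index):
        with pytest.raises(MetadataError):
            classify.profile_sample([], marker_index,
                                    dict(sample_id="S", env="paddy"))

    def test_single_taxon_counts_only_its_genes(self, refset, marker_index):
        taxon = next(t for t in refset.taxa if t.kind == "diazotroph")
        s = synthesize.SyntheticSample(
            sample_id="S", environment="paddy", latitude=0, longitude=0,
            abundances={taxon.taxon_id: 1.0}, n_reads=5_000)
        reads = synthesize.simulate_reads(s, refset, error_rate=0.0, seed=5)
        prof = classify.profile_sample(reads, marker_index, self.META)
        for fam, genes in prof.counts.items():
            for gid in genes:
                if gid != "_ssu":
                    assert gid.startswith(taxon.taxon_id)

    def test_no_16s_reads_leaves_composition_empty(self, marker_index):
        prof = classify.profile_sample([], marker_index, self.META)
        assert prof.ssu_composition == {}
        with pytest.raises(InputError):
            classify.summarize_composition(prof, "phylum")

    def test_counts_match_length_weighted_expectation(self, refset,
                                                      marker_index,
                                                      paddy_reads,
                                                      paddy_profile):
        sample, reads = paddy_reads
        read_len = 150
        # a read is countable when it overlaps the gene by roughly the
        # identity-threshold fraction of its length
        eff = lambda L: L + read_len - 2 * int(0.6 * read_len)
        total_w = sum(sample.abundances[t.taxon_id]
                      * refset.genome_length(t.taxon_id) for t in refset.taxa)
        for fam in ("nifD", "nifK", "nifH", "rplB"):
            expected = 0.0
            for t in refset.taxa:
                genes = [g for g in refset.db.genome(t.taxon_id)
                         if g.family == fam]
                L_t = refset.genome_length(t.taxon_id)
                w_t = sample.abundances[t.taxon_id] * L_t / total_w
                expected += sum(w_t * eff(g.length_nt) / L_t for g in genes)
            expected *= len(reads)
            sd = math.sqrt(expected)
            obs = paddy_profile.family_count(fam)
            assert abs(obs - expected) <= 3 * sd + 0.03 * expected

    def test_subsampling_halves_counts(self, marker_index, paddy_reads,
                                       paddy_profile):
        _, reads = paddy_reads
        half = classify.profile_sample(reads[::2], marker_index, self.META)
        for fam in ("nifD", "nifK", "rplB"):
            full_c = paddy_profile.family_count(fam)
            half_c = half.family_count(fam)
            sd = math.sqrt(full_c * 0.25)
            assert abs(half_c - full_c / 2) <= 3 * sd + 2

    def test_batch_route_agrees_with_alignment_route(self, refset,
                                                     marker_index,
                                                     paddy_reads):
        _, reads = paddy_reads
        subset = reads[:700] + reads[10_000:10_300]
        seqs = [r[1] for r in subset]
        batch = classify._classify_batch_protein(seqs, marker_index,
                                                 marker_index.config)
        agree = 0
        for i, r in enumerate(subset):
            mine = classify.assign_protein_marker(r, marker_index).gene_id
            other = batch.get(i, (None,))[0]
            agree += mine == other
        assert agree / len(subset) >= 0.99


class TestComposition:
    def _profile(self, lineage_counts):
        p = classify.SampleProfile(sample_id="S", metadata={})
        p.ssu_lineage_counts = lineage_counts
        return p

    def test_single_taxon(self):
        lin = ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales")
        comp = classify.summarize_composition(self._profile({lin: 7}), "order")
        assert comp == {"Lactobacillales": 1.0}

    def test_three_to_one_split(self):
        a = ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales")
        b = ("Bacteria", "Acidobacteria", "Acidobacteriia", "Acidobacteriales")
        comp = classify.summarize_composition(self._profile({a: 3, b: 1}),
                                              "phylum")
        assert comp == {"Acidobacteria": 0.25, "Firmicutes": 0.75}

    def test_proteobacterial_classes_split_at_phylum(self):
        a = ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "X")
        b = ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Y")
        comp = classify.summarize_composition(self._profile({a: 1, b: 1}),
                                              "phylum")
        assert set(comp) == {"Deltaproteobacteria", "Alphaproteobacteria"}

    def test_unknown_rank_rejected(self):
        with pytest.raises(InputError):
            classify.summarize_composition(
                self._profile({("Bacteria",): 1}), "species")
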