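# Methods

This note documents the models, conventions and numerical choices behind
`diazoscope`, and what the synthetic-data experiments do and do not show
about real soil metagenomes.

## Reference database

Marker genes are extracted from annotated reference genomes. Annotation
coordinates are 1-based inclusive; strand `-` means the CDS is
reverse-complemented before storage and translation. Translation uses the
bacterial genetic code (table 11); a CDS whose length is not divisible by
3 is rejected, and internal stop codons raise a warning and are stripped
(the gene is kept, as truncated pseudogenes still recruit reads).

The ribosomal-protein normalisation set is configurable; the shipped
default is a 15-gene universal single-copy set (`rplA rplB rplC rplD rplE
rplF rplM rplN rpsB rpsC rpsE rpsG rpsH rpsK rpsS`). The exact membership
matters little for the nif:ribosomal ratio as long as the set is fixed
across samples, because the denominator is a per-sample sum over the whole
set.

Diazotroph screening requires all three core genes (*nifH*, *nifD*,
*nifK*) on one genome; archaeal genomes are excluded throughout. GC
content of a marker is computed on the concatenation of all qualifying
copies (16S copies must be ≥ 1000 nt), with ambiguous bases excluded from
numerator and denominator. When a genome carries several *nifH* copies,
the copy nearest to a *nifD/K* annotation on the same contig is taken as
the functional one (ties resolve to the smaller start coordinate); copies
far from any *nifD/K* are the pseudo-*nifH* candidates.

## Read classification

Reads are quality-filtered (defaults: length ≥ 100 nt, mean Phred ≥ 20)
and assigned to protein markers by translated search: all six reading
frames are computed, amino-acid 8-mers shared with the reference seed
candidate genes, and candidates are scored with affine-gap local alignment
(BLOSUM62, gap open −11, extend −1). A read is assigned to the top-scoring
gene when the bit score (Karlin–Altschul conversion, λ = 0.267,
K = 0.041) reaches 50 and the identity reaches 0.6; ties break by higher
identity, then lexicographically smaller gene id. One read receives at
most one marker assignment; 16S assignment (nucleotide best hit on either
strand, identity ≥ 0.8) is attempted only for reads the protein search
left unassigned.

Whole-sample profiling uses a vectorised batch route that seeds
identically but verifies candidates with an edit-distance identity check
(requiring identity ≥ 0.6 over a translated frame and ≥ 25 matching
residues, the identity-equivalent of the 50-bit floor) instead of the full
dynamic program. Agreement between the two routes on mixed synthetic reads
is a tested property (≥ 99%); the per-read alignment route is itself
checked against an independent exhaustive Smith–Waterman implementation.
Batch seeding subsamples read-side k-mer start positions (stride 3 for
proteins, 8 for 16S): a genuine marker read shares tens of consecutive
seeds with its source gene, so subsampling changes cost, not outcome.

## Quantification

RPKM applies the per-gene length correction before summation. The
dominance ratio sums RPKM over the six nitrogenase D/K families and
divides by the summed RPKM of the ribosomal-protein set. Sum versus mean
in numerator and denominator is a fixed package convention; group fold
comparisons are invariant to the choice. A sample with nif signal but no
ribosomal-protein signal has an undefined ratio and is marked unusable
rather than given a sentinel value.

Expected *nifH* uses the mean reference length per family,
`E_H = L̄_H (c_D/L̄_D + c_K/L̄_K)/2`, which reduces to `0.6 × mean(c_D,
c_K)` at exactly 3:5:5. The pseudo-*nifH* threshold "1.5 times or higher"
is inclusive (≥); with `E_H = 0`, any observed *nifH* read flags the
sample.

## Curation

Distances between sampling points use the haversine formula with the IUGG
mean Earth radius (6371.0088 km); at the 1-km decision scale the
divergence from an ellipsoidal geodesic is far below 1%, so no ellipsoid
dependency is taken. "Within 1 km" is strict (<), and clustering is the
transitive closure (single linkage) of that relation. Merging sums counts
and read totals exactly, averages coordinates, refuses mixed environment
categories, and records provenance.

Contamination thresholds default to 0.25 for both the Lactobacillales and
chloroplast 16S fractions; real screening cutoffs are survey-specific, so
both are configuration, not constants. Samples with no 16S reads cannot be
screened and are kept with a warning. The *nifD/K* depth filter uses the
combined count (D + K ≥ 50, inclusive).

## Phylogenetic placement

A translated read is anchored on its best-scoring reference leaf to find
the covered alignment columns, then every leaf is scored on that window so
leaves are compared over the same homologous region. Scores become a mass
distribution over pendant edges through `softmax(β · score)` with β = 0.5
per score point — calibrated so a 10-point score gap concentrates > 0.99
of the mass — and the mass descending through an internal edge is the sum
over its pendant descendants. This is a deliberate simplification of
maximum-likelihood evolutionary placement: it preserves the contract
(normalised per-edge mass, LCA accounting, confidence thresholding) while
remaining fully deterministic and dependency-free.

Annotation takes the deepest taxonomy node whose descendant leaves hold at
least τ = 0.8 of the mass; if no node at or below domain rank qualifies,
the read is discarded as unreliable. Raising τ can only shorten an
annotation. Deltaproteobacterial reads annotated above family rank whose
confident descendant families (≥ 5% of the mass) are all Geobacteraceae or
Anaeromyxobacteraceae form the "possibly Geobacteraceae or
Anaeromyxobacteraceae" category; this requires reference packages that
contain family-unlabelled deltaproteobacterial leaves, which the synthetic
packages provide.

Nearest-isolate mapping is an exhaustive global-alignment scan
(Needleman–Wunsch, BLOSUM62, affine gaps); identity is identities over
alignment columns, and exact inter-partition ties are reported as their
own class.

## Statistics

UniFrac is the normalised weighted variant,
`d = Σ_b l_b |P_A(b) − P_B(b)| / Σ_b l_b (P_A(b) + P_B(b))`, computed on
per-sample placement-mass distributions and averaged element-wise over the
NifD and NifK matrices. Weighted is the appropriate variant because
placements carry read masses; normalisation bounds distances in [0, 1] for
NMDS comparability.

The Brunner–Munzel statistic uses midranks and Welch-type degrees of
freedom; the estimate is `p̂ = P(X<Y) + 0.5 P(X=Y)`. Under complete
separation both rank variances vanish and the t-form is undefined; the
test then reports p̂ ∈ {0, 1} and falls back to a label-permutation
p-value so pairwise letter displays stay total. Letters are maximal
cliques of the not-significantly-different graph, so two groups share a
letter iff their corrected p ≥ α.

PERMANOVA partitions squared distances (`SS_total = Σ_{i<j} d²/n`,
`SS_within = Σ_g Σ_{i<j∈g} d²/n_g`) and permutes labels with the
`(1 + hits)/(1 + n_perm)` convention, so p is never zero; 999 permutations
by default.

NMDS minimises Kruskal stress-1 with pool-adjacent-violators monotone
regression and Guttman-transform updates; the update is rejected if it
would increase stress, so the per-restart stress path is non-increasing.
The first restart starts from classical metric scaling of the
dissimilarities, the rest from seeded random configurations; the best of
4 restarts is returned. Two samples embed exactly (stress 0).

Spearman correlation delegates to the scipy midrank implementation, with
an explicit error for constant vectors.

## Primer mismatch counting

Primer binding sites are explicit column ranges on a reference MSA (the
sites on curated *nifH* alignments are placed by hand, not searched de
novo), so the column count must equal the primer length. Reverse primers
are reverse-complemented before comparison; IUPAC codes match when their
expansions intersect; a template gap counts as a mismatch because a
deleted position cannot anneal.

## Synthetic data: what it emulates, and what it does not

The generator produces taxa in four classes — diazotrophs (nifHDK +
ribosomal proteins + 16S), pseudo-*nifH* genomes (*nifH* without
*nifD/K*), plain bacteria, and contaminants (Lactobacillales; chloroplast
16S) — with lineages drawn from pools that include Geobacteraceae,
Anaeromyxobacteraceae and family-unlabelled Deltaproteobacteria. Marker
lengths honour the ~3:5:5 *nifH*:*nifD*:*nifK* proportion
(900:1500:1500 nt ± 10%); ribosomal proteins are 300–700 nt; 16S is
~1500 nt. Proteins of one family descend from a common ancestor along a
three-level tree (class, family, leaf; substitution fractions 0.40 / 0.25
/ 0.08 per level), so per-family alignments are gap-free and the
generative tree doubles as the placement reference tree. Per-taxon GC
(0.35–0.70) is applied directly to neutral spacer DNA (which makes up
~10× the marker length, so most reads are non-marker, as in real
metagenomes) and through GC-weighted synonymous codon choice in coding
genes.

Communities draw log-normal abundances (σ = 1) within each taxon class and
pin class totals to generative fractions: aerobic diazotroph fraction 0.02
by default, anaerobic = 17.6 × aerobic (the fold contrast between oxygen
classes observed in global soil surveys), pseudo-*nifH* mass 0.01. Within
anaerobic communities, deltaproteobacterial diazotrophs receive a 4×
within-class weight, emulating the Geobacteraceae/Anaeromyxobacteraceae
dominance of anaerobic soils; this is what gives the PERMANOVA and the
16S-vs-*nifD/K* Spearman correlation a real signal to find. Reads are
single-end 150-mers with substitution errors only (default 0.5%), drawn
proportionally to abundance × genome length, with an optional logistic
GC-acceptance bias `σ(−λ(GC − 0.5))` emulating the GC bias of short-read
platforms. Read identifiers embed the source taxon, position and strand as
ground truth.

Passing the recovery experiments therefore shows that the pipeline's
estimators are unbiased and calibrated under this generative model. It
does not show robustness to real-data features the generator omits:
indels and structured error profiles, paired-end artefacts, horizontal
gene transfer, genuinely novel clades absent from the reference, strain
mixtures, or realistic abundance distributions.

## Problem sizes

The fold-recovery check uses 20 + 20 samples at 200,000 reads each
(the reproduction script uses 10 + 10 at 100,000 reads); placement sanity
uses 500 reads; statistical calibration uses 2,000 Brunner–Munzel
replicates and 200 PERMANOVA replicates at 199 permutations; the
end-to-end demo uses 12 sites at 200,000 reads. These sizes make every
binomial tolerance in the tests comfortably wider than the residual model
bias (read-edge effects shorten each gene's countable span by ~30 nt,
~2% of a *nifD*-length gene).

## Known limitations

* The placement mass is score-based, not likelihood-based; confidences are
  comparable within a run but are not posterior probabilities.
* The batch classifier's identity verification slightly truncates the
  countable span of each gene at its edges; counts inherit a ~2% downward
  bias that cancels in all ratio statistics.
* Compact letter displays are exponential in the worst case (maximal
  clique enumeration); with the six environment categories of this domain
  that is irrelevant.
* The Spearman wrapper requires n ≥ 3 and non-constant inputs rather than
  returning NaN.
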