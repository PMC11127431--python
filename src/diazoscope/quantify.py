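"""RPKM normalisation, the nif:ribosomal dominance ratio and pseudo-nifH flags.

The dominance of nitrogen fixers in a metagenome is summarised as

    ratio = RPKM(nifD + nifK + vnfD + vnfK + anfD + anfK)
            / RPKM(single-copy ribosomal proteins)

where RPKM(f) = sum over genes g of family f of
``count_g / (L_g / 1000) / (N / 1e6)`` with L_g the reference gene length
and N the sample's QC-passing read total.  Normalising against single-copy
ribosomal proteins rather than total reads makes the ratio robust to
non-prokaryotic (plant/animal) read fractions.

Because nifH:nifD:nifK reference lengths are roughly 3:5:5, nifH read
counts are expected near (3/5) x mean(nifD, nifK) counts; samples whose
observed nifH count reaches 1.5x that expectation likely carry pseudo-nifH
genes (nifH-like genes on genomes lacking nifD/K) and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

from diazoscope.classify import SampleProfile
from diazoscope.errors import ConfigError, ConsistencyError
from diazoscope.refdb import NITROGENASE_DK, ReferenceDB

PSEUDO_NIFH_FACTOR = 1.5  # "1.5 times or higher", inclusive


@dataclass
class RatioResult:
    sample_id: str
    rpkm: dict[str, float] = field(default_factory=dict)
    nif_rpkm: float = 0.0
    ribo_rpkm: float = 0.0
    ratio: float | None = 0.0          # None when undefined (no rp signal)
    observed_nifh: int = 0
    expected_nifh: float = 0.0
    pseudo_flag: bool = False
    usable: bool = True

    @property
    def pseudo_nifh_factor_observed(self) -> float | None:
        if self.expected_nifh == 0:
            return None
        return self.observed_nifh / self.expected_nifh


def rpkm(counts: dict[str, int], length_table: dict[str, int] | list[tuple[str, int]],
         total_reads: int) -> float:
    """Reads per kilobase of reference sequence per million sample reads.

    ``counts`` maps gene ids of one family to read counts; every counted
    gene must have a length entry.  Per-gene length correction happens
    before summation.
    """
    if total_reads < 1:
        raise ConfigError("total_reads must be >= 1")
    lengths = dict(length_table) if not isinstance(length_table, dict) else length_table
    total = 0.0
    for gene_id, c in counts.items():
        if gene_id not in lengths:
            raise ConsistencyError(f"gene {gene_id!r} has a count but no length")
        total += c / (lengths[gene_id] / 1000.0)
    return total / (total_reads / 1e6)


def expected_nifh(c_nifd: int, c_nifk: int,
                  lengths: tuple[float, float, float] = (900.0, 1500.0, 1500.0)
                  ) -> float:
    """Expected nifH read count given nifD/K counts and mean gene lengths.

    ``lengths`` is (mean nifH, mean nifD, mean nifK) reference length; at
    the canonical 3:5:5 proportion this reduces to 0.6 x mean(c_D, c_K).
    """
    lh, ld, lk = lengths
    if min(lh, ld, lk) <= 0:
        raise ConfigError("mean gene lengths must be positive")
    return lh * (c_nifd / ld + c_nifk / lk) / 2.0


def pseudo_nifh_flag(observed: int, expected: float,
                     factor: float = PSEUDO_NIFH_FACTOR) -> bool:
    """Flag disproportionate nifH: observed >= factor x expected (inclusive).

    With a zero expectation any observed nifH read flags the sample.
    """
    if factor <= 0:
        raise ConfigError("factor must be > 0")
    if expected == 0:
        return observed > 0
    return observed >= factor * expected


def nif_ratio(profile: SampleProfile, db: ReferenceDB) -> RatioResult:
    """Compute the per-sample nitrogenase:ribosomal-protein RPKM ratio.

    A sample with nif signal but zero ribosomal-protein RPKM has no defined
    ratio and is flagged unusable.
    """
    lengths = {g.gene_id: g.length_nt for g in db.genes.values()}
    n = max(1, profile.total_reads_qc)
    result = RatioResult(sample_id=profile.sample_id)
    for fam in sorted(set(NITROGENASE_DK) | set(db.rp_genes) | {"nifH"}):
        counts = profile.counts.get(fam, {})
        result.rpkm[fam] = rpkm(counts, lengths, n) if counts else 0.0
    result.nif_rpkm = sum(result.rpkm[f] for f in NITROGENASE_DK)
    result.ribo_rpkm = sum(result.rpkm[f] for f in db.rp_genes)

    if result.ribo_rpkm == 0:
        if result.nif_rpkm > 0:
            result.ratio = None
            result.usable = False
        else:
            result.ratio = 0.0
    else:
        result.ratio = result.nif_rpkm / result.ribo_rpkm

    result.observed_nifh = profile.family_count("nifH")
    fam_mean = {}
    for fam in ("nifH", "nifD", "nifK"):
        fam_lengths = [g.length_nt for g in db.family(fam)]
        fam_mean[fam] = mean(fam_lengths) if fam_lengths else 0.0
    if all(fam_mean.values()):
        result.expected_nifh = expected_nifh(
            profile.family_count("nifD"), profile.family_count("nifK"),
            (fam_mean["nifH"], fam_mean["nifD"], fam_mean["nifK"]))
    result.pseudo_flag = pseudo_nifh_flag(result.observed_nifh,
                                          result.expected_nifh)
    return result
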