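"""Sample-level curation.

Three steps precede taxonomic analysis of a metagenome collection:

1. contamination screening — samples whose 16S composition is dominated by
   order Lactobacillales (a hallmark of fermentation/host contamination)
   or by plant-plastid (chloroplast) 16S are excluded;
2. geographic deduplication — samples taken within 1 km of each other
   (technical or field replicates) are clustered by single linkage on
   great-circle distance and merged into one profile;
3. depth filtering — taxonomic composition is only analysed for samples
   with at least 50 nifD/K reads combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from diazoscope.classify import SampleProfile
from diazoscope.errors import ConfigError, CoordinateError, MergeConflictError

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


@dataclass
class CurationConfig:
    max_lactobacillales_frac: float = 0.25
    max_chloroplast_frac: float = 0.25
    cluster_radius_km: float = 1.0
    min_nifdk_reads: int = 50
    earth_radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        for name in ("max_lactobacillales_frac", "max_chloroplast_frac",
                     "cluster_radius_km", "min_nifdk_reads"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not math.isfinite(self.earth_radius_km):
            raise ConfigError("earth_radius_km must be finite")


@dataclass
class ExclusionRecord:
    sample_id: str
    reason: str
    fraction: float


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float,
                 radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between two points in decimal degrees."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise CoordinateError(f"latitude {lat} out of range")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise CoordinateError(f"longitude {lon} out of range")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(a)))


def _contaminant_fractions(profile: SampleProfile) -> tuple[float, float]:
    total = profile.n_ssu_reads
    if total == 0:
        return 0.0, 0.0
    lacto = sum(n for lin, n in profile.ssu_lineage_counts.items()
                if "Lactobacillales" in lin)
    chloro = sum(n for lin, n in profile.ssu_lineage_counts.items()
                 if "Chloroplast" in lin)
    return lacto / total, chloro / total


def contamination_filter(
    profiles: list[SampleProfile],
    config: CurationConfig | None = None,
) -> tuple[list[SampleProfile], list[ExclusionRecord]]:
    """Split profiles into kept and excluded-with-reason.

    Samples without any 16S read cannot be screened; they are kept (the
    exclusion list notes them with reason ``no_16s_warning``).
    """
    config = config or CurationConfig()
    kept, excluded = [], []
    for p in profiles:
        if p.n_ssu_reads == 0:
            kept.append(p)
            excluded.append(ExclusionRecord(p.sample_id, "no_16s_warning", 0.0))
            continue
        lacto, chloro = _contaminant_fractions(p)
        if lacto > config.max_lactobacillales_frac:
            excluded.append(ExclusionRecord(p.sample_id, "lactobacillales", lacto))
        elif chloro > config.max_chloroplast_frac:
            excluded.append(ExclusionRecord(p.sample_id, "chloroplast", chloro))
        else:
            kept.append(p)
    return kept, excluded


def cluster_samples(
    profiles: list[SampleProfile],
    config: CurationConfig | None = None,
) -> dict[str, int]:
    """Single-linkage geographic clustering: connected components of the
    graph with an edge wherever two samples lie strictly within
    ``cluster_radius_km`` of each other.

    Returns ``sample_id -> cluster index``; indices are assigned in sorted
    sample-id order, so the labelling is input-order invariant.
    """
    config = config or CurationConfig()
    ordered = sorted(profiles, key=lambda p: p.sample_id)
    n = len(ordered)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        mi = ordered[i].metadata
        for j in range(i + 1, n):
            mj = ordered[j].metadata
            d = haversine_km(mi["latitude"], mi["longitude"],
                             mj["latitude"], mj["longitude"],
                             config.earth_radius_km)
            if d < config.cluster_radius_km:
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    out = {}
    for i, p in enumerate(ordered):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        out[p.sample_id] = roots[r]
    return out


def merge_cluster(members: list[SampleProfile]) -> SampleProfile:
    """Merge co-located profiles into one: counts and totals are summed,
    coordinates become the centroid, provenance is retained.

    Members must share one environment category.
    """
    if not members:
        raise MergeConflictError("cannot merge an empty cluster")
    members = sorted(members, key=lambda p: p.sample_id)
    envs = {p.metadata["env"] for p in members}
    if len(envs) > 1:
        raise MergeConflictError(
            f"mixed environment categories in cluster: {sorted(envs)}")
    if len(members) == 1:
        return members[0]
    first = members[0]
    merged = SampleProfile(
        sample_id=first.sample_id,
        metadata=dict(first.metadata),
        total_reads_qc=sum(p.total_reads_qc for p in members),
        provenance=[sid for p in members for sid in p.provenance],
    )
    merged.metadata["latitude"] = sum(p.metadata["latitude"] for p in members) / len(members)
    merged.metadata["longitude"] = sum(p.metadata["longitude"] for p in members) / len(members)
    for p in members:
        for fam, genes in p.counts.items():
            dst = merged.counts.setdefault(fam, {})
            for gid, c in genes.items():
                dst[gid] = dst.get(gid, 0) + c
        for lin, c in p.ssu_lineage_counts.items():
            merged.ssu_lineage_counts[lin] = merged.ssu_lineage_counts.get(lin, 0) + c
        for fam, fam_reads in p.marker_reads.items():
            merged.marker_reads.setdefault(fam, []).extend(fam_reads)
    return merged


def merge_clusters(profiles: list[SampleProfile],
                   assignment: dict[str, int]) -> list[SampleProfile]:
    """Apply :func:`merge_cluster` to every cluster of an assignment."""
    groups: dict[int, list[SampleProfile]] = {}
    for p in profiles:
        groups.setdefault(assignment[p.sample_id], []).append(p)
    return [merge_cluster(groups[c]) for c in sorted(groups)]


def min_nifdk_filter(profiles: list[SampleProfile],
                     config: CurationConfig | None = None) -> list[SampleProfile]:
    """Keep samples with combined nifD + nifK counts >= the threshold."""
    config = config or CurationConfig()
    return [p for p in profiles if p.nifdk_count >= config.min_nifdk_reads]
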