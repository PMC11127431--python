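"""End-to-end orchestration on synthetic metagenome bundles.

Stages: simulate (reference set, communities, reads, coordinates) ->
classify -> quantify -> curate (contamination, geographic clustering and
merging, nifD/K depth filter) -> place -> beta-diversity and group
statistics.  The manifest records the root seed and the sample-count
funnel across curation stages.

All randomness flows from one root seed; a rerun with the same
configuration reproduces every number exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from diazoscope import betastats, classify, curate, place, quantify, refdb, synthesize
from diazoscope.errors import DiazoscopeError
from diazoscope.synthesize import AEROBIC_ENVS, ANAEROBIC_ENVS

PLACEMENT_MARKERS = ("nifD", "nifK")


def _child_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + 7919 * k + 1) % (2**31 - 1)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_taxa: int = 24
    n_sites: int = 6
    replicates_per_site: int = 1
    jitter_km: float = 0.4
    environments: tuple[str, ...] = ("cropland", "forest", "grassland",
                                     "paddy", "sediment", "tundra")
    contaminated_sites: int = 0          # first k sites get heavy contamination
    n_reads: int = 200_000
    read_len: int = 150
    error_rate: float = 0.005
    gc_bias_lambda: float = 0.0
    reference: synthesize.ReferenceConfig = field(
        default_factory=synthesize.ReferenceConfig)
    community: synthesize.CommunityConfig = field(
        default_factory=synthesize.CommunityConfig)
    classify: classify.ClassifyConfig = field(
        default_factory=classify.ClassifyConfig)
    curation: curate.CurationConfig = field(default_factory=curate.CurationConfig)
    beta: float = 0.5
    tau: float = 0.8
    n_permutations: int = 999
    nmds_restarts: int = 4
    place_max_reads_per_marker: int = 150

    @staticmethod
    def oxygen_class(env: str) -> str:
        if env in ANAEROBIC_ENVS:
            return "anaerobic"
        if env in AEROBIC_ENVS:
            return "aerobic"
        raise DiazoscopeError(f"unknown environment {env!r}")


@dataclass
class PipelineResult:
    config: PipelineConfig
    refset: synthesize.SyntheticReferenceSet
    samples: list[synthesize.SyntheticSample]
    profiles: list[classify.SampleProfile]
    excluded: list[curate.ExclusionRecord]
    merged: list[classify.SampleProfile]
    ratios: list[quantify.RatioResult]
    deep: list[classify.SampleProfile]          # >= min nifD/K reads
    placements: dict[str, dict[str, list[place.Placement]]]  # marker -> sample -> reads
    family_fractions: dict[str, dict[str, float]]
    distance: "betastats.DistanceMatrix | None"
    nmds: "betastats.NMDSResult | None"
    permanova: "betastats.PermanovaResult | None"
    bm_letters: dict[str, str] | None
    bm_results: dict | None
    spearman_rho: float | None
    spearman_p: float | None
    manifest: dict


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DiazoscopeError as exc:
                raise DiazoscopeError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def best_frame_peptide(seq: str, min_len: int = 20) -> str | None:
    """Longest stop-free translated segment across the six reading frames."""
    best = ""
    for aa in classify._frame_strings(seq):
        for seg in aa.split("*"):
            if len(seg) > len(best):
                best = seg
    return best if len(best) >= min_len else None


@_stage("simulate")
def _simulate(config: PipelineConfig):
    refset = synthesize.simulate_reference_set(
        config.n_taxa, _child_seed(config.seed, 1), config.reference)
    meta = synthesize.simulate_geo_metadata(
        config.n_sites, config.replicates_per_site, config.jitter_km,
        _child_seed(config.seed, 2), environments=list(config.environments))
    samples, reads = [], {}
    for si, site in enumerate(sorted(meta["site"].unique())):
        rows = meta[meta["site"] == site]
        env = rows["env"].iloc[0]
        params = config.community
        if si < config.contaminated_sites:
            params = synthesize.CommunityConfig(**{
                **asdict(config.community), "contaminant_fraction": 0.5})
        community = synthesize.simulate_community(
            refset.taxa, env, params, _child_seed(config.seed, 100 + si),
            sample_id=site)
        for ri, row in enumerate(rows.itertuples()):
            sample = synthesize.SyntheticSample(
                sample_id=row.sample_id, environment=env,
                latitude=row.latitude, longitude=row.longitude,
                abundances=community.abundances, n_reads=config.n_reads,
                truth=community.truth)
            samples.append(sample)
            reads[sample.sample_id] = synthesize.simulate_reads(
                sample, refset, read_len=config.read_len,
                error_rate=config.error_rate,
                gc_bias_lambda=config.gc_bias_lambda,
                seed=_child_seed(config.seed, 10_000 + 100 * si + ri))
    return refset, samples, reads


@_stage("classify")
def _classify(config, refset, samples, reads):
    index = classify.MarkerIndex(refset.db, config.classify)
    profiles = []
    for s in samples:
        profiles.append(classify.profile_sample(
            reads[s.sample_id], index,
            dict(sample_id=s.sample_id, env=s.environment,
                 latitude=s.latitude, longitude=s.longitude),
            config.classify,
            collect_families=PLACEMENT_MARKERS,
        ))
    return profiles


@_stage("place")
def _place(config, refset, deep_profiles, marker_reads):
    placements: dict[str, dict[str, list[place.Placement]]] = {}
    refpkgs = {m: place.RefPackage.from_reference_set(refset, m)
               for m in PLACEMENT_MARKERS}
    for marker in PLACEMENT_MARKERS:
        placements[marker] = {}
        for p in deep_profiles:
            reads = marker_reads.get((p.sample_id, marker), [])
            reads = reads[: config.place_max_reads_per_marker]
            placed = []
            for rid, seq in reads:
                pep = best_frame_peptide(seq)
                if pep is None:
                    continue
                try:
                    placed.append(place.place_and_annotate(
                        pep, refpkgs[marker], beta=config.beta,
                        tau=config.tau, read_id=rid))
                except DiazoscopeError:
                    continue
            placements[marker][p.sample_id] = placed
    return refpkgs, placements


def _delta_fraction_16s(profile: classify.SampleProfile) -> float | None:
    if profile.n_ssu_reads == 0:
        return None
    comp = classify.summarize_composition(profile, "class")
    return comp.get("Deltaproteobacteria", 0.0)


def _delta_fraction_placements(placed: list[place.Placement]) -> float | None:
    usable = [p for p in placed if p.annotation is not None]
    if not usable:
        return None
    hits = sum(1 for p in usable if "Deltaproteobacteria" in p.annotation)
    return hits / len(usable)


def run_end_to_end(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic-bundle analysis and assemble the manifest."""
    refset, samples, reads = _simulate(config)
    profiles = _classify(config, refset, samples, reads)

    kept, excluded = curate.contamination_filter(profiles, config.curation)
    hard_excluded = {e.sample_id for e in excluded
                     if e.reason != "no_16s_warning"}
    post_contamination = [p for p in kept if p.sample_id not in hard_excluded]

    assignment = curate.cluster_samples(post_contamination, config.curation)
    merged = curate.merge_clusters(post_contamination, assignment)
    ratios = [quantify.nif_ratio(p, refset.db) for p in merged]
    deep = curate.min_nifdk_filter(merged, config.curation)

    merged_reads = {(p.sample_id, marker): p.marker_reads.get(marker, [])
                    for p in deep for marker in PLACEMENT_MARKERS}
    refpkgs, placements = _place(config, refset, deep, merged_reads)

    family_fractions = {}
    for p in deep:
        pooled = [pl for marker in PLACEMENT_MARKERS
                  for pl in placements[marker].get(p.sample_id, [])]
        family_fractions[p.sample_id] = place.family_composition(pooled)

    distance = nmds_res = perma = None
    if len(deep) >= 3:
        per_marker = {}
        for marker in PLACEMENT_MARKERS:
            masses = {p.sample_id: betastats.aggregate_placements(
                        placements[marker][p.sample_id])
                      for p in deep if placements[marker].get(p.sample_id)}
            if len(masses) == len(deep):
                per_marker[marker] = betastats.unifrac_matrix(
                    masses, refpkgs[marker].tree)
        if len(per_marker) == len(PLACEMENT_MARKERS):
            distance = betastats.average_marker_distance(
                per_marker["nifD"], per_marker["nifK"])
            nmds_res = betastats.nmds(distance, dims=2,
                                      n_restarts=config.nmds_restarts,
                                      seed=_child_seed(config.seed, 3))
            oxy = [config.oxygen_class(
                       next(p for p in deep if p.sample_id == sid).metadata["env"])
                   for sid in distance.ids]
            if len(set(oxy)) == 2:
                perma = betastats.permanova(distance, oxy,
                                            n_perm=config.n_permutations,
                                            seed=_child_seed(config.seed, 4))

    groups: dict[str, list[float]] = {}
    for p, r in zip(merged, ratios):
        if r.ratio is None:
            continue
        groups.setdefault(config.oxygen_class(p.metadata["env"]), []).append(r.ratio)
    bm_letters = bm_results = None
    if len([g for g in groups.values() if len(g) >= 2]) >= 2:
        bm_letters, bm_results = betastats.pairwise_bm_bonferroni(
            groups, seed=_child_seed(config.seed, 5))

    xs, ys = [], []
    for p in deep:
        x = _delta_fraction_16s(p)
        pooled = [pl for marker in PLACEMENT_MARKERS
                  for pl in placements[marker].get(p.sample_id, [])]
        y = _delta_fraction_placements(pooled)
        if x is not None and y is not None:
            xs.append(x)
            ys.append(y)
    rho = rho_p = None
    if len(xs) >= 3 and np.ptp(xs) > 0 and np.ptp(ys) > 0:
        rho, rho_p = betastats.spearman(xs, ys)

    manifest = {
        "seed": config.seed,
        "funnel": {
            "input": len(profiles),
            "post_contamination": len(post_contamination),
            "post_clustering": len(merged),
            "min_nifdk": len(deep),
        },
        "n_taxa": config.n_taxa,
        "n_reads_per_sample": config.n_reads,
        "markers": list(PLACEMENT_MARKERS),
    }
    return PipelineResult(
        config=config, refset=refset, samples=samples, profiles=profiles,
        excluded=excluded, merged=merged, ratios=ratios, deep=deep,
        placements=placements, family_fractions=family_fractions,
        distance=distance, nmds=nmds_res, permanova=perma,
        bm_letters=bm_letters, bm_results=bm_results,
        spearman_rho=rho, spearman_p=rho_p, manifest=manifest)


def fold_recovery_experiment(
    n_per_group: int = 20,
    n_reads: int = 200_000,
    seed: int = 0,
    n_taxa: int = 24,
    community: synthesize.CommunityConfig | None = None,
) -> dict:
    """Recover the anaerobic:aerobic enrichment of diazotrophs.

    Simulates ``n_per_group`` samples per oxygen class (environments cycled
    within each class), runs classification and RPKM-ratio quantification,
    and compares the estimated fold-difference in mean nif:ribosomal ratio
    against the generative fold, together with the Brunner–Munzel contrast
    of the two groups.
    """
    community = community or synthesize.CommunityConfig(n_reads=n_reads)
    refset = synthesize.simulate_reference_set(
        n_taxa, _child_seed(seed, 11))
    index = classify.MarkerIndex(refset.db)
    env_cycle = {"aerobic": ("cropland", "forest", "grassland"),
                 "anaerobic": ("paddy", "sediment", "tundra")}
    ratios: dict[str, list[float]] = {"aerobic": [], "anaerobic": []}
    for i in range(n_per_group):
        for k, cls in enumerate(("aerobic", "anaerobic")):
            env = env_cycle[cls][i % 3]
            s = synthesize.simulate_community(
                refset.taxa, env, community,
                _child_seed(seed, 300 + 2 * i + k), sample_id=f"{cls}{i}")
            reads = synthesize.simulate_reads(
                s, refset, seed=_child_seed(seed, 700 + 2 * i + k))
            prof = classify.profile_sample(
                reads, index,
                dict(sample_id=s.sample_id, env=env, latitude=0.0,
                     longitude=0.0))
            r = quantify.nif_ratio(prof, refset.db)
            if r.ratio is not None:
                ratios[cls].append(r.ratio)
    fold = (float(np.mean(ratios["anaerobic"]))
            / float(np.mean(ratios["aerobic"])))
    letters, bm = betastats.pairwise_bm_bonferroni(
        ratios, seed=_child_seed(seed, 13))
    return {
        "ratios": ratios,
        "fold_estimate": fold,
        "generative_fold": community.anaerobic_fold,
        "bm_letters": letters,
        "bm_p_adj": bm[("aerobic", "anaerobic")].p_adj,
        "n_samples": sum(len(v) for v in ratios.values()),
    }


def placement_recovery_experiment(
    n_reads: int = 500, seed: int = 0, n_taxa: int = 24, tau: float = 0.8,
) -> dict:
    """Annotate error-free fragments excised from reference leaves.

    Returns the fraction annotated at a rank containing their source leaf
    (placement sanity at the configured LCA confidence ``tau``).
    """
    rng = np.random.default_rng(_child_seed(seed, 17))
    refset = synthesize.simulate_reference_set(n_taxa, _child_seed(seed, 11))
    pkgs = {m: place.RefPackage.from_reference_set(refset, m)
            for m in PLACEMENT_MARKERS}
    ok = annotated = 0
    for i in range(n_reads):
        marker = PLACEMENT_MARKERS[i % 2]
        genes = sorted(g.gene_id for g in refset.db.family(marker))
        gid = genes[rng.integers(0, len(genes))]
        aa = refset.db.genes[gid].aa_sequence
        start = int(rng.integers(0, len(aa) - 50))
        pl = place.place_and_annotate(aa[start:start + 50], pkgs[marker],
                                      tau=tau, read_id=gid)
        if pl.annotation is not None:
            annotated += 1
            lineage = pkgs[marker].taxonomy[gid]
            ok += lineage[:len(pl.annotation)] == pl.annotation
    return {"n_reads": n_reads, "n_annotated": annotated,
            "consistent_fraction": ok / n_reads}


def export_figure_tables(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Tidy tables mirroring the figure-level data layers."""
    env_of = {p.sample_id: p.metadata["env"] for p in result.merged}
    ratio_rows = [
        dict(sample_id=r.sample_id, env=env_of[r.sample_id],
             nif_rpkm=r.nif_rpkm, ribo_rpkm=r.ribo_rpkm,
             ratio=r.ratio if r.ratio is not None else float("nan"),
             observed_nifh=r.observed_nifh, expected_nifh=r.expected_nifh,
             pseudo_flag=r.pseudo_flag)
        for r in result.ratios
    ]
    fam_rows = [
        dict(sample_id=sid, family=fam, fraction=frac)
        for sid, fracs in sorted(result.family_fractions.items())
        for fam, frac in fracs.items()
    ]
    tables = {
        "ratios": pd.DataFrame(ratio_rows),
        "family_composition": pd.DataFrame(
            fam_rows, columns=["sample_id", "family", "fraction"]),
    }
    if result.nmds is not None:
        tables["nmds"] = pd.DataFrame(
            result.nmds.coordinates, columns=["NMDS1", "NMDS2"]
        ).assign(sample_id=result.nmds.ids)[["sample_id", "NMDS1", "NMDS2"]]
    return tables


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in export_figure_tables(result).items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.10g")
    stats = {
        "permanova": asdict(result.permanova) if result.permanova else None,
        "nmds_stress": result.nmds.stress if result.nmds else None,
        "bm_letters": result.bm_letters,
        "spearman_rho": result.spearman_rho,
        "spearman_p": result.spearman_p,
    }
    (out / "stats.json").write_text(json.dumps(stats, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True))
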