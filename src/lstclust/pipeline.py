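"""End-to-end orchestration of the re-clustering pipeline.

Stages: (optional read trimming) -> per-locus subsequence removal and
coarse identity clustering -> best-hit annotation of secondary-locus
representatives -> profile-based tertiary merging (with an optional
nucleotide fallback and contaminant flagging) -> short-transcript filter
-> cutoff estimation from within-tertiary alignments -> all-against-all
alignment and single-linkage final clustering -> representative selection.
Every run writes a manifest with per-stage counters; reruns with identical
inputs and configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import annotate as ann
from .coarse_cluster import Cluster, coarse_cluster_all
from .evaluate import (
    family_size_correlation,
    n50,
    redundancy_metrics,
    single_copy_fragmentation,
)
from .lstc import (
    ClusterThresholds,
    estimate_cutoffs,
    final_cluster,
    length_filter,
    select_representative,
    within_cluster_pairstats,
)
from .pairalign import Scoring, all_vs_all
from .seqio import HitRecord, ReferenceProtein, Transcript, write_clusters, write_fasta
from .synthetic import SimConfig, SimResult, generate, score_vs_truth
from .translated import TranslatedSearch

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "cluster_transcripts", "run_synthetic_study"]

_SCORING_KEYS = {
    "match", "mismatch", "gap_open", "gap_extend", "max_gap",
    "min_aln_len", "min_block_identity", "overlap_denominator",
}


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters with their defaults; unknown keys rejected."""

    coarse_identity: float = 0.85
    min_bitscore: float = 85.0
    max_evalue: float = 1e-20
    contaminant_max_evalue: float = 1e-5
    min_transcript_len: int = 350
    tail_fraction: float = 0.01
    quantile_mode: str = "lower"
    linkage: str = "single"
    min_identity: float | None = None  # manual overrides for the cutoffs
    min_overlap: float | None = None
    prefilter: bool = True
    prefilter_k: int = 12
    rep_tie_tolerance: float = 0.01
    subsequence_scope: str = "per_locus"
    membership: str = "seed"
    seed: int = 0
    scoring: Scoring = Scoring()

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        scoring_data = data.pop("scoring", {})
        unknown = set(data) - {f for f in cls.__dataclass_fields__} | (
            set(scoring_data) - _SCORING_KEYS
        )
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if scoring_data:
            data["scoring"] = Scoring(**scoring_data)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    secondary: list[Cluster]
    tertiary: list[Cluster]
    final: list[Cluster]
    contaminants: list[Cluster]
    thresholds: ClusterThresholds
    representatives: dict[str, str]  # final cluster id -> transcript id
    short_ids: set[str]
    discarded_subsequences: list[str]
    manifest: dict


def _search_hits(search, transcript: Transcript) -> list[HitRecord]:
    return search.hits_for(transcript) if search is not None else []


def cluster_transcripts(
    transcripts: Sequence[Transcript],
    proteins_by_species: Mapping[str, Sequence[ReferenceProtein]] | None,
    config: RunConfig = RunConfig(),
    est_hits: Mapping[str, Sequence[HitRecord]] | None = None,
    contaminant_hits: Mapping[str, Sequence[HitRecord]] | None = None,
    precomputed_hits: Mapping[str, Sequence[HitRecord]] | None = None,
) -> PipelineResult:
    """Run the clustering stages in memory and return all intermediates.

    ``precomputed_hits`` (transcript id -> HSPs) replaces the internal
    translated search when supplied; ``est_hits`` feeds the nucleotide
    fallback and ``contaminant_hits`` the contaminant flagging.
    """
    by_id = {t.id: t for t in transcripts}
    if len(by_id) != len(transcripts):
        raise ValueError("duplicate transcript ids")
    species = sorted(proteins_by_species) if proteins_by_species else []

    search = None
    if precomputed_hits is None and proteins_by_species:
        search = TranslatedSearch(proteins_by_species)

    def hits_for(tid: str) -> list[HitRecord]:
        if precomputed_hits is not None:
            return list(precomputed_hits.get(tid, ()))
        return _search_hits(search, by_id[tid])

    # Stage 1: subsequence removal + coarse clustering (never crosses loci)
    secondary, retained, discarded = coarse_cluster_all(
        transcripts,
        config.coarse_identity,
        config.scoring,
        config.membership,
        config.subsequence_scope,
    )
    retained_ids = {t.id for t in retained}

    # Stage 2: annotation profiles on secondary representatives
    for c in secondary:
        rep = c.representative or max(c.members, key=lambda tid: (by_id[tid].length, tid))
        c.profile = ann.best_hit_profile(
            hits_for(rep), species, config.min_bitscore, config.max_evalue
        )
    tertiary = ann.merge_by_profile(secondary)
    for c in tertiary:
        c.representative = max(c.members, key=lambda tid: (by_id[tid].length, tid))

    # Nucleotide fallback for unannotated clusters
    if est_hits is not None:
        for c in tertiary:
            if c.profile is not None and c.profile.is_annotated:
                continue
            rep = c.representative
            c.profile = ann.nucleotide_fallback_profile(
                est_hits.get(rep, ()), species, config.min_bitscore, config.max_evalue
            )
        tertiary = ann.merge_by_profile(tertiary)
        for c in tertiary:
            c.representative = max(c.members, key=lambda tid: (by_id[tid].length, tid))

    # Contaminant flagging of still-unannotated clusters
    contaminants: list[Cluster] = []
    kept_tertiary: list[Cluster] = []
    for c in tertiary:
        annotated = c.profile is not None and c.profile.is_annotated
        if not annotated and contaminant_hits is not None:
            rep = c.representative
            flags = ann.flag_contaminants(
                contaminant_hits.get(rep, ()), (), config.contaminant_max_evalue
            )
            if flags:
                c.flags |= flags
                contaminants.append(c)
                continue
        kept_tertiary.append(c)

    # Short-transcript filter
    lengths = {t.id: t.length for t in transcripts}
    main_tertiary, short_ids = length_filter(
        kept_tertiary, lengths, config.min_transcript_len
    )

    # Cutoff estimation from within-tertiary alignments
    if config.min_identity is not None and config.min_overlap is not None:
        thresholds = ClusterThresholds(
            config.min_identity, config.min_overlap, config.tail_fraction, 0
        )
    else:
        stats_within = within_cluster_pairstats(main_tertiary, by_id, config.scoring)
        thresholds = estimate_cutoffs(
            stats_within, config.tail_fraction, config.quantile_mode
        )

    # All-against-all + single-linkage final clustering
    main_ids = sorted({tid for c in main_tertiary for tid in c.members})
    pairstats = all_vs_all(
        [by_id[t] for t in main_ids],
        scoring=config.scoring,
        prefilter=config.prefilter,
        prefilter_k=config.prefilter_k,
    )
    flags_by_tid = {
        tid: set(c.flags) for c in main_tertiary for tid in c.members
    }
    finals = final_cluster(main_ids, pairstats, thresholds, flags_by_tid, config.linkage)

    # Profiles and representatives for final clusters
    best_scores: dict[str, float | None] = {}
    for tid in main_ids:
        best = None
        for h in hits_for(tid):
            if h.bitscore > config.min_bitscore and h.evalue <= config.max_evalue:
                best = h.bitscore if best is None else max(best, h.bitscore)
        best_scores[tid] = best
    representatives: dict[str, str] = {}
    for c in finals:
        rep = select_representative(c, best_scores, lengths, config.rep_tie_tolerance)
        c.representative = rep
        representatives[c.id] = rep
        c.profile = ann.best_hit_profile(
            hits_for(rep), species, config.min_bitscore, config.max_evalue
        )

    n_final_annotated = sum(
        1 for c in finals if c.profile is not None and c.profile.is_annotated
    )
    tert_annotated = sum(
        1 for c in kept_tertiary if c.profile is not None and c.profile.is_annotated
    )
    rep_lengths = [lengths[r] for r in representatives.values()]
    manifest = {
        "total_transcripts": len(transcripts),
        "subsequence_discarded": len(discarded),
        "retained": len(retained_ids),
        "secondary_loci": len(secondary),
        "tertiary_loci": len(kept_tertiary),
        "tertiary_annotated": tert_annotated,
        "tertiary_unannotated": len(kept_tertiary) - tert_annotated,
        "contaminant_clusters": len(contaminants),
        "contaminant_transcripts": sum(len(c.members) for c in contaminants),
        "short_transcripts": len(short_ids),
        "final_clusters": len(finals),
        "final_annotated": n_final_annotated,
        "final_unannotated": len(finals) - n_final_annotated,
        "min_identity": thresholds.min_identity,
        "min_overlap": thresholds.min_overlap,
        "threshold_pairs_used": thresholds.n_pairs_used,
        "n50_representative": n50(rep_lengths) if rep_lengths else 0,
    }
    return PipelineResult(
        secondary=secondary,
        tertiary=kept_tertiary,
        final=finals,
        contaminants=contaminants,
        thresholds=thresholds,
        representatives=representatives,
        short_ids=short_ids,
        discarded_subsequences=sorted(t.id for t in discarded),
        manifest=manifest,
    )


def run_pipeline(
    transcripts: Sequence[Transcript],
    proteins_by_species: Mapping[str, Sequence[ReferenceProtein]] | None,
    config: RunConfig,
    outdir: str | Path,
    **hit_sources,
) -> PipelineResult:
    """File-emitting wrapper around :func:`cluster_transcripts`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = cluster_transcripts(transcripts, proteins_by_species, config, **hit_sources)
    by_id = {t.id: t for t in transcripts}
    write_clusters(result.secondary, outdir / "secondary.tsv")
    write_clusters(result.tertiary, outdir / "tertiary.tsv")
    write_clusters(result.final, outdir / "final.tsv")
    if result.contaminants:
        write_clusters(result.contaminants, outdir / "contaminants.tsv")
    write_fasta(
        sorted(
            (f"{cid} {tid}", by_id[tid].sequence)
            for cid, tid in result.representatives.items()
        ),
        outdir / "representatives.fasta",
    )
    with open(outdir / "short_transcripts.txt", "w") as fh:
        for tid in sorted(result.short_ids):
            fh.write(tid + "\n")
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump(asdict(result.thresholds), fh, sort_keys=True, indent=2)
        fh.write("\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, sort_keys=True, indent=2)
        fh.write("\n")
    return result


# ---------------------------------------------------------------------------
# Synthetic study: quantify the improvement over the noisy initial clustering
# ---------------------------------------------------------------------------

def _clustering_metrics(
    clusters: Sequence[Cluster],
    sim: SimResult,
    search: TranslatedSearch,
    config: RunConfig,
) -> dict:
    """Proxy + truth metrics for one clustering of a synthetic instance."""
    by_id = {t.id: t for t in sim.transcripts}
    lengths = {t.id: t.length for t in sim.transcripts}
    ref_species = sorted(sim.proteins)[0]

    def qualifying(h: HitRecord) -> bool:
        return h.bitscore > config.min_bitscore and h.evalue <= config.max_evalue

    best_scores = {}
    for c in clusters:
        for tid in c.members:
            scores = [h.bitscore for h in search.hits_for(by_id[tid]) if qualifying(h)]
            best_scores[tid] = max(scores) if scores else None
    reps = [
        select_representative(c, best_scores, lengths, config.rep_tie_tolerance)
        for c in clusters
    ]

    rep_best_hit: dict[str, str] = {}
    rep_family: dict[str, str] = {}
    protein_family = {
        p.id: p.family_id for p in sim.proteins[ref_species]
    }
    for rep in reps:
        hits = [
            h
            for h in search.hits_for(by_id[rep])
            if h.subject_species == ref_species and qualifying(h)
        ]
        if not hits:
            continue
        best = min(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        rep_best_hit[rep] = best.subject_id
        fam = protein_family.get(best.subject_id)
        if fam:
            rep_family[rep] = fam

    distinct, mean_reps = redundancy_metrics(rep_best_hit)
    family_sizes: dict[str, int] = {}
    for g, fam in sim.truth.gene_to_family.items():
        family_sizes[fam] = family_sizes.get(fam, 0) + 1
    corr = family_size_correlation(rep_family, family_sizes)

    single_copy = [
        sim.truth.gene_to_ortholog[g][ref_species]
        for g, fam in sim.truth.gene_to_family.items()
        if family_sizes[sim.truth.gene_to_family[g]] == 1
    ]
    gene_rep_hits: dict[str, set[str]] = {pid: set() for pid in single_copy}
    for rep in reps:
        for h in search.hits_for(by_id[rep]):
            if qualifying(h) and h.subject_id in gene_rep_hits:
                gene_rep_hits[h.subject_id].add(rep)
    frag = single_copy_fragmentation(single_copy, gene_rep_hits)

    ari, splits, merges = score_vs_truth(
        {tid: c.id for c in clusters for tid in c.members}, sim.truth
    )
    return {
        "ari": ari,
        "splits": splits,
        "merges": merges,
        "distinct_matched": distinct,
        "mean_reps_per_matched": mean_reps,
        "family_correlation": corr,
        "fragmentation": frag,
        "n_clusters": len(clusters),
        "n50_representative": n50([lengths[r] for r in reps]) if reps else 0,
    }


def run_synthetic_study(
    seed: int,
    sim_config: SimConfig | None = None,
    run_config: RunConfig | None = None,
) -> dict:
    """Generate one synthetic instance, run the pipeline, and compare the
    final LSTC partition against the noisy initial (assembler) partition.

    Both partitions are evaluated on the transcript set the pipeline
    retained, so the comparison covers identical elements.
    """
    sim_config = sim_config or SimConfig(seed=seed)
    if sim_config.seed != seed:
        sim_config = SimConfig(**{**asdict(sim_config), "seed": seed})
    run_config = run_config or RunConfig(seed=seed)
    sim = generate(sim_config)
    result = cluster_transcripts(sim.transcripts, sim.proteins, run_config)
    retained = {tid for c in result.final for tid in c.members}
    initial_clusters: dict[str, Cluster] = {}
    for t in sim.transcripts:
        if t.id not in retained:
            continue
        c = initial_clusters.get(t.initial_locus)
        if c is None:
            initial_clusters[t.initial_locus] = Cluster(
                id=t.initial_locus, stage="initial", members={t.id}
            )
        else:
            c.members.add(t.id)
    search = TranslatedSearch(sim.proteins)
    initial = _clustering_metrics(
        sorted(initial_clusters.values(), key=lambda c: c.id), sim, search, run_config
    )
    final = _clustering_metrics(result.final, sim, search, run_config)
    return {
        "seed": seed,
        "n_transcripts": len(sim.transcripts),
        "n_retained": len(retained),
        "n_genes": len(sim.truth.gene_to_family),
        "thresholds": {
            "min_identity": result.thresholds.min_identity,
            "min_overlap": result.thresholds.min_overlap,
        },
        "initial": initial,
        "final": final,
        "manifest": result.manifest,
    }
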