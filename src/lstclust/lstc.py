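"""Final clustering: data-driven cutoffs, single-linkage merging,
representative selection, and the short-transcript filter.

Minimum identity and overlap cutoffs are estimated from the distributions
of within-tertiary-locus pair alignments: the nearest-rank lower
``tail_fraction`` quantile of each distribution, so that all but a
``tail_fraction`` share of genuine within-locus pairs pass each cutoff
marginally.  The final clusters are the connected components of the graph
whose edges are transcript pairs passing both cutoffs (single linkage —
chains of qualifying matches merge).  Representatives of annotated
clusters are the members with the highest translated-search bitscore,
ties within 1% resolved toward the shortest member (penalizing retained
introns); unannotated clusters are represented by their longest member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .coarse_cluster import Cluster
from .pairalign import DEFAULT_SCORING, PairStat, Scoring, align_pair
from .seqio import Transcript

__all__ = [
    "ClusterThresholds",
    "within_cluster_pairstats",
    "estimate_cutoffs",
    "length_filter",
    "final_cluster",
    "select_representative",
]


@dataclass(frozen=True)
class ClusterThresholds:
    min_identity: float
    min_overlap: float
    tail_fraction: float = 0.01
    n_pairs_used: int = 0

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_overlap):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")


def within_cluster_pairstats(
    tertiary: Sequence[Cluster],
    transcripts: Mapping[str, Transcript],
    scoring: Scoring = DEFAULT_SCORING,
) -> list[PairStat]:
    """All qualifying within-cluster pair alignments; cross-cluster pairs excluded."""
    stats: list[PairStat] = []
    for c in sorted(tertiary, key=lambda c: c.id):
        for ia, ib in combinations(sorted(c.members), 2):
            s = align_pair(transcripts[ia], transcripts[ib], scoring)
            if s is not None:
                stats.append(s)
    return stats


def _nearest_rank_lower(values: Sequence[float], q: float) -> float:
    xs = sorted(values)
    k = max(1, math.ceil(q * len(xs)))
    return xs[k - 1]


def estimate_cutoffs(
    stats: Sequence[PairStat], tail_fraction: float = 0.01, mode: str = "lower"
) -> ClusterThresholds:
    """Nearest-rank quantiles of the within-locus identity and overlap
    distributions, estimated independently.

    ``lower`` (default) takes the value below which a ``tail_fraction``
    share of within-locus pairs falls, so 1 - tail_fraction of genuine
    within-locus pairs pass each cutoff.  ``upper`` takes the symmetric
    upper-tail quantile instead.
    """
    if not stats:
        raise ValueError(
            "no within-cluster pair alignments available to estimate cutoffs; "
            "supply min_identity/min_overlap manually"
        )
    if mode not in ("lower", "upper"):
        raise ValueError(f"unknown quantile mode {mode!r}")
    q = tail_fraction if mode == "lower" else 1.0 - tail_fraction
    return ClusterThresholds(
        min_identity=_nearest_rank_lower([s.identity for s in stats], q),
        min_overlap=_nearest_rank_lower([s.overlap for s in stats], q),
        tail_fraction=tail_fraction,
        n_pairs_used=len(stats),
    )


def length_filter(
    clusters: Sequence[Cluster],
    lengths: Mapping[str, int],
    min_len: int = 350,
) -> tuple[list[Cluster], set[str]]:
    """Route transcripts shorter than ``min_len`` to a separate short set.

    Clusters left empty vanish; no transcript is lost.
    """
    short: set[str] = set()
    main: list[Cluster] = []
    for c in clusters:
        keep = {tid for tid in c.members if lengths[tid] >= min_len}
        short |= c.members - keep
        if keep:
            rep = c.representative if c.representative in keep else None
            main.append(
                Cluster(
                    id=c.id,
                    stage=c.stage,
                    members=keep,
                    representative=rep,
                    profile=c.profile,
                    flags=set(c.flags),
                )
            )
    return main, short


def final_cluster(
    transcript_ids: Iterable[str],
    pairstats: Iterable[PairStat],
    thresholds: ClusterThresholds,
    flags_by_transcript: Mapping[str, set[str]] | None = None,
    linkage: str = "single",
) -> list[Cluster]:
    """Connected components of the qualifying-alignment graph.

    With ``linkage='single'`` (default) any chain of qualifying matches
    merges transcripts into one cluster; ``'complete'`` instead requires
    every within-cluster pair to qualify (greedy maximal cliques over the
    same edge set, deterministic order).
    """
    id_set = set(transcript_ids)
    ids = sorted(id_set)
    edges = [
        (s.id_a, s.id_b)
        for s in pairstats
        if s.identity >= thresholds.min_identity
        and s.overlap >= thresholds.min_overlap
        and s.id_a in id_set
        and s.id_b in id_set
    ]
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(edges)
    if linkage == "single":
        raw_groups = [sorted(comp) for comp in nx.connected_components(g)]
    elif linkage == "complete":
        raw_groups = []
        unassigned = set(ids)
        for tid in ids:
            if tid not in unassigned:
                continue
            group = [tid]
            unassigned.discard(tid)
            for other in sorted(unassigned):
                if all(g.has_edge(other, m) for m in group):
                    group.append(other)
                    unassigned.discard(other)
            raw_groups.append(sorted(group))
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    raw_groups.sort(key=lambda grp: grp[0])
    clusters = []
    for i, grp in enumerate(raw_groups):
        flags: set[str] = set()
        if flags_by_transcript:
            for tid in grp:
                flags |= flags_by_transcript.get(tid, set())
        clusters.append(
            Cluster(id=f"LSTC{i + 1:05d}", stage="final", members=set(grp), flags=flags)
        )
    return clusters


def select_representative(
    cluster: Cluster,
    best_bitscores: Mapping[str, float | None],
    lengths: Mapping[str, int],
    tie_tolerance: float = 0.01,
) -> str:
    """Pick the cluster's representative transcript.

    Annotated clusters: the member with the highest qualifying
    translated-search bitscore; members within ``tie_tolerance`` of the top
    score count as ties and the shortest of them wins (then id order).
    Unannotated clusters: the longest member (then id order).
    """
    scored = {
        tid: best_bitscores.get(tid)
        for tid in cluster.members
        if best_bitscores.get(tid) is not None
    }
    if scored:
        top = max(scored.values())
        candidates = [tid for tid, s in scored.items() if s >= top * (1.0 - tie_tolerance)]
        return min(candidates, key=lambda tid: (lengths[tid], tid))
    return min(cluster.members, key=lambda tid: (-lengths[tid], tid))
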