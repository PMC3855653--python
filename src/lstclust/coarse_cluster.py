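"""Coarse identity clustering: split each initial locus into secondary loci.

Transcripts that are perfect subsequences of another transcript (on either
strand) are discarded first.  The remainder of each initial locus is then
clustered with the greedy longest-first incremental scheme: transcripts are
visited longest-first and each joins the first existing cluster whose seed
(its longest, founding member) shows at least ``identity_threshold`` overall
identity to it, otherwise it founds a new cluster.  This reproduces the
semantics of greedy incremental tools such as CD-HIT-EST, including the
guarantee that every member has the required overall identity to its
cluster's longest transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pairalign import DEFAULT_SCORING, Scoring, global_identity
from .seqio import Transcript, revcomp

__all__ = ["Cluster", "remove_subsequences", "coarse_cluster", "coarse_cluster_all"]

STAGES = ("initial", "secondary", "tertiary", "final")


@dataclass
class Cluster:
    """A set of transcript ids at one clustering stage."""

    id: str
    stage: str
    members: set[str]
    representative: str | None = None
    profile: object | None = None  # AnnotationProfile once annotated
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown cluster stage {self.stage!r}")
        if not self.members:
            raise ValueError(f"cluster {self.id!r} has no members")
        if self.representative is not None and self.representative not in self.members:
            raise ValueError(
                f"representative {self.representative!r} not a member of {self.id!r}"
            )


def remove_subsequences(
    transcripts: Sequence[Transcript],
) -> tuple[list[Transcript], list[Transcript]]:
    """Discard transcripts that are exact substrings of another (either strand).

    Among exact duplicates the lexicographically smallest id is retained.
    Retained transcripts keep their input relative order.
    """
    order = sorted(transcripts, key=lambda t: (-t.length, t.id))
    retained: list[Transcript] = []
    discarded_ids: set[str] = set()
    for t in order:
        rc = revcomp(t.sequence)
        contained = any(
            t.sequence in keeper.sequence or rc in keeper.sequence
            for keeper in retained
        )
        if contained:
            discarded_ids.add(t.id)
        else:
            retained.append(t)
    kept = [t for t in transcripts if t.id not in discarded_ids]
    dropped = [t for t in transcripts if t.id in discarded_ids]
    return kept, dropped


def coarse_cluster(
    locus_transcripts: Sequence[Transcript],
    identity_threshold: float = 0.85,
    scoring: Scoring = DEFAULT_SCORING,
    membership: str = "seed",
    locus_id: str | None = None,
) -> list[Cluster]:
    """Greedy longest-first clustering of one initial locus.

    ``membership='seed'`` tests candidates against the founding seed only
    (the cited greedy tools' behaviour); ``'longest_current'`` re-evaluates
    against the longest member at join time.
    """
    if membership not in ("seed", "longest_current"):
        raise ValueError(f"unknown membership mode {membership!r}")
    if not locus_transcripts:
        return []
    locus = locus_id or locus_transcripts[0].initial_locus
    order = sorted(locus_transcripts, key=lambda t: (-t.length, t.id))
    groups: list[list[Transcript]] = []
    for t in order:
        placed = False
        for g in groups:
            ref = g[0] if membership == "seed" else max(g, key=lambda x: (x.length, x.id))
            if global_identity(t, ref, scoring) >= identity_threshold:
                g.append(t)
                placed = True
                break
        if not placed:
            groups.append([t])
    return [
        Cluster(
            id=f"{locus}.S{i + 1}",
            stage="secondary",
            members={t.id for t in g},
            representative=g[0].id,  # longest member, ties broken by id
        )
        for i, g in enumerate(groups)
    ]


def coarse_cluster_all(
    transcripts: Sequence[Transcript],
    identity_threshold: float = 0.85,
    scoring: Scoring = DEFAULT_SCORING,
    membership: str = "seed",
    subsequence_scope: str = "per_locus",
) -> tuple[list[Cluster], list[Transcript], list[Transcript]]:
    """Per-locus subsequence removal followed by coarse clustering.

    Returns (secondary clusters, retained transcripts, discarded transcripts).
    Clustering never crosses initial-locus boundaries.
    """
    if subsequence_scope not in ("per_locus", "global"):
        raise ValueError(f"unknown subsequence scope {subsequence_scope!r}")
    by_locus: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_locus.setdefault(t.initial_locus, []).append(t)
    if subsequence_scope == "global":
        retained_all, discarded_all = remove_subsequences(list(transcripts))
        retained_by_locus: dict[str, list[Transcript]] = {}
        for t in retained_all:
            retained_by_locus.setdefault(t.initial_locus, []).append(t)
    else:
        retained_all, discarded_all = [], []
        retained_by_locus = {}
        for locus in sorted(by_locus):
            kept, dropped = remove_subsequences(by_locus[locus])
            retained_by_locus[locus] = kept
            retained_all.extend(kept)
            discarded_all.extend(dropped)
    clusters: list[Cluster] = []
    for locus in sorted(retained_by_locus):
        clusters.extend(
            coarse_cluster(
                retained_by_locus[locus], identity_threshold, scoring, membership, locus
            )
        )
    return clusters, retained_all, discarded_all
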