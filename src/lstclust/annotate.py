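"""Best-hit annotation profiles, profile-based merging, contaminant flags.

The longest transcript of each secondary locus is searched against the
reference peptides of every annotation species.  Per species, the best
qualifying hit (bitscore strictly over 85, e-value at most 1e-20) fills the
corresponding profile slot.  Secondary loci with identical, non-empty
profiles are merged into tertiary loci — this reconnects discontiguous
fragments of the same gene that the coarse stage split.  Loci still
unannotated at the protein level may repeat the procedure with nucleotide
(EST/cDNA) hits; protein- and nucleotide-sourced profiles are never
compared to one another.  Unannotated loci whose representatives hit
contaminant collections (non-plant, tRNA/rRNA) at e-value <= 1e-5 are
flagged and set aside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .coarse_cluster import Cluster
from .seqio import HitRecord

__all__ = [
    "AnnotationProfile",
    "best_hit_profile",
    "merge_by_profile",
    "nucleotide_fallback_profile",
    "flag_contaminants",
]

DEFAULT_MIN_BITSCORE = 85.0  # strict: a hit must score over this
DEFAULT_MAX_EVALUE = 1e-20  # inclusive
CONTAMINANT_MAX_EVALUE = 1e-5  # inclusive


@dataclass(frozen=True)
class AnnotationProfile:
    """Per-species best-hit subject ids over a declared species list."""

    species: tuple[str, ...]
    slots: tuple[str | None, ...]
    source: str = "protein"  # 'protein' | 'nucleotide' | 'none'

    def __post_init__(self) -> None:
        if len(self.species) != len(self.slots):
            raise ValueError("profile slots must align with the species list")
        if self.source not in ("protein", "nucleotide", "none"):
            raise ValueError(f"unknown profile source {self.source!r}")

    @property
    def is_annotated(self) -> bool:
        return any(s is not None for s in self.slots)

    @classmethod
    def empty(cls, species: Sequence[str]) -> "AnnotationProfile":
        return cls(tuple(species), (None,) * len(species), "none")


def _qualifies(hit: HitRecord, min_bitscore: float, max_evalue: float) -> bool:
    return hit.bitscore > min_bitscore and hit.evalue <= max_evalue


def best_hit_profile(
    rep_hits: Iterable[HitRecord],
    species: Sequence[str],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    source: str = "protein",
) -> AnnotationProfile:
    """Per species, the subject of the best qualifying hit.

    Ties break by bitscore, then lower e-value, then subject id, so the
    profile is independent of input order.
    """
    best: dict[str, HitRecord] = {}
    for h in rep_hits:
        if h.subject_species not in species or not _qualifies(h, min_bitscore, max_evalue):
            continue
        cur = best.get(h.subject_species)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[h.subject_species] = h
    slots = tuple(best[sp].subject_id if sp in best else None for sp in species)
    if not any(s is not None for s in slots):
        return AnnotationProfile(tuple(species), slots, "none")
    return AnnotationProfile(tuple(species), slots, source)


def nucleotide_fallback_profile(
    rep_hits: Iterable[HitRecord],
    species: Sequence[str],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> AnnotationProfile:
    """Best-hit profile from nucleotide (EST/cDNA) searches, same semantics."""
    return best_hit_profile(rep_hits, species, min_bitscore, max_evalue, "nucleotide")


def merge_by_profile(secondary: Sequence[Cluster]) -> list[Cluster]:
    """Union secondary loci with slot-wise identical, non-empty profiles.

    All-empty-profile clusters pass through unmerged.  Grouping is an
    equivalence-class partition, hence transitive and order-independent.
    """
    groups: dict[tuple, list[Cluster]] = {}
    passthrough: list[Cluster] = []
    for c in secondary:
        prof: AnnotationProfile | None = c.profile
        if prof is None or not prof.is_annotated:
            passthrough.append(c)
        else:
            key = (prof.source, prof.species, prof.slots)
            groups.setdefault(key, []).append(c)
    merged: list[Cluster] = []
    for key in groups:
        cs = groups[key]
        members: set[str] = set()
        flags: set[str] = set()
        for c in cs:
            if members & c.members:
                raise ValueError("secondary clusters share members")
            members |= c.members
            flags |= c.flags
        merged.append(
            Cluster(
                id="",
                stage="tertiary",
                members=members,
                profile=cs[0].profile,
                flags=flags,
            )
        )
    for c in passthrough:
        merged.append(
            Cluster(
                id="",
                stage="tertiary",
                members=set(c.members),
                profile=c.profile,
                flags=set(c.flags),
            )
        )
    merged.sort(key=lambda c: min(c.members))
    for i, c in enumerate(merged):
        c.id = f"T{i + 1:05d}"
    return merged


def flag_contaminants(
    rep_hits_nonplant: Iterable[HitRecord],
    rep_hits_trna_rrna: Iterable[HitRecord],
    max_evalue: float = CONTAMINANT_MAX_EVALUE,
) -> set[str]:
    """Contaminant flag for an unannotated cluster's representative hits.

    Any hit against the non-plant or tRNA/rRNA collections with e-value at
    most ``max_evalue`` marks the cluster.
    """
    for h in list(rep_hits_nonplant) + list(rep_hits_trna_rrna):
        if h.evalue <= max_evalue:
            return {"contaminant"}
    return set()
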