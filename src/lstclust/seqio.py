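"""Readers and writers for the formats the pipeline consumes and emits.

Transcripts arrive as FASTA whose headers either follow the Oases locus
dialect (``Locus_<n>_Transcript_<m>`` with an optional ``/<total>`` suffix)
or are tied to initial loci through a two-column TSV map.  Similarity-search
hits arrive as 12-column tabular output (BLAST outfmt-6 dialect).  Internal
coordinates are 0-based half-open; the tabular hit format keeps its native
1-based inclusive convention, converted only at the parser boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "Transcript",
    "ReferenceProtein",
    "HitRecord",
    "revcomp",
    "read_transcripts",
    "read_proteins",
    "read_hits",
    "write_clusters",
    "read_clusters",
    "write_fasta",
]

_OASES_HEADER = re.compile(r"^(Locus_[A-Za-z0-9.]+?)_(Transcript_\d+)(?:/\d+)?$")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(sequence: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """An assembled sequence with its initial (assembler) locus label."""

    id: str
    initial_locus: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceProtein:
    """A reference peptide from one annotation species."""

    id: str
    species: str
    sequence: str
    family_id: str | None = None
    go_terms: tuple[str, ...] = ()


@dataclass(frozen=True)
class HitRecord:
    """One similarity-search alignment (an HSP) in outfmt-6 field order.

    Coordinates are 1-based inclusive, as in the tabular format itself.
    ``q_start > q_end`` (or a negative ``frame``) marks a minus-strand query.
    """

    query_id: str
    subject_id: str
    subject_species: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    frame: int | None = None


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _read_locus_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def parse_oases_header(header: str) -> tuple[str, str] | None:
    """Return (transcript_id, locus_id) for an Oases-dialect header, else None."""
    m = _OASES_HEADER.match(header)
    if m is None:
        return None
    return f"{m.group(1)}_{m.group(2)}", m.group(1)


def read_transcripts(
    fasta_path: str | Path, locus_map: str | Path | None = None
) -> list[Transcript]:
    """Read assembled transcripts and attach their initial locus labels.

    Sequences are uppercased and U is converted to T.  A header that matches
    no dialect and has no map entry is a fatal error, as is a duplicate id.
    """
    mapping = _read_locus_map(locus_map) if locus_map is not None else None
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        header = rec.id
        parsed = parse_oases_header(header)
        if mapping is not None and (header in mapping):
            tid, locus = header, mapping[header]
        elif parsed is not None:
            tid, locus = parsed
        else:
            raise ValueError(
                f"header {header!r} matches no known locus dialect and no "
                "locus map entry was supplied"
            )
        if tid in seen:
            raise ValueError(f"duplicate transcript id {tid!r}")
        seen.add(tid)
        out.append(Transcript(tid, locus, _normalize(str(rec.seq))))
    return out


def read_proteins(
    fasta_path: str | Path,
    species: str,
    family_map: str | Path | None = None,
    go_map: str | Path | None = None,
) -> list[ReferenceProtein]:
    """Read one species' reference peptides, with optional family/GO tables."""
    families = _read_locus_map(family_map) if family_map else {}
    gos: dict[str, tuple[str, ...]] = {}
    if go_map:
        for pid, terms in _read_locus_map(go_map).items():
            gos[pid] = tuple(terms.split(","))
    out = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {species}")
        seen.add(rec.id)
        out.append(
            ReferenceProtein(
                rec.id,
                species,
                str(rec.seq).upper(),
                families.get(rec.id),
                gos.get(rec.id, ()),
            )
        )
    return out


def read_hits(tsv_path: str | Path, species: str) -> list[HitRecord]:
    """Parse 12-column tabular search output, attaching the subject species."""
    out: list[HitRecord] = []
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(
                    f"{tsv_path}: line {lineno}: expected >= 12 tab-separated "
                    f"fields, got {len(f)}"
                )
            out.append(
                HitRecord(
                    query_id=f[0],
                    subject_id=f[1],
                    subject_species=species,
                    percent_identity=float(f[2]),
                    aln_length=int(f[3]),
                    mismatches=int(f[4]),
                    gap_opens=int(f[5]),
                    q_start=int(f[6]),
                    q_end=int(f[7]),
                    s_start=int(f[8]),
                    s_end=int(f[9]),
                    evalue=float(f[10]),
                    bitscore=float(f[11]),
                    frame=int(f[12]) if len(f) > 12 and f[12] not in ("", ".") else None,
                )
            )
    return out


def write_hits(hits: Sequence[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fields = [
                h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                str(h.aln_length), str(h.mismatches), str(h.gap_opens),
                str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
            ]
            if h.frame is not None:
                fields.append(str(h.frame))
            fh.write("\t".join(fields) + "\n")


_CLUSTER_COLUMNS = ("cluster_id", "stage", "transcript_id", "is_representative", "flags")


def write_clusters(
    clusters: Sequence,
    out_path: str | Path,
    transcripts: Mapping[str, Transcript] | None = None,
) -> None:
    """Write a cluster partition as TSV, plus per-cluster FASTA when sequences
    are available.

    Ordering is deterministic (cluster_id, then transcript_id) so identical
    inputs produce byte-identical files.  A transcript appearing in two
    clusters is a fatal error.
    """
    out_path = Path(out_path)
    seen: dict[str, str] = {}
    for c in clusters:
        for tid in c.members:
            if tid in seen:
                raise ValueError(
                    f"transcript {tid!r} appears in clusters {seen[tid]!r} and {c.id!r}"
                )
            seen[tid] = c.id
    rows = []
    for c in sorted(clusters, key=lambda c: c.id):
        flags = ";".join(sorted(c.flags)) if c.flags else "-"
        for tid in sorted(c.members):
            rep = "1" if tid == c.representative else "0"
            rows.append((c.id, c.stage, tid, rep, flags))
    with open(out_path, "w") as fh:
        fh.write("\t".join(_CLUSTER_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    if transcripts is not None:
        fasta_dir = out_path.parent / (out_path.stem + "_fasta")
        fasta_dir.mkdir(exist_ok=True)
        for c in sorted(clusters, key=lambda c: c.id):
            with open(fasta_dir / f"{c.id}.fasta", "w") as fh:
                for tid in sorted(c.members):
                    fh.write(f">{tid}\n{transcripts[tid].sequence}\n")


def read_clusters(tsv_path: str | Path) -> list:
    """Re-read a cluster TSV written by :func:`write_clusters`."""
    from .coarse_cluster import Cluster  # runtime import avoids a cycle

    rows: dict[str, dict] = {}
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CLUSTER_COLUMNS:
            raise ValueError(f"{tsv_path}: unexpected cluster TSV header")
        for line in fh:
            cid, stage, tid, rep, flags = line.rstrip("\n").split("\t")
            entry = rows.setdefault(
                cid,
                {
                    "stage": stage,
                    "members": set(),
                    "rep": None,
                    "flags": set() if flags == "-" else set(flags.split(";")),
                },
            )
            entry["members"].add(tid)
            if rep == "1":
                entry["rep"] = tid
    return [
        Cluster(
            id=cid,
            stage=rows[cid]["stage"],
            members=rows[cid]["members"],
            representative=rows[cid]["rep"],
            flags=rows[cid]["flags"],
        )
        for cid in sorted(rows)
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
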