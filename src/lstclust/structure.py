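"""UTR and retained-intron inference from translated-search HSP chains.

Assuming co-linearity of coding sequence between a transcript and its
reference ortholog and conservation of CDS length, the maximum-bitscore
chain of HSPs that is strictly co-linear in both query and subject defines
the coding frame of the transcript:

* 5'/3' UTRs are the transcript spans outside the terminal HSPs, after
  subtracting three nucleotides per unaligned N-/C-terminal amino acid;
* putative retained introns are inter-HSP query gaps in excess of the
  expected coding length (3 nt per subject-side gap amino acid, which is
  allotted adjacent to the upstream HSP); excesses below ``min_intron``
  (default 30 nt) are treated as alignment jitter and not called;
* a transcript is "confidently annotated" when its chained HSPs cover more
  than 75% of the ortholog protein.

Transcripts hit on the minus strand are reverse-complemented before span
arithmetic; all spans are 0-based half-open on the sense orientation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .evaluate import n50
from .seqio import HitRecord, ReferenceProtein, Transcript

__all__ = [
    "StructureAnnotation",
    "CoverageProfile",
    "infer_structure",
    "gc_stats",
    "coverage_fold",
    "aggregate_coverage_fold",
    "n50_excluding_introns",
    "write_structure_bed",
]

Span = tuple[int, int]


@dataclass(frozen=True)
class StructureAnnotation:
    transcript_id: str
    length: int
    utr5: Span  # possibly empty (start == end)
    utr3: Span
    cds_spans: tuple[Span, ...]
    intron_spans: tuple[Span, ...]
    expected_cds_len: int  # 3 x ortholog protein length
    confident: bool
    sense_strand: str = "+"

    @property
    def intron_total(self) -> int:
        return sum(e - s for s, e in self.intron_spans)


@dataclass(frozen=True)
class CoverageProfile:
    transcript_id: str
    depth: tuple[float, ...]  # per-base read depth, sense orientation


@dataclass
class _Hsp:
    q_start: int  # 0-based half-open nt, sense orientation
    q_end: int
    s_start: int  # 0-based half-open aa
    s_end: int
    bitscore: float


def _empty(transcript: Transcript, plen: int, strand: str = "+") -> StructureAnnotation:
    return StructureAnnotation(
        transcript_id=transcript.id,
        length=transcript.length,
        utr5=(0, 0),
        utr3=(transcript.length, transcript.length),
        cds_spans=(),
        intron_spans=(),
        expected_cds_len=3 * plen,
        confident=False,
        sense_strand=strand,
    )


def _to_sense(hsps: Sequence[HitRecord], length: int) -> tuple[list[_Hsp], str]:
    """Orient HSPs; minus-strand hits are mapped onto the reverse complement."""
    plus = [h for h in hsps if h.q_start <= h.q_end and (h.frame is None or h.frame > 0)]
    minus = [h for h in hsps if h not in plus]
    if sum(h.bitscore for h in minus) > sum(h.bitscore for h in plus):
        chosen, strand = minus, "-"
    else:
        chosen, strand = plus, "+"
    out = []
    for h in chosen:
        if strand == "+":
            q0, q1 = h.q_start - 1, h.q_end
        else:
            # coordinates on the reverse-complemented transcript
            q0, q1 = length - h.q_start, length - h.q_end + 1
        out.append(_Hsp(q0, q1, h.s_start - 1, h.s_end, h.bitscore))
    return out, strand


def _best_chain(hsps: list[_Hsp]) -> list[_Hsp]:
    """Maximum-bitscore subset strictly co-linear in query and subject.

    Small overlaps (<= 2 aa / 6 nt) are tolerated during selection and
    clipped from the downstream HSP afterwards.
    """
    order = sorted(hsps, key=lambda h: (h.s_start, h.q_start))
    n = len(order)
    best = [h.bitscore for h in order]
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            a, b = order[i], order[j]
            if (
                b.s_start > a.s_start
                and b.q_start > a.q_start
                and b.s_start >= a.s_end - 2
                and b.q_start >= a.q_end - 6
            ):
                cand = best[i] + order[j].bitscore
                if cand > best[j]:
                    best[j] = cand
                    prev[j] = i
    if not order:
        return []
    j = int(np.argmax(best))
    chain = []
    while j != -1:
        chain.append(order[j])
        j = prev[j]
    chain.reverse()
    # clip residual overlaps onto the downstream HSP
    clipped: list[_Hsp] = []
    for h in chain:
        if clipped:
            p = clipped[-1]
            trim_aa = max(p.s_end - h.s_start, math.ceil(max(p.q_end - h.q_start, 0) / 3))
            if trim_aa > 0:
                h = _Hsp(h.q_start + 3 * trim_aa, h.q_end, h.s_start + trim_aa, h.s_end, h.bitscore)
                if h.q_start >= h.q_end or h.s_start >= h.s_end:
                    continue
        clipped.append(h)
    return clipped


def infer_structure(
    transcript: Transcript,
    ortholog: ReferenceProtein,
    hsps: Sequence[HitRecord],
    min_intron: int = 30,
    confident_coverage: float = 0.75,
) -> StructureAnnotation:
    """Infer UTR, CDS and retained-intron spans from HSPs against one ortholog."""
    plen = len(ortholog.sequence)
    relevant = [h for h in hsps if h.subject_id == ortholog.id]
    if not relevant:
        return _empty(transcript, plen)
    oriented, strand = _to_sense(relevant, transcript.length)
    chain = _best_chain(oriented)
    if not chain:
        return _empty(transcript, plen, strand)
    L = transcript.length
    first, last = chain[0], chain[-1]
    cds_start = max(0, first.q_start - 3 * first.s_start)
    cds_end = min(L, last.q_end + 3 * (plen - last.s_end))
    introns: list[Span] = []
    for a, b in zip(chain, chain[1:]):
        q_gap = b.q_start - a.q_end
        s_gap = b.s_start - a.s_end
        excess = q_gap - 3 * s_gap
        if excess >= min_intron:
            # coding nucleotides for the subject-side gap sit next to the
            # upstream HSP; the remainder is the putative intron
            introns.append((a.q_end + 3 * s_gap, b.q_start))
    cds_spans: list[Span] = []
    pos = cds_start
    for s, e in introns:
        if s > pos:
            cds_spans.append((pos, s))
        pos = e
    if cds_end > pos:
        cds_spans.append((pos, cds_end))
    coverage = sum(h.s_end - h.s_start for h in chain) / plen if plen else 0.0
    return StructureAnnotation(
        transcript_id=transcript.id,
        length=L,
        utr5=(0, cds_start),
        utr3=(cds_end, L),
        cds_spans=tuple(cds_spans),
        intron_spans=tuple(introns),
        expected_cds_len=3 * plen,
        confident=coverage > confident_coverage,
        sense_strand=strand,
    )


def _gc_fraction(seq: str) -> float:
    counts = {c: seq.count(c) for c in "ACGT"}
    denom = sum(counts.values())
    return (counts["G"] + counts["C"]) / denom if denom else float("nan")


def gc_stats(span_sets: Mapping[str, Sequence[str]]) -> dict[str, float]:
    """Per-class GC means/SDs and a Welch t-test between CDS and intron GC.

    ``span_sets`` maps 'cds' and 'intron' to lists of sequences; GC is the
    per-sequence fraction of G+C over unambiguous bases.
    """
    out: dict[str, float] = {}
    samples: dict[str, np.ndarray] = {}
    for cls in ("cds", "intron"):
        seqs = span_sets.get(cls, ())
        vals = np.array([_gc_fraction(s) for s in seqs], dtype=float)
        vals = vals[~np.isnan(vals)]
        samples[cls] = vals
        if len(vals) == 0:
            warnings.warn(f"no {cls} sequences; GC statistics undefined")
            out[f"mean_gc_{cls}"] = float("nan")
            out[f"sd_gc_{cls}"] = float("nan")
        else:
            out[f"mean_gc_{cls}"] = float(vals.mean())
            out[f"sd_gc_{cls}"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    if len(samples["cds"]) >= 2 and len(samples["intron"]) >= 2:
        out["p_value"] = float(
            sps.ttest_ind(samples["cds"], samples["intron"], equal_var=False).pvalue
        )
    else:
        out["p_value"] = float("nan")
    return out


def _mean_depth(depth: Sequence[float], spans: Sequence[Span]) -> float:
    total = sum(e - s for s, e in spans)
    if total == 0:
        return float("nan")
    acc = sum(sum(depth[s:e]) for s, e in spans)
    return acc / total


def coverage_fold(profile: CoverageProfile, annotation: StructureAnnotation) -> float:
    """Mean read depth over CDS spans divided by mean depth over introns.

    NaN when the transcript has no intron spans or zero intron depth
    (such transcripts are excluded from aggregates).
    """
    if len(profile.depth) != annotation.length:
        raise ValueError("depth vector length does not match the transcript")
    if not annotation.intron_spans or not annotation.cds_spans:
        return float("nan")
    exon = _mean_depth(profile.depth, annotation.cds_spans)
    intron = _mean_depth(profile.depth, annotation.intron_spans)
    if intron == 0:
        return float("nan")
    return exon / intron


def aggregate_coverage_fold(
    profiles: Sequence[CoverageProfile], annotations: Sequence[StructureAnnotation]
) -> dict[str, float]:
    """Exon/intron depth fold across transcripts, both aggregation conventions.

    ``ratio_of_means`` (default reading) divides the pooled mean exon depth
    by the pooled mean intron depth; ``mean_of_ratios`` averages the
    per-transcript folds over transcripts where the fold is defined.
    """
    by_id = {p.transcript_id: p for p in profiles}
    exon_depth = exon_len = intron_depth = intron_len = 0.0
    ratios = []
    for ann in annotations:
        p = by_id.get(ann.transcript_id)
        if p is None or not ann.intron_spans or not ann.cds_spans:
            continue
        e_len = sum(e - s for s, e in ann.cds_spans)
        i_len = sum(e - s for s, e in ann.intron_spans)
        e_sum = sum(sum(p.depth[s:e]) for s, e in ann.cds_spans)
        i_sum = sum(sum(p.depth[s:e]) for s, e in ann.intron_spans)
        exon_depth += e_sum
        exon_len += e_len
        intron_depth += i_sum
        intron_len += i_len
        fold = coverage_fold(p, ann)
        if not math.isnan(fold):
            ratios.append(fold)
    out = {"ratio_of_means": float("nan"), "mean_of_ratios": float("nan")}
    if exon_len and intron_len and intron_depth > 0:
        out["ratio_of_means"] = (exon_depth / exon_len) / (intron_depth / intron_len)
    if ratios:
        out["mean_of_ratios"] = float(np.mean(ratios))
    return out


def n50_excluding_introns(annotations: Sequence[StructureAnnotation]) -> int:
    """N50 over transcript lengths after removing putative retained introns."""
    return n50([a.length - a.intron_total for a in annotations])


def write_structure_bed(
    annotations: Sequence[StructureAnnotation], path: str | Path
) -> None:
    """BED6 spans (utr5/cds/intron/utr3) per transcript, deterministic order."""
    with open(path, "w") as fh:
        for ann in sorted(annotations, key=lambda a: a.transcript_id):
            rows: list[tuple[int, int, str]] = []
            if ann.utr5[1] > ann.utr5[0]:
                rows.append((*ann.utr5, "utr5"))
            rows.extend((*s, "cds") for s in ann.cds_spans)
            rows.extend((*s, "intron") for s in ann.intron_spans)
            if ann.utr3[1] > ann.utr3[0]:
                rows.append((*ann.utr3, "utr3"))
            for start, end, label in sorted(rows):
                fh.write(
                    f"{ann.transcript_id}\t{start}\t{end}\t{label}\t0\t{ann.sense_strand}\n"
                )
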