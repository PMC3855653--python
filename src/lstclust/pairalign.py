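"""Pairwise nucleotide alignment statistics for transcript clustering.

Every clustering stage consumes two numbers per transcript pair:

* ``identity`` — matching columns over aligned columns of the reported
  alignment block, gap columns included (the BLAST ``pident`` convention);
* ``overlap`` — the aligned span on the shorter sequence divided by the
  shorter sequence's length.

The best local alignment (match +1, mismatch -2, gap of length L costs
5 + 2L; a megablast-like regime) is computed on both strands and the
better-scoring strand is reported.  Because a retained intron in one
isoform would otherwise be bridged by one enormous gap — collapsing the
identity of a perfectly good isoform pair — the alignment is split into
blocks wherever an indel run reaches ``max_gap`` (default 30 nt), and the
highest-scoring block provides the pair statistics.  This mirrors how a
local search tool reports separate HSPs around a retained intron.

``global_identity`` implements the greedy-clustering ("overall identity")
convention instead: identical bases anywhere in the unsplit best local
alignment divided by the shorter sequence's length, which deliberately
tolerates differential intron retention.

Ambiguity codes (including N) score as mismatches against everything,
themselves included.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import Transcript, revcomp

__all__ = ["PairStat", "Scoring", "align_pair", "all_vs_all", "global_identity"]

_ALPHABET = "ACGTNRYSWKMBDHV"


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = 5  # affine gap of length L costs gap_open + gap_extend * L
    gap_extend: int = 2
    max_gap: int = 30  # indel run >= this splits the alignment into blocks
    min_aln_len: int = 30  # noise floor: qualifying blocks need this many columns
    min_block_identity: float = 0.5
    overlap_denominator: str = "shorter"  # or "longer"


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class PairStat:
    """Symmetric alignment summary for one transcript pair.

    ``id_a < id_b`` always holds, so ``stat(a, b) == stat(b, a)``.
    """

    id_a: str
    id_b: str
    identity: float
    overlap: float
    aln_length: int
    strand: str  # '+' or '-'


@lru_cache(maxsize=8)
def _aligner(scoring: Scoring) -> PairwiseAligner:
    mat = substitution_matrices.Array(_ALPHABET, dims=2)
    for x in _ALPHABET:
        for y in _ALPHABET:
            mat[x, y] = scoring.match if (x == y and x in "ACGT") else scoring.mismatch
    a = PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = mat
    # Biopython charges open_gap_score for the first gap column and
    # extend_gap_score for each further column: open+extend, extend
    # reproduces the gap_open + gap_extend * L cost model.
    a.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    a.extend_gap_score = -scoring.gap_extend
    return a


def _seq_of(x: Transcript | str) -> str:
    return x.sequence if isinstance(x, Transcript) else x


def _id_of(x: Transcript | str, fallback: str) -> str:
    return x.id if isinstance(x, Transcript) else fallback


@dataclass
class _Block:
    matches: int = 0
    mismatches: int = 0
    gap_cols: int = 0
    score: int = 0
    a_start: int = -1
    a_end: int = -1
    b_start: int = -1
    b_end: int = -1

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_cols

    @property
    def identity(self) -> float:
        cols = self.columns
        return self.matches / cols if cols else 0.0


def _segment_counts(a: str, b: str, qs: int, qe: int, ss: int, se: int) -> tuple[int, int]:
    av = np.frombuffer(a[qs:qe].encode(), dtype=np.uint8)
    bv = np.frombuffer(b[ss:se].encode(), dtype=np.uint8)
    plain = np.isin(av, np.frombuffer(b"ACGT", dtype=np.uint8))
    matches = int(np.count_nonzero((av == bv) & plain))
    return matches, (qe - qs) - matches


def _blocks_of(a: str, b: str, segments, scoring: Scoring) -> list[_Block]:
    """Split an alignment's aligned segments into blocks at long indel runs."""
    blocks: list[_Block] = []
    cur: _Block | None = None
    prev_qe = prev_se = None
    for (qs, qe), (ss, se) in segments:
        if cur is not None:
            dq = qs - prev_qe
            ds = ss - prev_se
            if max(dq, ds) >= scoring.max_gap:
                blocks.append(cur)
                cur = None
            else:
                for gap in (dq, ds):
                    if gap > 0:
                        cur.gap_cols += gap
                        cur.score -= scoring.gap_open + scoring.gap_extend * gap
        if cur is None:
            cur = _Block(a_start=qs, b_start=ss)
        m, mm = _segment_counts(a, b, qs, qe, ss, se)
        cur.matches += m
        cur.mismatches += mm
        cur.score += m * scoring.match + mm * scoring.mismatch
        cur.a_end, cur.b_end = qe, se
        prev_qe, prev_se = qe, se
    if cur is not None:
        blocks.append(cur)
    return blocks


def _best_local(a: str, b: str, scoring: Scoring):
    """Best local alignment of b against a; returns (blocks, total_matches)."""
    aligner = _aligner(scoring)
    alignments = aligner.align(a, b)
    if alignments.score <= 0:
        return [], 0
    aln = alignments[0]
    seg_a, seg_b = aln.aligned
    segments = list(zip(map(tuple, seg_a), map(tuple, seg_b)))
    blocks = _blocks_of(a, b, segments, scoring)
    return blocks, sum(bl.matches for bl in blocks)


@lru_cache(maxsize=100_000)
def _oriented(a: str, b: str, scoring: Scoring):
    """Align b on both strands; return (blocks, matches, strand) of the better."""
    fwd_blocks, fwd_matches = _best_local(a, b, scoring)
    rev_blocks, rev_matches = _best_local(a, revcomp(b), scoring)
    fwd_score = max((bl.score for bl in fwd_blocks), default=-1)
    rev_score = max((bl.score for bl in rev_blocks), default=-1)
    if rev_score > fwd_score:
        return rev_blocks, rev_matches, "-"
    return fwd_blocks, fwd_matches, "+"


def _canonical(a, b) -> tuple[str, str, str, str, bool]:
    """Order a pair by (length, id) so results are symmetric by construction."""
    sa, sb = _seq_of(a), _seq_of(b)
    ia, ib = _id_of(a, "a"), _id_of(b, "b")
    if (len(sa), ia) <= (len(sb), ib):
        return sa, sb, ia, ib, False
    return sb, sa, ib, ia, True


def align_pair(
    a: Transcript | str, b: Transcript | str, scoring: Scoring = DEFAULT_SCORING
) -> PairStat | None:
    """Identity/overlap statistics for one pair, or None below the noise floor.

    The shorter sequence is the alignment target, so ``overlap`` (with the
    default denominator) measures how much of the shorter transcript is
    covered by the reported block.
    """
    short, long_, id_s, id_l, _ = _canonical(a, b)
    blocks, _, strand = _oriented(short, long_, scoring)
    best = None
    for bl in blocks:
        if bl.columns < scoring.min_aln_len or bl.identity < scoring.min_block_identity:
            continue
        if best is None or bl.score > best.score:
            best = bl
    if best is None:
        return None
    if scoring.overlap_denominator == "shorter":
        overlap = (best.a_end - best.a_start) / len(short)
    else:
        overlap = (best.b_end - best.b_start) / len(long_)
    id_a, id_b = sorted((id_s, id_l))
    return PairStat(
        id_a=id_a,
        id_b=id_b,
        identity=best.identity,
        overlap=overlap,
        aln_length=best.columns,
        strand=strand,
    )


def global_identity(
    a: Transcript | str, b: Transcript | str, scoring: Scoring = DEFAULT_SCORING
) -> float:
    """Identical bases in the unsplit best local alignment over the shorter
    sequence's length — the greedy incremental clustering convention.

    Returns 0.0 when the pair has no block above the noise floor.
    """
    short, long_, _, _, _ = _canonical(a, b)
    blocks, matches, _ = _oriented(short, long_, scoring)
    if not any(
        bl.columns >= scoring.min_aln_len and bl.identity >= scoring.min_block_identity
        for bl in blocks
    ):
        return 0.0
    return matches / len(short)


def _canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        out.add(min(kmer, revcomp(kmer)))
    return out


def candidate_pairs(
    transcripts: Sequence[Transcript], k: int = 12
) -> set[tuple[str, str]]:
    """Pairs sharing at least one k-mer on either strand (greedy prefilter)."""
    index: dict[str, list[int]] = {}
    for idx, t in enumerate(transcripts):
        for kmer in _canonical_kmers(t.sequence, k):
            index.setdefault(kmer, []).append(idx)
    pairs: set[tuple[str, str]] = set()
    for idxs in index.values():
        for i, j in combinations(idxs, 2):
            ia, ib = transcripts[i].id, transcripts[j].id
            pairs.add((min(ia, ib), max(ia, ib)))
    return pairs


def all_vs_all(
    transcripts: Sequence[Transcript],
    min_identity: float = 0.0,
    min_overlap: float = 0.0,
    scoring: Scoring = DEFAULT_SCORING,
    prefilter: bool = True,
    prefilter_k: int = 12,
) -> list[PairStat]:
    """All-against-all pair statistics passing both thresholds.

    The shared-k-mer prefilter is an explicit approximation: a qualifying
    pair without any shared k-mer would be skipped.  Disable it where exact
    agreement with an exhaustive oracle is required.
    """
    by_id = {t.id: t for t in transcripts}
    if len(by_id) != len(transcripts):
        raise ValueError("duplicate transcript ids in all_vs_all input")
    if prefilter:
        wanted = candidate_pairs(transcripts, prefilter_k)
    else:
        ids = sorted(by_id)
        wanted = set(combinations(ids, 2))
    out: list[PairStat] = []
    for ia, ib in sorted(wanted):
        stat = align_pair(by_id[ia], by_id[ib], scoring)
        if stat is None:
            continue
        if stat.identity >= min_identity and stat.overlap >= min_overlap:
            out.append(stat)
    return out
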