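"""Minimal internal translated (nucleotide vs protein) similarity search.

A deliberately small, deterministic stand-in for a full translated aligner:
each transcript is translated in all six frames and searched against a
peptide collection with a seeded, ungapped diagonal scan (BLOSUM80).  Shared
5-mer seeds nominate (protein, diagonal) candidates; the best-scoring
ungapped segment on each candidate diagonal is reported as one HSP when its
raw score clears ``min_raw_score``.  Bitscores and e-values use approximate
ungapped BLOSUM80 Karlin-Altschul constants; they are adequate for best-hit
ranking and thresholding, not for publication-grade statistics.

Because the scan is ungapped, a retained intron in the query (which shifts
the reading frame and/or the diagonal) naturally splits a hit into separate
HSPs — exactly the structure the intron/UTR inference consumes.  External
searches supplied as 12-column TSVs can replace this backend everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import HitRecord, ReferenceProtein, Transcript, revcomp

__all__ = ["TranslatedSearch", "six_frame_translations"]

# Approximate ungapped BLOSUM80 Karlin-Altschul parameters.
_LAMBDA = 0.3447
_K = 0.177
_LN2 = math.log(2.0)

_BLOSUM80 = substitution_matrices.load("BLOSUM80")
_AA_ALPHABET = _BLOSUM80.alphabet  # includes 'X' and '*'
_AA_INDEX = {c: i for i, c in enumerate(_AA_ALPHABET)}
_SCORE = np.asarray(_BLOSUM80, dtype=np.int32)

_SEED_K = 5


def _encode(aa: str) -> np.ndarray:
    return np.fromiter(
        (_AA_INDEX.get(c, _AA_INDEX["X"]) for c in aa), dtype=np.int32, count=len(aa)
    )


def bitscore(raw: float) -> float:
    return (_LAMBDA * raw - math.log(_K)) / _LN2


def six_frame_translations(sequence: str) -> list[tuple[int, str]]:
    """(frame, peptide) for frames +1..+3 and -1..-3 (BLAST frame convention)."""
    out = []
    rc = revcomp(sequence)
    for f in (1, 2, 3):
        for strand_seq, sign in ((sequence, 1), (rc, -1)):
            sub = strand_seq[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            out.append((sign * f, str(Seq(sub).translate())))
    order = {1: 0, 2: 1, 3: 2, -1: 3, -2: 4, -3: 5}
    out.sort(key=lambda x: order[x[0]])
    return out


@dataclass
class _Segment:
    q_start: int  # 0-based aa positions within the frame translation
    q_end: int
    s_start: int
    s_end: int
    raw: int
    matches: int


_STOP_CODE = _AA_INDEX["*"]


def _best_subarray(scores: np.ndarray) -> tuple[int, int, int] | None:
    """Maximal-scoring contiguous subarray: (start, end, score)."""
    prefix = np.concatenate(([0], np.cumsum(scores)))
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    end = int(np.argmax(gains))
    raw = int(gains[end])
    if raw <= 0:
        return None
    start = int(np.argmin(prefix[: end + 1]))
    return start, end + 1, raw


def _segments_on_diagonal(qe: np.ndarray, se: np.ndarray, diag: int) -> list[_Segment]:
    """Best ungapped segment per stop-free stretch of one diagonal.

    Query stop codons split the diagonal: a translated segment never spans
    a stop, so an HSP always ends at a reading-frame disruption.
    """
    q0 = max(0, diag)
    s0 = q0 - diag
    n = min(len(qe) - q0, len(se) - s0)
    if n <= 0:
        return []
    qs = qe[q0 : q0 + n]
    scores = _SCORE[qs, se[s0 : s0 + n]]
    stops = np.nonzero(qs == _STOP_CODE)[0]
    bounds = [0, *(int(i) for i in stops), *(int(i) + 1 for i in stops), n]
    bounds = sorted(set(b for b in bounds if 0 <= b <= n))
    out: list[_Segment] = []
    for lo, hi in zip(bounds, bounds[1:]):
        if hi <= lo or (lo < n and qs[lo] == _STOP_CODE):
            continue  # the chunk starting at a stop is the stop itself
        found = _best_subarray(scores[lo:hi])
        if found is None:
            continue
        start, end, raw = found
        a, b = q0 + lo + start, q0 + lo + end
        sa, sb = s0 + lo + start, s0 + lo + end
        matches = int(np.count_nonzero(qe[a:b] == se[sa:sb]))
        out.append(_Segment(a, b, sa, sb, raw, matches))
    return out


class TranslatedSearch:
    """Six-frame ungapped search of transcripts against reference peptides.

    Results are cached per transcript id, so repeated queries (annotation,
    representative selection, evaluation) pay for the search once.
    """

    def __init__(
        self,
        proteins_by_species: Mapping[str, Sequence[ReferenceProtein]],
        min_raw_score: int = 40,
        seed_k: int = _SEED_K,
    ) -> None:
        self.min_raw_score = min_raw_score
        self.seed_k = seed_k
        self.proteins_by_species = {
            sp: list(prots) for sp, prots in sorted(proteins_by_species.items())
        }
        self._proteins: list[ReferenceProtein] = []
        self._encoded: list[np.ndarray] = []
        self._index: dict[str, list[tuple[int, int]]] = {}
        self.db_residues = 0
        for sp, prots in self.proteins_by_species.items():
            for p in prots:
                pi = len(self._proteins)
                self._proteins.append(p)
                self._encoded.append(_encode(p.sequence))
                self.db_residues += len(p.sequence)
                for pos in range(len(p.sequence) - seed_k + 1):
                    kmer = p.sequence[pos : pos + seed_k]
                    self._index.setdefault(kmer, []).append((pi, pos))
        self._cache: dict[str, list[HitRecord]] = {}

    # -- coordinate mapping -------------------------------------------------
    @staticmethod
    def _nt_span(frame: int, q_aa_start: int, q_aa_end: int, length: int) -> tuple[int, int]:
        """1-based inclusive nt coordinates on the original transcript."""
        f = abs(frame)
        start0 = (f - 1) + 3 * q_aa_start
        end0 = (f - 1) + 3 * q_aa_end  # half-open on the reading strand
        if frame > 0:
            return start0 + 1, end0
        # reverse strand: positions counted from the 3' end
        return length - start0, length - end0 + 1

    def _search_protein(
        self, frame: int, pep: str, qe: np.ndarray, pi: int, diags: Iterable[int], length: int
    ) -> list[HitRecord]:
        prot = self._proteins[pi]
        se = self._encoded[pi]
        hits = []
        segments = [
            seg
            for diag in sorted(set(diags))
            for seg in _segments_on_diagonal(qe, se, diag)
            if seg.raw >= self.min_raw_score
        ]
        for seg in segments:
            bits = bitscore(seg.raw)
            evalue = len(pep) * self.db_residues * math.pow(2.0, -bits)
            q1, q2 = self._nt_span(frame, seg.q_start, seg.q_end, length)
            aln_len = seg.q_end - seg.q_start
            hits.append(
                HitRecord(
                    query_id="",
                    subject_id=prot.id,
                    subject_species=prot.species,
                    percent_identity=100.0 * seg.matches / aln_len,
                    aln_length=aln_len,
                    mismatches=aln_len - seg.matches,
                    gap_opens=0,
                    q_start=q1,
                    q_end=q2,
                    s_start=seg.s_start + 1,
                    s_end=seg.s_end,
                    evalue=evalue,
                    bitscore=round(bits, 1),
                    frame=frame,
                )
            )
        return hits

    def hits_for(self, transcript: Transcript) -> list[HitRecord]:
        """All HSPs of one transcript against the whole peptide collection."""
        cached = self._cache.get(transcript.id)
        if cached is not None:
            return cached
        hits: list[HitRecord] = []
        for frame, pep in six_frame_translations(transcript.sequence):
            qe = _encode(pep)
            cands: dict[int, set[int]] = {}
            for qpos in range(len(pep) - self.seed_k + 1):
                kmer = pep[qpos : qpos + self.seed_k]
                for pi, spos in self._index.get(kmer, ()):
                    cands.setdefault(pi, set()).add(qpos - spos)
            for pi in sorted(cands):
                hits.extend(
                    self._search_protein(
                        frame, pep, qe, pi, cands[pi], transcript.length
                    )
                )
        hits = [
            HitRecord(**{**h.__dict__, "query_id": transcript.id}) for h in hits
        ]
        hits.sort(key=lambda h: (-h.bitscore, h.subject_species, h.subject_id, h.q_start))
        self._cache[transcript.id] = hits
        return hits

    def hsps_vs(self, transcript: Transcript, protein_id: str) -> list[HitRecord]:
        """HSPs of one transcript against one named peptide, in query order."""
        hits = [h for h in self.hits_for(transcript) if h.subject_id == protein_id]
        hits.sort(key=lambda h: (min(h.q_start, h.q_end)))
        return hits

    def best_qualifying_bitscore(
        self, transcript: Transcript, min_bitscore: float = 85.0, max_evalue: float = 1e-20
    ) -> float | None:
        best = None
        for h in self.hits_for(transcript):
            if h.bitscore > min_bitscore and h.evalue <= max_evalue:
                best = h.bitscore if best is None else max(best, h.bitscore)
        return best
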