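"""Iterative 3'-end quality trimming of paired sequencing reads.

A read is trimmed one base at a time from the 3' end until the remaining
prefix simultaneously satisfies four conditions: the median Phred score is
at least ``min_median_q``; fewer than ``max_bases_q10`` bases have Q <= 10;
fewer than ``max_bases_q20`` bases have Q <= 20; and the cumulative error
metric is below ``max_cum_error``, where the per-base error probability is
p_i = 10^(-Q_i/10).  The "cumulative error" is not defined unambiguously in
the field; both readings are implemented: the mean per-base error (default;
~Q20 average, consistent with realistic retention on HiSeq-era data) and
the raw sum of error probabilities.  Reads whose longest compliant prefix
is shorter than ``min_length`` are rejected outright.

The median of an even-length list is the lower of the two central values,
which keeps every threshold an integer comparison.
"""

from __future__ import annotations

import gzip
import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = ["QualityRead", "TrimPolicy", "TrimStats", "trim_read", "trim_pairs"]


@dataclass(frozen=True)
class QualityRead:
    id: str
    sequence: str
    quals: tuple[int, ...]
    mate: int = 1

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.quals)} quality values for "
                f"{len(self.sequence)} bases"
            )


@dataclass(frozen=True)
class TrimPolicy:
    min_median_q: int = 25
    max_bases_q10: int = 5  # exclusive bound: count(Q <= 10) must be < this
    max_bases_q20: int = 10  # exclusive bound: count(Q <= 20) must be < this
    max_cum_error: float = 1e-2
    min_length: int = 60
    cum_error_mode: str = "mean_per_base"  # or "sum"

    def __post_init__(self) -> None:
        if self.cum_error_mode not in ("mean_per_base", "sum"):
            raise ValueError(f"unknown cum_error_mode {self.cum_error_mode!r}")


@dataclass
class TrimStats:
    total_pairs: int = 0
    surviving_pairs: int = 0
    orphan_reads: int = 0
    mean_length: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def _prefix_lower_medians(quals: Sequence[int]) -> list[int]:
    """Lower median of every prefix, via the classic two-heap stream."""
    low: list[int] = []  # max-heap (negated); holds the lower half
    high: list[int] = []  # min-heap; holds the upper half
    medians = []
    for q in quals:
        if not low or q <= -low[0]:
            heapq.heappush(low, -q)
        else:
            heapq.heappush(high, q)
        if len(low) > len(high) + 1:
            heapq.heappush(high, -heapq.heappop(low))
        elif len(high) > len(low):
            heapq.heappush(low, -heapq.heappop(high))
        medians.append(-low[0])
    return medians


def trim_read(read: QualityRead, policy: TrimPolicy = TrimPolicy()) -> QualityRead | None:
    """Trim from the 3' end until all policy conditions hold; None = rejected.

    Removing bases only from the 3' end one at a time and stopping at the
    first compliant state returns the longest compliant prefix.
    """
    quals = read.quals
    n = len(quals)
    medians = _prefix_lower_medians(quals)
    # prefix counts and error sums, O(1) per candidate length
    c10 = [0] * (n + 1)
    c20 = [0] * (n + 1)
    perr = [0.0] * (n + 1)
    for i, q in enumerate(quals):
        c10[i + 1] = c10[i] + (q <= 10)
        c20[i + 1] = c20[i] + (q <= 20)
        perr[i + 1] = perr[i] + 10.0 ** (-q / 10.0)
    for length in range(n, 0, -1):
        if medians[length - 1] < policy.min_median_q:
            continue
        if c10[length] >= policy.max_bases_q10:
            continue
        if c20[length] >= policy.max_bases_q20:
            continue
        err = perr[length]
        if policy.cum_error_mode == "mean_per_base":
            err /= length
        if err >= policy.max_cum_error:
            continue
        if length < policy.min_length:
            return None
        if length == n:
            return read
        return QualityRead(read.id, read.sequence[:length], quals[:length], read.mate)
    return None


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(
    path: str | Path, mate: int = 1, phred_offset: int = 33
) -> Iterator[QualityRead]:
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            qual = fh.readline().rstrip("\n")
            yield QualityRead(
                header[1:].split()[0],
                seq.upper(),
                tuple(ord(c) - phred_offset for c in qual),
                mate,
            )


def write_fastq(
    reads: Iterable[QualityRead], path: str | Path, phred_offset: int = 33
) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + phred_offset) for q in r.quals)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def _pair_key(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def trim_pairs(
    fastq1: str | Path,
    fastq2: str | Path,
    policy: TrimPolicy = TrimPolicy(),
    out_prefix: str | Path | None = None,
    phred_offset: int = 33,
) -> tuple[list[tuple[QualityRead, QualityRead]], list[QualityRead], TrimStats]:
    """Trim mate-synchronized FASTQ files.

    A pair survives iff both mates survive; a read whose mate is rejected
    becomes an orphan.  Desynchronized files are fatal at the first
    mismatching id.
    """
    pairs: list[tuple[QualityRead, QualityRead]] = []
    orphans: list[QualityRead] = []
    stats = TrimStats()
    total_len = 0
    n_reads = 0
    it2 = parse_fastq(fastq2, 2, phred_offset)
    for r1 in parse_fastq(fastq1, 1, phred_offset):
        r2 = next(it2, None)
        if r2 is None:
            raise ValueError(f"{fastq2} ended before {fastq1} (at read {r1.id!r})")
        if _pair_key(r1.id) != _pair_key(r2.id):
            raise ValueError(f"desynchronized mate files at {r1.id!r} vs {r2.id!r}")
        stats.total_pairs += 1
        t1 = trim_read(r1, policy)
        t2 = trim_read(r2, policy)
        if t1 is not None and t2 is not None:
            pairs.append((t1, t2))
            stats.surviving_pairs += 1
            total_len += len(t1.sequence) + len(t2.sequence)
            n_reads += 2
        elif t1 is not None:
            orphans.append(t1)
            stats.orphan_reads += 1
            total_len += len(t1.sequence)
            n_reads += 1
        elif t2 is not None:
            orphans.append(t2)
            stats.orphan_reads += 1
            total_len += len(t2.sequence)
            n_reads += 1
    if next(it2, None) is not None:
        raise ValueError(f"{fastq1} ended before {fastq2}")
    stats.mean_length = total_len / n_reads if n_reads else 0.0
    if out_prefix is not None:
        out_prefix = str(out_prefix)
        write_fastq((p[0] for p in pairs), out_prefix + "_1.fastq", phred_offset)
        write_fastq((p[1] for p in pairs), out_prefix + "_2.fastq", phred_offset)
        write_fastq(orphans, out_prefix + "_orphans.fastq", phred_offset)
    return pairs, orphans, stats
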