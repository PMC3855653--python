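"""Independent brute-force oracles used to pin down expected values.

Everything here is written against the definitions, not against the
package internals: a Gotoh affine-gap local aligner with explicit
traceback, a longest-first prefix scan for read trimming, a sort-and-index
quantile, union-find connected components, and closed-form statistics.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from numba import njit

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, 5, 2  # gap of length L costs 5 + 2L

NEG = -(10**9)


def _sub(a: str, b: str) -> int:
    return MATCH if (a == b and a in "ACGT") else MISMATCH


@njit(cache=False)
def _gotoh_fill(av, bv, match, mismatch, open_cost, extend):  # pragma: no cover
    m, n = len(av), len(bv)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - open_cost, E[i, j - 1] - extend)
            F[i, j] = max(H[i - 1, j] - open_cost, F[i - 1, j] - extend)
            if av[i - 1] == bv[j - 1] and av[i - 1] < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] + mismatch
            best = diag
            if E[i, j] > best:
                best = E[i, j]
            if F[i, j] > best:
                best = F[i, j]
            if best < 0:
                best = 0
            H[i, j] = best
    return H, E, F


_ENC = {c: i for i, c in enumerate("ACGT")}


def _encode_dna(s: str) -> np.ndarray:
    return np.array([_ENC.get(c, 4) for c in s], dtype=np.int8)


def sw_local(a: str, b: str):
    """Smith-Waterman/Gotoh local alignment with affine gaps.

    Returns (score, columns) where columns is a list of (i, j) pairs with
    None marking a gap, covering only the aligned (local) region.
    """
    open_cost = GAP_OPEN + GAP_EXTEND
    H, E, F = _gotoh_fill(
        _encode_dna(a), _encode_dna(b), MATCH, MISMATCH, open_cost, GAP_EXTEND
    )
    score = int(H.max())
    if score <= 0:
        return 0, []
    i, j = map(int, np.unravel_index(int(np.argmax(H)), H.shape))
    cols: list[tuple[int | None, int | None]] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + _sub(a[i - 1], b[j - 1])
            if H[i, j] == diag:
                cols.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append((None, j - 1))
            if E[i, j] == H[i, j - 1] - open_cost:
                state = "H"
            j -= 1
        else:
            cols.append((i - 1, None))
            if F[i, j] == H[i - 1, j] - open_cost:
                state = "H"
            i -= 1
    cols.reverse()
    return score, cols


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def split_blocks(cols, a: str, b: str, max_gap: int = 30):
    """Split alignment columns into blocks at indel runs >= max_gap.

    Returns per-block dicts with matches, mismatches, gap columns, spans
    and the block score under the same scoring model.
    """
    blocks = []
    cur = None
    run_char = None
    run_len = 0
    pending: list = []

    def close(block):
        if block and (block["matches"] + block["mismatches"]) > 0:
            blocks.append(block)

    def fresh():
        return {
            "matches": 0, "mismatches": 0, "gaps": 0, "score": 0,
            "a_start": None, "a_end": None, "b_start": None, "b_end": None,
        }

    for i, j in cols:
        if i is None or j is None:
            kind = "a" if i is None else "b"
            if run_char == kind:
                run_len += 1
            else:
                run_char, run_len = kind, 1
            pending.append((i, j))
            continue
        if pending:
            if run_len >= max_gap or cur is None:
                close(cur)
                cur = None
            else:
                gaps_a = sum(1 for x, _ in pending if x is None)
                gaps_b = sum(1 for _, y in pending if y is None)
                cur["gaps"] += len(pending)
                for g in (gaps_a, gaps_b):
                    if g:
                        cur["score"] -= GAP_OPEN + GAP_EXTEND * g
            pending = []
            run_char, run_len = None, 0
        if cur is None:
            cur = fresh()
            cur["a_start"], cur["b_start"] = i, j
        if a[i] == b[j] and a[i] in "ACGT":
            cur["matches"] += 1
            cur["score"] += MATCH
        else:
            cur["mismatches"] += 1
            cur["score"] += MISMATCH
        cur["a_end"], cur["b_end"] = i + 1, j + 1
    close(cur)
    return blocks


def pair_stat_oracle(seq_a: str, seq_b: str, max_gap: int = 30,
                     min_cols: int = 30, min_ident: float = 0.5):
    """(identity, overlap, strand) of the best qualifying block, or None.

    The shorter sequence (ties by the caller's ordering) is the overlap
    denominator; both strands of the longer partner are tried.
    """
    short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    best = None
    for strand, other in (("+", long_), ("-", _revcomp(long_))):
        _, cols = sw_local(short, other)
        for bl in split_blocks(cols, short, other, max_gap):
            ncols = bl["matches"] + bl["mismatches"] + bl["gaps"]
            ident = bl["matches"] / ncols
            if ncols < min_cols or ident < min_ident:
                continue
            key = (bl["score"], strand == "+")
            if best is None or key > best[0]:
                overlap = (bl["a_end"] - bl["a_start"]) / len(short)
                best = (key, ident, overlap, strand)
    if best is None:
        return None
    return best[1], best[2], best[3]


def global_identity_oracle(seq_a: str, seq_b: str) -> float:
    """Matches in the unsplit best local alignment over the shorter length."""
    if pair_stat_oracle(seq_a, seq_b) is None:
        return 0.0
    short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    best = 0
    for other in (long_, _revcomp(long_)):
        score, cols = sw_local(short, other)
        matches = sum(
            1 for i, j in cols
            if i is not None and j is not None and short[i] == other[j] and short[i] in "ACGT"
        )
        scored = (score, matches)
        best = max(best, matches) if score > 0 else best
    return best / len(short)


def union_find_components(ids, edges):
    """Connected components by plain union-find, sorted deterministically."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


def nearest_rank_quantile(values, q: float) -> float:
    """Sort-and-index oracle: the ceil(q*n)-th smallest value."""
    xs = sorted(values)
    k = max(1, math.ceil(q * len(xs)))
    return xs[k - 1]


def longest_compliant_prefix(quals, policy) -> int:
    """Longest-first scan over all prefixes applying the four trim rules."""
    for length in range(len(quals), 0, -1):
        prefix = list(quals[:length])
        med = sorted(prefix)[(length - 1) // 2]  # lower median
        if med < policy.min_median_q:
            continue
        if sum(q <= 10 for q in prefix) >= policy.max_bases_q10:
            continue
        if sum(q <= 20 for q in prefix) >= policy.max_bases_q20:
            continue
        err = sum(10 ** (-q / 10) for q in prefix)
        if policy.cum_error_mode == "mean_per_base":
            err /= length
        if err >= policy.max_cum_error:
            continue
        return length
    return 0


def pearson_closed_form(x, y) -> float:
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def welch_t_closed_form(x, y):
    """Welch two-sample t statistic, df, and two-sided p via scipy's CDF."""
    from scipy.stats import t as tdist

    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def paired_t_closed_form(a, b):
    from scipy.stats import t as tdist

    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    md = sum(d) / n
    sd = math.sqrt(sum((v - md) ** 2 for v in d) / (n - 1))
    t = md / (sd / math.sqrt(n))
    p = 2 * tdist.sf(abs(t), n - 1)
    return t, p


def n50_brute_force(lengths) -> int:
    """Scan all candidate lengths for the largest L meeting the definition."""
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) >= total / 2:
            best = max(best, L)
    return best


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(rng, seq: str, positions) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)
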