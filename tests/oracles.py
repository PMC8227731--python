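"""Independent brute-force reference implementations used as test oracles.

These are deliberately written in the most literal way possible — per-window
loops, per-pair double loops — and share no scoring code with the package.
"""

from __future__ import annotations

import math


def brute_force_info(freq_row) -> float:
    return sum(f * math.log(4.0 * f) for f in freq_row)


def brute_force_score(frequencies, window: str, lo: int, hi: int) -> float:
    """Min–max-normalized information-weighted similarity over positions [lo, hi)."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    cur = mx = mn = 0.0
    for i in range(lo, hi):
        row = frequencies[i]
        info = brute_force_info(row)
        cur += info * (min(row) if window[i] == "N" else row[idx[window[i]]])
        mx += info * max(row)
        mn += info * min(row)
    if mx - mn <= 0:
        return 0.0
    return (cur - mn) / (mx - mn)


def brute_force_core_window(frequencies, width: int = 5) -> tuple[int, int]:
    L = len(frequencies)
    if L <= width:
        return (0, L)
    # leftmost window within 1e-9 of the maximal sum (mathematically distinct
    # window sums differ by far more; this absorbs summation-order noise)
    best_start, best_sum = 0, -1.0
    for s in range(L - width + 1):
        total = sum(brute_force_info(frequencies[i]) for i in range(s, s + width))
        if total > best_sum + 1e-9:
            best_start, best_sum = s, total
    return (best_start, best_start + width)


_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def brute_force_scan(sequence: str, pwms, core_cutoff: float, matrix_cutoff: float):
    """Every (start, strand, pwm) window scored independently.

    Returns a set of (pwm_id, start, end, strand, core6, matrix6) with scores
    rounded to 6 decimals.
    """
    hits = set()
    n = len(sequence)
    for pwm in pwms:
        freqs = [list(row) for row in pwm.frequencies]
        L = len(freqs)
        lo, hi = brute_force_core_window(freqs)
        for strand in "+-":
            seq = sequence if strand == "+" else brute_force_revcomp(sequence)
            for j in range(n - L + 1):
                window = seq[j : j + L]
                mat = brute_force_score(freqs, window, 0, L)
                core = brute_force_score(freqs, window, lo, hi)
                if core >= core_cutoff and mat >= matrix_cutoff:
                    start = j if strand == "+" else n - j - L
                    hits.add(
                        (pwm.id, start, start + L, strand, round(core, 6), round(mat, 6))
                    )
    return hits


def brute_force_pairs(sites, d_min: int, d_max: int):
    """Double loop over all site pairs; edge-gap distance max(start)-min(end).

    ``sites`` are (tf_name, promoter_id, start, end) tuples.  Returns a list
    of (frozenset of the two tf names, promoter_id, distance).
    """
    out = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = sites[i], sites[j]
            if a[1] != b[1] or a[0] == b[0]:
                continue
            d = max(a[2], b[2]) - min(a[3], b[3])
            if d_min <= d <= d_max:
                out.append((frozenset((a[0], b[0])), a[1], d))
    return out


def enumerate_dinucleotide_arrangements(seq: str) -> set[str]:
    """All permutations of ``seq`` with identical dinucleotide counts
    (exhaustive; only for short strings)."""
    from itertools import permutations

    def counts(s):
        c = {}
        for a, b in zip(s, s[1:]):
            c[a + b] = c.get(a + b, 0) + 1
        return c

    target = counts(seq)
    return {"".join(p) for p in permutations(seq) if counts("".join(p)) == target}
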