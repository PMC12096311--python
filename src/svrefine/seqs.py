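"""Low-level nucleotide-string helpers shared across modules.

Everything here operates on plain uppercase strings over {A,C,G,T,N} with
0-based half-open coordinates.
"""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: A run of at least this many consecutive Ns counts as an assembly gap.
DEFAULT_GAP_MIN_N = 10


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and validate a nucleotide string."""
    s = seq.upper()
    if re.search(r"[^ACGTN]", s):
        bad = re.search(r"[^ACGTN]", s).group(0)
        raise ValueError(f"non-nucleotide character {bad!r} in sequence")
    return s


def find_gap_runs(seq: str, gap_min_n: int = DEFAULT_GAP_MIN_N) -> list[tuple[int, int]]:
    """0-based half-open intervals of runs of >= ``gap_min_n`` consecutive Ns."""
    return [
        (m.start(), m.end())
        for m in re.finditer("N{%d,}" % gap_min_n, seq)
    ]


def common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    lo, hi = 0, n
    # binary search on the first mismatch keeps this O(log n) string compares
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if a[:mid] == b[:mid]:
            lo = mid
        else:
            hi = mid - 1
    return lo


def common_suffix_len(a: str, b: str, cap: int | None = None) -> int:
    n = min(len(a), len(b))
    if cap is not None:
        n = min(n, cap)
    lo, hi = 0, n
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if a[len(a) - mid:] == b[len(b) - mid:]:
            lo = mid
        else:
            hi = mid - 1
    return lo


def trim_common(a: str, b: str) -> tuple[int, int]:
    """Lengths (prefix, suffix) shared by ``a`` and ``b``.

    The suffix is capped so that prefix + suffix never exceeds the shorter
    string; the remainder ``a[p:len(a)-s]`` vs ``b[p:len(b)-s]`` is the
    differing block (possibly empty on one side).
    """
    p = common_prefix_len(a, b)
    s = common_suffix_len(a, b, cap=min(len(a), len(b)) - p)
    return p, s


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the overlap of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 for empty intervals."""
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    ov = intervals_overlap(a, b)
    return min(ov / la, ov / lb)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and disjoint."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
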