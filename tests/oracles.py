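"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: per-base
coverage arrays instead of interval sweeps, full enumeration of nested
pairings instead of dynamic programming, and plain all-pairs scans.
"""

from __future__ import annotations

_CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def regions_oracle(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Connected components under >= 1-base overlap, by brute-force BFS.

    Bookended spans (end == start) share no base and stay separate, matching
    the strict reading of "overlapping reads".
    """
    n = len(spans)
    seen = [False] * n
    out = []
    for i in range(n):
        if seen[i]:
            continue
        comp = [i]
        seen[i] = True
        queue = [i]
        while queue:
            a = queue.pop()
            for b in range(n):
                if seen[b]:
                    continue
                if spans[a][0] < spans[b][1] and spans[b][0] < spans[a][1]:
                    seen[b] = True
                    comp.append(b)
                    queue.append(b)
        out.append(
            (min(spans[k][0] for k in comp), max(spans[k][1] for k in comp))
        )
    return sorted(out)


def covered_bases(spans: list[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for s, e in spans:
        out.update(range(s, e))
    return out


def aapd_oracle(
    sense: list[tuple[int, int]], anti: list[tuple[int, int]], strand: str = "+"
) -> float:
    """All-pairs mean displacement of overlapping sense/antisense spans."""
    disps = []
    for ss, se in sense:
        for as_, ae in anti:
            if ss < ae and as_ < se:
                disps.append(abs(ss - as_) if strand == "+" else abs(se - ae))
    return sum(disps) / len(disps) if disps else 0.0


def neighbor_oracle(
    locus: tuple[int, int],
    region_spans: list[tuple[int, int]],
    positive_spans: list[tuple[int, int]],
    half_window: int,
    own_index: int | None = None,
) -> int:
    s, e = locus
    lo, hi = s - half_window, e + half_window
    n = 0
    for i, (gs, ge) in enumerate(region_spans):
        if i == own_index:
            continue
        if ge <= lo or gs >= hi:
            continue
        if any(gs < pe and ps < ge for ps, pe in positive_spans):
            continue
        n += 1
    return n


def max_pairs_exhaustive(seq: str, min_loop: int = 3) -> int:
    """Maximum pair count over ALL nested pairings, by full enumeration."""
    s = seq.upper().replace("U", "T")

    def rec(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in _CANONICAL:
                inner = rec(i + 1, k - 1)
                right = rec(k + 1, j) if k < j else 0
                best = max(best, 1 + inner + right)
        return best

    return rec(0, len(s) - 1) if s else 0
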