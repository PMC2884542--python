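"""RNA secondary structure: folding engines and hairpin extraction.

Two folding engines are provided behind one interface: the production engine
binds ViennaRNA (minimum free energy fold) and a built-in baseline computes a
maximum-base-pair nested structure by dynamic programming over canonical
pairs (A-T, G-C, G-T on the DNA alphabet; N never pairs; minimum loop 3).
The baseline is deterministic: among equal-pair structures it pairs the
leftmost available 5' base with the rightmost admissible partner, resolved
recursively.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GenomeSequence

__all__ = [
    "DotBracketStructure",
    "Hairpin",
    "FoldWindow",
    "select_fold_windows",
    "fold_sequence",
    "fold_baseline",
    "parse_structure",
    "extract_hairpins",
]

MIN_LOOP = 3
DEFAULT_WINDOW_SIZE = 150
DEFAULT_MIN_HAIRPIN_LENGTH = 20
DEFAULT_MERGE_GAP = 8

_CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


@dataclass
class DotBracketStructure:
    seq: str
    structure: str
    pair_table: list[int | None]
    energy: float | None = None

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pair_table) if j is not None and j > i)


@dataclass
class FoldWindow:
    """A genomic window folded on one strand.

    Window coordinates run 5'->3' along the folded strand; ``to_window`` maps
    a genomic half-open span into that frame (and back via ``to_genomic``).
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start

    def to_window(self, gstart: int, gend: int) -> tuple[int, int]:
        if self.strand == "+":
            return gstart - self.start, gend - self.start
        return self.end - gend, self.end - gstart

    def to_genomic(self, wstart: int, wend: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.start + wstart, self.start + wend
        return self.end - wend, self.end - wstart

    def sequence(self, genome) -> str:
        return genome[self.chrom].fetch(self.start, self.end, self.strand)


@dataclass
class Hairpin:
    """A stem-loop parsed from a dot-bracket structure (window coordinates).

    ``hairpin_length`` spans the outermost paired base on the 5p arm to the
    outermost paired base on the 3p arm, inclusive.  Hairpins shorter than the
    minimum are flagged (``too_short``), never silently dropped.
    """

    fivep_arm: tuple[int, int]
    loop: tuple[int, int]
    threep_arm: tuple[int, int]
    n_pairs: int
    hairpin_length: int
    too_short: bool = False
    window_start: int = 0

    @property
    def span(self) -> tuple[int, int]:
        return self.fivep_arm[0], self.threep_arm[1]


def select_fold_windows(
    region, genome: dict[str, GenomeSequence], window_size: int = DEFAULT_WINDOW_SIZE
) -> list[tuple[int, int]]:
    """Up to three candidate fold windows for a read region.

    Region centered in the window; region at the window's 5' end; region at
    the window's 3' end — each clipped to chromosome bounds and deduplicated.
    A region longer than the window is returned as a single window equal to
    its own span.
    """
    chrom_len = len(genome[region.chrom])
    if region.length >= window_size:
        return [(region.start, region.end)]
    mid = (region.start + region.end) // 2
    raw = [
        (mid - window_size // 2, mid - window_size // 2 + window_size),
        (region.start, region.start + window_size),
        (region.end - window_size, region.end),
    ]
    out: list[tuple[int, int]] = []
    for s, e in raw:
        if s < 0:
            s, e = 0, min(window_size, chrom_len)
        if e > chrom_len:
            s, e = max(0, chrom_len - window_size), chrom_len
        if (s, e) not in out:
            out.append((s, e))
    return out


def fold_baseline(seq: str) -> DotBracketStructure:
    """Maximum-base-pair nested fold (Nussinov-style DP), deterministic."""
    n = len(seq)
    s = seq.upper().replace("U", "T")
    # M[i][j]: max pairs in s[i..j] inclusive
    M = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1][j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    cand = 1 + (M[i + 1][k - 1] if k - 1 > i else 0)
                    if k + 1 <= j:
                        cand += M[k + 1][j]
                    if cand > best:
                        best = cand
            M[i][j] = best
    pt: list[int | None] = [None] * n
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if i >= j or M[i][j] == 0:
            continue
        paired = False
        # leftmost base pairs with the rightmost admissible partner
        for k in range(j, i + MIN_LOOP, -1):
            if not _can_pair(s[i], s[k]):
                continue
            cand = 1 + (M[i + 1][k - 1] if k - 1 > i else 0)
            if k + 1 <= j:
                cand += M[k + 1][j]
            if cand == M[i][j]:
                pt[i], pt[k] = k, i
                if k - 1 > i + 1:
                    stack.append((i + 1, k - 1))
                if k + 1 < j + 1 and k + 1 <= j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    structure = "".join(
        "." if p is None else ("(" if p > i else ")") for i, p in enumerate(pt)
    )
    return DotBracketStructure(seq, structure, pt)


def _fold_vienna(seq: str) -> DotBracketStructure:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "ViennaRNA python bindings unavailable; use engine='baseline'"
        ) from exc
    structure, energy = RNA.fold(seq.upper().replace("T", "U"))
    db = parse_structure(seq, structure)
    db.energy = float(energy)
    return db


def fold_sequence(seq: str, engine: str = "auto") -> DotBracketStructure:
    """Fold a sequence with the requested engine.

    ``engine`` is ``"vienna"``, ``"baseline"``, ``"auto"`` (Vienna when its
    bindings import, baseline otherwise) or any callable mapping a sequence to
    a dot-bracket string.
    """
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    if callable(engine):
        return parse_structure(seq, engine(seq))
    if engine == "auto":
        try:
            import RNA  # noqa: F401
            engine = "vienna"
        except ImportError:  # pragma: no cover
            engine = "baseline"
    if engine == "vienna":
        return _fold_vienna(seq)
    if engine == "baseline":
        return fold_baseline(seq)
    raise ValueError(f"unknown folding engine {engine!r}")


def parse_structure(seq: str, structure: str) -> DotBracketStructure:
    """Build a pair table from a Vienna-dialect dot-bracket string."""
    if len(seq) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    pt: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[j], pt[i] = i, j
        elif c != ".":
            raise ValueError(f"unexpected character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return DotBracketStructure(seq, structure, pt)


def _stem_walk(pt: list[int | None], a: int, b: int) -> tuple[int, int]:
    """Extend pair (a, b) outward through nested pairs (bulges allowed),
    stopping at branching."""
    while True:
        p = a - 1
        while p >= 0 and pt[p] is None:
            p -= 1
        if p < 0:
            break
        q = pt[p]
        if q is None or q < a:  # sibling helix to the left
            break
        if any(pt[x] is not None for x in range(b + 1, q)):  # sibling right
            break
        a, b = p, q
    return a, b


def _count_arm_pairs(pt, five: tuple[int, int], three: tuple[int, int]) -> int:
    return sum(
        1
        for i in range(five[0], five[1])
        if pt[i] is not None and three[0] <= pt[i] < three[1]
    )


def extract_hairpins(
    db: DotBracketStructure,
    min_hairpin_length: int = DEFAULT_MIN_HAIRPIN_LENGTH,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[Hairpin]:
    """One hairpin per innermost helix, plus double-loop merging.

    The loop is the unpaired span enclosed by the innermost pair; arms extend
    outward through nested pairs to the outermost pair of the stem.  Two
    adjacent hairpins separated by an unpaired gap of at most ``merge_gap``
    and enclosed by a common outer helix are merged into a single hairpin
    whose loop runs from the first loop's start to the second loop's end.
    """
    pt = db.pair_table
    n = len(pt)
    raw = []  # (outer5, inner5, inner3, outer3)
    for i in range(n):
        j = pt[i]
        if j is None or j <= i:
            continue
        if all(pt[x] is None for x in range(i + 1, j)):
            o5, o3 = _stem_walk(pt, i, j)
            raw.append((o5, i, j, o3))
    raw.sort()

    merged: list[tuple[int, int, int, int]] = []
    k = 0
    while k < len(raw):
        if k + 1 < len(raw):
            o5a, i5a, i3a, o3a = raw[k]
            o5b, i5b, i3b, o3b = raw[k + 1]
            gap = o5b - o3a - 1
            if 0 <= gap <= merge_gap and all(
                pt[x] is None for x in range(o3a + 1, o5b)
            ):
                p = o5a - 1
                while p >= 0 and pt[p] is None:
                    p -= 1
                q = pt[p] if p >= 0 else None
                if q is not None and q > o3b:
                    o5, o3 = _stem_walk(pt, p, q)
                    merged.append((o5, i5a, i3b, o3))
                    k += 2
                    continue
        merged.append(raw[k])
        k += 1

    out = []
    for o5, i5, i3, o3 in merged:
        hp_len = o3 - o5 + 1
        five = (o5, i5 + 1)
        three = (i3, o3 + 1)
        out.append(
            Hairpin(
                fivep_arm=five,
                loop=(i5 + 1, i3),
                threep_arm=three,
                n_pairs=_count_arm_pairs(pt, five, three),
                hairpin_length=hp_len,
                too_short=hp_len < min_hairpin_length,
            )
        )
    return out
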