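"""Degenerate 7-mer mutation-category patterns and categorizations.

A point mutation together with three flanking bases on each side is written
as an 8-character string: positions 1-3 are the 5' flank, position 4 the
original (pyrimidine) base, position 5 the new base, and positions 6-8 the
3' flank.  The universe of valid sequences has 2 x 3 x 4**6 = 24,576
members.  A category is an 8-symbol IUPAC pattern in which every symbol is
a single base, a dinucleotide (two-base) code, or the wildcard N; the
all-wildcard "joker" pattern NNNNNNNN is the unique pattern exempt from the
structural constraints on positions 4 and 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"
BASE_CODE: Mapping[str, int] = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# IUPAC codes of cardinality 1, 2 and 4.  Three-base codes (B, D, H, V) are
# deliberately not part of the pattern language.
IUPAC_TO_BASES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "N": "ACGT",
}
BASES_TO_IUPAC: Mapping[frozenset, str] = {
    frozenset(v): k for k, v in IUPAC_TO_BASES.items()
}

JOKER_TEXT = "NNNNNNNN"
UNIVERSE_SIZE = 24_576


class PatternError(ValueError):
    """Raised for text that is not a valid category pattern."""


def _sets_to_bool(sets: Sequence[frozenset]) -> np.ndarray:
    out = np.zeros((8, 4), dtype=bool)
    for i, s in enumerate(sets):
        for b in s:
            out[i, BASE_CODE[b]] = True
    return out


@dataclass(frozen=True)
class CategoryPattern:
    """An 8-symbol degenerate pattern over the mutation-sequence universe."""

    text: str                       # canonical uppercase IUPAC form
    sets: tuple = field(repr=False)  # 8 frozensets of bases
    is_joker: bool = False

    @property
    def membership(self) -> np.ndarray:
        """(8, 4) boolean base-membership table (A, C, G, T columns)."""
        return _sets_to_bool(self.sets)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.text


def parse_pattern(text: str) -> CategoryPattern:
    """Parse an 8-character IUPAC string into a :class:`CategoryPattern`.

    Non-joker patterns must have a single C or T at position 4 and a
    1- or 2-base set at position 5 disjoint from position 4.
    """
    t = text.upper()
    if len(t) != 8:
        raise PatternError(f"pattern must have 8 symbols, got {len(t)}: {text!r}")
    sets = []
    for i, ch in enumerate(t):
        if ch not in IUPAC_TO_BASES:
            raise PatternError(f"invalid IUPAC symbol {ch!r} at position {i + 1}")
        sets.append(frozenset(IUPAC_TO_BASES[ch]))
    if t == JOKER_TEXT:
        return CategoryPattern(text=t, sets=tuple(sets), is_joker=True)
    ref, alt = sets[3], sets[4]
    if ref not in ({frozenset("C"), frozenset("T")}):
        raise PatternError(f"position 4 must be C or T, got {t[3]!r}")
    if len(alt) > 2:
        raise PatternError("position 5 must be a single base or a dinucleotide")
    if ref & alt:
        raise PatternError(f"position 5 ({t[4]!r}) intersects position 4 ({t[3]!r})")
    return CategoryPattern(text=t, sets=tuple(sets))


def pattern_size(p: CategoryPattern) -> int:
    """Number of valid mutation sequences matching ``p``.

    Counted over the 24,576-sequence universe, so the joker's size is
    24,576 rather than 4**8.  For non-joker patterns this equals the
    product of the per-position set cardinalities.
    """
    if p.is_joker:
        return UNIVERSE_SIZE
    n = 1
    for s in p.sets:
        n *= len(s)
    return n


def pattern_span(p: CategoryPattern) -> int:
    """Inclusive position count from the first to the last non-N symbol."""
    non_n = [i for i, s in enumerate(p.sets) if len(s) < 4]
    if not non_n:
        return 0
    return non_n[-1] - non_n[0] + 1


def pattern_reach(p: CategoryPattern) -> int:
    """Largest flank offset of a non-N symbol from the mutated site.

    A left-flank symbol at position i (1-3) is 4-i away from the original
    base; a right-flank symbol at position j (6-8) is j-5 away from the new
    base; positions 4-5 contribute 0.
    """
    reach = 0
    for i, s in enumerate(p.sets):
        if len(s) == 4:
            continue
        if i < 3:
            reach = max(reach, 3 - i)
        elif i > 4:
            reach = max(reach, i - 4)
    return reach


# ---------------------------------------------------------------------------
# The valid-sequence universe and its integer encoding
# ---------------------------------------------------------------------------

def encode_sequence(seq: str) -> int:
    """Map a valid 8-character mutation sequence to its index in [0, 24576)."""
    codes = [BASE_CODE[c] for c in seq.upper()]
    return encode_codes(*codes)


def encode_codes(l1, l2, l3, ref, alt, r1, r2, r3) -> int:
    if ref not in (1, 3):
        raise ValueError("position 4 must be C or T")
    if alt == ref:
        raise ValueError("position 5 must differ from position 4")
    fl = l1 * 16 + l2 * 4 + l3
    ref_bit = 0 if ref == 1 else 1
    alt_rank = alt - (1 if alt > ref else 0)
    fr = r1 * 16 + r2 * 4 + r3
    return ((fl * 2 + ref_bit) * 3 + alt_rank) * 64 + fr


@lru_cache(maxsize=1)
def universe() -> np.ndarray:
    """(24576, 8) int8 array of base codes for every valid sequence.

    Row order matches :func:`encode_sequence`.
    """
    u = np.empty((UNIVERSE_SIZE, 8), dtype=np.int8)
    idx = 0
    flanks = [(a, b, c) for a in range(4) for b in range(4) for c in range(4)]
    for fl in flanks:
        for ref in (1, 3):  # C, T
            alts = [a for a in range(4) if a != ref]
            for alt in alts:
                for fr in flanks:
                    u[idx, :3] = fl
                    u[idx, 3] = ref
                    u[idx, 4] = alt
                    u[idx, 5:] = fr
                    idx += 1
    assert idx == UNIVERSE_SIZE
    return u


def decode_sequence(idx: int) -> str:
    row = universe()[idx]
    return "".join(BASES[c] for c in row)


def matches(seq, p: CategoryPattern) -> bool:
    """True iff every concrete base of ``seq`` lies in the pattern's sets."""
    s = seq.upper() if isinstance(seq, str) else "".join(BASES[c] for c in seq)
    return all(base in p.sets[i] for i, base in enumerate(s))


def _match_matrix(patterns: Sequence[CategoryPattern]) -> np.ndarray:
    """(P, 24576) boolean matrix: pattern p matches sequence s."""
    u = universe()
    mem = np.stack([p.membership for p in patterns])  # (P, 8, 4)
    m = np.ones((len(patterns), UNIVERSE_SIZE), dtype=bool)
    for pos in range(8):
        m &= mem[:, pos, :][:, u[:, pos]]
    return m


def _match_row(p: CategoryPattern) -> np.ndarray:
    """(24576,) boolean match vector for a single pattern."""
    u = universe()
    mem = p.membership
    m = np.ones(UNIVERSE_SIZE, dtype=bool)
    for pos in range(8):
        m &= mem[pos][u[:, pos]]
    return m


def _pattern_keys(patterns: Sequence[CategoryPattern]) -> np.ndarray:
    """Lexicographic tie-break key (size, span, reach), smaller wins."""
    return np.array(
        [(pattern_size(p) << 6) | (pattern_span(p) << 2) | pattern_reach(p)
         for p in patterns],
        dtype=np.int64,
    )


@dataclass
class AssignmentResult:
    assignment: np.ndarray     # (24576,) int32 category index
    ambiguous: np.ndarray      # (24576,) bool
    tie_counts: np.ndarray     # (P,) int64: ambiguous ties each category joins

    @property
    def conflict_rate(self) -> float:
        return float(self.ambiguous.mean())


def _assign_from_match(m: np.ndarray, keys: np.ndarray,
                       tie_rng: np.random.Generator) -> AssignmentResult:
    sentinel = np.int64(np.iinfo(np.int64).max)
    k = np.where(m, keys[:, None], sentinel)
    best = k.min(axis=0)
    if np.any(best == sentinel):
        raise ValueError("some sequences match no category; include a joker")
    tied = k == best[None, :]
    n_tied = tied.sum(axis=0)
    ambiguous = n_tied > 1
    assignment = np.argmax(tied, axis=0).astype(np.int32)
    amb_cols = np.nonzero(ambiguous)[0]
    tie_counts = np.zeros(m.shape[0], dtype=np.int64)
    if amb_cols.size:
        ta = tied[:, amb_cols]
        tie_counts = ta.sum(axis=1).astype(np.int64)
        # uniformly random tied winner, vectorized over columns
        target = (tie_rng.random(amb_cols.size)
                  * n_tied[amb_cols]).astype(np.int64) + 1
        ranks = np.cumsum(ta, axis=0)
        assignment[amb_cols] = ((ranks == target[None, :]) & ta).argmax(axis=0)
    return AssignmentResult(assignment, ambiguous, tie_counts)


def assign_universe(patterns: Sequence[CategoryPattern],
                    tie_rng: np.random.Generator) -> AssignmentResult:
    """Assign every valid sequence to its best-matching category.

    Among matching patterns the winner minimizes (size, span, reach)
    lexicographically; residual ties are broken uniformly at random from
    ``tie_rng`` and flagged ambiguous.
    """
    return _assign_from_match(_match_matrix(patterns),
                              _pattern_keys(patterns), tie_rng)


def assign_sequence(seq, patterns: Sequence[CategoryPattern],
                    tie_rng: np.random.Generator | None = None):
    """Assign one sequence; returns (category index, ambiguous flag).

    Reference single-sequence path; catalog construction uses the cached
    universe table instead.
    """
    cand = [i for i, p in enumerate(patterns) if matches(seq, p)]
    if not cand:
        raise ValueError(f"{seq} matches no category")
    keys = [(pattern_size(patterns[i]), pattern_span(patterns[i]),
             pattern_reach(patterns[i])) for i in cand]
    best = min(keys)
    tied = [c for c, key in zip(cand, keys) if key == best]
    if len(tied) == 1:
        return tied[0], False
    rng = tie_rng if tie_rng is not None else np.random.default_rng(0)
    return int(rng.choice(tied)), True


# ---------------------------------------------------------------------------
# Categorizations
# ---------------------------------------------------------------------------

class Categorization:
    """An ordered set of category patterns with a cached assignment table.

    Two flavours exist: pattern-based (the usual case, including exactly
    one joker for sampled categorizations) and table-based (the random
    baseline, which has no patterns and maps sequences directly to labels).
    """

    def __init__(self, patterns: Sequence[CategoryPattern] | None = None,
                 name: str = "categorization",
                 table: np.ndarray | None = None,
                 n_categories: int | None = None,
                 tie_seed: int = 0):
        if (patterns is None) == (table is None):
            raise ValueError("provide exactly one of patterns or table")
        self.name = name
        self.tie_seed = tie_seed
        self._result: AssignmentResult | None = None
        if patterns is not None:
            self.patterns = list(patterns)
            self.n_categories = len(self.patterns)
        else:
            table = np.asarray(table, dtype=np.int32)
            if table.shape != (UNIVERSE_SIZE,):
                raise ValueError("table must cover the full sequence universe")
            self.patterns = None
            self.n_categories = int(n_categories or table.max() + 1)
            self._result = AssignmentResult(
                table, np.zeros(UNIVERSE_SIZE, bool),
                np.zeros(self.n_categories, np.int64))

    # -- assignment ---------------------------------------------------------

    def build_assignment_table(self, tie_seed: int | None = None) -> AssignmentResult:
        """Build (and cache) the full 24,576-sequence assignment table."""
        if self._result is None:
            seed = self.tie_seed if tie_seed is None else tie_seed
            self._result = assign_universe(
                self.patterns, np.random.default_rng(seed))
        return self._result

    @property
    def assignment(self) -> np.ndarray:
        return self.build_assignment_table().assignment

    @property
    def conflict_rate(self) -> float:
        return self.build_assignment_table().conflict_rate

    def category_labels(self) -> list[str]:
        if self.patterns is not None:
            return [p.text for p in self.patterns]
        return [f"cat{i:02d}" for i in range(self.n_categories)]

    def invalidate(self) -> None:
        self._result = None

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        if self.patterns is not None:
            payload = {"name": self.name,
                       "patterns": [p.text for p in self.patterns],
                       "seed_info": {"tie_seed": self.tie_seed}}
        else:
            payload = {"name": self.name,
                       "table": self.assignment.tolist(),
                       "n_categories": self.n_categories,
                       "seed_info": {"tie_seed": self.tie_seed}}
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Categorization":
        d = json.loads(text)
        seed = d.get("seed_info", {}).get("tie_seed", 0)
        if "patterns" in d:
            return cls(patterns=[parse_pattern(t) for t in d["patterns"]],
                       name=d.get("name", "categorization"), tie_seed=seed)
        return cls(table=np.array(d["table"], dtype=np.int32),
                   n_categories=d.get("n_categories"),
                   name=d.get("name", "categorization"), tie_seed=seed)

    def export_table_tsv(self, path) -> None:
        labels = self.category_labels()
        res = self.build_assignment_table()
        with open(path, "w") as fh:
            fh.write("sequence\tcategory_index\tcategory_pattern\tambiguous\n")
            for i in range(UNIVERSE_SIZE):
                c = int(res.assignment[i])
                fh.write(f"{decode_sequence(i)}\t{c}\t{labels[c]}\t"
                         f"{int(res.ambiguous[i])}\n")


_SUBSTITUTIONS = [("C", "A"), ("C", "G"), ("C", "T"),
                  ("T", "A"), ("T", "C"), ("T", "G")]


def standard_category_label(pattern_text: str) -> str:
    """COSMIC-style label l[R>A]r for a standard-category pattern."""
    return f"{pattern_text[2]}[{pattern_text[3]}>{pattern_text[4]}]{pattern_text[5]}"


def standard_categorization() -> Categorization:
    """The classical 96-category trinucleotide categorization.

    Patterns NN l REF ALT r NN, ordered substitution-class major in COSMIC
    order (A[C>A]A ... T[T>G]T); exhaustive and pairwise disjoint, so no
    joker is needed and the conflict rate is exactly 0.
    """
    pats = [parse_pattern(f"NN{left}{ref}{alt}{right}NN")
            for ref, alt in _SUBSTITUTIONS
            for left in BASES for right in BASES]
    return Categorization(pats, name="standard")


def two_flank_categorization() -> Categorization:
    """The 1536-category variant with two flanking bases on each side."""
    pats = [parse_pattern(f"N{l2}{l1}{ref}{alt}{r1}{r2}N")
            for ref, alt in _SUBSTITUTIONS
            for l2 in BASES for l1 in BASES
            for r1 in BASES for r2 in BASES]
    return Categorization(pats, name="two_flank")


def random_categorization(seed: int, n_categories: int = 96) -> Categorization:
    """Assign every valid sequence uniformly at random to one of 96 labels."""
    rng = np.random.default_rng(seed)
    table = rng.integers(0, n_categories, size=UNIVERSE_SIZE, dtype=np.int32)
    return Categorization(table=table, n_categories=n_categories,
                          name=f"random(seed={seed})")


# ---------------------------------------------------------------------------
# Transformation to the standard categories
# ---------------------------------------------------------------------------

@dataclass
class TransformationMatrix:
    """Row-stochastic map from a categorization's categories to the 96
    standard categories; rows of empty source categories are all zero."""

    matrix: np.ndarray          # (M, 96)
    empty_rows: np.ndarray      # (M,) bool


def transformation_matrix(cat: Categorization,
                          standard: Categorization | None = None
                          ) -> TransformationMatrix:
    """T[i, j] = fraction of category i's sequences that fall in standard
    category j."""
    std = standard if standard is not None else standard_categorization()
    a = cat.assignment
    b = std.assignment
    m, k = cat.n_categories, std.n_categories
    counts = np.bincount(a.astype(np.int64) * k + b, minlength=m * k)
    counts = counts.reshape(m, k).astype(float)
    totals = counts.sum(axis=1)
    empty = totals == 0
    t = np.zeros_like(counts)
    t[~empty] = counts[~empty] / totals[~empty, None]
    return TransformationMatrix(matrix=t, empty_rows=empty)
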