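"""Residue-class consensus strings and internal-repeat comparison.

NCX-type exchangers carry two internally similar regions, the α1 and α2
repeats, left by an ancient duplication; they overlap the reentrant
loops that line the ion pathway.  This module builds the compact
consensus alphabet used to compare such regions:

* uppercase letter — totally conserved residue,
* lowercase letter — most common residue (above a plurality threshold),
* class symbol — all residues fall within one physicochemical class
  ('@' aromatic, 'u' aliphatic, '1' basic, '2' acidic, 'p' charged,
  '$' hydroxylic, 'm' methyl, 'o' small),
* '.' — no consensus; '-' — gap-majority column,

and pairs the α1 and α2 columns to categorise each position as
identical across the repeats, of similar physicochemical nature, or
unrelated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import GAP, AlignmentMatrix


@dataclass(frozen=True)
class ResidueClassScheme:
    """Symbol -> residue-set mapping; smaller sets are more specific."""

    classes: tuple[tuple[str, frozenset[str]], ...] = (
        ("@", frozenset("FWYH")),
        ("u", frozenset("ILV")),
        ("1", frozenset("HKR")),
        ("2", frozenset("DE")),
        ("p", frozenset("HKRDE")),
        ("$", frozenset("ST")),
        ("m", frozenset("ASC")),
        ("o", frozenset("GASC")),
    )

    def __post_init__(self) -> None:
        by_symbol = dict(self.classes)
        if any(not s for s in by_symbol.values()):
            raise ValueError("empty residue class")
        if "p" in by_symbol and "1" in by_symbol and "2" in by_symbol:
            if by_symbol["p"] != by_symbol["1"] | by_symbol["2"]:
                raise ValueError("'p' must equal the union of '1' and '2'")

    def as_dict(self) -> dict[str, frozenset[str]]:
        return dict(self.classes)

    def classify_residue(self, residue: str) -> list[str]:
        """All class symbols containing ``residue``, most specific first.

        'X' (and any unknown letter) belongs to no class.
        """
        residue = residue.upper()
        hits = [(len(s), sym) for sym, s in self.classes if residue in s]
        hits.sort()
        return [sym for _, sym in hits]

    def smallest_class_containing(self, residues: Iterable[str]) -> str | None:
        rs = set(residues)
        best: tuple[int, str] | None = None
        for sym, s in self.classes:
            if rs <= s and (best is None or len(s) < best[0]):
                best = (len(s), sym)
        return best[1] if best else None


DEFAULT_SCHEME = ResidueClassScheme()


def classify_residue(scheme: ResidueClassScheme, residue: str) -> list[str]:
    return scheme.classify_residue(residue)


@dataclass
class ConsensusString:
    """Per-column consensus of an alignment subset."""

    text: str
    subset: tuple[str, ...]
    plurality_threshold: float
    class_threshold: float

    def __str__(self) -> str:
        return self.text

    def __len__(self) -> int:
        return len(self.text)


def _consensus_symbol(
    residues: Sequence[str],
    scheme: ResidueClassScheme,
    plurality_threshold: float,
    class_threshold: float,
) -> str:
    n = len(residues)
    gaps = sum(1 for r in residues if r == GAP)
    if gaps * 2 > n:
        return GAP
    nongap = [r for r in residues if r != GAP]
    counts = Counter(nongap)
    top_res, top_n = counts.most_common(1)[0]
    if gaps == 0 and top_n == n and top_res != "X":
        return top_res.upper()
    if top_res != "X" and top_n / n >= plurality_threshold:
        return top_res.lower()
    if "X" not in counts:
        # most-specific class covering >= class_threshold of the residues
        best: tuple[int, str] | None = None
        for sym, cls in scheme.classes:
            inside = sum(counts[r] for r in counts if r in cls)
            if inside / len(nongap) >= class_threshold and (
                best is None or len(cls) < best[0]
            ):
                best = (len(cls), sym)
        if best:
            return best[1]
    return "."


def build_consensus(
    alignment: AlignmentMatrix,
    subset: Iterable[str],
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
    plurality_threshold: float = 0.7,
    class_threshold: float = 1.0,
    columns: Sequence[int] | None = None,
) -> ConsensusString:
    """Build the class-alphabet consensus of ``subset`` column by column.

    Uppercase marks total conservation (all members, no gaps, not 'X');
    lowercase the most common residue when its frequency over all
    members reaches ``plurality_threshold``; a class symbol when a
    fraction >= ``class_threshold`` of the residues falls within one
    scheme class; '.' otherwise.  Columns with a gap majority render
    '-'.  ``columns`` restricts the consensus to the given 1-based
    alignment columns (default: all).
    """
    ids = sorted(set(subset))
    if not ids:
        raise ValueError("empty subset")
    if not 0.5 < plurality_threshold <= 1.0:
        raise ValueError("plurality_threshold must lie in (0.5, 1.0]")
    if not 0.5 < class_threshold <= 1.0:
        raise ValueError("class_threshold must lie in (0.5, 1.0]")
    cols = list(columns) if columns is not None else range(1, alignment.n_columns + 1)
    out = []
    for col in cols:
        residues = [alignment.row(sid)[col - 1] for sid in ids]
        out.append(
            _consensus_symbol(residues, scheme, plurality_threshold, class_threshold)
        )
    return ConsensusString("".join(out), tuple(ids), plurality_threshold, class_threshold)


# ---------------------------------------------------------------------------
# Repeat comparison
# ---------------------------------------------------------------------------

IDENTICAL = "identical_in_most_or_all"
SIMILAR = "similar_nature"
NONE = "none"


@dataclass(frozen=True)
class PairedColumn:
    column1: int | None
    column2: int | None
    category: str
    consensus1: str
    consensus2: str


@dataclass
class RepeatComparison:
    """Column-paired comparison of two repeat regions.

    ``pairs`` lists the paired columns with their per-pair category;
    ``combined_consensus`` is the class-alphabet consensus computed over
    both repeats jointly (each member sequence contributes its residues
    from both regions), approximating the pre-duplication ancestral
    sequence.
    """

    pairs: list[PairedColumn]
    combined_consensus: str
    majority_fraction: float

    def category_counts(self) -> dict[str, int]:
        counts = Counter(p.category for p in self.pairs if p.category != GAP)
        return {k: counts.get(k, 0) for k in (IDENTICAL, SIMILAR, NONE)}


def _region_columns(
    alignment: AlignmentMatrix, reference_id: str, region: tuple[int, int]
) -> list[int]:
    start, end = region
    c1 = alignment.residue_to_column(reference_id, start)
    c2 = alignment.residue_to_column(reference_id, end)
    return list(range(c1, c2 + 1))


def _apply_pairing_gaps(columns: list[int], gap_string: str | None) -> list[int | None]:
    """Expand a region's column list with explicit pairing gaps.

    ``gap_string`` uses '*' for a real column and '-' for a pairing gap,
    e.g. '**-**' pairs five positions of the partner region against four
    real columns here.  None keeps the columns as-is.
    """
    if gap_string is None:
        return list(columns)
    if gap_string.count("*") != len(columns):
        raise ValueError(
            f"pairing string {gap_string!r} has {gap_string.count('*')} column slots "
            f"but region has {len(columns)} columns"
        )
    out: list[int | None] = []
    it = iter(columns)
    for ch in gap_string:
        if ch == "*":
            out.append(next(it))
        elif ch == GAP:
            out.append(None)
        else:
            raise ValueError(f"pairing strings may contain only '*' and '-': {gap_string!r}")
    return out


def compare_repeats(
    alignment: AlignmentMatrix,
    region1: tuple[int, int],
    region2: tuple[int, int],
    subset: Iterable[str],
    reference_id: str,
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
    majority_fraction: float = 0.8,
    pairing: tuple[str, str] | None = None,
    plurality_threshold: float = 0.7,
) -> RepeatComparison:
    """Pair two repeat regions column by column and categorise each pair.

    Regions are 1-based closed residue intervals on ``reference_id``.
    A pair is *identical_in_most_or_all* when at least
    ``majority_fraction`` of the member sequences carry the same residue
    at both paired positions; *similar_nature* when that fraction of
    members carries residues sharing a scheme class at the two
    positions; *none* otherwise.  ``pairing`` optionally supplies
    ('*'/'-') gap-placement strings for the two regions (the repeats may
    need manual gapping to pair well); without it the regions must have
    equal column counts.
    """
    ids = sorted(set(subset))
    if not ids:
        raise ValueError("empty subset")
    cols1 = _region_columns(alignment, reference_id, region1)
    cols2 = _region_columns(alignment, reference_id, region2)
    g1, g2 = pairing if pairing is not None else (None, None)
    p1 = _apply_pairing_gaps(cols1, g1)
    p2 = _apply_pairing_gaps(cols2, g2)
    if len(p1) != len(p2):
        raise ValueError(
            f"paired regions have unequal length after gap placement: "
            f"{len(p1)} vs {len(p2)}"
        )
    cons1 = build_consensus(
        alignment, ids, scheme, plurality_threshold, columns=[c for c in p1 if c]
    ).text
    cons2 = build_consensus(
        alignment, ids, scheme, plurality_threshold, columns=[c for c in p2 if c]
    ).text
    it1, it2 = iter(cons1), iter(cons2)
    pairs: list[PairedColumn] = []
    for c1, c2 in zip(p1, p2):
        s1 = next(it1) if c1 else GAP
        s2 = next(it2) if c2 else GAP
        if c1 is None or c2 is None:
            pairs.append(PairedColumn(c1, c2, GAP, s1, s2))
            continue
        n = len(ids)
        same = 0
        similar = 0
        for sid in ids:
            r1 = alignment.row(sid)[c1 - 1]
            r2 = alignment.row(sid)[c2 - 1]
            if r1 == GAP or r2 == GAP or "X" in (r1, r2):
                continue
            if r1 == r2:
                same += 1
                similar += 1
            elif scheme.smallest_class_containing((r1, r2)):
                similar += 1
        if same / n >= majority_fraction:
            cat = IDENTICAL
        elif similar / n >= majority_fraction:
            cat = SIMILAR
        else:
            cat = NONE
        pairs.append(PairedColumn(c1, c2, cat, s1, s2))
    # combined consensus: both repeats contribute rows at each pair
    combined = []
    for c1, c2 in zip(p1, p2):
        residues = []
        for sid in ids:
            for c in (c1, c2):
                residues.append(alignment.row(sid)[c - 1] if c else GAP)
        combined.append(
            _consensus_symbol(residues, scheme, plurality_threshold, 1.0)
        )
    return RepeatComparison(pairs, "".join(combined), majority_fraction)
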