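"""Rule-based conservation analytics over a protein family alignment.

This module carries the package's core comparisons between the plant
MHX family of vacuolar Mg2+/H+ exchangers and the NCX Na+/Ca2+
exchangers of the CaCA superfamily:

* **Column classification** — declarative "conserved in subset A,
  differing from subset B" rules evaluated per alignment column, the
  machinery behind colour-coded family alignments (residues conserved in
  all MHXs and NCXs, MHX-only, vascular-vs-bryophyte, monocot-vs-eudicot
  differences, ...).
* **Differential-site scanning** — the diagnostic residues at which one
  family differs from another (strict: both families internally
  conserved; disjoint: one family conserved and its residue absent from
  the other).
* **Conserved-run (motif) discovery** — maximal runs of totally
  conserved columns, reported in the residue numbering of a reference
  sequence (e.g. a hexapeptide at position 430 of a reference).
* **Per-region conservation statistics** — identical/total residue
  counts and percent identity per topological region, with
  transmembrane vs non-transmembrane aggregates.
* **Pairwise percent scores** — global-alignment identity percentages
  between two sequences.

A column counts as conserved for a subset only when every member shows
the same residue there and that residue is neither a gap nor 'X':
partial conservation is never called.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import GAP, AlignmentMatrix, GroupPartition


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Column-level primitives
# ---------------------------------------------------------------------------


def conserved_residue(alignment: AlignmentMatrix, column: int, subset: Iterable[str]) -> str | None:
    """The single residue shared by every subset member at ``column``.

    Returns None unless all members carry the same residue and that
    residue is neither a gap nor 'X'.
    """
    residue: str | None = None
    n = 0
    for sid in subset:
        ch = alignment.row(sid)[column - 1]
        if ch == GAP or ch == "X":
            return None
        if residue is None:
            residue = ch
        elif ch != residue:
            return None
        n += 1
    return residue if n else None


def _column_residues(alignment: AlignmentMatrix, column: int, subset: Iterable[str]) -> list[str]:
    return [alignment.row(sid)[column - 1] for sid in subset]


# ---------------------------------------------------------------------------
# Rules and classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConservationRule:
    """A per-column conservation predicate.

    ``conserved_in`` names the subset that must be totally conserved at
    the column.  If ``differs_from`` is given the column only matches
    when that subset differs: in ``strict`` mode the second subset must
    itself be internally conserved with a different residue; in
    ``disjoint`` mode no member of it may carry the first subset's
    residue (gap or X anywhere in either subset disqualifies the
    column).
    """

    name: str
    conserved_in: str
    differs_from: str | None = None
    mode: str = "strict"

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "disjoint"):
            raise ValueError(f"unknown rule mode {self.mode!r}")


@dataclass
class ColumnMatch:
    column: int
    rule: str
    residue: str
    reference_position: int | None
    other_residues: str | None = None


@dataclass
class ColumnClassification:
    """Per-column rule matches, rules evaluated independently."""

    rules: list[ConservationRule]
    matches: list[ColumnMatch]
    reference_id: str | None = None
    n_columns: int = 0

    def columns_matching(self, rule_name: str) -> list[int]:
        self._check_rule(rule_name)
        return [m.column for m in self.matches if m.rule == rule_name]

    def matches_for(self, rule_name: str) -> list[ColumnMatch]:
        self._check_rule(rule_name)
        return [m for m in self.matches if m.rule == rule_name]

    def rules_at(self, column: int) -> list[str]:
        """Rule names matching at a column, in rule (precedence) order."""
        hit = {m.rule for m in self.matches if m.column == column}
        return [r.name for r in self.rules if r.name in hit]

    def _check_rule(self, rule_name: str) -> None:
        if rule_name not in {r.name for r in self.rules}:
            raise KeyError(f"unknown rule {rule_name!r}")

    def to_rows(self) -> list[dict]:
        return [
            {
                "column": m.column,
                "reference_position": m.reference_position,
                "rule": m.rule,
                "residue": m.residue,
                "other_residues": m.other_residues or "",
            }
            for m in self.matches
        ]


def _rule_matches_column(
    alignment: AlignmentMatrix,
    column: int,
    conserved_ids: Sequence[str],
    differ_ids: Sequence[str],
    mode: str,
) -> tuple[str, str | None] | None:
    residue = conserved_residue(alignment, column, conserved_ids)
    if residue is None:
        return None
    if not differ_ids:
        return residue, None
    others = _column_residues(alignment, column, differ_ids)
    if any(ch == GAP or ch == "X" for ch in others):
        return None
    if mode == "strict":
        if len(set(others)) == 1 and others[0] != residue:
            return residue, others[0]
        return None
    # disjoint: no overlap with the conserved residue
    if residue not in others:
        return residue, "".join(sorted(set(others)))
    return None


def classify_columns(
    alignment: AlignmentMatrix,
    partition: GroupPartition,
    rules: Sequence[ConservationRule],
    reference_id: str | None = None,
) -> ColumnClassification:
    """Evaluate every rule at every alignment column.

    Rules are independent: a column may match several.  Reference
    positions are reported in the 1-based residue numbering of
    ``reference_id`` (None on reference-gap columns).
    """
    partition.validate_against(alignment)
    resolved: dict[str, tuple[list[str], list[str]]] = {}
    for rule in rules:
        cons = sorted(partition.resolve(rule.conserved_in))
        if not cons:
            raise ValueError(f"rule {rule.name!r}: conserved_in resolves to empty set")
        diff = sorted(partition.resolve(rule.differs_from)) if rule.differs_from else []
        resolved[rule.name] = (cons, diff)
    matches: list[ColumnMatch] = []
    for col in range(1, alignment.n_columns + 1):
        refpos: int | None = None
        if reference_id is not None:
            rp = alignment.column_to_residue(reference_id, col)
            refpos = rp if isinstance(rp, int) else None
        for rule in rules:
            cons, diff = resolved[rule.name]
            hit = _rule_matches_column(alignment, col, cons, diff, rule.mode)
            if hit is not None:
                matches.append(ColumnMatch(col, rule.name, hit[0], refpos, hit[1]))
    return ColumnClassification(
        list(rules), matches, reference_id, alignment.n_columns
    )


def conserved_residue_composition(
    classification: ColumnClassification, rule_name: str
) -> dict[str, int]:
    """Amino-acid composition of a rule's conserved residues.

    Counts sum to the rule's total matched columns — e.g. how many of
    the residues conserved across two families are glycines.
    """
    counts = Counter(m.residue for m in classification.matches_for(rule_name))
    return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# Differential sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentialSite:
    column: int
    reference_position: int | None
    residue_a: str
    residues_b: str
    mode: str


def find_differential_sites(
    alignment: AlignmentMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    mode: str = "strict",
    reference_id: str | None = None,
) -> list[DifferentialSite]:
    """Columns at which group A differs diagnostically from group B.

    ``strict``: both groups internally conserved with different
    residues.  ``disjoint``: A conserved and no B member carries A's
    residue.  Gaps/X anywhere in either group disqualify a column.
    Groups must be disjoint and non-empty.
    """
    ids_a = sorted(set(group_a))
    ids_b = sorted(set(group_b))
    if not ids_a or not ids_b:
        raise ValueError("both groups must be non-empty")
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if mode not in ("strict", "disjoint"):
        raise ValueError(f"unknown mode {mode!r}")
    sites: list[DifferentialSite] = []
    for col in range(1, alignment.n_columns + 1):
        hit = _rule_matches_column(alignment, col, ids_a, ids_b, mode)
        if hit is None:
            continue
        refpos: int | None = None
        if reference_id is not None:
            rp = alignment.column_to_residue(reference_id, col)
            refpos = rp if isinstance(rp, int) else None
        sites.append(DifferentialSite(col, refpos, hit[0], hit[1] or "", mode))
    return sites


# ---------------------------------------------------------------------------
# Conserved runs (motifs)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifRun:
    subset: str
    start_column: int
    end_column: int
    reference_id: str
    reference_start: int
    residues: str
    spans_reference_gap: bool = False

    def __len__(self) -> int:
        return self.end_column - self.start_column + 1


def find_conserved_runs(
    alignment: AlignmentMatrix,
    subset: Iterable[str],
    min_len: int,
    reference_id: str,
    subset_label: str = "",
) -> list[MotifRun]:
    """Maximal runs of consecutive totally conserved columns.

    Runs of length >= ``min_len`` are reported with the conserved
    residue string and the 1-based position of their first column in
    ``reference_id`` coordinates (first non-gap column when the
    reference is gapped there, with ``spans_reference_gap`` set).
    Sorted by reference start.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    ids = sorted(set(subset))
    if not ids:
        raise ValueError("empty subset")
    per_col = [
        conserved_residue(alignment, col, ids)
        for col in range(1, alignment.n_columns + 1)
    ]
    runs: list[MotifRun] = []
    col = 1
    n = alignment.n_columns
    while col <= n:
        if per_col[col - 1] is None:
            col += 1
            continue
        start = col
        while col <= n and per_col[col - 1] is not None:
            col += 1
        end = col - 1
        if end - start + 1 < min_len:
            continue
        residues = "".join(per_col[c - 1] for c in range(start, end + 1))
        ref_start = None
        spans_gap = False
        for c in range(start, end + 1):
            rp = alignment.column_to_residue(reference_id, c)
            if isinstance(rp, int):
                ref_start = rp
                spans_gap = c != start
                break
        if ref_start is None:
            # reference entirely gapped under the run; report the residue
            # index of the next reference residue to the right
            spans_gap = True
            nxt = end + 1
            while nxt <= n and not isinstance(
                alignment.column_to_residue(reference_id, nxt), int
            ):
                nxt += 1
            ref_start = (
                alignment.column_to_residue(reference_id, nxt)
                if nxt <= n
                else len(alignment.ungapped(reference_id)) + 1
            )
        runs.append(
            MotifRun(
                subset_label or "+".join(ids),
                start,
                end,
                reference_id,
                ref_start,
                residues,
                spans_gap,
            )
        )
    runs.sort(key=lambda r: (r.reference_start, r.start_column))
    return runs


# ---------------------------------------------------------------------------
# Region conservation statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionConservationStat:
    region: str
    identical: int
    total: int

    @property
    def percent_identity(self) -> int:
        """Percent identity rounded half-up to an integer for display."""
        if self.total == 0:
            return 0
        return _round_half_up(100.0 * self.identical / self.total)


@dataclass
class RegionConservationReport:
    per_region: list[RegionConservationStat]
    tms_aggregate: RegionConservationStat
    non_tms_aggregate: RegionConservationStat
    reference_id: str = ""
    #: Totals count reference-sequence residues, not alignment columns.
    counting: str = "reference_residues"


def region_conservation_stats(
    alignment: AlignmentMatrix,
    subset: Iterable[str],
    projected_regions: Sequence[tuple[str, int, int]],
    reference_id: str,
) -> RegionConservationReport:
    """Identical/total residue counts per region of the reference.

    ``projected_regions`` is an ordered list of ``(name, start, end)``
    1-based closed intervals that must tile the reference sequence
    without overlap.  A reference residue counts as identical when its
    alignment column is totally conserved across ``subset``.  Regions
    named ``TMS*`` feed the transmembrane aggregate; all others the
    non-transmembrane aggregate.
    """
    ids = sorted(set(subset))
    if not ids:
        raise ValueError("empty subset")
    ref_len = len(alignment.ungapped(reference_id))
    covered = 0
    prev_end = 0
    for name, start, end in projected_regions:
        if start != prev_end + 1 or end < start:
            raise ValueError(
                f"regions must tile the reference without overlap; bad interval "
                f"{name!r} [{start},{end}] after position {prev_end}"
            )
        prev_end = end
        covered += end - start + 1
    if prev_end != ref_len or covered != ref_len:
        raise ValueError(
            f"regions cover {covered} residues but reference has {ref_len}"
        )
    conserved_flags = {}
    stats: list[RegionConservationStat] = []
    for name, start, end in projected_regions:
        identical = 0
        for res in range(start, end + 1):
            col = alignment.residue_to_column(reference_id, res)
            if col not in conserved_flags:
                conserved_flags[col] = conserved_residue(alignment, col, ids) is not None
            if conserved_flags[col]:
                identical += 1
        stats.append(RegionConservationStat(name, identical, end - start + 1))
    is_tms = lambda s: s.region.upper().startswith("TMS")
    tms = [s for s in stats if is_tms(s)]
    non = [s for s in stats if not is_tms(s)]
    agg = lambda name, part: RegionConservationStat(
        name, sum(s.identical for s in part), sum(s.total for s in part)
    )
    return RegionConservationReport(
        stats, agg("All TMSs", tms), agg("All non-TMS regions", non), reference_id
    )


# ---------------------------------------------------------------------------
# Pairwise percent scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseParams:
    """Global-alignment scoring parameters.

    Defaults follow the convention of the classic progressive-alignment
    programs: BLOSUM62, gap open 10, gap extend 0.1, with the identity
    percentage taken over the shorter ungapped sequence.  The
    denominator is configurable because different programs report
    "score" over different lengths.
    """

    matrix: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.1
    denominator: str = "shorter"  # shorter | longer | alignment


_MAX_OPTIMAL_ALIGNMENTS = 1000


def pairwise_percent_score(a: str, b: str, params: PairwiseParams | None = None) -> int:
    """Percent identity of the optimal global alignment of two sequences.

    The identity count is the maximum over co-optimal alignments, so the
    value does not depend on traceback tie-breaking.  Returned as an
    integer percentage in [0, 100].
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    params = params or PairwiseParams()
    a, b = a.upper(), b.upper()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if params.matrix:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    else:
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    best_ident = 0
    best_cols = max(len(a), len(b))
    for k, alignment in enumerate(aligner.align(a, b)):
        ra, rb = str(alignment[0]), str(alignment[1])
        ident = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
        if ident > best_ident:
            best_ident = ident
            best_cols = len(ra)
        if k + 1 >= _MAX_OPTIMAL_ALIGNMENTS:
            break
    if params.denominator == "shorter":
        denom = min(len(a), len(b))
    elif params.denominator == "longer":
        denom = max(len(a), len(b))
    elif params.denominator == "alignment":
        denom = best_cols
    else:
        raise ValueError(f"unknown denominator {params.denominator!r}")
    return _round_half_up(100.0 * best_ident / denom)
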