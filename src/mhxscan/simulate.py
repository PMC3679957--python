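"""Seeded generators for synthetic exchanger families and 5' UTRs.

Every detector in this package is exercised offline against families in
which the detected structure was *planted*: group-conserved columns,
family-diagnostic differential sites, conserved motif runs, hydrophobic
transmembrane stretches, a duplicated internal repeat with controlled
divergence, optional indels, and 5' UTRs with upstream AUGs of chosen
Kozak strength.  The generator emits both the sequences and a
machine-readable truth object derived from the construction plan, so
precision and recall of each detector can be measured exactly.

Construction guarantees (zero noise):

* a column planted as conserved for a subset is conserved for exactly
  that subset — rows outside it are forced to break both strict and
  disjoint differential patterns;
* a free (background) column is never conserved within any declared
  group of two or more members;
* substitution noise, when requested, is applied only to background
  and background-conserved columns — never to planted differential
  sites, motif runs, or the repeat — and only ever destroys
  conservation, so planted differential sites survive noise exactly.

All randomness flows from one integer-seeded ``random.Random``; equal
seeds give byte-identical output.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from . import uorf as _uorf
from .io import (
    GAP,
    AlignmentMatrix,
    GroupPartition,
    ProteinRecord,
    UTRRecord,
    write_alignment,
    write_group_manifest,
    write_sequences,
)
from .topology import Region, TopologyModel

ALL_AAS = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC_POOL = "ILVFAM"

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One taxon group: ``name`` doubles as its taxon tag."""

    name: str
    family: str
    size: int
    taxa: tuple[str, ...] = ()


@dataclass(frozen=True)
class DiffPlan:
    """Plant ``count`` differential columns between two label sets."""

    conserved_in: str
    differs_from: str
    count: int
    mode: str = "strict"


@dataclass(frozen=True)
class RepeatPlan:
    """Duplicate ``interval1`` into ``interval2`` with planted divergence.

    Intervals are 1-based closed, equal length, non-overlapping, and
    ``interval1`` must precede ``interval2``.  ``n_divergent`` paired
    positions are forced to differ in every sequence.
    """

    interval1: tuple[int, int]
    interval2: tuple[int, int]
    n_divergent: int


@dataclass(frozen=True)
class IndelOp:
    seq_id: str
    kind: str  # "insertion" | "deletion"
    position: int  # 1-based ancestral coordinate (first affected / insert-after)
    length: int


#: 30 sequences mirroring the composition of the analysed family set:
#: 24 plant MHXs across four taxa plus 6 NCX outgroup members.
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("eudicot", "MHX", 12, ("angiosperm", "vascular")),
    GroupSpec("monocot", "MHX", 8, ("angiosperm", "vascular")),
    GroupSpec("lycophyte", "MHX", 2, ("vascular",)),
    GroupSpec("bryophyte", "MHX", 2, ()),
    GroupSpec("NCX", "NCX", 6, ("animal",)),
)

#: A 550-residue 9-TMS / 2-reentrant-loop layout in the style of the
#: NCX1 topology model (large cytosolic loop d, short loop f before the
#: C-terminal TMS).  Orientations follow an extracellular N-terminus.
DEFAULT_REGIONS: tuple[tuple, ...] = (
    ("N-ter", 1, 37, "out"),
    ("TMS1", 38, 58, None),
    ("loop a", 59, 94, "in"),
    ("TMS2", 95, 115, None),
    ("RE-loop1", 116, 124, "out"),
    ("TMS3", 125, 145, None),
    ("loop b", 146, 157, "in"),
    ("TMS4", 158, 178, None),
    ("loop c", 179, 182, "out"),
    ("TMS5", 183, 203, None),
    ("loop d", 204, 352, "in"),
    ("TMS6", 353, 373, None),
    ("loop e", 374, 378, "out"),
    ("TMS7", 379, 399, None),
    ("RE-loop2", 400, 466, "in"),
    ("TMS8", 467, 487, None),
    ("loop f", 488, 501, "out"),
    ("TMS9", 502, 522, None),
    ("C-ter", 523, 550, "in"),
)

DEFAULT_OVERLAYS: tuple[tuple, ...] = (
    ("alpha1", 108, 132, None),
    ("alpha2", 440, 464, None),
    ("XIP", 210, 229, None),
    ("CBD1", 240, 280, None),
    ("CBD2", 290, 330, None),
)

#: Target per-region fractions of family-conserved columns, shaped like
#: the conservation profile of a real exchanger family: transmembrane
#: segments much more conserved than loops, the second reentrant loop
#: and the short last loop strongly conserved, the large central loop
#: weakly conserved.
DEFAULT_REGION_CONSERVATION: tuple[tuple[str, float], ...] = (
    ("N-ter", 0.03),
    ("TMS1", 0.34),
    ("loop a", 0.03),
    ("TMS2", 0.34),
    ("RE-loop1", 0.22),
    ("TMS3", 0.34),
    ("loop b", 0.25),
    ("TMS4", 0.34),
    ("loop c", 0.25),
    ("TMS5", 0.34),
    ("loop d", 0.08),
    ("TMS6", 0.34),
    ("loop e", 0.0),
    ("TMS7", 0.34),
    ("RE-loop2", 0.40),
    ("TMS8", 0.34),
    ("loop f", 0.50),
    ("TMS9", 0.34),
    ("C-ter", 0.0),
)

DEFAULT_DIFFERENTIALS: tuple[DiffPlan, ...] = (
    DiffPlan("MHX", "NCX", 3, "strict"),
    DiffPlan("MHX", "NCX", 5, "disjoint"),
    DiffPlan("vascular", "bryophyte", 4, "disjoint"),
)


@dataclass(frozen=True)
class FamilySpec:
    """Everything the family generator needs; the defaults are the
    package's standard study conditions (30 sequences x 550 residues)."""

    seed: int
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    length: int = 550
    regions: tuple[tuple, ...] = DEFAULT_REGIONS
    overlays: tuple[tuple, ...] = DEFAULT_OVERLAYS
    region_conservation: tuple[tuple[str, float], ...] = DEFAULT_REGION_CONSERVATION
    n_conserved_all: int = 32
    n_conserved_all_glycines: int = 10
    motif_run_lengths: tuple[int, ...] = (6, 5, 5)
    differentials: tuple[DiffPlan, ...] = DEFAULT_DIFFERENTIALS
    repeat: RepeatPlan | None = RepeatPlan((108, 132), (440, 464), 5)
    indels: tuple[IndelOp, ...] = ()
    auto_indels: int = 0
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must lie in [0, 1)")
        end = 0
        for name, s, e, _ in self.regions:
            if s != end + 1 or e < s:
                raise ValueError(f"regions must tile 1..length; bad region {name!r}")
            end = e
        if end != self.length:
            raise ValueError(f"regions cover {end} residues, spec length is {self.length}")
        if self.repeat is not None:
            (a1, a2), (b1, b2) = self.repeat.interval1, self.repeat.interval2
            if a2 - a1 != b2 - b1:
                raise ValueError("repeat intervals must have equal length")
            if not (1 <= a1 <= a2 < b1 <= b2 <= self.length):
                raise ValueError("repeat intervals must be ordered and disjoint")
            if self.repeat.n_divergent > a2 - a1 + 1:
                raise ValueError("n_divergent exceeds repeat length")


def default_family_spec(seed: int, **overrides) -> FamilySpec:
    return replace(FamilySpec(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    column: int  # final alignment column
    position: int  # ancestral/reference 1-based position
    conserved_in: str
    differs_from: str
    mode: str


@dataclass(frozen=True)
class PlantedRun:
    start: int  # ancestral positions
    end: int
    residues: str


@dataclass
class FamilyTruth:
    """Construction-plan truth for one generated family."""

    spec: FamilySpec
    alignment: AlignmentMatrix
    partition: GroupPartition
    reference_id: str
    topology: TopologyModel
    #: per final-alignment-column category: free / conserved_all /
    #: family_conserved / run / diff / copy / copy_divergent / inserted
    categories: list[str]
    #: final columns conserved across the reference family (plan-level)
    family_conserved_columns: list[int]
    #: final columns conserved across family plus outgroup
    conserved_all_columns: list[int]
    sites: list[PlantedSite]
    planted_runs: list[PlantedRun]
    repeat_plan: RepeatPlan | None
    divergent_offsets: list[int]
    tm_segments: list[tuple[int, int]]  # reference coordinates
    noised_columns: list[int]
    #: per sequence, per region name: (start, end) residue interval or None
    projected_regions: dict[str, dict[str, tuple[int, int] | None]]
    anc_to_col: dict[int, int]

    # -- derived expectations ------------------------------------------------

    def expected_sites(self, conserved_in: str, differs_from: str, mode: str) -> list[int]:
        """Planted columns a differential scan of the pair must report.

        Strict-mode planted sites also satisfy the disjoint predicate,
        so a disjoint query expects the union.
        """
        cols = [
            s.column
            for s in self.sites
            if s.conserved_in == conserved_in
            and s.differs_from == differs_from
            and (s.mode == mode or (mode == "disjoint" and s.mode == "strict"))
        ]
        return sorted(cols)

    def expected_runs(self, min_len: int) -> list[tuple[int, int, str]]:
        """Maximal family-conserved column runs of length >= min_len.

        Computed from the plan's conserved-column set; residues read
        from the reference row.
        """
        cols = set(self.family_conserved_columns)
        runs: list[tuple[int, int, str]] = []
        c = 1
        n = self.alignment.n_columns
        ref = self.alignment.row(self.reference_id)
        while c <= n:
            if c not in cols:
                c += 1
                continue
            start = c
            while c in cols:
                c += 1
            end = c - 1
            if end - start + 1 >= min_len:
                runs.append((start, end, ref[start - 1 : end]))
        return runs

    def expected_region_identity(self) -> dict[str, tuple[int, int]]:
        """(identical, total) per region over the family subset, in
        reference residues, from the plan's conserved-column set."""
        cols = set(self.family_conserved_columns)
        out: dict[str, tuple[int, int]] = {}
        for r in self.topology.regions:
            ident = 0
            for pos in range(r.start, r.end + 1):
                if self.anc_to_col[pos] in cols:
                    ident += 1
            out[r.name] = (ident, len(r))
        return out

    def family_ids(self) -> frozenset[str]:
        return self.partition.members(self.spec.groups[0].family)

    def records(self) -> list[ProteinRecord]:
        labels = {i: self.partition.labels_of(i) for i in self.alignment.ids}
        return self.alignment.records(labels)


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------


def _build_partition(groups: Sequence[GroupSpec]) -> tuple[GroupPartition, dict[str, list[str]]]:
    partition = GroupPartition()
    by_group: dict[str, list[str]] = {}
    for g in groups:
        ids = [f"{g.name}_{k:02d}" for k in range(1, g.size + 1)]
        by_group[g.name] = ids
        for i in ids:
            partition.add(i, g.family, (g.name, *g.taxa))
    return partition, by_group


def _draw(rng: random.Random, pool: str, *, avoid: str = "") -> str:
    choices = [a for a in pool if a not in avoid]
    return choices[rng.randrange(len(choices))]


def _ensure_group_diversity(
    col: list[str],
    atomic_groups: list[list[int]],
    rng: random.Random,
    pool: str,
    forbidden: Mapping[int, str] | None = None,
) -> None:
    """Force every group of >= 2 rows to show >= 2 distinct residues."""
    forbidden = forbidden or {}
    for rows in atomic_groups:
        if len(rows) < 2:
            continue
        values = {col[r] for r in rows if col[r] != GAP}
        if len(values) > 1 or not values:
            continue
        victim = rows[rng.randrange(len(rows))]
        avoid = col[victim] + forbidden.get(victim, "")
        col[victim] = _draw(rng, pool, avoid=avoid)


def generate_family(spec: FamilySpec) -> tuple[list[ProteinRecord], FamilyTruth]:
    """Generate a family alignment with planted, machine-readable truth.

    Returns the ungapped records and a :class:`FamilyTruth` holding the
    true alignment, the partition, the topology model on the reference
    (first sequence of the first group), and the planted feature
    coordinates.  Identical seeds give identical output.
    """
    rng = random.Random(spec.seed)
    partition, by_group = _build_partition(spec.groups)
    ids = [i for g in spec.groups for i in by_group[g.name]]
    row_of = {sid: k for k, sid in enumerate(ids)}
    n_rows = len(ids)
    L = spec.length
    reference_id = ids[0]
    family_label = spec.groups[0].family
    family_rows = [row_of[i] for i in sorted(partition.members(family_label))]
    atomic_groups = [
        [row_of[i] for i in by_group[g.name]] for g in spec.groups
    ]
    family_row_set = set(family_rows)
    outside_rows = [r for r in range(n_rows) if r not in family_row_set]

    tm_cols: set[int] = set()
    for name, s, e, _ in spec.regions:
        if name.upper().startswith("TMS"):
            tm_cols.update(range(s, e + 1))

    # -- position bookkeeping (ancestral coordinates) -----------------------
    category = ["free"] * (L + 1)  # 1-based
    interval1: set[int] = set()
    interval2: set[int] = set()
    copy_src: dict[int, int] = {}
    divergent: set[int] = set()
    if spec.repeat is not None:
        a1, a2 = spec.repeat.interval1
        b1, b2 = spec.repeat.interval2
        interval1 = set(range(a1, a2 + 1))
        interval2 = set(range(b1, b2 + 1))
        for off in range(a2 - a1 + 1):
            copy_src[b1 + off] = a1 + off
            category[b1 + off] = "copy"
        div_offsets = sorted(rng.sample(range(a2 - a1 + 1), spec.repeat.n_divergent))
        for off in div_offsets:
            divergent.add(b1 + off)
            category[b1 + off] = "copy_divergent"
    else:
        div_offsets = []

    def free_positions() -> list[int]:
        return [p for p in range(1, L + 1) if category[p] == "free"]

    # motif runs: contiguous family-conserved stretches outside the repeat,
    # kept to weakly conserved regions so per-region quotas stay feasible
    rates = dict(spec.region_conservation)
    run_allowed: set[int] = set()
    for name, s, e, _ in spec.regions:
        if rates.get(name, 0.0) <= 0.1:
            run_allowed.update(range(s, e + 1))
    run_allowed -= interval1 | interval2
    planted_runs: list[PlantedRun] = []
    run_spans: list[tuple[int, int]] = []
    for run_len in spec.motif_run_lengths:
        placed = False
        for _ in range(2000):
            start = rng.randrange(2, L - run_len)
            span = range(start, start + run_len)
            if all(
                category[p] == "free" and p in run_allowed for p in span
            ):
                for p in span:
                    category[p] = "run"
                run_spans.append((start, start + run_len - 1))
                placed = True
                break
        if not placed:
            raise ValueError(f"could not place a motif run of length {run_len}")

    # per-region family-conserved quotas
    quota_cols: list[int] = []
    for name, s, e, _ in spec.regions:
        rate = rates.get(name, 0.0)
        k = round(rate * (e - s + 1))
        candidates = [
            p for p in range(s, e + 1) if category[p] == "free"
        ]
        if k > len(candidates):
            raise ValueError(f"region {name!r}: quota {k} exceeds free positions")
        for p in sorted(rng.sample(candidates, k)):
            category[p] = "family_conserved"
            quota_cols.append(p)

    # promote a subset to conserved-across-everything, with a glycine quota
    if spec.n_conserved_all > len(quota_cols):
        raise ValueError("n_conserved_all exceeds available conserved columns")
    conserved_all_anc = sorted(rng.sample(quota_cols, spec.n_conserved_all))
    glycine_anc = set(
        rng.sample(conserved_all_anc, min(spec.n_conserved_all_glycines, len(conserved_all_anc)))
    )
    for p in conserved_all_anc:
        category[p] = "conserved_all"

    # differential sites
    site_plan: list[tuple[int, DiffPlan]] = []
    for plan in spec.differentials:
        a_ids = sorted(partition.resolve(plan.conserved_in))
        b_ids = sorted(partition.resolve(plan.differs_from))
        if not a_ids or not b_ids or set(a_ids) & set(b_ids):
            raise ValueError(
                f"differential plan {plan.conserved_in!r} vs {plan.differs_from!r}: "
                "labels must resolve to disjoint non-empty sets"
            )
        if plan.mode == "disjoint" and len(b_ids) < 2:
            raise ValueError("disjoint plan needs >= 2 sequences on the differing side")
        candidates = [p for p in free_positions() if p not in interval1]
        if plan.count > len(candidates):
            raise ValueError("not enough free positions for differential plan")
        for p in sorted(rng.sample(candidates, plan.count)):
            category[p] = "diff"
            site_plan.append((p, plan))
    site_by_pos = dict(site_plan)

    # -- residue matrix ------------------------------------------------------
    matrix: list[list[str]] = [["?"] * (L + 1) for _ in range(n_rows)]

    def pool_at(pos: int) -> str:
        return HYDROPHOBIC_POOL if pos in tm_cols else ALL_AAS

    def fill_conserved(pos: int, rows_conserved: Iterable[int], residue: str) -> None:
        for r in rows_conserved:
            matrix[r][pos] = residue

    for pos in range(1, L + 1):
        cat = category[pos]
        pool = pool_at(pos)
        if cat in ("copy", "copy_divergent"):
            src = copy_src[pos]
            if cat == "copy":
                for r in range(n_rows):
                    matrix[r][pos] = matrix[r][src]
            else:
                col = [
                    _draw(rng, pool, avoid=matrix[r][src]) for r in range(n_rows)
                ]
                forbidden = {r: matrix[r][src] for r in range(n_rows)}
                _ensure_group_diversity(col, atomic_groups, rng, pool, forbidden)
                for r in range(n_rows):
                    matrix[r][pos] = col[r]
            continue
        if cat == "conserved_all":
            residue = "G" if pos in glycine_anc else _draw(rng, pool)
            fill_conserved(pos, range(n_rows), residue)
            continue
        if cat in ("family_conserved", "run"):
            residue = _draw(rng, pool)
            fill_conserved(pos, family_rows, residue)
            # outsiders: one shares the residue (blocks a disjoint call),
            # one differs (blocks a strict call), the rest are random
            if outside_rows:
                matrix[outside_rows[0]][pos] = residue
                if len(outside_rows) > 1:
                    matrix[outside_rows[1]][pos] = _draw(rng, pool, avoid=residue)
                for r in outside_rows[2:]:
                    matrix[r][pos] = _draw(rng, pool)
            continue
        if cat == "diff":
            plan = site_by_pos[pos]
            a_rows = [row_of[i] for i in sorted(partition.resolve(plan.conserved_in))]
            b_rows = [row_of[i] for i in sorted(partition.resolve(plan.differs_from))]
            residue = _draw(rng, pool)
            fill_conserved(pos, a_rows, residue)
            if plan.mode == "strict":
                other = _draw(rng, pool, avoid=residue)
                fill_conserved(pos, b_rows, other)
            else:
                first = _draw(rng, pool, avoid=residue)
                matrix[b_rows[0]][pos] = first
                if len(b_rows) > 1:
                    matrix[b_rows[1]][pos] = _draw(rng, pool, avoid=residue + first)
                for r in b_rows[2:]:
                    matrix[r][pos] = _draw(rng, pool, avoid=residue)
            rest = [r for r in range(n_rows) if r not in set(a_rows) | set(b_rows)]
            if rest:
                col = [matrix[r][pos] for r in range(n_rows)]
                for r in rest:
                    col[r] = _draw(rng, pool)
                _ensure_group_diversity(
                    col, [g for g in atomic_groups if set(g) <= set(rest)], rng, pool
                )
                for r in rest:
                    matrix[r][pos] = col[r]
            continue
        # free column
        col = [_draw(rng, pool) for _ in range(n_rows)]
        _ensure_group_diversity(col, atomic_groups, rng, pool)
        for r in range(n_rows):
            matrix[r][pos] = col[r]

    # -- substitution noise (background only) --------------------------------
    noised: list[int] = []
    if spec.noise_rate > 0:
        protected = interval1 | interval2 | {p for p, _ in site_plan}
        for s, e in run_spans:
            protected.update(range(s, e + 1))
        for pos in range(1, L + 1):
            if pos in protected or rng.random() >= spec.noise_rate:
                continue
            cat = category[pos]
            pool = pool_at(pos)
            if cat in ("conserved_all", "family_conserved"):
                r = family_rows[rng.randrange(len(family_rows))]
                matrix[r][pos] = _draw(rng, pool, avoid=matrix[r][pos])
            else:
                r = rng.randrange(n_rows)
                col = [matrix[k][pos] for k in range(n_rows)]
                col[r] = _draw(rng, pool, avoid=col[r])
                _ensure_group_diversity(col, atomic_groups, rng, pool)
                for k in range(n_rows):
                    matrix[k][pos] = col[k]
            noised.append(pos)

    # -- indels --------------------------------------------------------------
    ops = list(spec.indels)
    if spec.auto_indels:
        candidates = [p for p in free_positions() if p not in interval1 | interval2]
        non_ref = [i for i in ids if i != reference_id]
        for _ in range(spec.auto_indels):
            sid = non_ref[rng.randrange(len(non_ref))]
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            length = rng.randrange(2, 7)
            if kind == "deletion":
                starts = [
                    p
                    for p in candidates
                    if all(category[q] == "free" for q in range(p, min(p + length, L + 1)))
                    and p + length - 1 <= L
                ]
                if not starts:
                    continue
                ops.append(IndelOp(sid, "deletion", starts[rng.randrange(len(starts))], length))
            else:
                ops.append(
                    IndelOp(sid, "insertion", candidates[rng.randrange(len(candidates))], length)
                )
    for op in ops:
        if op.seq_id == reference_id:
            raise ValueError("indels in the reference sequence are not supported")
        if op.kind == "deletion":
            span = range(op.position, op.position + op.length)
            if any(category[p] != "free" for p in span):
                raise ValueError(
                    f"deletion at {op.position} overlaps planted columns"
                )
            for p in span:
                matrix[row_of[op.seq_id]][p] = GAP

    insertions: dict[int, list[tuple[str, int]]] = {}
    for op in ops:
        if op.kind == "insertion":
            insertions.setdefault(op.position, []).append((op.seq_id, op.length))

    # -- assemble final gapped rows and the ancestral->column map ------------
    final_rows = ["" for _ in range(n_rows)]
    anc_to_col: dict[int, int] = {}
    col = 0
    inserted_cols: list[int] = []
    for pos in range(1, L + 1):
        col += 1
        anc_to_col[pos] = col
        for r in range(n_rows):
            final_rows[r] += matrix[r][pos]
        for sid, length in insertions.get(pos, ()):  # insert after this position
            for _ in range(length):
                col += 1
                inserted_cols.append(col)
                for r in range(n_rows):
                    final_rows[r] += (
                        _draw(rng, ALL_AAS) if r == row_of[sid] else GAP
                    )

    alignment = AlignmentMatrix(ids, final_rows)

    # -- truth ---------------------------------------------------------------
    categories_final = ["inserted"] * alignment.n_columns
    for pos in range(1, L + 1):
        categories_final[anc_to_col[pos] - 1] = category[pos]
    family_flag: list[int] = []
    conserved_all_final: list[int] = []
    for pos in range(1, L + 1):
        cat = category[pos]
        c = anc_to_col[pos]
        src_cat = category[copy_src[pos]] if cat == "copy" else cat
        if src_cat in ("conserved_all", "family_conserved", "run", "diff"):
            if src_cat == "diff":
                plan = site_by_pos[pos if cat != "copy" else copy_src[pos]]
                if partition.resolve(plan.conserved_in) >= partition.members(family_label):
                    family_flag.append(c)
            else:
                family_flag.append(c)
        if src_cat == "conserved_all":
            conserved_all_final.append(c)

    sites = [
        PlantedSite(
            anc_to_col[pos], pos, plan.conserved_in, plan.differs_from, plan.mode
        )
        for pos, plan in site_plan
    ]
    runs = [
        PlantedRun(s, e, "".join(matrix[row_of[reference_id]][p] for p in range(s, e + 1)))
        for s, e in run_spans
    ]

    topology = TopologyModel(
        reference_id=reference_id,
        regions=[Region(n, s, e, o) for n, s, e, o in spec.regions],
        overlays=[Region(n, s, e, o) for n, s, e, o in spec.overlays],
    )
    tm_segments = [
        (r.start, r.end) for r in topology.regions if r.name.upper().startswith("TMS")
    ]

    projected: dict[str, dict[str, tuple[int, int] | None]] = {}
    for sid in ids:
        row = alignment.row(sid)
        per_region: dict[str, tuple[int, int] | None] = {}
        for r in topology.regions:
            c1 = anc_to_col[r.start]
            c2 = anc_to_col[r.end]
            residues = [
                alignment.column_to_residue(sid, c)
                for c in range(c1, c2 + 1)
                if row[c - 1] != GAP
            ]
            per_region[r.name] = (residues[0], residues[-1]) if residues else None
        projected[sid] = per_region

    truth = FamilyTruth(
        spec=spec,
        alignment=alignment,
        partition=partition,
        reference_id=reference_id,
        topology=topology,
        categories=categories_final,
        family_conserved_columns=sorted(family_flag),
        conserved_all_columns=sorted(conserved_all_final),
        sites=sites,
        planted_runs=runs,
        repeat_plan=spec.repeat,
        divergent_offsets=div_offsets,
        tm_segments=tm_segments,
        noised_columns=noised,
        projected_regions=projected,
        anc_to_col=anc_to_col,
    )
    return truth.records(), truth


# ---------------------------------------------------------------------------
# UTR generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedUAUG:
    strength: str  # strong | sub-optimal | weak
    peptide_codons: int | None = 2  # None: no stop planted within the UTR


@dataclass(frozen=True)
class UTRGenePlan:
    gene_id: str
    group: str
    length: int
    uaugs: tuple[PlantedUAUG, ...] = ()
    with_cds: bool = False


@dataclass(frozen=True)
class UTRSpec:
    seed: int
    genes: tuple[UTRGenePlan, ...]
    allow_extra_atg: bool = False


@dataclass(frozen=True)
class UORFTruth:
    gene_id: str
    position: int
    strength: str
    peptide: str
    status: str


def default_utr_spec(seed: int) -> UTRSpec:
    """The standard UTR study set: ten eudicot genes all carrying at
    least one upstream AUG (one gene heavily loaded), six monocot genes
    of which three carry none."""
    rng = random.Random(seed ^ 0x5EED)
    genes: list[UTRGenePlan] = []
    strengths = [_uorf.STRONG, _uorf.SUB_OPTIMAL, _uorf.WEAK]
    for k in range(1, 11):
        n_uaugs = 11 if k == 1 else 1 + (k % 3)
        uaugs = tuple(
            PlantedUAUG(strengths[(k + j) % 3], peptide_codons=1 + (j % 4))
            for j in range(n_uaugs)
        )
        genes.append(
            UTRGenePlan(
                f"eudicot_gene_{k:02d}",
                "eudicot",
                rng.randrange(430, 520) if k == 1 else rng.randrange(150, 420),
                uaugs,
                with_cds=k % 2 == 0,
            )
        )
    for k in range(1, 7):
        uaugs = (
            (PlantedUAUG(strengths[k % 3], peptide_codons=2),) if k <= 3 else ()
        )
        genes.append(
            UTRGenePlan(
                f"monocot_gene_{k:02d}",
                "monocot",
                rng.randrange(100, 350),
                uaugs,
                with_cds=k % 2 == 1,
            )
        )
    return UTRSpec(seed=seed, genes=tuple(genes))


_SAFE_CODONS = [
    a + b + c for a in "CGT" for b in "CGT" for c in "CGT"
]  # no A anywhere: cannot contain or frame-shift into ATG or a stop codon


def _background_nt(rng: random.Random, n: int) -> list[str]:
    out: list[str] = []
    for _ in range(n):
        out.append("ACGT"[rng.randrange(4)])
        if len(out) >= 3 and "".join(out[-3:]) == "ATG":
            out[-1] = "C"
    return out


def generate_utrs(spec: UTRSpec) -> tuple[list[UTRRecord], list[UORFTruth]]:
    """Generate 5' UTRs with planted upstream AUGs and exact truth.

    Planted uAUGs carry the requested Kozak strength at -3/+4; unless
    ``allow_extra_atg`` is set, no other ATG occurs anywhere in the
    emitted UTRs (a repair pass mutates accidental ones, never touching
    planted windows).  Each planted uORF's peptide codons are drawn from
    an A-free codon set, so no stop or start can arise inside it in any
    frame.
    """
    rng = random.Random(spec.seed)
    records: list[UTRRecord] = []
    truths: list[UORFTruth] = []
    for gene in spec.genes:
        L = gene.length
        # choose well-separated uAUG positions
        positions: list[int] = []
        needed = len(gene.uaugs)
        no_stop = [k for k, u in enumerate(gene.uaugs) if u.peptide_codons is None]
        if len(no_stop) > 1:
            raise ValueError(
                f"{gene.gene_id}: at most one uAUG without a planted stop is supported"
            )
        # one uAUG per equal slot of the usable range, jittered within the
        # slot; consecutive plants stay >= 28 nt apart so their windows
        # (context + peptide + stop) can never collide
        if needed:
            lo, hi = 5, max(6, L - 20)
            slot = (hi - lo) // needed
            if slot < 28:
                raise ValueError(
                    f"could not place {needed} uAUGs in a {L} nt UTR for {gene.gene_id}"
                )
            positions = [
                lo + k * slot + rng.randrange(slot - 27) for k in range(needed)
            ]
        if no_stop:
            # a uORF running off the UTR end must be the 3'-most plant,
            # as its tail rewrite reaches the UTR boundary
            mx = max(range(needed), key=lambda i: positions[i])
            positions[no_stop[0]], positions[mx] = positions[mx], positions[no_stop[0]]
        order = sorted(range(needed), key=lambda i: positions[i])
        seq = _background_nt(rng, L)
        protected: set[int] = set()  # 0-based indices that repairs must not touch
        gene_truth: list[UORFTruth] = []
        cds = ""
        if gene.with_cds:
            cds = "ATG" + "".join(
                _SAFE_CODONS[rng.randrange(len(_SAFE_CODONS))] for _ in range(9)
            )
        for idx in order:
            p = positions[idx]  # 1-based position of the A of ATG
            plant = gene.uaugs[idx]
            i = p - 1
            seq[i : i + 3] = ["A", "T", "G"]
            # -3 / +4 context per requested strength
            strong_m3 = plant.strength == _uorf.STRONG or (
                plant.strength == _uorf.SUB_OPTIMAL and rng.random() < 0.5
            )
            strong_p4 = (
                plant.strength == _uorf.STRONG
                or (plant.strength == _uorf.SUB_OPTIMAL and not strong_m3)
            )
            if i - 3 >= 0:
                seq[i - 3] = "AG"[rng.randrange(2)] if strong_m3 else "CT"[rng.randrange(2)]
            plus4 = "G" if strong_p4 else "CT"[rng.randrange(2)]
            if i + 3 < L:
                seq[i + 3] = plus4
            # only -3, the AUG itself and +4 are plant-fixed; -2/-1 stay
            # repairable so an accidental ATG there can always be removed
            protected.update(
                j for j in (i - 3, i, i + 1, i + 2, i + 3) if 0 <= j < L
            )
            # peptide codons + stop, all within the UTR when requested
            n_cod = plant.peptide_codons
            codons: list[str] = []
            status = _uorf.STOPPED_IN_UTR
            if n_cod is not None and i + 3 + 3 * n_cod + 3 <= L:
                for k in range(n_cod):
                    codon = _SAFE_CODONS[rng.randrange(len(_SAFE_CODONS))]
                    if k == 0:
                        # keep the planted +4 base as the codon's first nt
                        codon = plus4.replace("A", "C") + codon[1:]
                        if i + 3 < L:
                            seq[i + 3] = codon[0]
                    codons.append(codon)
                    seq[i + 3 + 3 * k : i + 6 + 3 * k] = list(codon)
                stop_at = i + 3 + 3 * n_cod
                seq[stop_at : stop_at + 3] = list("TAA")
                protected.update(range(i + 3, stop_at + 3))
                peptide = "M" + str(Seq("".join(codons)).translate())
            else:
                # runs off the end of the UTR; rewrite the tail with safe
                # codons so no stop arises before the boundary
                if p != max(positions):
                    raise ValueError(
                        f"{gene.gene_id}: uORF at {p} overruns the UTR but is "
                        "not the 3'-most planted uAUG"
                    )
                k = i + 3
                while k < L:
                    take = min(3, L - k)
                    codon = _SAFE_CODONS[rng.randrange(len(_SAFE_CODONS))]
                    seq[k : k + take] = list(codon[:take])
                    k += take
                protected.update(range(i + 3, L))
                full = "".join(seq[i:]) + cds
                n_full = (len(full)) // 3
                pep = []
                status = _uorf.OVERLAPS_MAIN_ORF if cds else _uorf.TRUNCATED
                for k in range(n_full):
                    codon = full[3 * k : 3 * k + 3]
                    if codon in ("TAA", "TAG", "TGA"):
                        break
                    pep.append(codon)
                peptide = str(Seq("".join(pep)).translate()) if pep else ""
            gene_truth.append(
                UORFTruth(gene.gene_id, p, plant.strength, peptide, status)
            )
        # repair pass: remove accidental ATGs outside planted windows
        if not spec.allow_extra_atg:
            text = "".join(seq)
            idx = text.find("ATG")
            while idx >= 0:
                window = {idx, idx + 1, idx + 2}
                if any(
                    t.position - 1 == idx for t in gene_truth
                ):
                    pass  # planted
                else:
                    mutable = [j for j in sorted(window) if j not in protected]
                    if not mutable:  # fully protected yet unplanted: cannot happen
                        raise AssertionError("unrepairable accidental ATG")
                    j = mutable[-1]
                    seq[j] = "C"
                    text = "".join(seq)
                idx = text.find("ATG", idx + 1)
        rec = UTRRecord(gene.gene_id, "".join(seq), cds or None)
        records.append(rec)
        truths.extend(sorted(gene_truth, key=lambda t: t.position))
    return records, truths


def utr_grouping(spec: UTRSpec) -> dict[str, str]:
    return {g.gene_id: g.group for g in spec.genes}


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------


def write_fixture_bundle(
    path,
    family: tuple[list[ProteinRecord], FamilyTruth] | None = None,
    utrs: tuple[list[UTRRecord], list[UORFTruth]] | None = None,
) -> dict[str, str]:
    """Write a self-contained fixture directory and return its manifest.

    Emits FASTA, aligned FASTA, group manifest, topology config and
    truth tables for whatever outputs are supplied, plus a
    ``checksums.sha256`` manifest.  Returns {filename: sha256}.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        p = out / name
        with open(p, "w") as fh:
            writer(fh)
        written.append(p)

    if family is not None:
        records, truth = family
        emit("family.fasta", lambda fh: write_sequences(records, fh))
        emit("family.aln.fasta", lambda fh: write_alignment(truth.alignment, fh))
        emit("groups.tsv", lambda fh: write_group_manifest(truth.partition, fh))
        truth.topology.save(out / "topology.yaml")
        written.append(out / "topology.yaml")

        def truth_writer(fh):
            fh.write(f"# seed={truth.spec.seed}\n")
            fh.write("column\tcategory\n")
            for c, cat in enumerate(truth.categories, start=1):
                fh.write(f"{c}\t{cat}\n")

        emit("column_truth.tsv", truth_writer)

        def sites_writer(fh):
            fh.write(f"# seed={truth.spec.seed}\n")
            fh.write("column\tposition\tconserved_in\tdiffers_from\tmode\n")
            for s in truth.sites:
                fh.write(
                    f"{s.column}\t{s.position}\t{s.conserved_in}\t{s.differs_from}\t{s.mode}\n"
                )

        emit("site_truth.tsv", sites_writer)

    if utrs is not None:
        records, truths = utrs
        emit("utrs.fasta", lambda fh: write_sequences(records, fh))

        def cds_writer(fh):
            fh.write("# gene_id\tdownstream_cds\n")
            for r in records:
                if r.downstream_cds:
                    fh.write(f"{r.gene_id}\t{r.downstream_cds}\n")

        emit("cds.tsv", cds_writer)

        def utr_truth_writer(fh):
            fh.write("gene_id\tposition\tstrength\tpeptide\tstatus\n")
            for t in truths:
                fh.write(
                    f"{t.gene_id}\t{t.position}\t{t.strength}\t{t.peptide}\t{t.status}\n"
                )

        emit("uorf_truth.tsv", utr_truth_writer)

    manifest: dict[str, str] = {}
    for p in sorted(written):
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out / "checksums.sha256", "w") as fh:
        for name, digest in manifest.items():
            fh.write(f"{digest}  {name}\n")
    return manifest
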