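"""5' UTR census: upstream AUGs, Kozak context, and uORF peptides.

An AUG upstream of a gene's main open reading frame (a uAUG) can start
an upstream ORF (uORF) that represses translation of the main ORF and
can route the transcript into nonsense-mediated decay.  Whether the
ribosome recognises a uAUG depends largely on its Kozak context, the
nucleotides at positions -3 and +4 around the AUG (A of the AUG = +1):

* **strong** — purine (A/G) at -3 *and* G at +4,
* **sub-optimal** — exactly one of the two,
* **weak** — neither,
* **indeterminate** — either position falls outside the available
  sequence.

The scanner finds every uAUG in a UTR (all three frames), classifies
its context, translates the uORF peptide with the standard code, and
summarises uORF prevalence per gene group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .io import UTRRecord

STRONG = "strong"
SUB_OPTIMAL = "sub-optimal"
WEAK = "weak"
INDETERMINATE = "indeterminate"

STOPPED_IN_UTR = "stopped_in_utr"
OVERLAPS_MAIN_ORF = "overlaps_main_orf"
TRUNCATED = "truncated_no_sequence"

_STOPS = {"TAA", "TAG", "TGA"}
_PURINES = {"A", "G"}


def find_uaugs(utr_record: UTRRecord) -> list[int]:
    """1-based positions of every ATG in the UTR, ascending, any frame."""
    utr = utr_record.utr
    positions = []
    start = 0
    while True:
        idx = utr.find("ATG", start)
        if idx < 0:
            return positions
        positions.append(idx + 1)
        start = idx + 1


def kozak_classify(context: str) -> str:
    """Classify a 7-nt Kozak context string (positions -3..+4).

    The string covers -3,-2,-1,A,T,G,+4; any position outside the
    available sequence is represented by a non-ACGT character (e.g. '.'
    or 'N').  The -3 and +4 identities alone decide the class.
    """
    if len(context) != 7:
        raise ValueError("context must be 7 characters covering -3..+4")
    ctx = context.upper().replace("U", "T")
    minus3, plus4 = ctx[0], ctx[6]
    if minus3 not in "ACGT" or plus4 not in "ACGT":
        return INDETERMINATE
    strong_m3 = minus3 in _PURINES
    strong_p4 = plus4 == "G"
    if strong_m3 and strong_p4:
        return STRONG
    if strong_m3 or strong_p4:
        return SUB_OPTIMAL
    return WEAK


@dataclass(frozen=True)
class UORFHit:
    gene_id: str
    position: int  # 1-based uAUG position in the UTR
    context: str  # 7 characters, '.' where undetermined
    strength: str
    peptide: str  # includes initiator Met, excludes stop
    status: str


def _context_at(full: str, pos: int) -> str:
    """7-nt context around a 1-based ATG position; '.' pads missing ends."""
    chars = []
    for off in range(-3, 4):
        idx = pos - 1 + off  # 0-based
        chars.append(full[idx] if 0 <= idx < len(full) else ".")
    return "".join(chars)


def extract_uorf(
    utr_record: UTRRecord,
    uaug_position: int,
    classifier: Callable[[str], str] = kozak_classify,
) -> UORFHit:
    """Translate the uORF starting at ``uaug_position``.

    Codons are walked from the uAUG with the standard code.  A stop
    wholly within the UTR terminates the uORF there; otherwise
    translation continues into the downstream CDS when available (the
    hit then overlaps the main ORF) or is flagged truncated.  The
    Kozak ``classifier`` is pluggable so an alternative (e.g.
    plant-specific) consensus can be swapped in.
    """
    utr = utr_record.utr
    if not 1 <= uaug_position <= len(utr) - 2 or utr[uaug_position - 1 : uaug_position + 2] != "ATG":
        raise ValueError(f"position {uaug_position} is not an ATG within the UTR")
    cds = utr_record.downstream_cds or ""
    full = utr + cds
    context = _context_at(full, uaug_position)
    strength = classifier(context)
    peptide_codons: list[str] = []
    status = TRUNCATED
    i = uaug_position - 1
    while i + 3 <= len(full):
        codon = full[i : i + 3]
        if codon in _STOPS:
            # a stop whose codon starts within the UTR ends the uORF there
            status = STOPPED_IN_UTR if i + 3 <= len(utr) else OVERLAPS_MAIN_ORF
            break
        peptide_codons.append(codon)
        i += 3
        if i >= len(utr):
            if not cds:
                status = TRUNCATED
                break
            status = OVERLAPS_MAIN_ORF
    peptide = str(Seq("".join(peptide_codons)).translate()) if peptide_codons else ""
    return UORFHit(utr_record.gene_id, uaug_position, context, strength, peptide, status)


def scan_utr(utr_record: UTRRecord, classifier: Callable[[str], str] = kozak_classify) -> list[UORFHit]:
    """All uORF hits of one UTR, one per uAUG, ascending by position."""
    return [extract_uorf(utr_record, p, classifier) for p in find_uaugs(utr_record)]


@dataclass
class GroupPrevalence:
    group: str
    n_genes: int
    n_with_uaug: int
    percent: float  # exact value; display rounding is up to the caller
    fraction: Fraction
    strength_tally: dict[str, int]


@dataclass
class PrevalenceSummary:
    per_group: list[GroupPrevalence]
    per_gene_counts: dict[str, int]

    def group(self, name: str) -> GroupPrevalence:
        for g in self.per_group:
            if g.group == name:
                return g
        raise KeyError(f"no group {name!r}")


def summarize_prevalence(
    utr_records: Sequence[UTRRecord],
    grouping: Mapping[str, str],
    classifier: Callable[[str], str] = kozak_classify,
) -> PrevalenceSummary:
    """Per-group uORF prevalence and Kozak-strength tallies.

    ``grouping`` maps every gene id to a group name (e.g. eudicot /
    monocot).  Percentages are reported exactly (and as a Fraction)
    alongside the counts; groups are ordered by first appearance.
    """
    missing = [r.gene_id for r in utr_records if r.gene_id not in grouping]
    if missing:
        raise ValueError("genes absent from grouping: " + ", ".join(missing))
    order: list[str] = []
    by_group: dict[str, list[UTRRecord]] = {}
    for rec in utr_records:
        g = grouping[rec.gene_id]
        if g not in by_group:
            by_group[g] = []
            order.append(g)
        by_group[g].append(rec)
    per_gene_counts: dict[str, int] = {}
    groups: list[GroupPrevalence] = []
    for g in order:
        recs = by_group[g]
        tally: Counter[str] = Counter()
        n_with = 0
        for rec in recs:
            hits = scan_utr(rec, classifier)
            per_gene_counts[rec.gene_id] = len(hits)
            if hits:
                n_with += 1
            tally.update(h.strength for h in hits)
        frac = Fraction(n_with, len(recs))
        groups.append(
            GroupPrevalence(
                g,
                len(recs),
                n_with,
                100.0 * float(frac),
                frac,
                {k: tally.get(k, 0) for k in (STRONG, SUB_OPTIMAL, WEAK, INDETERMINATE)},
            )
        )
    return PrevalenceSummary(groups, per_gene_counts)
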