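"""Sequence, alignment and group-manifest I/O.

Every downstream analysis runs on three containers defined here:

``ProteinRecord`` / ``UTRRecord``
    A named, label-tagged ungapped sequence (amino-acid or nucleotide).
``AlignmentMatrix``
    Equal-length gapped rows with bidirectional column <-> residue
    coordinate maps, so any alignment column can be reported in the
    1-based residue numbering of a reference sequence and back.
``GroupPartition``
    The family/taxon labelling of every sequence, with a small label
    expression language ("MHX & vascular", "MHX - {P.patens_1}") used by
    the conservation rules to name subsets of the alignment.

Coordinates are 1-based and intervals closed throughout the package.
Parsing of the standard formats (FASTA, aligned FASTA, Clustal, PHYLIP)
is delegated to Biopython; this module adds validation and the
coordinate arithmetic.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: Sentinel returned by column->residue mapping on a gap cell.
GAP_MARKER = "gap"

_PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class SequenceFormatError(ValueError):
    """Malformed sequence input (bad character, duplicate id, ragged rows)."""


@dataclass(frozen=True)
class ProteinRecord:
    """An ungapped amino-acid sequence with group labels.

    ``labels`` holds free-form group tags such as ``family=MHX`` or
    ``taxon=eudicot``; the manifest loader fills them in.
    """

    id: str
    sequence: str
    labels: frozenset[str] = frozenset()
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceFormatError(f"empty sequence for record {self.id!r}")
        if GAP in self.sequence or "." in self.sequence:
            raise SequenceFormatError(
                f"record {self.id!r} contains gap characters; ungapped sequence expected"
            )
        _check_alphabet(self.id, self.sequence, _PROTEIN_ALPHABET)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UTRRecord:
    """A 5' UTR nucleotide sequence, optionally with its downstream CDS.

    U is normalised to T internally; ``downstream_cds``, when present,
    must begin at the main-ORF ATG.
    """

    gene_id: str
    utr: str
    downstream_cds: str | None = None

    def __post_init__(self) -> None:
        if not self.utr:
            raise SequenceFormatError(f"empty UTR for gene {self.gene_id!r}")
        object.__setattr__(self, "utr", _normalise_nt(self.gene_id, self.utr))
        if self.downstream_cds is not None:
            cds = _normalise_nt(self.gene_id, self.downstream_cds)
            if not cds.startswith("ATG"):
                raise SequenceFormatError(
                    f"downstream CDS of {self.gene_id!r} does not begin with ATG"
                )
            object.__setattr__(self, "downstream_cds", cds)

    def __len__(self) -> int:
        return len(self.utr)


def _normalise_nt(name: str, seq: str) -> str:
    out = seq.upper().replace("U", "T")
    _check_alphabet(name, out, _NUCLEOTIDE_ALPHABET)
    return out


def _check_alphabet(name: str, seq: str, alphabet: frozenset[str]) -> None:
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise SequenceFormatError(
                f"illegal character {ch!r} at position {pos} of {name!r}"
            )


class AlignmentMatrix:
    """Equal-length gapped rows plus column<->residue coordinate maps.

    Rows preserve input order.  For each row the matrix stores the map
    column -> 1-based ungapped residue index (``GAP_MARKER`` on gaps)
    and its inverse; stripping gaps from any row reproduces the stored
    ungapped sequence exactly.
    """

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows length mismatch")
        if not rows:
            raise SequenceFormatError("empty alignment")
        length = len(rows[0])
        ragged = [i for i, r in zip(ids, rows) if len(r) != length]
        if ragged:
            raise SequenceFormatError(
                "alignment rows of unequal length: " + ", ".join(ragged)
            )
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise SequenceFormatError(f"duplicate id {i!r} in alignment")
            seen.add(i)
        self.ids: list[str] = list(ids)
        self.rows: list[str] = [r.upper().replace(".", GAP) for r in rows]
        for i, r in zip(self.ids, self.rows):
            _check_alphabet(i, r.replace(GAP, ""), _PROTEIN_ALPHABET)
        self._index = {sid: k for k, sid in enumerate(self.ids)}
        # col_to_res[k][c0] = residue index (1-based) or 0 for gap
        self._col_to_res: list[list[int]] = []
        self._res_to_col: list[list[int]] = []
        for r in self.rows:
            c2r: list[int] = []
            r2c: list[int] = []
            n = 0
            for c0, ch in enumerate(r):
                if ch == GAP:
                    c2r.append(0)
                else:
                    n += 1
                    c2r.append(n)
                    r2c.append(c0 + 1)
            self._col_to_res.append(c2r)
            self._res_to_col.append(r2c)

    # -- basic introspection -------------------------------------------------

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def row(self, seq_id: str) -> str:
        return self.rows[self._row_index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, column: int) -> str:
        """Residues (including gaps) of 1-based alignment column."""
        if not 1 <= column <= self.n_columns:
            raise IndexError(f"column {column} out of range 1..{self.n_columns}")
        return "".join(r[column - 1] for r in self.rows)

    def _row_index(self, seq_id: str) -> int:
        try:
            return self._index[seq_id]
        except KeyError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    # -- coordinate arithmetic ----------------------------------------------

    def column_to_residue(self, seq_id: str, column: int) -> int | str:
        """1-based residue index at ``column``, or ``GAP_MARKER`` on a gap."""
        k = self._row_index(seq_id)
        if not 1 <= column <= self.n_columns:
            raise IndexError(f"column {column} out of range 1..{self.n_columns}")
        res = self._col_to_res[k][column - 1]
        return res if res else GAP_MARKER

    def residue_to_column(self, seq_id: str, residue: int) -> int:
        """Alignment column holding 1-based residue ``residue``."""
        k = self._row_index(seq_id)
        r2c = self._res_to_col[k]
        if not 1 <= residue <= len(r2c):
            raise IndexError(
                f"residue {residue} out of range 1..{len(r2c)} for {seq_id!r}"
            )
        return r2c[residue - 1]

    def records(self, labels: Mapping[str, frozenset[str]] | None = None) -> list[ProteinRecord]:
        labels = labels or {}
        return [
            ProteinRecord(i, self.ungapped(i), labels.get(i, frozenset()))
            for i in self.ids
        ]


def map_coordinate(
    alignment: AlignmentMatrix, seq_id: str, value: int, direction: str
) -> int | str:
    """Convert between alignment-column and residue coordinates.

    ``direction`` is ``"column_to_residue"`` or ``"residue_to_column"``.
    Column->residue on a gap cell returns :data:`GAP_MARKER`, never a
    number.
    """
    if direction == "column_to_residue":
        return alignment.column_to_residue(seq_id, value)
    if direction == "residue_to_column":
        return alignment.residue_to_column(seq_id, value)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# FASTA reading / writing
# ---------------------------------------------------------------------------


def _as_handle(stream):
    if isinstance(stream, (str, Path)):
        return open(stream), True
    if isinstance(stream, str):  # pragma: no cover - guarded above
        return _stdio.StringIO(stream), True
    return stream, False


def read_sequences(stream, kind: str = "protein"):
    """Read a FASTA stream into records.

    ``kind='protein'`` yields :class:`ProteinRecord`; ``kind='nucleotide'``
    yields :class:`UTRRecord` (U normalised to T).  Case is normalised to
    upper; multi-line entries are concatenated.  Duplicate ids and
    illegal characters raise :class:`SequenceFormatError`.
    """
    if kind not in ("protein", "nucleotide"):
        raise ValueError(f"unknown kind {kind!r}")
    handle, close = _as_handle(stream)
    try:
        raw = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(handle, "fasta")]
    finally:
        if close:
            handle.close()
    seen: set[str] = set()
    out = []
    for rid, seq in raw:
        if rid in seen:
            raise SequenceFormatError(f"duplicate id {rid!r}")
        seen.add(rid)
        if kind == "protein":
            out.append(ProteinRecord(rid, seq))
        else:
            out.append(UTRRecord(rid, seq))
    return out


def read_fasta_text(text: str, kind: str = "protein"):
    """Convenience wrapper: parse FASTA from an in-memory string."""
    return read_sequences(_stdio.StringIO(text), kind)


def write_sequences(records: Iterable[ProteinRecord | UTRRecord], stream, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    handle, close = _as_handle_w(stream)
    try:
        for rec in records:
            if isinstance(rec, UTRRecord):
                rid, seq = rec.gene_id, rec.utr
            else:
                rid, seq = rec.id, rec.sequence
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def _as_handle_w(stream):
    if isinstance(stream, (str, Path)):
        return open(stream, "w"), True
    return stream, False


# ---------------------------------------------------------------------------
# Alignment reading / writing
# ---------------------------------------------------------------------------

_DIALECTS = {"aligned-fasta": "fasta", "clustal": "clustal"}


def read_alignment(stream, dialect: str = "aligned-fasta") -> AlignmentMatrix:
    """Read an alignment in aligned-FASTA or Clustal dialect.

    The Clustal conservation line is ignored; block order defines row
    order.  '.' gaps are converted to '-'.  Rows of unequal length raise
    :class:`SequenceFormatError` naming the offending ids.
    """
    try:
        fmt = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        ) from None
    handle, close = _as_handle(stream)
    try:
        if fmt == "fasta":
            # AlignIO rejects ragged FASTA outright; parse leniently so the
            # error can name the offending rows.
            entries = [(r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]
        else:
            aln = AlignIO.read(handle, fmt)
            entries = [(r.id, str(r.seq)) for r in aln]
    finally:
        if close:
            handle.close()
    if not entries:
        raise SequenceFormatError("empty alignment stream")
    return AlignmentMatrix([e[0] for e in entries], [e[1] for e in entries])


def write_alignment(alignment: AlignmentMatrix, stream, dialect: str = "aligned-fasta") -> None:
    """Write an alignment as aligned-FASTA or (relaxed, sequential) PHYLIP.

    The PHYLIP export exists so alignments can be handed to external
    tree-inference tools; this package never builds trees itself.
    """
    handle, close = _as_handle_w(stream)
    try:
        if dialect == "aligned-fasta":
            for sid, row in zip(alignment.ids, alignment.rows):
                handle.write(f">{sid}\n")
                for i in range(0, len(row), 60):
                    handle.write(row[i : i + 60] + "\n")
        elif dialect == "phylip":
            recs = [
                SeqRecord(Seq(row), id=sid, description="")
                for sid, row in zip(alignment.ids, alignment.rows)
            ]
            AlignIO.write(
                AlignIO.MultipleSeqAlignment(recs), handle, "phylip-relaxed"
            )
        else:
            raise ValueError(f"unknown output dialect {dialect!r}")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Group manifest and label expressions
# ---------------------------------------------------------------------------


@dataclass
class GroupPartition:
    """Family/taxon labelling of every sequence id.

    Each id carries exactly one family label and any number of taxon
    labels.  ``resolve`` evaluates label expressions over the ids:

    * a bare name denotes all ids whose family or any taxon equals it;
    * ``{id1, id2}`` is an explicit id set;
    * ``&`` (or ``∧``) intersection, ``|`` (or ``∨``) union,
      ``-`` (or ``∖``) difference; parentheses group.
    """

    family: dict[str, str] = field(default_factory=dict)
    taxa: dict[str, frozenset[str]] = field(default_factory=dict)

    def add(self, seq_id: str, family: str, taxa: Iterable[str] = ()) -> None:
        if seq_id in self.family:
            raise ValueError(f"duplicate family assignment for id {seq_id!r}")
        self.family[seq_id] = family
        self.taxa[seq_id] = frozenset(taxa)

    @property
    def ids(self) -> list[str]:
        return list(self.family)

    def labels_of(self, seq_id: str) -> frozenset[str]:
        return frozenset({self.family[seq_id]}) | self.taxa[seq_id]

    def members(self, label: str) -> frozenset[str]:
        return frozenset(
            i for i in self.family if label == self.family[i] or label in self.taxa[i]
        )

    def resolve(self, expression: str) -> frozenset[str]:
        return _ExpressionParser(expression, self).parse()

    def validate_against(self, alignment: AlignmentMatrix) -> None:
        missing = [i for i in alignment.ids if i not in self.family]
        if missing:
            raise ValueError(
                "alignment ids absent from manifest: " + ", ".join(missing)
            )


class _ExpressionParser:
    """Recursive-descent parser for group label expressions."""

    _OPS = {"&": "&", "∧": "&", "|": "|", "∨": "|", "-": "-", "∖": "-", "\\": "-"}

    def __init__(self, text: str, partition: GroupPartition):
        self.tokens = self._tokenise(text)
        self.pos = 0
        self.partition = partition
        self.text = text

    def _tokenise(self, text: str) -> list[str]:
        tokens: list[str] = []
        i = 0
        while i < len(text):
            ch = text[i]
            if ch.isspace():
                i += 1
            elif ch in "(){},":
                tokens.append(ch)
                i += 1
            elif ch in self._OPS:
                tokens.append(self._OPS[ch])
                i += 1
            else:
                j = i
                while j < len(text) and not (
                    text[j].isspace() or text[j] in "(){}," or text[j] in self._OPS
                ):
                    j += 1
                tokens.append(text[i:j])
                i = j
        return tokens

    def parse(self) -> frozenset[str]:
        result = self._expr()
        if self.pos != len(self.tokens):
            raise ValueError(f"trailing tokens in expression {self.text!r}")
        return result

    def _peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise ValueError(f"unexpected end of expression {self.text!r}")
        self.pos += 1
        return tok

    def _expr(self) -> frozenset[str]:
        left = self._term()
        while self._peek() in ("&", "|", "-"):
            op = self._next()
            right = self._term()
            if op == "&":
                left = left & right
            elif op == "|":
                left = left | right
            else:
                left = left - right
        return left

    def _term(self) -> frozenset[str]:
        tok = self._next()
        if tok == "(":
            inner = self._expr()
            if self._next() != ")":
                raise ValueError(f"unbalanced parentheses in {self.text!r}")
            return inner
        if tok == "{":
            ids: set[str] = set()
            while True:
                t = self._next()
                if t == "}":
                    break
                if t == ",":
                    continue
                ids.add(t)
            return frozenset(ids)
        members = self.partition.members(tok)
        if not members and tok not in set(self.partition.family.values()) and not any(
            tok in t for t in self.partition.taxa.values()
        ):
            raise ValueError(f"unknown group label {tok!r} in {self.text!r}")
        return members


def load_group_manifest(stream) -> GroupPartition:
    """Load a tab-separated group manifest: ``id<TAB>family<TAB>taxa``.

    ``taxa`` is a comma-separated (possibly empty) list.  Lines starting
    with '#' are comments.  A duplicate id raises ValueError.
    """
    handle, close = _as_handle(stream)
    partition = GroupPartition()
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"manifest line {lineno}: need id and family")
            seq_id, family = parts[0].strip(), parts[1].strip()
            taxa = []
            if len(parts) > 2 and parts[2].strip():
                taxa = [t.strip() for t in parts[2].split(",") if t.strip()]
            partition.add(seq_id, family, taxa)
    finally:
        if close:
            handle.close()
    return partition


def write_group_manifest(partition: GroupPartition, stream) -> None:
    handle, close = _as_handle_w(stream)
    try:
        handle.write("# id\tfamily\ttaxa\n")
        for sid in partition.ids:
            taxa = ",".join(sorted(partition.taxa[sid]))
            handle.write(f"{sid}\t{partition.family[sid]}\t{taxa}\n")
    finally:
        if close:
            handle.close()
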