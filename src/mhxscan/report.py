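"""Annotated-alignment reports in text and HTML.

Rendering is a pure presentation layer: category calls come from a
:class:`~mhxscan.conservation.ColumnClassification` computed upstream
and are never recomputed here.  The text rendering uses bracketed
category codes (diff-friendly); the HTML rendering colours residues by
the same precedence-resolved calls, underlines transmembrane spans,
and emits the rule legend.  Every emitted file opens with provenance
headers (parameter values and input checksums).
"""

from __future__ import annotations

import hashlib
import html as _html
from dataclasses import dataclass
from typing import Mapping, Sequence

from .conservation import ColumnClassification
from .io import GAP, AlignmentMatrix
from .topology import ProjectedRegion

#: Display precedence (first wins) and colours for the standard rule set.
DEFAULT_PRECEDENCE: tuple[str, ...] = (
    "red",
    "pink",
    "light_green",
    "orange",
    "dark_green",
    "olive",
    "gray",
)

_COLOURS: Mapping[str, str] = {
    "red": "#e41a1c",
    "pink": "#f781bf",
    "light_green": "#7fc97f",
    "orange": "#ff7f00",
    "dark_green": "#1b7837",
    "olive": "#808000",
    "gray": "#999999",
}

_CODES: Mapping[str, str] = {
    "red": "R",
    "pink": "P",
    "light_green": "L",
    "orange": "O",
    "dark_green": "D",
    "olive": "V",
    "gray": "G",
}


def _precedence(rules_at: Sequence[str], precedence: Sequence[str]) -> str | None:
    for name in precedence:
        if name in rules_at:
            return name
    return rules_at[0] if rules_at else None


def _winning_rules(
    classification: ColumnClassification, n_columns: int, precedence: Sequence[str]
) -> list[str | None]:
    per_column: dict[int, list[str]] = {}
    for m in classification.matches:
        per_column.setdefault(m.column, [])
    for col in per_column:
        per_column[col] = classification.rules_at(col)
    return [
        _precedence(per_column.get(c, []), precedence) for c in range(1, n_columns + 1)
    ]


def provenance_lines(params: Mapping[str, object], checksums: Mapping[str, str]) -> list[str]:
    lines = [f"parameter {k}={v}" for k, v in sorted(params.items())]
    lines += [f"input sha256 {name}={digest}" for name, digest in sorted(checksums.items())]
    return lines


def checksum_of(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


@dataclass
class AnnotatedAlignment:
    text: str
    html: str


def render_annotated_alignment(
    alignment: AlignmentMatrix,
    classification: ColumnClassification,
    topology: Mapping[str, list[ProjectedRegion]] | None = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    width: int = 60,
    provenance: Mapping[str, object] | None = None,
) -> AnnotatedAlignment:
    """Render category calls over the alignment, as text and HTML.

    Both renderings encode identical per-column winning-rule calls.
    Text marks a classified column by wrapping the residue in brackets
    with a one-letter rule code (``[R:G]``); HTML colours it.  When a
    projected topology is supplied, transmembrane spans are underlined
    per row.
    """
    if classification.n_columns not in (0, alignment.n_columns):
        raise ValueError("classification does not refer to this alignment")
    winners = _winning_rules(classification, alignment.n_columns, precedence)
    tm_cols: dict[str, set[int]] = {}
    if topology:
        for sid, regions in topology.items():
            cols: set[int] = set()
            for r in regions:
                if r.name.upper().startswith("TMS") and not r.empty:
                    c1 = alignment.residue_to_column(sid, r.start)
                    c2 = alignment.residue_to_column(sid, r.end)
                    cols.update(range(c1, c2 + 1))
            tm_cols[sid] = cols

    # -- text ---------------------------------------------------------------
    text_lines: list[str] = []
    head_params = dict(provenance or {})
    head_params.setdefault("precedence", ">".join(precedence))
    for line in provenance_lines(head_params, {}):
        text_lines.append(f"# {line}")
    legend = ", ".join(f"[{_CODES.get(r.name, r.name[0].upper())}]={r.name}" for r in classification.rules)
    text_lines.append(f"# legend: {legend}")
    for block_start in range(0, alignment.n_columns, width):
        cols = range(block_start + 1, min(block_start + width, alignment.n_columns) + 1)
        for sid in alignment.ids:
            row = alignment.row(sid)
            cells = []
            for c in cols:
                ch = row[c - 1]
                rule = winners[c - 1]
                if rule and ch != GAP:
                    cells.append(f"[{_CODES.get(rule, rule[0].upper())}:{ch}]")
                else:
                    cells.append(ch)
            text_lines.append(f"{sid:<20s} {''.join(cells)}")
        text_lines.append("")
    text = "\n".join(text_lines)

    # -- html ---------------------------------------------------------------
    h: list[str] = ["<!DOCTYPE html><html><head><meta charset='utf-8'><style>"]
    h.append("body{font-family:monospace;white-space:pre}")
    h.append(".tm{text-decoration:underline}")
    for name, colour in _COLOURS.items():
        h.append(f".{name}{{background:{colour};color:white}}")
    h.append("</style></head><body>")
    for line in provenance_lines(head_params, {}):
        h.append(f"<!-- {_html.escape(line)} -->")
    h.append("<div class='legend'>")
    for r in classification.rules:
        cls = r.name if r.name in _COLOURS else "gray"
        h.append(f"<span class='{cls}'>&nbsp;{_html.escape(r.name)}&nbsp;</span> ")
    h.append("</div>")
    for block_start in range(0, alignment.n_columns, width):
        cols = range(block_start + 1, min(block_start + width, alignment.n_columns) + 1)
        for sid in alignment.ids:
            row = alignment.row(sid)
            cells = [f"{_html.escape(sid):<20s} ".replace(" ", "&nbsp;")]
            for c in cols:
                ch = _html.escape(row[c - 1])
                classes = []
                rule = winners[c - 1]
                if rule and row[c - 1] != GAP:
                    classes.append(rule if rule in _COLOURS else "gray")
                if c in tm_cols.get(sid, ()):
                    classes.append("tm")
                if classes:
                    cells.append(f"<span class='{' '.join(classes)}'>{ch}</span>")
                else:
                    cells.append(ch)
            h.append("".join(cells) + "<br>")
        h.append("<br>")
    h.append("</body></html>")
    return AnnotatedAlignment(text, "\n".join(h))


def category_calls(
    classification: ColumnClassification, n_columns: int, precedence: Sequence[str] = DEFAULT_PRECEDENCE
) -> list[str | None]:
    """The per-column winning rule names both renderings encode."""
    return _winning_rules(classification, n_columns, precedence)
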