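"""Membrane topology models, projection, and hydropathy profiling.

The structural frame of reference is the biochemically mapped NCX1
topology: nine transmembrane segments (TMS1-9), two reentrant loops
that dip into the membrane without crossing it, connecting loops a-f
(loop d being the large regulatory cytosolic loop carrying the XIP
peptide and the CBD1/CBD2 Ca2+-binding domains), and the α1/α2 repeat
overlays.  A :class:`TopologyModel` stores these regions as 1-based
closed intervals on one reference sequence; :func:`project_topology`
carries them through an alignment onto any other family member.

Orientation semantics: ``in`` means cytosolic for both plasma-membrane
and tonoplast proteins; the vacuolar lumen plays the role of the
extracellular space (``out``), as the two compartments share pH and
electrochemical-potential polarity.

Hydropathy profiling uses a sliding-window mean of Kyte–Doolittle
residue values (window 19 by default).  The transmembrane-segment
caller built on it is a deliberately simple threshold method for
qualitative profile comparison — authoritative region coordinates come
from the reference topology model, not from prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .io import GAP, AlignmentMatrix

CORE_REGION_NAMES = (
    ["N-ter"]
    + [
        "TMS1", "loop a", "TMS2", "RE-loop1", "loop b", "TMS3", "loop c",
        "TMS4", "TMS5", "loop d", "TMS6", "loop e", "TMS7", "RE-loop2",
        "TMS8", "loop f", "TMS9", "C-ter",
    ]
)

OVERLAY_NAMES = ("alpha1", "alpha2", "XIP", "CBD1", "CBD2", "signal-peptide")

ACIDIC = frozenset("DE")
BASIC = frozenset("KRH")
BASIC_NO_HIS = frozenset("KR")


@dataclass(frozen=True)
class Region:
    name: str
    start: int
    end: int
    orientation: str | None = None  # in | out | None (TMS / membrane)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region {self.name!r}: end < start")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class TopologyModel:
    """Ordered core regions (tiling the reference) plus overlays.

    ``signal_peptide_length`` makes the precursor/mature numbering
    conversion explicit for references whose literature coordinates
    refer to the mature protein.
    """

    reference_id: str
    regions: list[Region]
    overlays: list[Region] = field(default_factory=list)
    signal_peptide_length: int = 0

    def __post_init__(self) -> None:
        prev_end = 0
        for r in self.regions:
            if r.start != prev_end + 1:
                raise ValueError(
                    f"core regions must tile the reference: {r.name!r} starts at "
                    f"{r.start}, expected {prev_end + 1}"
                )
            prev_end = r.end
        self.length = prev_end

    def region(self, name: str) -> Region:
        for r in self.regions + self.overlays:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r}")

    def core_intervals(self) -> list[tuple[str, int, int]]:
        return [(r.name, r.start, r.end) for r in self.regions]

    def mature_to_precursor(self, position: int) -> int:
        return position + self.signal_peptide_length

    def precursor_to_mature(self, position: int) -> int:
        return position - self.signal_peptide_length

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        enc = lambda r: {
            "name": r.name,
            "start": r.start,
            "end": r.end,
            **({"orientation": r.orientation} if r.orientation else {}),
        }
        return {
            "reference_id": self.reference_id,
            "signal_peptide_length": self.signal_peptide_length,
            "regions": [enc(r) for r in self.regions],
            "overlays": [enc(r) for r in self.overlays],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping) -> "TopologyModel":
        dec = lambda d: Region(
            d["name"], int(d["start"]), int(d["end"]), d.get("orientation")
        )
        return cls(
            reference_id=data["reference_id"],
            regions=[dec(d) for d in data["regions"]],
            overlays=[dec(d) for d in data.get("overlays", [])],
            signal_peptide_length=int(data.get("signal_peptide_length", 0)),
        )

    @classmethod
    def load(cls, path) -> "TopologyModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProjectedRegion:
    name: str
    target_id: str
    start: int | None
    end: int | None
    orientation: str | None = None

    @property
    def empty(self) -> bool:
        return self.start is None

    def __len__(self) -> int:
        return 0 if self.empty else self.end - self.start + 1


def project_topology(
    model: TopologyModel,
    alignment: AlignmentMatrix,
    target_ids: Iterable[str] | None = None,
) -> dict[str, list[ProjectedRegion]]:
    """Map the model's regions through the alignment onto targets.

    Each region's reference interval is converted to an alignment
    column span, then to the target's residues aligned within that
    span.  Regions where the target is entirely gapped yield an empty
    (flagged) interval.  Core regions of each target remain ordered and
    non-overlapping.
    """
    if model.reference_id not in alignment:
        raise KeyError(f"reference {model.reference_id!r} absent from alignment")
    ref_len = len(alignment.ungapped(model.reference_id))
    if model.length != ref_len:
        raise ValueError(
            f"model covers {model.length} residues but reference has {ref_len}"
        )
    targets = list(target_ids) if target_ids is not None else list(alignment.ids)
    out: dict[str, list[ProjectedRegion]] = {}
    for tid in targets:
        projected: list[ProjectedRegion] = []
        for r in model.regions + model.overlays:
            c1 = alignment.residue_to_column(model.reference_id, r.start)
            c2 = alignment.residue_to_column(model.reference_id, r.end)
            row = alignment.row(tid)
            first = last = None
            for c in range(c1, c2 + 1):
                if row[c - 1] != GAP:
                    res = alignment.column_to_residue(tid, c)
                    if first is None:
                        first = res
                    last = res
            projected.append(ProjectedRegion(r.name, tid, first, last, r.orientation))
        out[tid] = projected
    return out


# ---------------------------------------------------------------------------
# Hydropathy
# ---------------------------------------------------------------------------

SCALES: dict[str, Mapping[str, float]] = {"kyte-doolittle": dict(_KYTE_DOOLITTLE)}


@dataclass
class HydropathyProfile:
    sequence_id: str
    window: int
    scale: str
    values: np.ndarray  # length = len(sequence) - window + 1

    def midpoints(self) -> np.ndarray:
        """1-based residue positions of the window centres."""
        half = self.window // 2
        return np.arange(1 + half, 1 + half + len(self.values))


def hydropathy_profile(
    sequence: str,
    window: int = 19,
    scale: str = "kyte-doolittle",
    sequence_id: str = "",
) -> HydropathyProfile:
    """Sliding-window mean hydropathy of a sequence.

    ``window`` must be odd and no longer than the sequence.  'X'
    residues contribute the scale's mean value.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(sequence):
        raise ValueError("window longer than sequence")
    table = SCALES[scale]
    fallback = sum(table.values()) / len(table)
    vals = np.array([table.get(ch, fallback) for ch in sequence.upper()], dtype=float)
    kernel = np.ones(window) / window
    profile = np.convolve(vals, kernel, mode="valid")
    return HydropathyProfile(sequence_id, window, scale, profile)


@dataclass(frozen=True)
class TMSegment:
    start: int  # 1-based residue coordinates of the window-midpoint run
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1


def predict_tm_segments(
    profile: HydropathyProfile,
    threshold: float = 1.6,
    min_len: int = 9,
    max_len: int = 25,
) -> list[TMSegment]:
    """Threshold the profile into candidate transmembrane segments.

    Maximal runs of window midpoints whose mean hydropathy exceeds
    ``threshold`` are reported in residue coordinates; runs shorter
    than ``min_len`` are dropped, runs longer than ``max_len`` are split
    into consecutive pieces of at most ``max_len`` (a trailing piece
    shorter than ``min_len`` is merged into its neighbour).  Output
    intervals are ordered and non-overlapping.
    """
    mids = profile.midpoints()
    above = profile.values > threshold
    segments: list[TMSegment] = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        start, end = int(mids[i]), int(mids[j - 1])
        length = end - start + 1
        if length >= min_len:
            if length <= max_len:
                segments.append(TMSegment(start, end))
            else:
                pieces = math.ceil(length / max_len)
                base = length // pieces
                extra = length % pieces
                s = start
                for k in range(pieces):
                    ln = base + (1 if k < extra else 0)
                    segments.append(TMSegment(s, s + ln - 1))
                    s += ln
        i = j
    return segments


# ---------------------------------------------------------------------------
# Charge scans and residue-class counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChargeWindow:
    start: int
    end: int
    count: int


def scan_charge_density(
    sequence: str,
    interval: tuple[int, int],
    sign: str = "acidic",
    window: int = 15,
    min_count: int = 5,
    include_histidine: bool = True,
) -> list[ChargeWindow]:
    """Find charge-dense stretches inside ``interval``.

    Every window of ``window`` residues within the 1-based closed
    ``interval`` containing at least ``min_count`` residues of the
    signed class (acidic {D,E}; basic {K,R} plus H unless disabled) is
    collected; overlapping hits are merged into maximal intervals,
    each reported with its signed-residue count.
    """
    start, end = interval
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError(f"interval {interval} out of sequence bounds")
    if window > end - start + 1:
        raise ValueError("window longer than interval")
    if sign == "acidic":
        cls = ACIDIC
    elif sign == "basic":
        cls = BASIC if include_histidine else BASIC_NO_HIS
    else:
        raise ValueError(f"unknown sign {sign!r}")
    seq = sequence.upper()
    hits: list[tuple[int, int]] = []
    for s in range(start, end - window + 2):
        e = s + window - 1
        if sum(1 for ch in seq[s - 1 : e] if ch in cls) >= min_count:
            hits.append((s, e))
    merged: list[ChargeWindow] = []
    for s, e in hits:
        if merged and s <= merged[-1].end + 1:
            prev = merged[-1]
            ne = max(prev.end, e)
            merged[-1] = ChargeWindow(
                prev.start, ne, sum(1 for ch in seq[prev.start - 1 : ne] if ch in cls)
            )
        else:
            merged.append(
                ChargeWindow(s, e, sum(1 for ch in seq[s - 1 : e] if ch in cls))
            )
    return merged


def count_residues_of_class(
    sequence: str, interval: tuple[int, int], class_set: Iterable[str]
) -> int:
    """Count residues of ``class_set`` within a 1-based closed interval."""
    start, end = interval
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError(f"interval {interval} out of sequence bounds")
    cls = frozenset(c.upper() for c in class_set)
    return sum(1 for ch in sequence.upper()[start - 1 : end] if ch in cls)


def molecular_weight(sequence: str) -> float:
    """Average-isotopic molecular weight of a peptide in Da.

    Sum of residue masses plus one water; 'X' is an error because it
    has no defined mass.
    """
    seq = sequence.upper()
    if "X" in seq:
        raise ValueError("cannot compute molecular weight of a sequence containing 'X'")
    return float(_bio_molecular_weight(seq, seq_type="protein"))
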