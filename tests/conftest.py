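"""Shared fixtures: small hand-built alignments and one generated family."""

import pytest

from mhxscan.io import AlignmentMatrix, GroupPartition
from mhxscan.simulate import default_family_spec, default_utr_spec, generate_family, generate_utrs


@pytest.fixture
def toy_alignment() -> AlignmentMatrix:
    """Six rows, 10 columns, with a gap and planted structure.

    Columns (1-based):
      1: all G (conserved everywhere)
      2: MHX=A vs NCX=S (strict differential)
      3: MHX=L, NCX mixed {L, F} (blocks both modes)
      4: MHX=K, NCX = {R, N} (disjoint differential)
      5: free
      6-8: conserved-in-MHX run (D, W, P); NCX breaks each
      9: gap in mhx3
      10: X in mhx1
    """
    rows = {
        "mhx1": "GALKADWPAX",
        "mhx2": "GALKCDWPAA",
        "mhx3": "GALKDDWP-A",
        "mhx4": "GALKEDWPAA",
        "ncx1": "GSLRFDYPAA",
        "ncx2": "GSFNAEWGAA",
    }
    return AlignmentMatrix(list(rows), list(rows.values()))


@pytest.fixture
def toy_partition() -> GroupPartition:
    p = GroupPartition()
    for i in range(1, 5):
        p.add(f"mhx{i}", "MHX", ["plant"])
    for i in range(1, 3):
        p.add(f"ncx{i}", "NCX", ["animal"])
    return p


@pytest.fixture(scope="session")
def family():
    """Default zero-noise study family (30 sequences x 550 residues)."""
    return generate_family(default_family_spec(101))


@pytest.fixture(scope="session")
def noisy_family():
    """The same study conditions with 10% background column noise."""
    return generate_family(default_family_spec(101, noise_rate=0.10))


@pytest.fixture(scope="session")
def indel_family():
    """Study family with generator-chosen indels in non-reference rows."""
    return generate_family(default_family_spec(101, auto_indels=8))


@pytest.fixture(scope="session")
def utr_set():
    spec = default_utr_spec(101)
    records, truth = generate_utrs(spec)
    return spec, records, truth
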