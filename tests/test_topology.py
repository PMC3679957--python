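"""Topology models, projection, hydropathy, charge scans, masses."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhxscan.io import AlignmentMatrix
from mhxscan.topology import (
    SCALES,
    Region,
    TopologyModel,
    count_residues_of_class,
    hydropathy_profile,
    molecular_weight,
    predict_tm_segments,
    project_topology,
    scan_charge_density,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


class TestTopologyModel:
    def test_core_regions_must_tile(self):
        with pytest.raises(ValueError, match="tile"):
            TopologyModel("r", [Region("N-ter", 1, 5), Region("TMS1", 7, 10)])

    def test_yaml_round_trip(self, tmp_path, family):
        _, truth = family
        p = tmp_path / "model.yaml"
        truth.topology.save(p)
        back = TopologyModel.load(p)
        assert back.to_dict() == truth.topology.to_dict()

    def test_precursor_mature_conversion(self):
        m = TopologyModel("r", [Region("N-ter", 1, 10)], signal_peptide_length=32)
        assert m.mature_to_precursor(1) == 33
        assert m.precursor_to_mature(33) == 1


class TestProjection:
    def test_projection_onto_reference_is_identity(self, family):
        _, truth = family
        proj = project_topology(truth.topology, truth.alignment, [truth.reference_id])
        for r, model_r in zip(proj[truth.reference_id], truth.topology.regions):
            assert (r.start, r.end) == (model_r.start, model_r.end)

    def test_projection_with_indels_matches_generator_truth(self, indel_family):
        _, truth = indel_family
        proj = project_topology(truth.topology, truth.alignment)
        region_names = {r.name for r in truth.topology.regions}
        for sid, regions in proj.items():
            for r in regions:
                if r.name not in region_names:
                    continue  # overlays are not in the tiling truth
                expected = truth.projected_regions[sid][r.name]
                got = None if r.empty else (r.start, r.end)
                assert got == expected, (sid, r.name)

    def test_projected_core_regions_tile_each_target(self, indel_family):
        _, truth = indel_family
        proj = project_topology(truth.topology, truth.alignment)
        core = [r.name for r in truth.topology.regions]
        for sid, regions in proj.items():
            intervals = [
                (r.start, r.end) for r in regions if r.name in core and not r.empty
            ]
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 < s2  # ordered, non-overlapping

    def test_missing_reference_rejected(self, family):
        _, truth = family
        other = AlignmentMatrix(["x"], ["MKVLW"])
        with pytest.raises(KeyError):
            project_topology(truth.topology, other)


class TestHydropathy:
    def test_window_one_returns_scale_values(self):
        table = SCALES["kyte-doolittle"]
        prof = hydropathy_profile("MKWIV", window=1)
        assert list(prof.values) == [table[c] for c in "MKWIV"]

    def test_homopolymer_profile_is_constant(self):
        prof = hydropathy_profile("I" * 30, window=7)
        assert all(abs(v - SCALES["kyte-doolittle"]["I"]) < 1e-12 for v in prof.values)

    def test_matches_naive_recomputation_on_random_sequences(self):
        """Sliding mean equals position-by-position recomputation."""
        table = SCALES["kyte-doolittle"]
        rng = random.Random(13)
        for _ in range(25):
            seq = "".join(rng.choice(AAS) for _ in range(60))
            w = rng.choice([3, 5, 7, 9, 19])
            prof = hydropathy_profile(seq, window=w)
            for i, got in enumerate(prof.values):
                naive = sum(table[c] for c in seq[i : i + w]) / w
                assert abs(got - naive) < 1e-9

    def test_reversed_sequence_reverses_profile(self):
        rng = random.Random(5)
        seq = "".join(rng.choice(AAS) for _ in range(40))
        fwd = hydropathy_profile(seq, window=5).values
        rev = hydropathy_profile(seq[::-1], window=5).values
        assert list(rev) == pytest.approx(list(fwd[::-1]), abs=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_profile("MKWIV" * 4, window=4)


class TestTMPrediction:
    def test_all_below_threshold_is_empty(self):
        prof = hydropathy_profile("K" * 40, window=9)
        assert predict_tm_segments(prof) == []

    def test_planted_hydrophobic_stretch_is_recovered(self):
        seq = "K" * 40 + "I" * 21 + "K" * 40
        prof = hydropathy_profile(seq, window=9)
        segs = predict_tm_segments(prof, threshold=1.6, min_len=9, max_len=30)
        assert len(segs) == 1
        planted = set(range(41, 62))
        got = set(range(segs[0].start, segs[0].end + 1))
        assert len(got & planted) / len(planted) >= 0.8

    def test_two_separated_stretches_give_two_segments(self):
        seq = "K" * 30 + "I" * 21 + "KDKDE" * 4 + "L" * 21 + "K" * 30
        prof = hydropathy_profile(seq, window=9)
        segs = predict_tm_segments(prof, threshold=1.6, min_len=9, max_len=30)
        assert len(segs) == 2
        assert segs[0].end < segs[1].start

    def test_default_family_tm_segments_overlap_planted(self, family):
        """Each planted hydrophobic TMS is hit by a predicted segment."""
        _, truth = family
        ref = truth.alignment.ungapped(truth.reference_id)
        prof = hydropathy_profile(ref, window=19)
        segs = predict_tm_segments(prof, threshold=1.6, min_len=9, max_len=30)
        covered = set()
        for s in segs:
            covered.update(range(s.start, s.end + 1))
        for start, end in truth.tm_segments:
            planted = set(range(start, end + 1))
            assert len(planted & covered) / len(planted) >= 0.5, (start, end)

    def test_segments_never_overlap_and_respect_bounds(self, family):
        _, truth = family
        for sid in truth.alignment.ids[:5]:
            seq = truth.alignment.ungapped(sid)
            prof = hydropathy_profile(seq, window=19)
            segs = predict_tm_segments(prof, threshold=1.0, min_len=5, max_len=20)
            for a, b in zip(segs, segs[1:]):
                assert a.end < b.start
            for s in segs:
                assert 5 <= len(s) <= 20


class TestChargeScan:
    def test_poly_d_interval_is_one_window(self):
        hits = scan_charge_density("D" * 30, (1, 30), "acidic", window=10, min_count=5)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 30)

    def test_charge_free_interval_is_empty(self):
        assert scan_charge_density("G" * 30, (1, 30), "acidic", window=10, min_count=2) == []

    def test_matches_exhaustive_enumeration_on_random_sequences(self):
        rng = random.Random(99)
        for _ in range(25):
            seq = "".join(rng.choice(AAS) for _ in range(60))
            w, mc = rng.choice([(8, 3), (10, 4), (15, 5)])
            got = scan_charge_density(seq, (1, 60), "acidic", window=w, min_count=mc)
            qualifying = [
                (s, s + w - 1)
                for s in range(1, 60 - w + 2)
                if sum(1 for ch in seq[s - 1 : s + w - 1] if ch in "DE") >= mc
            ]
            merged = []
            for s, e in qualifying:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            assert [(h.start, h.end) for h in got] == merged

    def test_histidine_toggle_for_basic_class(self):
        seq = "HHHHHKRHHH"
        with_h = scan_charge_density(seq, (1, 10), "basic", window=5, min_count=5)
        without = scan_charge_density(
            seq, (1, 10), "basic", window=5, min_count=5, include_histidine=False
        )
        assert with_h and not without


class TestResidueCountsAndMass:
    def test_empty_class_counts_zero(self):
        assert count_residues_of_class("MKVLW", (1, 5), []) == 0

    def test_basic_count_in_overlay_interval(self, family):
        _, truth = family
        xip = truth.topology.region("XIP")
        ref = truth.alignment.ungapped(truth.reference_id)
        n = count_residues_of_class(ref, (xip.start, xip.end), "KRH")
        manual = sum(1 for ch in ref[xip.start - 1 : xip.end] if ch in "KRH")
        assert n == manual

    def test_single_glycine_is_free_glycine_mass(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_diglycine_mass(self):
        assert molecular_weight("GG") == pytest.approx(132.12, abs=0.01)

    def test_antibody_peptide_mass_against_independent_table(self):
        """17-mer peptide cross-checked against a second residue-mass table."""
        residue_masses = {  # average masses of amino-acid residues, Da
            "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
            "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
            "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
            "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
            "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
        }
        peptide = "CEEIDTSKDDNDNDVHD"
        expected = sum(residue_masses[c] for c in peptide) + 18.0153
        assert molecular_weight(peptide) == pytest.approx(expected, abs=0.5)

    def test_x_residue_rejected(self):
        with pytest.raises(ValueError):
            molecular_weight("GXG")


@settings(max_examples=60, deadline=None)
@given(
    a=st.text(alphabet=AAS, min_size=1, max_size=20),
    b=st.text(alphabet=AAS, min_size=1, max_size=20),
)
def test_molecular_weight_is_additive(a, b):
    """MW(a+b) = MW(a) + MW(b) - one water mass (peptide-bond loss)."""
    water = 18.0153
    assert molecular_weight(a + b) == pytest.approx(
        molecular_weight(a) + molecular_weight(b) - water, abs=0.01
    )
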