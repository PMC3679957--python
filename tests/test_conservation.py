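"""Column classification, differential scanning, runs, region stats,
and pairwise scores — checked against planted truth and a DP oracle."""

import random

import pytest
from Bio.Align import substitution_matrices

from mhxscan.conservation import (
    ConservationRule,
    PairwiseParams,
    classify_columns,
    conserved_residue_composition,
    find_conserved_runs,
    find_differential_sites,
    pairwise_percent_score,
    region_conservation_stats,
)

# ---------------------------------------------------------------------------
# Independent oracle: Gotoh affine-gap DP maximising (score, identities)
# lexicographically.  First gap position costs `open`, later ones `extend`.
# ---------------------------------------------------------------------------

NEG = (float("-inf"), 0)


def gotoh_best_score_and_identities(a, b, score_fn, gap_open, gap_extend):
    n, m = len(a), len(b)

    def add(v, ds, di):
        return (v[0] + ds, v[1] + di) if v[0] != float("-inf") else NEG

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = (0.0, 0)
    for i in range(1, n + 1):
        X[i][0] = (-gap_open - (i - 1) * gap_extend, 0)
    for j in range(1, m + 1):
        Y[0][j] = (-gap_open - (j - 1) * gap_extend, 0)
    for i in range(n + 1):
        for j in range(m + 1):
            if i and j:
                ds = score_fn(a[i - 1], b[j - 1])
                di = 1 if a[i - 1] == b[j - 1] else 0
                prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                M[i][j] = add(prev, ds, di)
                X[i][j] = max(
                    add(M[i - 1][j], -gap_open, 0),
                    add(X[i - 1][j], -gap_extend, 0),
                    add(Y[i - 1][j], -gap_open, 0),
                )
                Y[i][j] = max(
                    add(M[i][j - 1], -gap_open, 0),
                    add(Y[i][j - 1], -gap_extend, 0),
                    add(X[i][j - 1], -gap_open, 0),
                )
    return max(M[n][m], X[n][m], Y[n][m])


class TestPairwiseScore:
    def test_identical_sequences_score_100(self):
        assert pairwise_percent_score("MKTAYIAKQR", "MKTAYIAKQR") == 100

    def test_fully_mismatched_sequences_score_0(self):
        params = PairwiseParams(matrix=None, match=1, mismatch=-1, gap_open=2, gap_extend=0.5)
        assert pairwise_percent_score("AAAA", "CCCC", params) == 0

    def test_symmetry(self):
        rng = random.Random(7)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(aas) for _ in range(rng.randrange(4, 12)))
            b = "".join(rng.choice(aas) for _ in range(rng.randrange(4, 12)))
            assert pairwise_percent_score(a, b) == pairwise_percent_score(b, a)

    def test_matches_affine_dp_oracle_on_random_pairs(self):
        """100 random <=12-mer pairs against the lexicographic Gotoh DP."""
        blosum = substitution_matrices.load("BLOSUM62")
        rng = random.Random(42)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(100):
            a = "".join(rng.choice(aas) for _ in range(rng.randrange(1, 13)))
            b = "".join(rng.choice(aas) for _ in range(rng.randrange(1, 13)))
            _, ident = gotoh_best_score_and_identities(
                a, b, lambda x, y: float(blosum[x][y]), 10.0, 0.1
            )
            expected = int((100.0 * ident / min(len(a), len(b))) + 0.5)
            assert pairwise_percent_score(a, b) == expected, (a, b)


class TestClassifyColumns:
    def rules(self):
        return [
            ConservationRule("red", "MHX | NCX"),
            ConservationRule("light_green", "MHX"),
            ConservationRule("strict_diff", "MHX", "NCX", "strict"),
            ConservationRule("disjoint_diff", "MHX", "NCX", "disjoint"),
        ]

    def test_toy_alignment_calls(self, toy_alignment, toy_partition):
        cls = classify_columns(toy_alignment, toy_partition, self.rules(), "mhx2")
        assert cls.columns_matching("red") == [1]
        # gap (col 9) and X (col 10) disqualify conservation
        assert cls.columns_matching("light_green") == [1, 2, 3, 4, 6, 7, 8]
        assert cls.columns_matching("strict_diff") == [2]
        assert cls.columns_matching("disjoint_diff") == [2, 4]

    def test_reference_positions_reported(self, toy_alignment, toy_partition):
        cls = classify_columns(toy_alignment, toy_partition, self.rules(), "mhx3")
        by_col = {m.column: m.reference_position for m in cls.matches_for("light_green")}
        assert by_col[8] == 8
        # mhx3 has its gap at column 9, so later columns shift
        assert toy_alignment.column_to_residue("mhx3", 10) == 9

    def test_zero_noise_family_recovers_planted_columns_exactly(self, family):
        _, truth = family
        rules = [
            ConservationRule("red", "MHX | NCX"),
            ConservationRule("light_green", "MHX"),
        ]
        cls = classify_columns(truth.alignment, truth.partition, rules, truth.reference_id)
        assert cls.columns_matching("red") == truth.conserved_all_columns
        assert cls.columns_matching("light_green") == truth.family_conserved_columns

    def test_rule_monotonicity_enlarging_subset_shrinks_matches(self, family):
        """Adding the outgroup to conserved_in can only remove columns."""
        _, truth = family
        narrow = classify_columns(
            truth.alignment, truth.partition, [ConservationRule("c", "MHX")]
        )
        wide = classify_columns(
            truth.alignment, truth.partition, [ConservationRule("c", "MHX | NCX")]
        )
        assert set(wide.columns_matching("c")) <= set(narrow.columns_matching("c"))

    def test_composition_counts_sum_to_matches(self, family):
        _, truth = family
        cls = classify_columns(
            truth.alignment, truth.partition, [ConservationRule("red", "MHX | NCX")]
        )
        comp = conserved_residue_composition(cls, "red")
        assert sum(comp.values()) == len(truth.conserved_all_columns)
        # the generator plants a fixed glycine share among fully conserved sites
        assert comp.get("G", 0) >= truth.spec.n_conserved_all_glycines

    def test_unknown_rule_rejected(self, toy_alignment, toy_partition):
        cls = classify_columns(toy_alignment, toy_partition, self.rules())
        with pytest.raises(KeyError):
            conserved_residue_composition(cls, "nope")


class TestDifferentialSites:
    def test_identical_groups_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="overlap"):
            find_differential_sites(toy_alignment, ["mhx1"], ["mhx1"])

    def test_strict_sites_are_subset_of_disjoint_sites(self, family):
        _, truth = family
        mhx = truth.partition.members("MHX")
        ncx = truth.partition.members("NCX")
        strict = {s.column for s in find_differential_sites(truth.alignment, mhx, ncx, "strict")}
        disjoint = {s.column for s in find_differential_sites(truth.alignment, mhx, ncx, "disjoint")}
        assert strict <= disjoint

    def test_planted_sites_recovered_exactly(self, family):
        _, truth = family
        mhx = truth.partition.members("MHX")
        ncx = truth.partition.members("NCX")
        for mode in ("strict", "disjoint"):
            found = [s.column for s in find_differential_sites(truth.alignment, mhx, ncx, mode)]
            assert found == truth.expected_sites("MHX", "NCX", mode)

    def test_taxon_level_disjoint_sites_recovered(self, family):
        _, truth = family
        vas = truth.partition.resolve("vascular")
        bry = truth.partition.resolve("bryophyte")
        found = [s.column for s in find_differential_sites(truth.alignment, vas, bry, "disjoint")]
        assert found == truth.expected_sites("vascular", "bryophyte", "disjoint")

    def test_noise_never_corrupts_planted_strict_sites(self, noisy_family):
        _, truth = noisy_family
        assert truth.noised_columns  # noise did land somewhere
        mhx = truth.partition.members("MHX")
        ncx = truth.partition.members("NCX")
        found = [s.column for s in find_differential_sites(truth.alignment, mhx, ncx, "strict")]
        assert found == truth.expected_sites("MHX", "NCX", "strict")


class TestConservedRuns:
    def test_single_sequence_subset_yields_whole_sequence(self, toy_alignment):
        runs = find_conserved_runs(toy_alignment, ["mhx2"], 1, "mhx2")
        assert len(runs) == 1
        assert runs[0].residues == toy_alignment.ungapped("mhx2")

    def test_planted_runs_recovered_with_exact_boundaries(self):
        """A 6-mer planted amid 20% column noise keeps exact boundaries."""
        from mhxscan.simulate import DEFAULT_REGIONS, default_family_spec, generate_family

        spec = default_family_spec(
            55,
            region_conservation=tuple((n, 0.0) for n, *_ in DEFAULT_REGIONS),
            n_conserved_all=0,
            n_conserved_all_glycines=0,
            differentials=(),
            repeat=None,
            noise_rate=0.20,
        )
        _, truth = generate_family(spec)
        mhx = truth.partition.members("MHX")
        runs = find_conserved_runs(truth.alignment, mhx, 5, truth.reference_id)
        got = sorted((r.start_column, r.end_column, r.residues) for r in runs)
        exp = sorted((p.start, p.end, p.residues) for p in truth.planted_runs)
        assert got == exp

    def test_default_family_runs_match_plan(self, family):
        _, truth = family
        mhx = truth.partition.members("MHX")
        runs = find_conserved_runs(truth.alignment, mhx, 5, truth.reference_id)
        got = sorted((r.start_column, r.end_column, r.residues) for r in runs)
        assert got == sorted(truth.expected_runs(5))

    def test_runs_sorted_by_reference_start_and_maximal(self, family):
        _, truth = family
        mhx = truth.partition.members("MHX")
        runs = find_conserved_runs(truth.alignment, mhx, 3, truth.reference_id)
        starts = [r.reference_start for r in runs]
        assert starts == sorted(starts)
        for r in runs:  # maximality: flanking columns are not conserved
            flags = set(truth.family_conserved_columns)
            assert r.start_column - 1 not in flags
            assert r.end_column + 1 not in flags


class TestRegionStats:
    def test_identical_sequences_single_region_is_100(self):
        from mhxscan.io import AlignmentMatrix

        aln = AlignmentMatrix(["a", "b"], ["MKVLW", "MKVLW"])
        rep = region_conservation_stats(aln, ["a", "b"], [("all", 1, 5)], "a")
        assert rep.per_region[0].identical == 5
        assert rep.per_region[0].percent_identity == 100

    def test_planted_rates_recovered_exactly(self, family):
        _, truth = family
        mhx = truth.partition.members("MHX")
        rep = region_conservation_stats(
            truth.alignment, mhx, truth.topology.core_intervals(), truth.reference_id
        )
        expected = truth.expected_region_identity()
        for stat in rep.per_region:
            assert (stat.identical, stat.total) == expected[stat.region]

    def test_totals_tile_reference_and_aggregates_sum(self, family):
        _, truth = family
        mhx = truth.partition.members("MHX")
        rep = region_conservation_stats(
            truth.alignment, mhx, truth.topology.core_intervals(), truth.reference_id
        )
        ref_len = len(truth.alignment.ungapped(truth.reference_id))
        assert sum(s.total for s in rep.per_region) == ref_len
        assert rep.tms_aggregate.total + rep.non_tms_aggregate.total == ref_len
        assert rep.tms_aggregate.identical + rep.non_tms_aggregate.identical == sum(
            s.identical for s in rep.per_region
        )

    def test_percentages_round_half_up(self):
        from mhxscan.conservation import RegionConservationStat

        # 54/339 = 15.93 -> 16 and 68/199 = 34.17 -> 34
        assert RegionConservationStat("x", 54, 339).percent_identity == 16
        assert RegionConservationStat("x", 68, 199).percent_identity == 34
        assert RegionConservationStat("x", 11, 27).percent_identity == 41

    def test_non_tiling_regions_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="tile"):
            region_conservation_stats(
                toy_alignment, ["mhx1", "mhx2"], [("a", 1, 4), ("b", 6, 10)], "mhx2"
            )
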