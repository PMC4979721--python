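"""Pedigree ingestion, kinship algebra, depth, classification, cohorts."""

import numpy as np
import pytest

from ne_workbench.pedigree import (
    FOUNDER,
    OVERLAPPED,
    PedigreeError,
    SamplingScheme,
    classify_filial,
    compute_kinship,
    equivalent_generations,
    group_cohorts,
    load_pedigree,
)

from conftest import kinship_by_path_counting, make_pedigree, random_pedigree


class TestLoading:
    def test_founders_only_file(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text(
            "id,sire,dam,sex,birth_year\n"
            + "".join(f"F{k},0,,{'m' if k < 3 else 'f'},2002\n" for k in range(6))
        )
        ped = load_pedigree(p)
        assert len(ped) == 6
        assert len(ped.founders) == 6

    def test_three_generation_file_topological(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text(
            "id,sire,dam,sex,birth_year\n"
            # offspring rows first: loader must reorder
            "I,G,H,f,2002\n"
            "G,A,B,m,2001\n"
            "H,C,D,f,2001\n"
            "A,0,0,m,2000\nB,0,0,f,2000\nC,0,0,m,2000\n"
            "D,0,0,f,2000\nE,0,0,m,2000\nF,0,0,f,2000\n"
        )
        ped = load_pedigree(p)
        assert len(ped) == 9
        assert len(ped.founders) == 6
        order = {i: k for k, i in enumerate(ped.ids)}
        for ind in ped:
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    assert order[parent] < order[ind.id]

    def test_self_ancestor_rejected(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,sire,dam,sex,birth_year\nX,X,0,m,2000\n")
        with pytest.raises(PedigreeError, match="own sire"):
            load_pedigree(p)

    def test_cycle_rejected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            make_pedigree([
                ("A", "C", None, "m", None),
                ("B", "A", None, "m", None),
                ("C", "B", None, "m", None),
            ])

    def test_dangling_parent_rejected(self):
        with pytest.raises(PedigreeError, match="not in the pedigree"):
            make_pedigree([("A", "ZZ", None, "m", 2000)])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(PedigreeError, match="duplicated"):
            make_pedigree([("A", None, None, "m", 1), ("A", None, None, "f", 1)])

    def test_unknown_sex_code_rejected(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,sire,dam,sex,birth_year\nA,0,0,x,2000\n")
        with pytest.raises(PedigreeError, match="sex"):
            load_pedigree(p)

    def test_parent_younger_than_offspring_rejected(self):
        with pytest.raises(PedigreeError, match="older"):
            make_pedigree([
                ("A", None, None, "m", 2005),
                ("B", None, None, "f", 2000),
                ("C", "A", "B", "m", 2003),
            ])

    def test_wrong_parent_sex_rejected(self):
        with pytest.raises(PedigreeError, match="not male"):
            make_pedigree([
                ("A", None, None, "f", 2000),
                ("B", "A", None, "m", 2001),
            ])


class TestKinship:
    def test_offspring_of_unrelated_founders_not_inbred(
        self, three_generation_pedigree
    ):
        kin = compute_kinship(three_generation_pedigree)
        assert kin.inbreeding("G") == 0.0
        assert kin.inbreeding("I") == 0.0  # parents from distinct crosses

    def test_full_sib_mating_gives_quarter(self):
        ped = make_pedigree([
            ("A", None, None, "m", 2000),
            ("B", None, None, "f", 2000),
            ("S1", "A", "B", "m", 2001),
            ("S2", "A", "B", "f", 2001),
            ("X", "S1", "S2", "m", 2002),
        ])
        kin = compute_kinship(ped)
        assert kin.inbreeding("X") == pytest.approx(0.25)
        assert kin.coancestry("S1", "S2") == pytest.approx(0.25)

    def test_diagonal_and_symmetry_invariants(self):
        rng = np.random.default_rng(7)
        ped = random_pedigree(rng, 12, 4)
        kin = compute_kinship(ped)
        assert np.allclose(kin.C, kin.C.T)
        assert np.allclose(np.diag(kin.C), (1 + kin.F) / 2)
        for ind in ped:
            if ind.sire and ind.dam:
                assert kin.inbreeding(ind.id) == pytest.approx(
                    kin.coancestry(ind.sire, ind.dam)
                )

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_path_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        ped = random_pedigree(rng, n, founders=int(rng.integers(2, 5)))
        kin = compute_kinship(ped)
        ids = ped.ids
        for a in range(len(ids)):
            for b in range(a, len(ids)):
                expected = kinship_by_path_counting(ped, ids[a], ids[b])
                assert kin.coancestry(ids[a], ids[b]) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_inbreeding_bounded_on_shallow_pedigrees(self):
        # without selfing, F cannot exceed 0.5 in four generations
        rng = np.random.default_rng(42)
        for _ in range(20):
            ped = random_pedigree(rng, 12, 2)
            kin = compute_kinship(ped)
            assert np.all(kin.F >= 0.0)
            assert np.all(kin.F <= 0.5 + 1e-12)


class TestEquivalentGenerations:
    def test_founder_zero_and_half_parent(self):
        ped = make_pedigree([
            ("A", None, None, "m", 2000),
            ("B", "A", None, "f", 2001),
        ])
        t = equivalent_generations(ped)
        assert t["A"] == 0.0
        assert t["B"] == 0.5

    def test_complete_pedigree_depth_is_exact(self, three_generation_pedigree):
        t = equivalent_generations(three_generation_pedigree)
        assert t["G"] == 1.0
        assert t["I"] == 2.0

    def test_fully_pedigreed_f3_has_t_three(self):
        ped = make_pedigree([
            ("A", None, None, "m", 2000), ("B", None, None, "f", 2000),
            ("C", None, None, "m", 2000), ("D", None, None, "f", 2000),
            ("E", "A", "B", "m", 2001), ("F", "C", "D", "f", 2001),
            ("G", "A", "D", "m", 2001), ("H", "C", "B", "f", 2001),
            ("I", "E", "F", "m", 2002), ("J", "G", "H", "f", 2002),
            ("K", "I", "J", "f", 2003),
        ])
        t = equivalent_generations(ped)
        assert t["K"] == pytest.approx(3.0)


class TestFilialClassification:
    def test_ladder_and_overlap(self):
        ped = make_pedigree([
            ("A", None, None, "m", 2000), ("B", None, None, "f", 2000),
            ("C", None, None, "m", 2000), ("D", None, None, "f", 2000),
            ("F1a", "A", "B", "m", 2001), ("F1b", "C", "D", "f", 2001),
            ("F2a", "F1a", "F1b", "m", 2002), ("F2b", "F1a", "F1b", "f", 2002),
            ("MIX", "F2a", "F1b", "f", 2003),  # F2 x F1 cross
        ])
        labels = classify_filial(ped)
        assert labels["A"] == FOUNDER
        assert labels["F1a"] == "F1"
        assert labels["F2b"] == "F2"
        assert labels["MIX"] == OVERLAPPED

    def test_partition_and_idempotence(self):
        rng = np.random.default_rng(3)
        ped = random_pedigree(rng, 15, 4)
        labels = classify_filial(ped)
        assert set(labels) == set(ped.ids)  # total partition
        assert classify_filial(ped) == labels

    def test_one_unknown_parent_is_overlapped(self):
        ped = make_pedigree([
            ("A", None, None, "m", 2000),
            ("B", "A", None, "f", 2001),
        ])
        assert classify_filial(ped)["B"] == OVERLAPPED


class TestCohorts:
    @pytest.fixture
    def five_year_pedigree(self):
        rows = [("M", None, None, "m", 2000), ("F", None, None, "f", 2000)]
        for k, year in enumerate(range(2006, 2011)):
            rows.append((f"I{k}", "M", "F", "m", year))
            rows.append((f"J{k}", "M", "F", "f", year))
        return make_pedigree(rows)

    def test_yearly_scheme_gives_five_cohorts(self, five_year_pedigree):
        cohorts = group_cohorts(five_year_pedigree, SamplingScheme(kind="yearly"))
        years = [c for c in cohorts if c != "2000"]
        assert years == [str(y) for y in range(2006, 2011)]
        assert all(len(cohorts[y]) == 2 for y in years)

    def test_biannual_windows_overlap(self, five_year_pedigree):
        cohorts = group_cohorts(
            five_year_pedigree, SamplingScheme(kind="span", span_years=2)
        )
        labels = [c for c in cohorts if c.startswith("200") and int(c[:4]) >= 2006]
        assert labels == ["2006-2007", "2007-2008", "2008-2009", "2009-2010"]
        # each inner year appears in two windows
        assert set(cohorts["2006-2007"]) & set(cohorts["2007-2008"])

    def test_span_one_equals_yearly(self, five_year_pedigree):
        yearly = group_cohorts(five_year_pedigree, SamplingScheme(kind="yearly"))
        span1 = group_cohorts(
            five_year_pedigree, SamplingScheme(kind="span", span_years=1)
        )
        assert yearly == span1

    def test_discrete_scheme_groups_filial_classes(self):
        ped = make_pedigree([
            ("A", None, None, "m", 2000), ("B", None, None, "f", 2000),
            ("X", "A", "B", "m", 2001), ("Y", "A", "B", "f", 2001),
            ("Z", "X", "Y", "m", 2002),
        ])
        cohorts = group_cohorts(ped, SamplingScheme(kind="discrete_generation"))
        assert cohorts == {"F1": ["X", "Y"], "F2": ["Z"]}

    def test_invalid_scheme_kind(self):
        with pytest.raises(ValueError):
            SamplingScheme(kind="monthly")
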