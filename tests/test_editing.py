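import numpy as np
import pandas as pd
import pytest

from pedeval.editing import (EditingError, apply_editing_plan,
                             connectedness_filter, filter_min_count,
                             filter_range, genetic_links, with_cg)
from pedeval.pedigree import PedigreeTable, topological_sort


def make_records(rows):
    """rows: (cow, herd, year, evaluator, value)"""
    df = pd.DataFrame(rows, columns=["cow", "herd", "year", "evaluator", "value"])
    df["season"] = "dry"
    df["diet"] = "D1"
    df["dam_age"] = 1800.0
    df["trait"] = "STA"
    return with_cg(df)


def sire_family_pedigree(n_daughters=5, sires=("S1",), prefix="C"):
    entries = [(s, "0", "0") for s in sires]
    k = 0
    for s in sires:
        for _ in range(n_daughters):
            entries.append((f"{prefix}{k}", s, "0"))
            k += 1
    return topological_sort(PedigreeTable.from_entries(entries))


class TestFilterRange:
    def test_stature_biological_bounds(self):
        rows = [(f"C{i}", "H1", 2000, "E1", v)
                for i, v in enumerate([118, 119, 155, 156])]
        out, rep = filter_range(make_records(rows), {"STA": (119, 155)})
        assert sorted(out["value"]) == [119, 155]
        assert rep.removed == {"range": 2}

    def test_empty_input(self):
        out, rep = filter_range(make_records([]), {"STA": (119, 155)})
        assert len(out) == 0 and rep.surviving == 0

    def test_all_inside_unchanged(self):
        rows = [(f"C{i}", "H1", 2000, "E1", 130 + i) for i in range(5)]
        rec = make_records(rows)
        out, rep = filter_range(rec, {"STA": (119, 155)})
        assert len(out) == len(rec) and rep.total_removed == 0

    def test_score_trait_untouched(self):
        rows = [(f"C{i}", "H1", 2000, "E1", 9) for i in range(3)]
        rec = make_records(rows)
        out, _ = filter_range(rec, {}, score_traits=("STA",))
        assert len(out) == 3

    def test_missing_range_errors(self):
        rec = make_records([("C1", "H1", 2000, "E1", 1.0)])
        with pytest.raises(EditingError, match="range"):
            filter_range(rec, {})


class TestFilterMinCount:
    def test_threshold_is_fewer_than_five(self):
        rows = ([(f"A{i}", "H1", 2000, "E1", 1.0) for i in range(4)]
                + [(f"B{i}", "H1", 2000, "E2", 1.0) for i in range(5)]
                + [(f"C{i}", "H1", 2000, "E3", 1.0) for i in range(6)])
        out, rep = filter_min_count(make_records(rows), "evaluator", 5)
        assert len(out) == 11
        assert "E1" not in set(out["evaluator"])

    def test_all_levels_big_enough_unchanged(self):
        rows = [(f"A{i}", "H1", 2000, f"E{i % 2}", 1.0) for i in range(10)]
        rec = make_records(rows)
        out, rep = filter_min_count(rec, "evaluator", 5)
        assert len(out) == 10 and rep.total_removed == 0

    def test_all_small_levels_empty_output(self):
        rows = [(f"A{i}", "H1", 2000, f"E{i % 3}", 1.0) for i in range(9)]
        out, _ = filter_min_count(make_records(rows), "evaluator", 5)
        assert len(out) == 0

    def test_unknown_factor(self):
        with pytest.raises(EditingError):
            filter_min_count(make_records([("C", "H1", 2000, "E1", 1.0)]),
                             "nonsense")


class TestGeneticLinks:
    def test_paternal_halfsib_groups_fully_linked(self):
        ped = sire_family_pedigree(n_daughters=10)
        rows = ([(f"C{i}", "H1", 2000, "E1", 1.0) for i in range(5)]
                + [(f"C{i}", "H2", 2000, "E1", 1.0) for i in range(5, 10)])
        rec = make_records(rows)
        assert genetic_links("H1:2000", "H2:2000", rec, ped) == 25

    def test_links_match_exhaustive_enumeration(self, rng):
        from conftest import random_pedigree
        ped = random_pedigree(rng, n_founders=12, n_extra=60)
        recorded = [a for a in ped.ids if a.startswith("X")][:30]
        rows = [(a, "H1" if i < 15 else "H2", 2001, "E1", 1.0)
                for i, a in enumerate(recorded)]
        rec = make_records(rows)
        max_depth = 3

        def ancestors(a, depth):
            out = {a}
            frontier = {a}
            code = ped.code
            for _ in range(depth):
                nxt = set()
                for x in frontier:
                    i = code[x]
                    for p in (ped.sire[i], ped.dam[i]):
                        if p >= 0:
                            nxt.add(ped.ids[p])
                out |= nxt
                frontier = nxt
            return out

        brute = 0
        for x in recorded[:15]:
            for y in recorded[15:]:
                if ancestors(x, max_depth) & ancestors(y, max_depth):
                    brute += 1
        assert genetic_links("H1:2001", "H2:2001", rec, ped, max_depth) == brute

    def test_no_shared_ancestry_zero(self):
        ped = sire_family_pedigree(3, sires=("S1", "S2"))
        rows = ([(f"C{i}", "H1", 2000, "E1", 1.0) for i in range(3)]
                + [(f"C{i}", "H2", 2000, "E1", 1.0) for i in range(3, 6)])
        assert genetic_links("H1:2000", "H2:2000", make_records(rows), ped) == 0

    def test_same_cg_rejected(self):
        ped = sire_family_pedigree(2)
        rec = make_records([("C0", "H1", 2000, "E1", 1.0)])
        with pytest.raises(EditingError, match="distinct"):
            genetic_links("H1:2000", "H1:2000", rec, ped)

    def test_symmetric(self):
        ped = sire_family_pedigree(n_daughters=8)
        rows = ([(f"C{i}", "H1", 2000, "E1", 1.0) for i in range(4)]
                + [(f"C{i}", "H2", 2000, "E1", 1.0) for i in range(4, 8)])
        rec = make_records(rows)
        assert (genetic_links("H1:2000", "H2:2000", rec, ped)
                == genetic_links("H2:2000", "H1:2000", rec, ped))


class TestConnectednessFilter:
    def chain_records(self, ped, sizes=(5, 5, 5)):
        rows = []
        k = 0
        for h, size in enumerate(sizes):
            for _ in range(size):
                rows.append((f"C{k}", f"H{h + 1}", 2000, "E1", 1.0))
                k += 1
        return make_records(rows)

    def test_chain_fully_retained(self):
        ped = sire_family_pedigree(n_daughters=15)
        rec = self.chain_records(ped)
        out, rep, comp = connectedness_filter(rec, ped, min_links=10)
        assert len(out) == len(rec)
        assert len(set(comp.values())) == 1

    def test_isolated_cg_removed(self):
        # daughters of S1 in H1/H2 (connected), unrelated founder cows in H3
        entries = [("S1", "0", "0")]
        entries += [(f"C{i}", "S1", "0") for i in range(10)]
        entries += [(f"U{i}", "0", "0") for i in range(5)]
        ped = topological_sort(PedigreeTable.from_entries(entries))
        rows = ([(f"C{i}", "H1", 2000, "E1", 1.0) for i in range(5)]
                + [(f"C{i}", "H2", 2000, "E1", 1.0) for i in range(5, 10)]
                + [(f"U{i}", "H3", 2000, "E1", 1.0) for i in range(5)])
        out, rep, comp = connectedness_filter(make_records(rows), ped,
                                              min_links=10)
        assert set(out["cg"]) == {"H1:2000", "H2:2000"}
        assert rep.removed["disconnected"] == 5

    def test_equal_components_most_records_wins_then_label(self):
        # two 2-CG components; second has more records -> retained
        entries = [("S1", "0", "0"), ("S2", "0", "0")]
        entries += [(f"A{i}", "S1", "0") for i in range(8)]
        entries += [(f"B{i}", "S2", "0") for i in range(12)]
        ped = topological_sort(PedigreeTable.from_entries(entries))
        rows = ([(f"A{i}", "H1", 2000, "E1", 1.0) for i in range(4)]
                + [(f"A{i}", "H2", 2000, "E1", 1.0) for i in range(4, 8)]
                + [(f"B{i}", "H3", 2000, "E1", 1.0) for i in range(6)]
                + [(f"B{i}", "H4", 2000, "E1", 1.0) for i in range(6, 12)])
        out, _, _ = connectedness_filter(make_records(rows), ped, min_links=10)
        assert set(out["cg"]) == {"H3:2000", "H4:2000"}


class TestEditingPlan:
    def full_fixture(self):
        ped = sire_family_pedigree(n_daughters=30)
        rows = ([(f"C{i}", "H1", 2000, "E1", 130.0) for i in range(10)]
                + [(f"C{i}", "H2", 2000, "E1", 131.0) for i in range(10, 20)]
                + [(f"C{i}", "H1", 2001, "E2", 132.0) for i in range(20, 28)])
        return ped, make_records(rows)

    def test_cg_random_applies_cg_filters(self):
        ped, rec = self.full_fixture()
        out, rep = apply_editing_plan(rec, ped, cg_in_model=True,
                                      trait_ranges={"STA": (119, 155)})
        assert rep.surviving == len(out)
        assert "disconnected" in rep.removed

    def test_cg_excluded_skips_cg_filters(self):
        ped, rec = self.full_fixture()
        out, rep = apply_editing_plan(rec, ped, cg_in_model=False,
                                      trait_ranges={"STA": (119, 155)})
        assert "disconnected" not in rep.removed
        assert not any(k.startswith("cg<") for k in rep.removed)

    def test_clean_data_no_removals(self):
        ped, rec = self.full_fixture()
        out, rep = apply_editing_plan(rec, ped, cg_in_model=True,
                                      trait_ranges={"STA": (119, 155)})
        # the fixture chain is fully linked through the common sire
        assert rep.total_removed == 0

    def test_idempotent(self):
        ped = sire_family_pedigree(n_daughters=40)
        rng = np.random.default_rng(4)
        rows = [(f"C{i}", f"H{rng.integers(1, 4)}", int(rng.integers(2000, 2003)),
                 f"E{rng.integers(1, 4)}", float(rng.uniform(119, 156)))
                for i in range(40)]
        rec = make_records(rows)
        once, _ = apply_editing_plan(rec, ped, True, {"STA": (119, 155)})
        twice, rep2 = apply_editing_plan(once, ped, True, {"STA": (119, 155)})
        assert sorted(map(tuple, once[["cow", "year", "value"]].values.tolist())) == \
               sorted(map(tuple, twice[["cow", "year", "value"]].values.tolist()))

    def test_row_shuffle_invariance(self):
        ped = sire_family_pedigree(n_daughters=40)
        rng = np.random.default_rng(9)
        rows = [(f"C{i}", f"H{rng.integers(1, 4)}", int(rng.integers(2000, 2003)),
                 f"E{rng.integers(1, 4)}", float(rng.uniform(119, 156)))
                for i in range(40)]
        rec = make_records(rows)
        out1, _ = apply_editing_plan(rec, ped, True, {"STA": (119, 155)})
        shuffled = rec.sample(frac=1.0, random_state=1)
        out2, _ = apply_editing_plan(shuffled, ped, True, {"STA": (119, 155)})
        key = ["cow", "year", "evaluator", "value"]
        assert sorted(map(tuple, out1[key].values.tolist())) == \
               sorted(map(tuple, out2[key].values.tolist()))

    def test_report_counts_balance(self):
        ped, rec = self.full_fixture()
        out, rep = apply_editing_plan(rec, ped, True, {"STA": (119, 155)})
        assert rep.total_removed + rep.surviving == rep.input_count
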