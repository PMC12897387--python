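"""Record editing: biological ranges, minimum counts, CG connectedness.

Contemporary groups (CG) are herd-year classes.  The editing plan is:

1. remove records outside the biological range of continuous traits;
2. remove evaluators with fewer than five records;
3. remove CGs with fewer than five records;
4. keep only CGs in the largest genetically connected component, where two
   CGs are connected if at least ``min_links`` cross-CG pairs of recorded
   animals share a known common ancestor (ancestor search depth-capped);
5. re-check the min-count filters once after the connectedness removal.

For traits whose model carries no CG effect at all (neither fixed nor
random), the CG-based steps 3-5 are skipped: such traits are analysed on a
larger dataset edited only for ranges and evaluator counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .pedigree import PedigreeTable


class EditingError(ValueError):
    pass


@dataclass
class EditReport:
    """Per-rule removal counts; removed + surviving = input."""

    input_count: int
    removed: dict = field(default_factory=dict)
    surviving: int = 0

    def add(self, rule: str, count: int) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + int(count)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def finalize(self, surviving: int) -> "EditReport":
        self.surviving = int(surviving)
        assert self.total_removed + self.surviving == self.input_count
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"rule": "surviving", "removed": self.surviving})
        return pd.DataFrame(rows)


def with_cg(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the derived herd-year CG identifier column."""
    out = records.copy()
    out["cg"] = out["herd"].astype(str) + ":" + out["year"].astype(str)
    return out


def filter_range(records: pd.DataFrame, trait_ranges: dict,
                 score_traits=()) -> tuple:
    """Keep rows with min <= value <= max for continuous traits.

    ``trait_ranges`` maps trait name -> (min, max).  Score traits are left
    untouched; a continuous trait without a declared range is an error.
    """
    report = EditReport(input_count=len(records))
    if len(records) == 0:
        return records.copy(), report.finalize(0)
    keep = np.ones(len(records), dtype=bool)
    for trait, sub in records.groupby("trait"):
        if trait in score_traits:
            continue
        if trait not in trait_ranges:
            raise EditingError(f"no biological range declared for continuous trait {trait!r}")
        lo, hi = trait_ranges[trait]
        v = sub["value"].astype(float)
        bad = sub.index[(v < lo) | (v > hi)]
        keep[records.index.get_indexer(bad)] = False
    out = records.loc[keep].copy()
    report.add("range", (~keep).sum())
    return out, report.finalize(len(out))


def filter_min_count(records: pd.DataFrame, factor: str,
                     min_count: int = 5) -> tuple:
    """Remove all rows whose ``factor`` level has fewer than ``min_count`` rows.

    Within a single factor one pass is stable (levels partition the rows),
    but the pass is repeated until no level falls below the threshold to keep
    the contract obvious.
    """
    if factor == "cg" and "cg" not in records.columns:
        records = with_cg(records)
    if factor not in records.columns:
        raise EditingError(f"factor column {factor!r} not present")
    report = EditReport(input_count=len(records))
    out = records
    while True:
        counts = out[factor].value_counts()
        bad = counts[counts < min_count].index
        if len(bad) == 0:
            break
        mask = out[factor].isin(bad)
        report.add(f"{factor}<{min_count}", mask.sum())
        out = out.loc[~mask]
    return out.copy(), report.finalize(len(out))


def _ancestor_bitsets(pedigree: PedigreeTable, animals, max_depth: int) -> dict:
    """Map animal token -> python-int bitset of ancestor codes within
    max_depth generations (the animal itself counts at depth 0)."""
    code = pedigree.code
    sets = {}
    for a in animals:
        if a not in code:
            continue
        frontier = [code[a]]
        bits = 0
        for _ in range(max_depth + 1):
            nxt = []
            for i in frontier:
                bits |= 1 << i
                for p in (pedigree.sire[i], pedigree.dam[i]):
                    if p >= 0:
                        nxt.append(int(p))
            frontier = nxt
            if not frontier:
                break
        sets[a] = bits
    return sets


def genetic_links(cg_a: str, cg_b: str, records: pd.DataFrame,
                  pedigree: PedigreeTable, max_depth: int = 3) -> int:
    """Number of cross-CG pairs of recorded animals sharing a common ancestor.

    A "genetic link" is a pair (one recorded animal from each CG) with at
    least one known common ancestor within ``max_depth`` generations; an
    animal recorded in both CGs links to itself.  Symmetric in its CG
    arguments.
    """
    if cg_a == cg_b:
        raise EditingError("genetic_links requires two distinct CGs")
    if "cg" not in records.columns:
        records = with_cg(records)
    for cg in (cg_a, cg_b):
        if cg not in set(records["cg"]):
            raise EditingError(f"unknown CG {cg!r}")
    an_a = records.loc[records["cg"] == cg_a, "cow"].unique()
    an_b = records.loc[records["cg"] == cg_b, "cow"].unique()
    sets = _ancestor_bitsets(pedigree, np.union1d(an_a, an_b), max_depth)
    return _count_links(an_a, an_b, sets)


def _count_links(an_a, an_b, sets) -> int:
    n = 0
    bs_b = [sets[y] for y in an_b if y in sets]
    for x in an_a:
        bx = sets.get(x, 0)
        if bx:
            n += sum(1 for by in bs_b if bx & by)
    return n


def connectedness_filter(records: pd.DataFrame, pedigree: PedigreeTable,
                         min_links: int = 10, max_depth: int = 3) -> tuple:
    """Keep records of CGs in the largest connected component.

    CGs are graph nodes; an edge joins two CGs with >= ``min_links`` genetic
    links.  The component with the most records is retained (ties broken by
    the lexicographically smallest CG label it contains).  Returns
    ``(records, EditReport, component_map)``.
    """
    if "cg" not in records.columns:
        records = with_cg(records)
    report = EditReport(input_count=len(records))
    cgs = sorted(records["cg"].unique())
    if len(cgs) <= 1:
        comp = {cg: 0 for cg in cgs}
        return records.copy(), report.finalize(len(records)), comp

    cows_by_cg = {cg: records.loc[records["cg"] == cg, "cow"].unique() for cg in cgs}
    all_cows = records["cow"].unique()
    sets = _ancestor_bitsets(pedigree, all_cows, max_depth)

    G = nx.Graph()
    G.add_nodes_from(cgs)
    for i, ca in enumerate(cgs):
        for cb in cgs[i + 1:]:
            if _count_links(cows_by_cg[ca], cows_by_cg[cb], sets) >= min_links:
                G.add_edge(ca, cb)

    components = [sorted(c) for c in nx.connected_components(G)]
    counts = records["cg"].value_counts()
    # most records wins; tie -> smallest CG label
    components.sort(key=lambda c: (-sum(counts.get(cg, 0) for cg in c), c[0]))
    keep_cgs = set(components[0])
    comp_map = {}
    for k, comp in enumerate(components):
        for cg in comp:
            comp_map[cg] = k
    mask = records["cg"].isin(keep_cgs)
    report.add("disconnected", (~mask).sum())
    out = records.loc[mask].copy()
    return out, report.finalize(len(out)), comp_map


def apply_editing_plan(records: pd.DataFrame, pedigree: PedigreeTable,
                       cg_in_model: bool, trait_ranges: dict = None,
                       score_traits=(), min_count: int = 5,
                       min_links: int = 10, max_depth: int = 3) -> tuple:
    """Full editing plan; CG-based steps skipped when the model has no CG.

    ``cg_in_model`` is True when the trait's model carries CG as a fixed or
    random effect (full plan), False when CG is excluded (range + evaluator
    filters only).
    """
    report = EditReport(input_count=len(records))
    out = with_cg(records)
    if trait_ranges:
        out, r = filter_range(out, trait_ranges, score_traits=score_traits)
        report.removed.update(r.removed)
    out, r = filter_min_count(out, "evaluator", min_count)
    report.removed.update(r.removed)
    if cg_in_model:
        out, r = filter_min_count(out, "cg", min_count)
        report.removed.update(r.removed)
        out, r, _ = connectedness_filter(out, pedigree, min_links, max_depth)
        report.removed.update(r.removed)
        # one re-check of the min-count filters after connectedness removal
        for factor in ("evaluator", "cg"):
            out, r = filter_min_count(out, factor, min_count)
            for k, v in r.removed.items():
                report.add(k, v)
    return out, report.finalize(len(out))
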