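"""Method x hypothesis support matrix and min/max species counting.

Each delimitation method contributes a column of decisions over a set of
candidate species hypotheses (groups, their nested sub-groups, and
composite alternatives). A decision is ``'+'`` (supported as a putative
species), ``'-'`` (not supported), ``'na'`` (untestable for that method —
e.g. a singleton under distance rules) or ``''`` (not evaluated).

The species count implied by one method over a scope (a nominal taxon or
the whole genus) is obtained by *tiling*: enumerating the sets of
supported, pairwise-disjoint hypotheses whose union covers the scope.
Nesting makes a parent and its children mutually exclusive alternatives,
so the count is a range (min-max over tilings). Ids that only untestable
(na) hypotheses cover are dropped from the scope with a warning rather
than blocking every tiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .seqdata import GroupMap

__all__ = ["SupportMatrix", "SpeciesCountRange", "build_support_matrix",
           "count_species_range"]


@dataclass
class SupportMatrix:
    groups: GroupMap
    hypotheses: list[str]
    methods: list[str] = field(default_factory=list)
    cells: dict[tuple[str, str], str] = field(default_factory=dict)

    def set(self, hypothesis: str, method: str, decision: str) -> None:
        if decision not in ("+", "-", "na", ""):
            raise ValueError(f"invalid decision {decision!r}")
        if hypothesis not in self.hypotheses:
            raise ValueError(f"unknown hypothesis {hypothesis!r}")
        if method not in self.methods:
            self.methods.append(method)
        self.cells[(hypothesis, method)] = decision

    def get(self, hypothesis: str, method: str) -> str:
        return self.cells.get((hypothesis, method), "")

    def supported(self, method: str) -> list[str]:
        return [h for h in self.hypotheses if self.get(h, method) == "+"]

    def untestable(self, method: str) -> list[str]:
        return [h for h in self.hypotheses if self.get(h, method) == "na"]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: {h: self.get(h, m) for h in self.hypotheses} for m in self.methods}
        ).reindex(self.hypotheses)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


@dataclass
class SpeciesCountRange:
    scope: str
    min_count: int
    max_count: int
    min_tiling: list[str]
    max_tiling: list[str]
    all_tilings: list[list[str]]

    def __str__(self) -> str:
        if self.min_count == self.max_count:
            return str(self.min_count)
        return f"{self.min_count} or {self.max_count}"


def build_support_matrix(groups: GroupMap, hypotheses: list[str],
                         method_decisions: dict[str, dict[str, str]]) -> SupportMatrix:
    """Assemble a support matrix from per-method decision dicts.

    ``method_decisions`` maps method name -> {hypothesis: decision}. A
    method missing a hypothesis leaves the cell empty; a method with no
    decisions at all is dropped with a warning.
    """
    if not method_decisions:
        raise ValueError("no method results")
    matrix = SupportMatrix(groups, list(hypotheses))
    for method, decisions in method_decisions.items():
        if not decisions:
            warnings.warn(f"method {method!r} produced no decisions; column omitted",
                          stacklevel=2)
            continue
        unknown = set(decisions) - set(hypotheses)
        if unknown:
            raise ValueError(f"method {method!r} decided unknown hypotheses "
                             f"{sorted(unknown)}")
        matrix.methods.append(method)
        for h, d in decisions.items():
            matrix.set(h, method, d)
    return matrix


def _tilings(scope: frozenset, hyp_sets: list[tuple[str, frozenset]],
             chosen: tuple, out: list) -> None:
    if not scope:
        out.append(list(chosen))
        return
    # the smallest uncovered id anchors the search: each tiling contains
    # exactly one hypothesis covering it, so no tiling is produced twice
    pivot = min(scope)
    for name, ids in hyp_sets:
        if pivot in ids and ids <= scope:
            _tilings(scope - ids, hyp_sets, chosen + (name,), out)


def count_species_range(matrix: SupportMatrix, method: str,
                        scope_ids: set[str], scope_name: str = "scope") -> SpeciesCountRange:
    """Min/max number of species over exact tilings of the scope.

    A tiling is a set of supported hypotheses, pairwise disjoint, whose
    union equals the scope's id set (after removing ids covered only by
    untestable hypotheses). Exhaustive enumeration; intended for hypothesis
    counts up to a few dozen.
    """
    if method not in matrix.methods:
        raise ValueError(f"method {method!r} not in matrix")
    supported = matrix.supported(method)
    hyp_sets = [(h, frozenset(matrix.groups.members(h) & scope_ids))
                for h in supported]
    hyp_sets = [(h, s) for h, s in hyp_sets if s]
    coverable = frozenset().union(*[s for _, s in hyp_sets]) if hyp_sets else frozenset()
    uncovered = frozenset(scope_ids) - coverable
    if uncovered:
        na_cover = set()
        for h in matrix.untestable(method):
            na_cover |= matrix.groups.members(h) & uncovered
        if na_cover:
            warnings.warn(
                f"{len(na_cover)} id(s) only covered by untestable hypotheses "
                f"are excluded from scope {scope_name!r}", stacklevel=2)
        still = uncovered - na_cover
        if still:
            raise ValueError(
                f"no supported hypothesis covers ids {sorted(still)[:5]}... "
                f"in scope {scope_name!r}")
        scope = frozenset(scope_ids) - uncovered
    else:
        scope = frozenset(scope_ids)
    if not scope:
        raise ValueError(f"scope {scope_name!r} has no testable ids left")
    out: list[list[str]] = []
    _tilings(scope, hyp_sets, (), out)
    if not out:
        raise ValueError(f"no valid tiling of scope {scope_name!r} "
                         f"by the hypotheses supported under {method!r}")
    sizes = [len(t) for t in out]
    min_t = out[sizes.index(min(sizes))]
    max_t = out[sizes.index(max(sizes))]
    return SpeciesCountRange(scope_name, min(sizes), max(sizes),
                             sorted(min_t), sorted(max_t),
                             [sorted(t) for t in out])
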