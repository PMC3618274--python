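"""Barcode-gap analysis: overall (OGA) and pairwise (PGA) modes.

A barcode gap exists for a focal group when the smallest distance to the
comparison set exceeds the largest distance within the group; the gap range
is the width of that interval. OGA compares the focal group against the
amalgamation of all other groups; PGA compares it against one named partner
at a time, which also identifies the partner "blocking" a gap.

Four decision rules turn the distance statistics into a supported /
unsupported call per focal group:

* ``fixed_3pct`` / ``fixed_4pct`` — supported iff mean intra-group distance
  is below the threshold *and* the minimum inter-group distance is at or
  above it.
* ``fold_10x`` — supported iff mean inter >= 10 x mean intra.
* ``fold_3.2-4.1x`` — supported iff mean inter >= 3.2 x mean intra, with a
  ``strong`` flag at >= 4.1 x.

Singleton focal groups have no intra distances: fold rules and fixed rules
return ``na`` (provisional), matching the usual treatment of untestable
hypotheses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .distances import DistanceMatrix
from .seqdata import GroupMap

__all__ = [
    "GapAnalysisResult",
    "ThresholdDecision",
    "overall_gap_analysis",
    "pairwise_gap_analysis",
    "pga_blocking_groups",
    "apply_threshold_rules",
    "export_gap_histogram",
]

RULES = ("fixed_3pct", "fixed_4pct", "fold_10x", "fold_3.2-4.1x")


@dataclass
class GapAnalysisResult:
    focal: str
    scope: str  # "all-others" for OGA, partner label for PGA
    intra: list[float]
    inter: list[float]

    @property
    def max_intra(self) -> float | None:
        return max(self.intra) if self.intra else None

    @property
    def mean_intra(self) -> float | None:
        return sum(self.intra) / len(self.intra) if self.intra else None

    @property
    def min_inter(self) -> float:
        return min(self.inter)

    @property
    def mean_inter(self) -> float:
        return sum(self.inter) / len(self.inter)

    @property
    def gap_present(self) -> bool:
        # singleton focal: no intra distances, any separation counts as a gap
        if not self.intra:
            return self.min_inter > 0
        return self.min_inter > self.max_intra

    @property
    def gap_range(self) -> float | None:
        """min inter - max intra, when positive (the gap width)."""
        if not self.intra:
            return None
        delta = self.min_inter - self.max_intra
        return delta if delta > 0 else None


@dataclass
class ThresholdDecision:
    rule: str
    supported: str  # "+", "-", "na"
    statistics: dict = field(default_factory=dict)
    strong: bool | None = None  # fold_3.2-4.1x only: ratio >= 4.1


def _group_members(groups: GroupMap, label: str, universe: set[str]) -> set[str]:
    members = groups.members(label) & universe
    if not members:
        raise ValueError(f"group {label!r} has no members in the matrix")
    return members


def overall_gap_analysis(D: DistanceMatrix, groups: GroupMap,
                         focal: str,
                         universe: set[str] | None = None) -> GapAnalysisResult:
    """Focal group vs the amalgamation of all other ids."""
    universe = set(D.ids) if universe is None else set(universe)
    focal_ids = _group_members(groups, focal, universe)
    others = universe - focal_ids
    if not others:
        raise ValueError("complement of the focal group is empty")
    return GapAnalysisResult(
        focal, "all-others",
        intra=D.pairs(focal_ids),
        inter=D.pairs(focal_ids, others),
    )


def pairwise_gap_analysis(D: DistanceMatrix, groups: GroupMap,
                          g1: str, g2: str) -> GapAnalysisResult:
    """Focal group ``g1`` vs the single partner group ``g2``."""
    if g1 == g2:
        raise ValueError("focal and partner group must differ")
    universe = set(D.ids)
    a = _group_members(groups, g1, universe)
    b = _group_members(groups, g2, universe)
    if a & b:
        raise ValueError(f"groups {g1!r} and {g2!r} overlap")
    return GapAnalysisResult(g1, g2, intra=D.pairs(a), inter=D.pairs(a, b))


def pga_blocking_groups(D: DistanceMatrix, groups: GroupMap, focal: str,
                        partners: list[str]) -> tuple[dict[str, GapAnalysisResult], list[str]]:
    """Run PGA of ``focal`` against every partner; list partners with no gap."""
    results = {}
    blocking = []
    for p in partners:
        if p == focal:
            continue
        res = pairwise_gap_analysis(D, groups, focal, p)
        results[p] = res
        if not res.gap_present:
            blocking.append(p)
    return results, blocking


def apply_threshold_rules(result: GapAnalysisResult) -> list[ThresholdDecision]:
    """Evaluate the four fixed/fold threshold rules on one gap analysis."""
    stats = {
        "mean_intra": result.mean_intra,
        "max_intra": result.max_intra,
        "min_inter": result.min_inter,
        "mean_inter": result.mean_inter,
    }
    out = []
    if result.mean_intra is None:
        # singleton focal group: intra-based statistics undefined
        for rule in RULES:
            out.append(ThresholdDecision(rule, "na", dict(stats)))
        return out
    for rule in RULES:
        if rule in ("fixed_3pct", "fixed_4pct"):
            t = 0.03 if rule == "fixed_3pct" else 0.04
            ok = result.mean_intra < t and result.min_inter >= t
            out.append(ThresholdDecision(rule, "+" if ok else "-",
                                         {**stats, "threshold": t}))
        elif rule == "fold_10x":
            ratio = (math.inf if result.mean_intra == 0
                     else result.mean_inter / result.mean_intra)
            out.append(ThresholdDecision(rule, "+" if ratio >= 10 else "-",
                                         {**stats, "ratio": ratio}))
        else:  # fold_3.2-4.1x
            ratio = (math.inf if result.mean_intra == 0
                     else result.mean_inter / result.mean_intra)
            out.append(ThresholdDecision(rule, "+" if ratio >= 3.2 else "-",
                                         {**stats, "ratio": ratio},
                                         strong=ratio >= 4.1))
    return out


def export_gap_histogram(result: GapAnalysisResult,
                         bin_width: float = 0.01) -> pd.DataFrame:
    """Counts of intra and inter distances in half-open bins [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    all_d = result.intra + result.inter
    if not all_d:
        raise ValueError("no distances to bin")
    n_bins = int(max(all_d) / bin_width) + 1
    rows = []
    for k in range(n_bins):
        lo, hi = k * bin_width, (k + 1) * bin_width
        rows.append({
            "bin_low": lo,
            "bin_high": hi,
            "intra": sum(lo <= d < hi for d in result.intra),
            "inter": sum(lo <= d < hi for d in result.inter),
        })
    return pd.DataFrame(rows)
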