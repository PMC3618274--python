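"""Worked example: a published-style support matrix for a land-snail complex.

A Mediterranean decollate-snail complex (genus *Rumina*) is a classic hard
case for species delimitation: two nominal species, one of them harboring
several deeply diverged mitochondrial MOTUs, nested sub-MOTUs, a singleton
MOTU, and a composite hypothesis that reassigns two haplotypes from one
MOTU to another. This module encodes that hypothesis structure and the
decisions (+ / - / na) that a panel of delimitation methods reaches on the
COI barcode data, as a ready-made input for the consensus species counter.

Hypotheses (id sets are one pseudo-id per atomic MOTU; tiling counts do
not depend on within-MOTU sample sizes):

* atomic: A, B, C, Da, Db, Ea1-2, Ea3-4, Eb1-4, Eb5-8, F, Sa, Sb
* nested: D = Da+Db; Ea = Ea1-2+Ea3-4; Eb = Eb1-4+Eb5-8; E = Ea+Eb;
  S = Sa+Sb; R_decollata = A..F; Rumina = R_decollata + S
* composite: "F+Ea1-2" = F plus the two reassigned haplotypes
"""

from __future__ import annotations

from .consensus import SupportMatrix, build_support_matrix
from .seqdata import GroupMap

__all__ = ["snail_group_map", "snail_support_matrix", "HYPOTHESES",
           "METHOD_DECISIONS"]

_ATOMS = ["A", "B", "C", "Da", "Db", "Ea1-2", "Ea3-4", "Eb1-4", "Eb5-8",
          "F", "Sa", "Sb"]

HYPOTHESES = ["A", "B", "C", "D", "Da", "Db", "E", "Ea", "Eb", "Ea3-4",
              "Eb1-4", "Eb5-8", "F", "F+Ea1-2", "S", "Sa", "Sb"]

# method -> {hypothesis: decision}; hypotheses a method leaves blank are
# simply absent. Decisions for the overall gap analysis (OGA), the fixed and
# fold threshold rules, distance partitioning (ABGD) and the
# single-threshold mixed Yule-coalescent model (GMYC) on the barcode data.
METHOD_DECISIONS: dict[str, dict[str, str]] = {
    "OGA": {
        "A": "+", "B": "na", "C": "+", "D": "-", "Da": "+", "Db": "+",
        "E": "-", "Ea": "-", "Eb": "+", "Ea3-4": "+", "Eb1-4": "+",
        "Eb5-8": "+", "F": "-", "F+Ea1-2": "+", "S": "+", "Sa": "+",
        "Sb": "+",
    },
    "PGA": {
        "A": "+", "B": "na", "C": "+", "D": "-", "Da": "+", "Db": "+",
        "E": "-", "Ea": "-", "Eb": "+", "Ea3-4": "+", "Eb1-4": "+",
        "Eb5-8": "+", "F": "-", "F+Ea1-2": "+", "S": "+", "Sa": "+",
        "Sb": "+",
    },
    "3pct": {
        "A": "+", "B": "na", "C": "+", "D": "-", "Da": "+", "Db": "-",
        "E": "-", "Ea": "-", "Eb": "-", "Ea3-4": "+", "Eb1-4": "+",
        "Eb5-8": "+", "F": "-", "F+Ea1-2": "+", "S": "-", "Sa": "+",
        "Sb": "+",
    },
    "4pct": {
        "A": "+", "B": "na", "C": "+", "D": "-", "Da": "+", "Db": "+",
        "E": "-", "Ea": "-", "Eb": "-", "Ea3-4": "+", "Eb1-4": "+",
        "Eb5-8": "+", "F": "+", "F+Ea1-2": "+", "S": "+", "Sa": "+",
        "Sb": "+",
    },
    "10x": {
        "A": "-", "B": "na", "C": "+", "D": "-", "Da": "+", "Db": "-",
        "E": "-", "Ea": "-", "Eb": "-", "Ea3-4": "+", "Eb1-4": "+",
        "Eb5-8": "-", "F": "-", "F+Ea1-2": "+", "S": "-", "Sa": "+",
        "Sb": "+",
    },
    "3.2-4.1x": {
        "A": "+", "B": "na", "C": "+", "D": "-", "Da": "+", "Db": "+",
        "E": "-", "Ea": "-", "Eb": "-", "Ea3-4": "+", "Eb1-4": "+",
        "Eb5-8": "+", "F": "-", "F+Ea1-2": "+", "S": "+", "Sa": "+",
        "Sb": "+",
    },
    "ABGD": {
        "A": "+", "B": "na", "C": "+", "Da": "+", "Db": "+", "Ea": "-",
        "Eb": "+", "Ea3-4": "+", "Eb1-4": "-", "Eb5-8": "-", "F": "-",
        "F+Ea1-2": "+", "Sa": "+", "Sb": "+",
    },
    "GMYC": {
        "A": "+", "B": "na", "C": "+", "D": "-", "Da": "+", "Db": "+",
        "Ea": "-", "Eb": "-", "Ea3-4": "+", "Eb1-4": "+", "Eb5-8": "+",
        "F": "-", "F+Ea1-2": "+", "S": "-", "Sa": "+", "Sb": "+",
    },
}


def snail_group_map() -> GroupMap:
    """Group map with one pseudo-id per atomic MOTU and the full nesting."""
    assignments = {f"id_{a}": a for a in _ATOMS}
    nesting = {
        "D": {"Da", "Db"},
        "Ea": {"Ea1-2", "Ea3-4"},
        "Eb": {"Eb1-4", "Eb5-8"},
        "E": {"Ea", "Eb"},
        "S": {"Sa", "Sb"},
        "R_decollata": {"A", "B", "C", "D", "E", "F"},
        "Rumina": {"R_decollata", "S"},
    }
    aliases = {"F+Ea1-2": {"F", "Ea1-2"}}
    gm = GroupMap(assignments, nesting, aliases)
    gm.validate()
    return gm


def snail_support_matrix() -> SupportMatrix:
    """The method x hypothesis support matrix of the worked example."""
    return build_support_matrix(snail_group_map(), HYPOTHESES,
                                METHOD_DECISIONS)
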