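"""Shared fixtures: tiny alignments, trees and group maps built in memory."""

import dendropy
import pytest
from hypothesis import HealthCheck, settings

from motudelim.seqdata import AlignedLocus, GroupMap

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture
def toy_locus() -> AlignedLocus:
    """Four 12-bp sequences: two tight pairs separated by many differences."""
    return AlignedLocus(
        "toy",
        ["a1", "a2", "b1", "b2"],
        [
            "ACGTACGTACGT",
            "ACGTACGTACGA",  # 1 diff from a1
            "TGCATGCATGCA",
            "TGCATGCATGCC",  # 1 diff from b1
        ],
    )


@pytest.fixture
def toy_groups() -> GroupMap:
    return GroupMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


@pytest.fixture
def balanced_tree() -> dendropy.Tree:
    """Ultrametric 4-tip tree: ((a:1,b:1):1,(c:1,d:1):1);"""
    return tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
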