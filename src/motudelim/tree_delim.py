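"""Tree-topology delimitation statistics.

* monophyly test and the genealogical sorting index (GSI) with a
  tip-label permutation test,
* Holm's sequential Bonferroni correction,
* Rosenberg's P_AB — the probability that two labeled groups are
  reciprocally monophyletic under the equiprobable-coalescent-history null,
* Rodrigo's P(RD) — the probability that a clade is as "randomly distinct"
  as observed (crown-to-tip depth over stem length) under a neutral
  coalescent null,
* an SDP-style per-group summary: mean intra patristic distance, distance
  to the closest group, their ratio, and P ID(Strict) — the leave-one-out
  proportion of members whose nearest tip lies inside the group, with a
  Wilson 95% confidence interval.

GSI definition used here: with U the internal nodes of the minimal spanning
subtree connecting the group's tips up to and including their MRCA, and
``c_u`` the child count of node u,

    GS  = n / sum_{u in U} (c_u - 1)
    gsi = (GS - GS_min) / (GS_max - GS_min)

where GS_max is attained under monophyly (U = the n-1 binary nodes of an
exclusive clade) and GS_min when U spans every internal node of the tree.
gsi = 1 iff the group is monophyletic; the (c_u - 1) weight handles
polytomies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import dendropy
import numpy as np
from scipy.stats import norm

__all__ = [
    "GsiResult", "PabResult", "PrdResult", "SdpSummary",
    "is_monophyletic", "gsi", "gsi_test", "sequential_bonferroni",
    "rosenberg_pab", "rosenberg_pab_enumeration", "rodrigo_prd",
    "patristic_matrix", "sdp_summary", "simulate_coalescent_tree",
]


# ---------------------------------------------------------------- monophyly

def _tip_nodes(tree: dendropy.Tree, group: set[str]) -> list[dendropy.Node]:
    labels = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = set(group) - set(labels)
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")
    return [labels[g] for g in sorted(group)]


def is_monophyletic(tree: dendropy.Tree, group: set[str]) -> bool:
    """True iff the MRCA of ``group`` subtends exactly ``group``."""
    if not group:
        raise ValueError("empty group")
    nodes = _tip_nodes(tree, set(group))
    mrca = tree.mrca(taxa=[n.taxon for n in nodes])
    under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return under == set(group)


# ---------------------------------------------------------------------- GSI

def _gs_denominator(nodes) -> int:
    return sum(len(u.child_nodes()) - 1 for u in nodes)


def gsi(tree: dendropy.Tree, group: set[str]) -> float:
    """Genealogical sorting index of ``group`` on a rooted tree."""
    group = set(group)
    n = len(group)
    all_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if n < 2:
        raise ValueError("group must have at least two members")
    if group >= all_tips:
        raise ValueError("group must be a proper subset of the tips")
    tips = _tip_nodes(tree, group)
    mrca = tree.mrca(taxa=[t.taxon for t in tips])
    # U: internal nodes on paths tip -> MRCA, MRCA included
    uniting: set[int] = set()
    unodes = []
    for t in tips:
        node = t.parent_node
        while node is not None:
            if id(node) not in uniting:
                uniting.add(id(node))
                unodes.append(node)
            if node is mrca:
                break
            node = node.parent_node
    gs_obs = n / _gs_denominator(unodes)
    # maximal sorting: an exclusive binary clade of n tips has n-1 nodes of
    # 2 children each
    gs_max = n / (n - 1)
    # minimal sorting: U spans every internal node of the tree
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    gs_min = n / _gs_denominator(internal)
    if gs_max == gs_min:
        return 1.0
    return (gs_obs - gs_min) / (gs_max - gs_min)


@dataclass
class GsiResult:
    group: str
    gsi: float
    n: int
    p_value: float
    n_permutations: int
    seed: int | None


def gsi_test(tree: dendropy.Tree, group: set[str], n_perm: int = 10_000,
             seed: int | None = None, label: str = "group") -> GsiResult:
    """GSI with a permutation p-value.

    The null permutes tip labels (preserving group size) and recomputes the
    index; p = (1 + #{permuted gsi >= observed}) / (1 + n_perm), so p is
    never exactly zero.
    """
    group = set(group)
    observed = gsi(tree, group)
    all_tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = set(rng.choice(all_tips, size=len(group), replace=False))
        if gsi(tree, perm) >= observed - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return GsiResult(label, observed, len(group), p, n_perm, seed)


def sequential_bonferroni(p_values, alpha: float = 0.05) -> list[bool]:
    """Holm's step-down correction; returns a flag per input p-value."""
    p = list(p_values)
    if not p:
        raise ValueError("no p-values")
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    flags = [False] * m
    for rank, k in enumerate(order):
        if p[k] <= alpha / (m - rank):
            flags[k] = True
        else:
            break
    return flags


# ------------------------------------------------------------ Rosenberg P_AB

@dataclass
class PabResult:
    a: int
    b: int
    p_ab: float
    method: str


@lru_cache(maxsize=None)
def _pab_closed_form(a: int, b: int) -> float:
    """P(reciprocal monophyly) of groups sized a, b among a+b tips.

    Under the null that every sequence of coalescent joins is equally
    likely: both groups must resolve internally before the final root join,
    giving

        P = 2 * C(a+b-2, a-1) * a!(a-1)! * b!(b-1)! / [(a+b)! (a+b-1)!]

    (two singleton groups are trivially reciprocally monophyletic).
    """
    if a < 1 or b < 1:
        raise ValueError("group sizes must be >= 1")
    n = a + b
    num = (2 * math.comb(n - 2, a - 1)
           * math.factorial(a) * math.factorial(a - 1)
           * math.factorial(b) * math.factorial(b - 1))
    return num / (math.factorial(n) * math.factorial(n - 1))


def rosenberg_pab(a: int, b: int) -> PabResult:
    """Probability of chance reciprocal monophyly for group sizes a and b."""
    return PabResult(a, b, _pab_closed_form(a, b), "closed-form")


def rosenberg_pab_enumeration(a: int, b: int) -> PabResult:
    """Exhaustive enumeration over equiprobable coalescent join sequences.

    Independent of the closed form; exponential cost, intended for
    a + b <= 8.
    """
    if a < 1 or b < 1:
        raise ValueError("group sizes must be >= 1")
    # lineages are frozensets of tip indices; group A = 0..a-1, B = a..a+b-1
    group_a = frozenset(range(a))
    start = tuple(frozenset([i]) for i in range(a + b))

    @lru_cache(maxsize=None)
    def n_histories(k: int) -> int:
        """Join sequences taking k lineages down to 1: prod C(j,2)."""
        t = 1
        while k > 1:
            t *= k * (k - 1) // 2
            k -= 1
        return t

    def count(lineages: tuple) -> tuple[int, int]:
        """(#histories, #reciprocally-monophyletic histories) from state.

        Every lineage here is pure (all-A or all-B): a merge mixing the two
        groups before the final root join makes reciprocal monophyly
        impossible, so those subtrees are counted in closed form and not
        entered.
        """
        k = len(lineages)
        if k == 1:
            return 1, 1
        total = good = 0
        for i in range(k):
            for j in range(i + 1, k):
                x, y = lineages[i], lineages[j]
                x_in_a = bool(x & group_a)
                y_in_a = bool(y & group_a)
                if x_in_a != y_in_a:  # merge mixes the groups
                    total += n_histories(k - 1)
                    if k == 2:  # the root join of the two complete groups
                        good += 1
                    continue
                rest = tuple(l for idx, l in enumerate(lineages)
                             if idx not in (i, j)) + (x | y,)
                t, g = count(rest)
                total += t
                good += g
        return total, good

    total, good = count(start)
    return PabResult(a, b, good / total, "enumeration")


# -------------------------------------------------------------- Rodrigo P(RD)

@dataclass
class PrdResult:
    r_obs: float
    p_value: float
    n_sim: int
    clade_size: int
    seed: int | None
    tail: str = "lower"


def _node_age(node: dendropy.Node) -> float:
    """Mean path length from a node down to its tip descendants."""
    leaves = list(node.leaf_iter())
    total = 0.0
    for leaf in leaves:
        d, cur = 0.0, leaf
        while cur is not node:
            d += cur.edge.length or 0.0
            cur = cur.parent_node
        total += d
    return total / len(leaves)


def simulate_coalescent_tree(n_tips: int, rng: np.random.Generator,
                             pop_size: float = 1.0) -> dendropy.Tree:
    """Neutral Kingman coalescent tree with exponential waiting times.

    Times are in units of ``pop_size`` generations; branch lengths are the
    coalescent intervals.
    """
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    nodes = []
    for i in range(n_tips):
        nd = dendropy.Node(taxon=taxa[i])
        nd.age = 0.0
        nodes.append(nd)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(pop_size / (k * (k - 1) / 2))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.age = t
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - a.age
        b.edge.length = t - b.age
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def rodrigo_prd(tree: dendropy.Tree, clade: dendropy.Node | set[str],
                n_sim: int = 1_000, seed: int | None = None) -> PrdResult:
    """Probability that a clade is as distinct as observed by chance.

    Distinctiveness ratio r = (mean node-to-tip depth) / (stem branch
    length); small r means a shallow crown on a long stem, i.e. a distinct
    clade. The null distribution is built from size-matched clades on
    simulated neutral coalescent trees with the same tip count as the input
    tree; p = proportion of null ratios <= r_obs (lower tail).
    """
    if isinstance(clade, (set, frozenset, list, tuple)):
        nodes = _tip_nodes(tree, set(clade))
        node = tree.mrca(taxa=[n.taxon for n in nodes])
    else:
        node = clade
    if node.parent_node is None:
        raise ValueError("the root has no stem branch")
    stem = node.edge.length or 0.0
    crown = _node_age(node)
    size = len(list(node.leaf_iter()))
    r_obs = math.inf if stem == 0 else crown / stem
    n_tips = len(list(tree.leaf_node_iter()))
    rng = np.random.default_rng(seed)
    null: list[float] = []
    while len(null) < n_sim:
        sim = simulate_coalescent_tree(n_tips, rng)
        for nd in sim.preorder_internal_node_iter():
            if nd.parent_node is None:
                continue
            if len(list(nd.leaf_iter())) == size:
                s = nd.edge.length or 0.0
                null.append(math.inf if s == 0 else _node_age(nd) / s)
        if size == 1:  # singleton "clades" are the tips themselves
            for nd in sim.leaf_node_iter():
                null.append(0.0)
    null = null[:n_sim]
    if math.isinf(r_obs):
        p = 1.0
    else:
        p = sum(x <= r_obs for x in null) / len(null)
    return PrdResult(r_obs, p, len(null), size, seed)


# ------------------------------------------------------------------ SDP block

@dataclass
class SdpSummary:
    group: str
    closest_group: str
    intra: float | None  # None = n/c (singleton)
    inter: float
    ratio: float | None
    p_id_strict: float
    p_id_ci: tuple[float, float]


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip labels and the matrix of path lengths between tips."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return labels, mat


def _wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    z = norm.ppf(0.5 + conf / 2)
    phat = k / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def sdp_summary(tree: dendropy.Tree, groups, focal: str) -> SdpSummary:
    """Per-group summary of patristic differentiation and identifiability.

    Intra = mean pairwise patristic distance within the focal group (n/c for
    singletons); the closest group minimizes the mean between-group
    patristic distance, and Inter is that minimum. P ID(Strict) is a
    leave-one-out nearest-neighbor criterion: the proportion of focal
    members whose nearest tip (excluding themselves) belongs to the focal
    group, with a Wilson 95% CI. It approximates the "falls inside the
    clade" identification probability.
    """
    labels, mat = patristic_matrix(tree)
    idx = {l: k for k, l in enumerate(labels)}
    focal_ids = sorted(groups.members(focal) & set(labels))
    if not focal_ids:
        raise ValueError(f"focal group {focal!r} has no tips in the tree")
    partner_labels = [g for g in groups.terminal_labels()
                      if g != focal and not (groups.members(g) & set(focal_ids))]
    # mean between-group distance per partner
    best, best_d = None, math.inf
    for g in partner_labels:
        gids = sorted(groups.members(g) & set(labels))
        if not gids:
            continue
        d = float(np.mean([mat[idx[i], idx[j]] for i in focal_ids for j in gids]))
        if d < best_d:
            best, best_d = g, d
    if best is None:
        raise ValueError("no partner group shares tips with the tree")
    if len(focal_ids) >= 2:
        intra = float(np.mean([mat[idx[i], idx[j]]
                               for k, i in enumerate(focal_ids)
                               for j in focal_ids[k + 1:]]))
        ratio = intra / best_d if best_d > 0 else math.inf
    else:
        intra, ratio = None, None
    # leave-one-out nearest neighbor
    focal_set = set(focal_ids)
    hits = 0
    for i in focal_ids:
        row = mat[idx[i]].copy()
        row[idx[i]] = math.inf
        nearest = labels[int(np.argmin(row))]
        if nearest in focal_set:
            hits += 1
    p_hat = hits / len(focal_ids)
    return SdpSummary(focal, best, intra, best_d, ratio, p_hat,
                      _wilson_ci(hits, len(focal_ids)))
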