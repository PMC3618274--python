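"""General mixed Yule-coalescent (GMYC) species delimitation.

The model assumes an ultrametric, binary gene tree on which branching
switches from a between-species (diversification) process to within-species
(coalescent) processes at one or more transition points. For each
inter-node interval i of duration ``x_i`` the total branching rate is

    b_i = lambda_div * k_i^p_div  +  lambda_coal * sum_j (n_ij (n_ij - 1))^p_coal

where ``k_i`` counts species-level lineages and ``n_ij`` counts lineages
within species j during the interval. The log-likelihood over the waiting
intervals ending in a branching event is ``sum_i [ln b_i - b_i x_i]``.
The null model is a single process, ``b_i = lambda * (n_i (n_i-1))^p``,
i.e. all tips belong to one species.

The single-threshold fit profiles the transition age over the observed
inter-node intervals (any age within an interval gives the same
classification, so candidates are interval midpoints, including "above the
root" — which reproduces the null — and "below every node" — every tip its
own species). The likelihood-ratio test against the null uses df = 3
(5 free parameters against 2). The multiple-threshold fit refines the
single-threshold solution greedily: one species subtree at a time has its
crown node promoted to a diversification event, keeping the move that most
improves the likelihood, until AIC stops improving.

Tips below a transition point form entities: clusters (>= 2 tips) or
singletons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .seqdata import check_ultrametric

__all__ = [
    "GmycFit", "prepare_ultrametric", "fit_gmyc_null",
    "fit_gmyc_single", "fit_gmyc_multiple", "extract_entities",
]

_AGE_ATTR = "age"


# --------------------------------------------------------------- preparation

def _assign_ages(tree: dendropy.Tree) -> float:
    """Annotate every node with its age (height above the tips)."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[id(node)] = 0.0
        else:
            depths[id(node)] = depths[id(node.parent_node)] + (node.edge.length or 0.0)
    height = max(depths[id(l)] for l in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        node.age = height - depths[id(node)]
    return height


def prepare_ultrametric(tree: dendropy.Tree, tolerance: float = 1e-6,
                        jitter: float = 1e-8, seed: int | None = None) -> dendropy.Tree:
    """Validate ultrametricity, resolve polytomies, break age ties.

    Polytomies are resolved into bifurcations with zero-length branches,
    children taken in sorted leaf-label order so the resolution is
    deterministic. Branching-time ties (including the zero-length branches
    just created) are broken by a seeded jitter of ``jitter`` x tree height
    so every waiting interval is positive. Rate smoothing is not performed:
    non-ultrametric input beyond ``tolerance`` is an error.
    """
    tree = tree.clone(depth=1)
    check_ultrametric(tree, tolerance)

    def leaf_key(node):
        return min(l.taxon.label for l in node.leaf_iter())

    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        if len(children) <= 2:
            continue
        children = sorted(children, key=leaf_key)
        for ch in children:
            node.remove_child(ch)
        # left-ladder with zero-length internal branches
        current = node
        remaining = list(children)
        while len(remaining) > 2:
            new = dendropy.Node()
            new.edge.length = 0.0
            current.add_child(new)
            current.add_child(remaining.pop(0))
            current = new
        current.add_child(remaining.pop(0))
        current.add_child(remaining.pop(0))

    height = _assign_ages(tree)
    internal_ages = sorted({round(n.age, 12) for n in tree.preorder_internal_node_iter()})
    has_ties = len(internal_ages) < sum(1 for _ in tree.preorder_internal_node_iter())
    if has_ties and jitter > 0:
        rng = np.random.default_rng(seed)
        eps = jitter * height
        seen: set[float] = set()
        # push tied/zero-interval nodes apart by tiny, age-decreasing offsets
        for node in tree.preorder_internal_node_iter():
            a = node.age
            while a in seen or (node.parent_node is not None
                                and a >= node.parent_node.age):
                a -= eps * (1.0 + rng.random())
                if node.parent_node is not None:
                    a = min(a, node.parent_node.age - eps * (1.0 + rng.random()))
            node.age = max(a, 0.0 if node.is_leaf() else eps)
            seen.add(node.age)
        # rebuild branch lengths from the adjusted ages
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            child_age = node.age if not node.is_leaf() else 0.0
            node.edge.length = node.parent_node.age - child_age
        _assign_ages(tree)
    return tree


# ----------------------------------------------------------- interval tables

class _IntervalData:
    """Threshold-independent bookkeeping for one prepared tree.

    ``ages``: internal-node ages, descending (root first).
    ``x``: durations of the n-2 waiting intervals ending in an event.
    ``cross[e, i]``: edge e spans interval i.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.height = _assign_ages(tree)
        internals = list(tree.preorder_internal_node_iter())
        if len(internals) < 2:
            raise ValueError("need at least 3 tips (2 internal nodes)")
        for node in internals:
            if len(node.child_nodes()) != 2:
                raise ValueError("tree must be binary; resolve polytomies first")
        self.ages = np.sort(np.array([n.age for n in internals]))[::-1]
        if np.any(np.diff(self.ages) == 0):
            raise ValueError("tied node ages; run prepare_ultrametric with jitter")
        n_int = len(self.ages) - 1  # n - 2 intervals
        self.x = self.ages[:-1] - self.ages[1:]
        self.n_tips = len(internals) + 1
        # edges, excluding the root's (non-existent) stem
        self.edges = [nd for nd in tree.preorder_node_iter()
                      if nd.parent_node is not None]
        parent_age = np.array([e.parent_node.age for e in self.edges])
        child_age = np.array([e.age if not e.is_leaf() else 0.0
                              for e in self.edges])
        mid = (self.ages[:-1] + self.ages[1:]) / 2.0
        self.cross = ((parent_age[:, None] > mid[None, :])
                      & (child_age[:, None] < mid[None, :]))
        self.parent_age = parent_age
        self.n_intervals = n_int
        # candidate thresholds: midpoints of inter-node gaps, one above the
        # root (the null configuration) and one below the youngest node
        self.thresholds = np.concatenate([
            [self.ages[0] * 1.01 + 1e-12],
            mid,
            [self.ages[-1] / 2.0],
        ])

    def classify(self, threshold: float):
        """Per-interval diversification counts and coalescent class sizes.

        Returns ``(k, seg, pairs)``: ``k[i]`` species-level lineages in
        interval i; ``pairs`` the flat array of ``n (n-1)`` for every
        coalescent class with >= 2 lineages, ``seg`` its interval indices.
        """
        # species roots: maximal nodes with age < threshold (tips included)
        species_of: dict[int, int] = {}
        n_species = 0
        for node in self.tree.preorder_node_iter():
            age = node.age if not node.is_leaf() else 0.0
            parent = node.parent_node
            if parent is not None and id(parent) in species_of:
                species_of[id(node)] = species_of[id(parent)]
            elif age < threshold:
                species_of[id(node)] = n_species
                n_species += 1
        return self._tabulate(species_of, n_species)

    def _tabulate(self, species_of: dict[int, int], n_species: int):
        # coalescent edges are those whose parent lies inside a species
        coal_species = np.array([
            species_of.get(id(e.parent_node), -1) for e in self.edges
        ])
        is_coal = coal_species >= 0
        k = (~is_coal[:, None] & self.cross).sum(axis=0)
        seg_list, pair_list = [], []
        for i in range(self.n_intervals):
            active = coal_species[is_coal & self.cross[:, i]]
            if active.size:
                counts = np.bincount(active, minlength=n_species)
                sizes = counts[counts >= 2]
                for s in sizes:
                    seg_list.append(i)
                    pair_list.append(s * (s - 1))
        seg = np.array(seg_list, dtype=int)
        pairs = np.array(pair_list, dtype=float)
        return k.astype(float), seg, pairs

    def classify_roots(self, roots: list) -> tuple:
        """Classification from an explicit species-root node set."""
        species_of: dict[int, int] = {}
        root_ids = {id(r): s for s, r in enumerate(roots)}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            if id(node) in root_ids:
                species_of[id(node)] = root_ids[id(node)]
            elif parent is not None and id(parent) in species_of:
                species_of[id(node)] = species_of[id(parent)]
        return self._tabulate(species_of, len(roots))


# ------------------------------------------------------------------ fitting

@dataclass
class GmycFit:
    model: str  # "null" | "single" | "multiple"
    logL: float
    params: dict
    thresholds: list[float] = field(default_factory=list)
    entities: list[set[str]] = field(default_factory=list)
    logL_null: float | None = None
    df: int | None = None
    seed: int | None = None

    @property
    def lr(self) -> float | None:
        if self.logL_null is None:
            return None
        return 2.0 * (self.logL - self.logL_null)

    @property
    def p_value(self) -> float | None:
        if self.logL_null is None or self.df is None:
            return None
        return float(chi2.sf(max(self.lr, 0.0), self.df))

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_clusters(self) -> int:
        return sum(1 for e in self.entities if len(e) >= 2)

    @property
    def aic(self) -> float:
        k = {"null": 2, "single": 5}.get(self.model)
        if k is None:  # multiple: 4 rate params + #thresholds
            k = 4 + len(self.thresholds)
        return 2 * k - 2 * self.logL


def _null_loglik(data: _IntervalData, p: float) -> tuple[float, float]:
    n_lineages = np.arange(2, data.n_intervals + 2, dtype=float)
    g = (n_lineages * (n_lineages - 1.0)) ** p
    m = data.n_intervals
    lam = m / float(g @ data.x)
    logL = m * math.log(lam) + float(np.log(g).sum()) - m
    return logL, lam


def fit_gmyc_null(tree: dendropy.Tree, data: _IntervalData | None = None) -> GmycFit:
    """Single-process fit: every tip in one species.

    lambda has a closed-form profile at fixed p; p is optimized on [0, 2].
    """
    data = data or _IntervalData(tree)
    res = minimize_scalar(lambda p: -_null_loglik(data, p)[0],
                          bounds=(0.0, 2.0), method="bounded")
    p_hat = float(res.x)
    logL, lam = _null_loglik(data, p_hat)
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    return GmycFit("null", logL, {"lambda": lam, "p": p_hat},
                   entities=[tips])


def _mixed_loglik(theta, k, seg, pairs, x) -> float:
    log_ld, pd, log_lc, pc = theta
    lam_d, lam_c = math.exp(log_ld), math.exp(log_lc)
    b = np.zeros_like(x)
    nz = k > 0
    b[nz] += lam_d * k[nz] ** pd
    if pairs.size:
        np.add.at(b, seg, lam_c * pairs ** pc)
    if np.any(b <= 0):
        return -np.inf
    return float(np.log(b).sum() - b @ x)


def _optimize_mixed(k, seg, pairs, x, starts) -> tuple[float, np.ndarray]:
    bounds = [(-25.0, 25.0), (0.0, 2.0), (-25.0, 25.0), (0.0, 2.0)]
    best_val, best_theta = -np.inf, None
    for theta0 in starts:
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(lambda t: -_mixed_loglik(t, k, seg, pairs, x),
                       theta0, method="L-BFGS-B", bounds=bounds)
        if -res.fun > best_val:
            best_val, best_theta = -res.fun, res.x
    if best_theta is None or not np.isfinite(best_val):
        raise RuntimeError("GMYC optimization failed for every start point")
    return best_val, best_theta


def _default_starts(extra=None):
    starts = [np.array([0.0, 1.0, 0.0, 1.0]),
              np.array([math.log(10.0), 1.0, math.log(10.0), 1.0])]
    if extra is not None:
        starts.append(np.asarray(extra, dtype=float))
    return starts


def _theta_to_params(theta) -> dict:
    return {"lambda_div": math.exp(theta[0]), "p_div": float(theta[1]),
            "lambda_coal": math.exp(theta[2]), "p_coal": float(theta[3])}


def extract_entities(tree: dendropy.Tree, threshold: float) -> list[set[str]]:
    """Tip sets of the maximal subtrees whose root age is below ``threshold``."""
    _assign_ages(tree)
    entities = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        age = node.age if not node.is_leaf() else 0.0
        if age < threshold:
            entities.append({l.taxon.label for l in node.leaf_iter()})
        else:
            stack.extend(node.child_nodes())
    return sorted(entities, key=lambda s: sorted(s)[0])


def _species_roots(tree: dendropy.Tree, threshold: float) -> list:
    roots = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        age = node.age if not node.is_leaf() else 0.0
        if age < threshold:
            roots.append(node)
        else:
            stack.extend(node.child_nodes())
    return roots


def fit_gmyc_single(tree: dendropy.Tree, df: int = 3) -> GmycFit:
    """Single-threshold GMYC fit with a likelihood-ratio test vs the null.

    The transition age is profiled over the inter-node intervals; the four
    rate parameters are re-optimized for each candidate (warm-started from
    the previous optimum). df defaults to 3: (lambda_div, p_div,
    lambda_coal, p_coal, T) against (lambda, p).
    """
    data = _IntervalData(tree)
    null = fit_gmyc_null(tree, data)
    best = (-np.inf, None, None)  # logL, threshold, theta
    prev_theta = None
    for T in data.thresholds:
        k, seg, pairs = data.classify(T)
        logL, theta = _optimize_mixed(k, seg, pairs, data.x,
                                      _default_starts(prev_theta))
        prev_theta = theta
        if logL > best[0]:
            best = (logL, float(T), theta)
    logL, T, theta = best
    fit = GmycFit("single", logL, _theta_to_params(theta), thresholds=[T],
                  entities=extract_entities(tree, T),
                  logL_null=null.logL, df=df)
    if fit.lr < -1e-6:
        raise RuntimeError("single-threshold fit fell below the null; "
                           "optimization diagnostics: "
                           f"logL={logL:.4f} null={null.logL:.4f}")
    return fit


def fit_gmyc_multiple(tree: dendropy.Tree, max_thresholds: int = 10,
                      df: int | None = None) -> GmycFit:
    """Greedy multiple-threshold GMYC fit.

    Starting from the single-threshold solution, the crown node of one
    species subtree at a time is promoted to a diversification event (the
    move that most increases the likelihood), with all four rate parameters
    refit after each move; promotion stops when AIC no longer improves or
    ``max_thresholds`` is reached. Each promotion contributes one
    transition age. df for the LR test against the null defaults to
    2 + #thresholds (one per transition age plus the two extra rate
    parameters), which is configurable.
    """
    data = _IntervalData(tree)
    single = fit_gmyc_single(tree)
    roots = _species_roots(data.tree, single.thresholds[0])
    best_logL = single.logL
    theta = np.array([
        math.log(single.params["lambda_div"]), single.params["p_div"],
        math.log(single.params["lambda_coal"]), single.params["p_coal"]])
    thresholds = list(single.thresholds)
    n_extra = 0
    while len(thresholds) < max_thresholds:
        candidates = [r for r in roots if not r.is_leaf()]
        move_best = (-np.inf, None, None)
        for r in candidates:
            trial = [n for n in roots if n is not r] + r.child_nodes()
            k, seg, pairs = data.classify_roots(trial)
            logL, th = _optimize_mixed(k, seg, pairs, data.x,
                                       _default_starts(theta))
            if logL > move_best[0]:
                move_best = (logL, r, th)
        if move_best[1] is None:
            break
        # AIC gain: one extra threshold parameter per promotion
        aic_old = 2 * (4 + len(thresholds)) - 2 * best_logL
        aic_new = 2 * (4 + len(thresholds) + 1) - 2 * move_best[0]
        if aic_new >= aic_old:
            break
        logL, r, theta = move_best
        roots = [n for n in roots if n is not r] + r.child_nodes()
        best_logL = logL
        thresholds.append(float(r.age))
        n_extra += 1
    entities = [
        {l.taxon.label for l in r.leaf_iter()} if not r.is_leaf()
        else {r.taxon.label}
        for r in roots
    ]
    null = fit_gmyc_null(tree, data)
    if df is None:
        df = 2 + len(thresholds)
    fit = GmycFit("multiple", best_logL, _theta_to_params(theta),
                  thresholds=sorted(thresholds, reverse=True),
                  entities=sorted(entities, key=lambda s: sorted(s)[0]),
                  logL_null=null.logL, df=df)
    return fit
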