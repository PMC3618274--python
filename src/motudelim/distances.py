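"""Pairwise p- and Kimura 2-parameter distances and group summaries.

K2P corrects separately for transitions (proportion P) and transversions
(proportion Q) over the comparable sites of a pair:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Comparable sites are those where both sequences carry an unambiguous base
(A, C, G or T); gaps, ``'?'`` and IUPAC ambiguity codes are excluded.
Deletion policy ``complete`` removes every column with a non-base character
in *any* sequence before any pair is compared; ``pairwise`` removes columns
per pair. Saturated pairs (a log argument <= 0) are flagged inapplicable
(NaN), never clamped.

Group summaries mirror the usual barcode-study table: mean within-group
distance on the diagonal ("n/c" for singletons) and mean between-group
distance off it, with standard errors from a bootstrap over alignment sites.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdata import AlignedLocus, GroupMap

__all__ = [
    "DistanceMatrix",
    "GroupDistanceSummary",
    "p_distance",
    "k2p_distance",
    "compute_distance_matrix",
    "group_distance_summary",
]

_BASES = "ACGT"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)


def _comparable_mask(a: str, b: str) -> list[bool]:
    return [x in _BASES and y in _BASES for x, y in zip(a, b)]


def _complete_mask(rows: list[str]) -> list[bool]:
    return [all(r[j] in _BASES for r in rows) for j in range(len(rows[0]))]


def _pq(a: str, b: str, mask) -> tuple[float, float, int]:
    """Transition and transversion proportions over masked sites."""
    n = ts = tv = 0
    for x, y, m in zip(a, b, mask):
        if not m:
            continue
        n += 1
        if x != y:
            if _is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites between the two sequences")
    return ts / n, tv / n, n


def p_distance(a: str, b: str, deletion: str = "pairwise",
               mask=None) -> float:
    """Proportion of differing comparable sites."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if mask is None:
        mask = _comparable_mask(a, b) if deletion == "pairwise" else _complete_mask([a, b])
    P, Q, _ = _pq(a, b, mask)
    return P + Q


def k2p_distance(a: str, b: str, deletion: str = "pairwise",
                 mask=None) -> float:
    """Kimura 2-parameter distance; NaN when the correction saturates."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if mask is None:
        mask = _comparable_mask(a, b) if deletion == "pairwise" else _complete_mask([a, b])
    P, Q, _ = _pq(a, b, mask)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("nan")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over sequence or haplotype ids."""

    ids: list[str]
    matrix: np.ndarray
    model: str = "p"  # {"p", "K2P"}
    deletion: str = "pairwise"  # {"complete", "pairwise"}
    source: AlignedLocus | None = None  # alignment used, for site bootstrap

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.matrix)
        if not np.array_equal(self.matrix[finite & finite.T],
                              self.matrix.T[finite & finite.T]):
            raise ValueError("matrix must be symmetric")

    def get(self, i: str, j: str) -> float:
        a, b = self.ids.index(i), self.ids.index(j)
        return float(self.matrix[a, b])

    def pairs(self, ids_a, ids_b=None) -> list[float]:
        """Distances within ``ids_a`` or between ``ids_a`` and ``ids_b``.

        Inapplicable (NaN) entries are excluded with a warning.
        """
        index = {i: k for k, i in enumerate(self.ids)}
        if ids_b is None:
            raw = [self.matrix[index[i], index[j]]
                   for i, j in itertools.combinations(sorted(ids_a), 2)]
        else:
            raw = [self.matrix[index[i], index[j]]
                   for i in sorted(ids_a) for j in sorted(ids_b)]
        vals = [float(v) for v in raw if np.isfinite(v)]
        if len(vals) < len(raw):
            warnings.warn(
                f"{len(raw) - len(vals)} saturated/inapplicable pair(s) excluded",
                stacklevel=2)
        return vals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def compute_distance_matrix(locus: AlignedLocus, model: str = "K2P",
                            deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs distance matrix from an aligned locus."""
    if model not in ("p", "K2P"):
        raise ValueError(f"unknown model: {model!r}")
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion policy: {deletion!r}")
    fn = p_distance if model == "p" else k2p_distance
    n = len(locus.ids)
    mat = np.zeros((n, n))
    global_mask = _complete_mask(locus.rows) if deletion == "complete" else None
    for i in range(n):
        for j in range(i + 1, n):
            mask = global_mask
            if mask is None:
                mask = _comparable_mask(locus.rows[i], locus.rows[j])
            d = fn(locus.rows[i], locus.rows[j], mask=mask)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(list(locus.ids), mat, model=model,
                          deletion=deletion, source=locus)


@dataclass
class GroupDistanceSummary:
    """Within/between-group mean distances with bootstrap standard errors.

    ``within[g]`` and ``between[(g1, g2)]`` are ``(mean, se)``; singleton
    groups report ``None`` ("n/c", not computable) for within.
    """

    groups: list[str]
    within: dict[str, tuple[float, float] | None]
    between: dict[tuple[str, str], tuple[float, float]]
    model: str
    n_boot: int
    seed: int | None

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        for g1 in self.groups:
            row = {}
            for g2 in self.groups:
                if g1 == g2:
                    w = self.within[g1]
                    row[g2] = "n/c" if w is None else f"{w[0]:.3f}±{w[1]:.3f}"
                else:
                    key = (min(g1, g2), max(g1, g2))
                    m, se = self.between[key]
                    row[g2] = f"{m:.3f}±{se:.3f}"
            rows[g1] = row
        return pd.DataFrame(rows).T


def _group_means(D: DistanceMatrix, group_ids: dict[str, set[str]]):
    labels = sorted(group_ids)
    within = {}
    between = {}
    for g in labels:
        vals = D.pairs(group_ids[g])
        within[g] = float(np.mean(vals)) if vals else None
    for g1, g2 in itertools.combinations(labels, 2):
        vals = D.pairs(group_ids[g1], group_ids[g2])
        between[(g1, g2)] = float(np.mean(vals))
    return within, between


def group_distance_summary(D: DistanceMatrix, groups: GroupMap,
                           n_boot: int = 500, seed: int | None = None,
                           labels: list[str] | None = None) -> GroupDistanceSummary:
    """Mean within/between-group distances with site-bootstrap SEs.

    The standard error is the standard deviation of the group mean across
    ``n_boot`` alignments resampled column-wise with replacement, the usual
    convention for distance-table SEs. Requires ``D.source`` (the alignment
    the matrix came from).
    """
    if labels is None:
        labels = groups.terminal_labels()
    group_ids = {}
    for g in labels:
        members = groups.members(g) & set(D.ids)
        if not members:
            raise ValueError(f"group {g!r} has no members in the matrix")
        group_ids[g] = members
    within, between = _group_means(D, group_ids)
    if D.source is None:
        raise ValueError("distance matrix carries no source alignment; "
                         "bootstrap SEs need the sites")
    rng = np.random.default_rng(seed)
    L = D.source.length
    w_boot: dict[str, list[float]] = {g: [] for g in labels}
    b_boot: dict[tuple[str, str], list[float]] = {k: [] for k in between}
    arr = np.array([list(r) for r in D.source.rows])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_boot):
            cols = rng.integers(0, L, size=L)
            boot = AlignedLocus(D.source.locus_name, list(D.source.ids),
                                ["".join(r) for r in arr[:, cols]])
            Db = compute_distance_matrix(boot, model=D.model, deletion=D.deletion)
            wb, bb = _group_means(Db, group_ids)
            for g in labels:
                if wb[g] is not None:
                    w_boot[g].append(wb[g])
            for k, v in bb.items():
                b_boot[k].append(v)
    within_out = {
        g: None if within[g] is None
        else (within[g], float(np.std(w_boot[g], ddof=1)) if len(w_boot[g]) > 1 else 0.0)
        for g in labels
    }
    between_out = {
        k: (between[k], float(np.std(b_boot[k], ddof=1)) if len(b_boot[k]) > 1 else 0.0)
        for k in between
    }
    return GroupDistanceSummary(labels, within_out, between_out,
                                model=D.model, n_boot=n_boot, seed=seed)
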