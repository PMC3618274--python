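"""Automatic barcode-gap discovery: gap detection and recursive partitioning.

The procedure, for one prior limit P on intraspecific divergence:

1. Sort the pairwise distances. Scan successive gaps
   ``w_i = d[i+1] - d[i]``; the barcode gap is the first ``i`` where
   ``w_i > X * theta_i`` with ``theta_i = max(P, mean(d[1..i]))`` — the
   local intraspecific scale, floored at the prior — and ``d[i+1] > P``
   (the far side of the gap must exceed the prior). The detected gap
   distance is the midpoint of ``(d[i], d[i+1])``.
2. Partition by single linkage: connected components of the graph joining
   pairs with distance below the gap distance (the primary partition).
3. Recurse: re-run detection within each component on its own distances
   until no further gap is found (the recursive partition).

The whole procedure is evaluated over a log-spaced series of priors from
``Pmin`` to ``Pmax``. ``X`` is the relative gap width: larger X demands a
wider gap relative to the local divergence scale, so fewer splits.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

__all__ = ["AbgdConfig", "AbgdResult", "detect_barcode_gap",
           "single_linkage_partition", "abgd_partition"]


@dataclass
class AbgdConfig:
    """Prior series and gap-width settings.

    Defaults follow common barcode practice: priors log-spaced on
    [0.001, 0.1] in 10 steps, 20 histogram bins. The relative gap width
    defaults to 1.5; studies sometimes quote larger values, so it is a
    plain parameter.
    """

    Pmin: float = 0.001
    Pmax: float = 0.1
    steps: int = 10
    X: float = 1.5
    n_bins: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.Pmin < self.Pmax):
            raise ValueError("need 0 < Pmin < Pmax")
        if self.steps < 2:
            raise ValueError("need at least 2 prior steps")
        if self.X <= 0:
            raise ValueError("relative gap width X must be positive")

    def priors(self) -> list[float]:
        return list(np.geomspace(self.Pmin, self.Pmax, self.steps))


@dataclass
class AbgdResult:
    config: AbgdConfig
    per_prior: dict[float, dict] = field(default_factory=dict)
    # per prior: {"gap": float|None, "primary": [set,...], "recursive": [set,...]}

    def n_groups(self, prior: float, which: str = "primary") -> int:
        return len(self.per_prior[prior][which])

    def to_json(self) -> str:
        payload = {
            "config": vars(self.config),
            "per_prior": {
                f"{p:g}": {
                    "gap": rec["gap"],
                    "primary": [sorted(s) for s in rec["primary"]],
                    "recursive": [sorted(s) for s in rec["recursive"]],
                    "n_primary": len(rec["primary"]),
                    "n_recursive": len(rec["recursive"]),
                }
                for p, rec in self.per_prior.items()
            },
        }
        return json.dumps(payload, indent=2)


def detect_barcode_gap(distances, P: float, X: float) -> float | None:
    """First qualifying gap in the sorted distance list, or ``None``.

    Returns the midpoint of the gap interval when found.
    """
    d = sorted(float(x) for x in distances)
    if len(d) < 2:
        raise ValueError("need at least two distances")
    running_sum = 0.0
    for i in range(len(d) - 1):
        running_sum += d[i]
        w = d[i + 1] - d[i]
        theta = max(P, running_sum / (i + 1))
        if d[i + 1] > P and w > X * theta:
            return 0.5 * (d[i] + d[i + 1])
    return None


def single_linkage_partition(D: DistanceMatrix, threshold: float,
                             ids=None) -> list[set[str]]:
    """Connected components of the graph joining pairs with d < threshold."""
    ids = sorted(D.ids if ids is None else ids)
    index = {i: k for k, i in enumerate(D.ids)}
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(ids, 2):
        d = D.matrix[index[a], index[b]]
        if np.isfinite(d) and d < threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    comps: dict[str, set[str]] = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    return [comps[k] for k in sorted(comps)]


def _recurse(D: DistanceMatrix, ids: set[str], P: float, X: float) -> list[set[str]]:
    index = {i: k for k, i in enumerate(D.ids)}
    dists = [D.matrix[index[a], index[b]]
             for a, b in itertools.combinations(sorted(ids), 2)]
    dists = [d for d in dists if np.isfinite(d)]
    if len(dists) < 2:
        return [set(ids)]
    gap = detect_barcode_gap(dists, P, X)
    if gap is None:
        return [set(ids)]
    parts = single_linkage_partition(D, gap, ids=ids)
    if len(parts) == 1:
        return parts
    out = []
    for part in parts:
        out.extend(_recurse(D, part, P, X))
    return out


def abgd_partition(D: DistanceMatrix, config: AbgdConfig | None = None) -> AbgdResult:
    """Primary and recursive partitions over the configured prior series."""
    config = config or AbgdConfig()
    if not np.all(np.isfinite(D.matrix)):
        # saturated pairs cannot anchor a linkage graph deterministically
        raise ValueError("distance matrix contains inapplicable entries")
    result = AbgdResult(config)
    all_ids = set(D.ids)
    dists = [float(x) for x in
             D.matrix[np.triu_indices(len(D.ids), k=1)]]
    for P in config.priors():
        gap = detect_barcode_gap(dists, P, config.X) if len(dists) >= 2 else None
        if gap is None:
            primary = [set(all_ids)]
        else:
            primary = single_linkage_partition(D, gap)
        recursive: list[set[str]] = []
        for part in primary:
            recursive.extend(_recurse(D, part, P, config.X))
        result.per_prior[P] = {"gap": gap, "primary": primary,
                               "recursive": recursive}
    return result
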