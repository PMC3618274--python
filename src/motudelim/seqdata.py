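"""Aligned sequence data, group maps, haplotype collapsing and diagnostic columns.

The central objects are :class:`AlignedLocus` (one aligned locus, gaps as
``'-'``, missing data as ``'?'``) and :class:`GroupMap` (assignment of
sequence ids to delimitation hypotheses, with nesting among hypotheses and
composite aliases such as a union of one group plus part of another).

Coordinates reported by :func:`find_diagnostic_columns` are 1-based,
inclusive, in alignment space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
import dendropy

__all__ = [
    "AlignedLocus",
    "GroupMap",
    "HaplotypeTable",
    "AlignmentError",
    "read_alignment",
    "read_tree",
    "read_group_map",
    "collapse_haplotypes",
    "concatenate_loci",
    "split_by_provenance",
    "find_diagnostic_columns",
]

#: characters compatible with any base under the missing-tolerant rule
MISSING_STATES = frozenset("?N")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate ids, ...)."""


@dataclass
class AlignedLocus:
    """An aligned locus: equal-length rows of upper-case sequence characters.

    ``provenance`` tracks, per column, the source locus name and the
    original (0-based) column index; it is populated by
    :func:`concatenate_loci` so concatenated alignments can be split back
    into their parts.
    """

    locus_name: str
    ids: list[str]
    rows: list[str]
    provenance: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        if not self.rows:
            raise AlignmentError("alignment has no records")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"rows have unequal lengths {sorted(lengths)}; refusing to pad"
            )
        if self.length == 0:
            raise AlignmentError("alignment has zero columns")
        self.rows = [r.upper() for r in self.rows]
        if self.provenance is not None and len(self.provenance) != self.length:
            raise AlignmentError("provenance length does not match alignment length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string in row order."""
        return "".join(r[j] for r in self.rows)

    def subset(self, keep_ids: list[str]) -> "AlignedLocus":
        idx = {i: k for k, i in enumerate(self.ids)}
        return AlignedLocus(
            self.locus_name,
            list(keep_ids),
            [self.rows[idx[i]] for i in keep_ids],
            provenance=list(self.provenance) if self.provenance else None,
        )

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


def read_alignment(path, locus_name: str) -> AlignedLocus:
    """Read an aligned FASTA file. Rows must be equal length; no padding."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return AlignedLocus(
        locus_name,
        [r.id for r in records],
        [str(r.seq).upper() for r in records],
    )


@dataclass
class GroupMap:
    """Assignment of ids to terminal group labels, with hypothesis structure.

    ``assignments`` maps every id to exactly one *terminal* label.
    ``nesting`` maps a parent hypothesis to its child hypotheses (children
    partition the parent). ``aliases`` define composite hypotheses as unions
    of other labels (e.g. one group plus a named part of another).
    """

    assignments: dict[str, str]
    nesting: dict[str, set[str]] = field(default_factory=dict)
    aliases: dict[str, set[str]] = field(default_factory=dict)

    def terminal_labels(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def labels(self) -> list[str]:
        return sorted(
            set(self.assignments.values())
            | set(self.nesting)
            | set(self.aliases)
        )

    def members(self, label: str) -> set[str]:
        """All ids belonging to ``label``, resolving nesting and aliases."""
        if label in self.aliases:
            out: set[str] = set()
            for part in self.aliases[label]:
                out |= self.members(part)
            return out
        if label in self.nesting:
            out = set()
            for child in self.nesting[label]:
                out |= self.members(child)
            return out
        members = {i for i, g in self.assignments.items() if g == label}
        if not members:
            raise KeyError(f"unknown group label: {label!r}")
        return members

    def complement(self, label: str, universe: set[str] | None = None) -> set[str]:
        universe = set(self.assignments) if universe is None else set(universe)
        return universe - self.members(label)

    def validate(self) -> None:
        for parent, children in self.nesting.items():
            child_sets = [self.members(c) for c in sorted(children)]
            union: set[str] = set()
            for s in child_sets:
                if union & s:
                    raise ValueError(f"children of {parent!r} overlap")
                union |= s
            # parent may itself be only defined through its children; when it
            # also has direct assignments the two must agree
            direct = {i for i, g in self.assignments.items() if g == parent}
            if direct and direct != union:
                raise ValueError(
                    f"children of {parent!r} do not cover its assigned ids"
                )


def read_group_map(assignments_tsv, nesting_tsv=None) -> GroupMap:
    """Read a 2-column (id, group) TSV plus an optional (parent, child) TSV."""
    assignments: dict[str, str] = {}
    with open(assignments_tsv) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, grp = line.split("\t")[:2]
            if sid in assignments:
                raise ValueError(f"id {sid!r} assigned twice")
            assignments[sid] = grp
    nesting: dict[str, set[str]] = {}
    if nesting_tsv is not None:
        with open(nesting_tsv) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parent, child = line.split("\t")[:2]
                nesting.setdefault(parent, set()).add(child)
    return GroupMap(assignments, nesting)


@dataclass
class HaplotypeTable:
    """Partition of specimens into haplotypes with a representative row."""

    members: dict[str, list[str]]  # haplotype id -> specimen ids
    representatives: dict[str, str]  # haplotype id -> sequence row

    @property
    def n_haplotypes(self) -> int:
        return len(self.members)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("haplotype\tmembers\n")
            for hap in sorted(self.members):
                fh.write(f"{hap}\t{','.join(self.members[hap])}\n")


def _compatible(a: str, b: str) -> bool:
    return all(
        x == y or x in MISSING_STATES or y in MISSING_STATES
        for x, y in zip(a, b)
    )


def collapse_haplotypes(locus: AlignedLocus, equality_rule: str = "strict") -> HaplotypeTable:
    """Collapse identical sequences into haplotypes.

    ``strict``: exact string equality (gaps and ambiguity codes are ordinary
    states). ``missing-tolerant``: ``'?'``/``'N'`` match any base and merging
    is the transitive closure over pairwise compatibility, taken in
    lexicographic id order so the result is deterministic.
    """
    if equality_rule not in ("strict", "missing-tolerant"):
        raise ValueError(f"unknown equality rule: {equality_rule!r}")
    order = sorted(range(len(locus.ids)), key=lambda k: locus.ids[k])
    if equality_rule == "strict":
        buckets: dict[str, list[str]] = {}
        for k in order:
            buckets.setdefault(locus.rows[k], []).append(locus.ids[k])
        groups = sorted(buckets.values(), key=lambda g: g[0])
    else:
        # union-find over pairwise-compatible rows, ids pre-sorted
        parent = list(range(len(order)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                if _compatible(locus.rows[order[a]], locus.rows[order[b]]):
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
        comp: dict[int, list[str]] = {}
        for a in range(len(order)):
            comp.setdefault(find(a), []).append(locus.ids[order[a]])
        groups = sorted(comp.values(), key=lambda g: g[0])
    members = {f"H{k + 1}": g for k, g in enumerate(groups)}
    reps = {h: locus.row(g[0]) for h, g in members.items()}
    return HaplotypeTable(members, reps)


def concatenate_loci(loci: list[AlignedLocus], policy: str = "drop-incomplete",
                     name: str = "concat") -> AlignedLocus:
    """Concatenate loci over a shared id namespace.

    ``drop-incomplete`` keeps only ids present in every locus (the usual
    treatment when some specimens lack one marker); ``pad-missing`` keeps
    every id and fills absent loci with ``'?'`` columns. Column provenance
    (locus name, original column index) is recorded.
    """
    if policy not in ("drop-incomplete", "pad-missing"):
        raise ValueError(f"unknown policy: {policy!r}")
    if not loci:
        raise ValueError("no loci to concatenate")
    if policy == "drop-incomplete":
        keep = set(loci[0].ids)
        for loc in loci[1:]:
            keep &= set(loc.ids)
        if not keep:
            raise ValueError("no id is present in every locus under drop-incomplete")
    else:
        keep = set()
        for loc in loci:
            keep |= set(loc.ids)
    ids = sorted(keep)
    parts: dict[str, list[str]] = {i: [] for i in ids}
    provenance: list[tuple[str, int]] = []
    for loc in loci:
        idx = {i: k for k, i in enumerate(loc.ids)}
        blank = "?" * loc.length
        for i in ids:
            parts[i].append(loc.rows[idx[i]] if i in idx else blank)
        provenance.extend((loc.locus_name, j) for j in range(loc.length))
    return AlignedLocus(name, ids, ["".join(parts[i]) for i in ids],
                        provenance=provenance)


def split_by_provenance(concat: AlignedLocus) -> list[AlignedLocus]:
    """Invert :func:`concatenate_loci` using the recorded provenance."""
    if concat.provenance is None:
        raise ValueError("alignment carries no provenance")
    out: list[AlignedLocus] = []
    j = 0
    while j < concat.length:
        name = concat.provenance[j][0]
        k = j
        while k < concat.length and concat.provenance[k][0] == name:
            k += 1
        out.append(AlignedLocus(name, list(concat.ids),
                                [r[j:k] for r in concat.rows]))
        j = k
    return out


def find_diagnostic_columns(locus: AlignedLocus, groups: GroupMap,
                            focal: str) -> list[tuple[int, set[str], set[str]]]:
    """Columns whose focal-group states are disjoint from all other states.

    A column qualifies when the set of states observed in the focal group
    does not intersect the set observed in the remaining ids; a group may be
    polymorphic at a diagnostic column as long as the state sets stay
    disjoint. ``'?'`` is treated as unobserved and ignored; ``'-'`` is an
    ordinary state, so group-specific indels are diagnostic. Columns are
    reported 1-based in alignment coordinates.
    """
    focal_ids = groups.members(focal)
    other_ids = set(locus.ids) - focal_ids
    if not focal_ids & set(locus.ids):
        raise ValueError(f"focal group {focal!r} has no members in the alignment")
    if not other_ids:
        raise ValueError("complement of the focal group is empty")
    focal_rows = [locus.row(i) for i in sorted(focal_ids & set(locus.ids))]
    other_rows = [locus.row(i) for i in sorted(other_ids)]
    out = []
    for j in range(locus.length):
        fstates = {r[j] for r in focal_rows} - {"?"}
        ostates = {r[j] for r in other_rows} - {"?"}
        if fstates and ostates and not fstates & ostates:
            out.append((j + 1, fstates, ostates))
    return out


def read_tree(path, require_ultrametric: bool = False,
              tolerance: float = 1e-6, require_lengths: bool = True) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths.

    When ``require_ultrametric`` is set, root-to-tip depths must agree within
    ``tolerance`` x tree height.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    if require_lengths:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has edges without branch lengths")
            if edge.length < 0:
                raise ValueError("tree has negative branch lengths")
    if require_ultrametric:
        check_ultrametric(tree, tolerance)
    return tree


def check_ultrametric(tree: dendropy.Tree, tolerance: float = 1e-6) -> None:
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    height = max(depths)
    if height <= 0:
        raise ValueError("tree has zero height")
    if max(depths) - min(depths) > tolerance * height:
        raise ValueError(
            f"tree is not ultrametric: depth spread {max(depths) - min(depths):g} "
            f"exceeds tolerance {tolerance:g} x height {height:g}"
        )
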