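"""Synthetic multispecies datasets: gene trees, sequences, indels, truth.

The generator emulates the divergence structure typical of deeply
subdivided land-snail barcode data: several strongly diverged groups
(between-group divergence on the order of 15-21% substitutions per site),
shallow within-group variation (fractions of a percent to a few percent),
group sample sizes from 1 (a singleton group) to a few dozen haplotypes,
and group-specific indel blocks in rDNA-like loci.

Construction: a Yule species tree scaled to a target depth, with an
independent neutral coalescent for each species' samples grafted at the
species tip; sequences evolve along the resulting ultrametric gene tree
under a two-parameter transition/transversion process whose branch lengths
are expected substitutions per site (so pairwise K2P estimates recover
path lengths); diagnostic indels are injected post hoc as disjoint
species-specific deletion blocks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .seqdata import AlignedLocus, GroupMap

__all__ = ["SimConfig", "TruthSet", "simulate_tree", "evolve_sequences",
           "inject_indels", "write_dataset", "simulate_dataset"]

_BASES = np.array(list("ACGT"))
# transition partner of A,C,G,T; transversion partners are the other two
_TS_PARTNER = np.array([2, 3, 0, 1])


@dataclass
class SimConfig:
    """Defaults emulate a deeply structured barcode study: 7 species with
    sample sizes 26, 1, 12, 6, 12, 6, 19 haplotypes; species-tree depth
    0.09 expected substitutions/site (pairwise between-species divergence
    ~0.15-0.21 once ancestral coalescence is added); within-species
    coalescent scale 0.002, i.e. pairwise within-species divergence around
    0.4% — the scale of the well-sorted barcode clusters such studies
    delimit; a 655 bp COI-like locus; transition/transversion rate ratio
    kappa = 4."""

    K: int = 7
    n_k: tuple = (26, 1, 12, 6, 12, 6, 19)
    species_depth: float = 0.09
    pop_scale: float = 0.002
    seq_length: int = 655
    kappa: float = 4.0
    birth_rate: float = 1.0
    indel_blocks: int = 0  # per species
    indel_length: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("need at least one species")
        if len(self.n_k) != self.K:
            raise ValueError("n_k must have one entry per species")
        if min(self.n_k) < 1:
            raise ValueError("every species needs at least one sample")
        for name in ("species_depth", "pop_scale", "kappa", "birth_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seq_length < 1:
            raise ValueError("sequence length must be positive")


@dataclass
class TruthSet:
    tree: dendropy.Tree
    partition: dict[str, str]  # tip id -> species label
    config: SimConfig
    diagnostic_columns: dict[str, list[int]] = field(default_factory=dict)

    def group_map(self) -> GroupMap:
        return GroupMap(dict(self.partition))

    @property
    def species(self) -> list[str]:
        return sorted(set(self.partition.values()))


#: species splits are mapped into [SPLIT_BAND * depth, depth]: even the
#: shallowest between-species divergence stays a large fraction of the
#: deepest, the structure typical of long-isolated barcode clusters
SPLIT_BAND = 0.55


def _yule_topology(K: int, birth_rate: float, rng: np.random.Generator):
    """Forward Yule simulation; returns (root, list of split nodes).

    Each internal node carries ``split_time`` (forward time of its split);
    the root splits first.
    """
    root = dendropy.Node()
    leaves = [root]
    t = 0.0
    for k in range(1, K):
        t += rng.exponential(1.0 / (birth_rate * k))
        victim = leaves[int(rng.integers(len(leaves)))]
        victim.split_time = t
        a, b = dendropy.Node(), dendropy.Node()
        victim.add_child(a)
        victim.add_child(b)
        leaves.remove(victim)
        leaves.extend([a, b])
    return root, leaves


def simulate_tree(config: SimConfig) -> TruthSet:
    """Species tree with grafted within-species coalescents; ultrametric, binary.

    Yule split times are rescaled to ages in [0.55, 1] x ``species_depth``
    (root split exactly at ``species_depth``); each species-tree join adds
    an ancestral coalescent waiting time of scale ``pop_scale`` on top, and
    each species' samples coalesce at scale ``pop_scale``. ``node.time``
    holds the age above the tips.
    """
    rng = np.random.default_rng(config.seed)
    taxa = dendropy.TaxonNamespace()
    partition: dict[str, str] = {}

    def coalesce(nodes: list) -> dendropy.Node:
        """Kingman coalescent over ``nodes`` (each with .time); returns root."""
        t = max(n.time for n in nodes)
        while len(nodes) > 1:
            k = len(nodes)
            t += rng.exponential(config.pop_scale / (k * (k - 1) / 2))
            i, j = sorted(int(v) for v in rng.choice(k, size=2, replace=False))
            parent = dendropy.Node()
            parent.time = t
            for idx in (j, i):
                child = nodes.pop(idx)
                parent.add_child(child)
                child.edge.length = t - child.time
            nodes.append(parent)
        return nodes[0]

    def sample_tips(species_index: int) -> dendropy.Node:
        label = f"sp{species_index + 1}"
        tips = []
        for i in range(config.n_k[species_index]):
            taxon = taxa.new_taxon(label=f"{label}_{i + 1}")
            nd = dendropy.Node(taxon=taxon)
            nd.time = 0.0
            tips.append(nd)
            partition[taxon.label] = label
        return tips[0] if len(tips) == 1 else coalesce(tips)

    if config.K == 1:
        root = sample_tips(0)
    else:
        sp_root, sp_leaves = _yule_topology(config.K, config.birth_rate, rng)
        splits = sorted(nd.split_time for nd in _iter_nodes(sp_root)
                        if nd.child_nodes())
        s_min, s_max = splits[0], splits[-1]
        span = s_max - s_min
        D = config.species_depth

        def split_age(s: float) -> float:
            if span == 0:
                return D
            frac = (s - s_min) / span  # 0 = root split, 1 = youngest split
            return D * (1.0 - (1.0 - SPLIT_BAND) * frac)

        order = {id(l): k for k, l in enumerate(sp_leaves)}

        def build(node) -> dendropy.Node:
            if not node.child_nodes():
                return sample_tips(order[id(node)])
            left = build(node.child_nodes()[0])
            right = build(node.child_nodes()[1])
            parent = dendropy.Node()
            base = max(split_age(node.split_time), left.time, right.time)
            parent.time = base + rng.exponential(config.pop_scale)
            for child in (left, right):
                parent.add_child(child)
                child.edge.length = parent.time - child.time
            return parent

        root = build(sp_root)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return TruthSet(tree, partition, config)


def _iter_nodes(root):
    stack = [root]
    while stack:
        nd = stack.pop()
        yield nd
        stack.extend(nd.child_nodes())


def evolve_sequences(tree: dendropy.Tree, config: SimConfig,
                     locus_name: str = "locus") -> AlignedLocus:
    """Evolve sequences along the tree under a two-parameter process.

    Branch lengths are expected substitutions per site; the transition:
    transversion *rate* ratio is ``kappa`` (each of the two transversion
    partners receives half the transversion rate). Pairwise K2P distances
    therefore estimate path lengths.
    """
    if config.seq_length < 1:
        raise ValueError("zero-length sequences requested")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    L = config.seq_length
    kappa = config.kappa
    root_seq = rng.integers(0, 4, size=L)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        d = node.edge.length or 0.0
        parent_seq = seqs[id(node.parent_node)]
        if d == 0:
            child_seq = parent_seq.copy()
        else:
            # K2P transition probabilities at branch length d (subs/site):
            # alpha*t = kappa*d/(kappa+2), beta*t = d/(kappa+2)
            bt = d / (kappa + 2.0)
            at = kappa * bt
            e1 = np.exp(-4.0 * bt)          # controls transversions
            e2 = np.exp(-2.0 * (at + bt))   # controls transitions
            p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
            p_tv_each = 0.25 - 0.25 * e1
            u = rng.random(L)
            child_seq = parent_seq.copy()
            ts_mask = u < p_ts
            tv1_mask = (u >= p_ts) & (u < p_ts + p_tv_each)
            tv2_mask = (u >= p_ts + p_tv_each) & (u < p_ts + 2 * p_tv_each)
            child_seq[ts_mask] = _TS_PARTNER[parent_seq[ts_mask]]
            # transversion partners: for purines (A=0,G=2) -> C=1 / T=3;
            # for pyrimidines (C=1,T=3) -> A=0 / G=2
            purine = parent_seq % 2 == 0
            child_seq[tv1_mask & purine] = 1
            child_seq[tv1_mask & ~purine] = 0
            child_seq[tv2_mask & purine] = 3
            child_seq[tv2_mask & ~purine] = 2
        seqs[id(node)] = child_seq
    ids, rows = [], []
    for leaf in sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label):
        ids.append(leaf.taxon.label)
        rows.append("".join(_BASES[seqs[id(leaf)]]))
    return AlignedLocus(locus_name, ids, rows)


def inject_indels(locus: AlignedLocus, groups: GroupMap,
                  config: SimConfig) -> tuple[AlignedLocus, dict[str, list[int]]]:
    """Delete species-specific column blocks; returns truth columns (1-based).

    Blocks are laid out left to right, disjoint across species by
    construction; overlap (alignment too short for the requested blocks)
    is an error because diagnosability must hold by construction.
    """
    species = sorted({g for g in groups.assignments.values()})
    n_blocks_total = len(species) * config.indel_blocks
    needed = n_blocks_total * (config.indel_length + 1)
    if config.indel_blocks and needed > locus.length:
        raise ValueError(
            f"{n_blocks_total} blocks of {config.indel_length} columns do not "
            f"fit in {locus.length} columns without overlap")
    if not config.indel_blocks:
        return locus, {}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    # evenly spaced disjoint block starts with a seeded offset
    stride = locus.length // n_blocks_total
    offset = int(rng.integers(0, max(1, stride - config.indel_length)))
    rows = [list(r) for r in locus.rows]
    id_index = {i: k for k, i in enumerate(locus.ids)}
    truth: dict[str, list[int]] = {}
    block = 0
    for sp in species:
        cols: list[int] = []
        for _ in range(config.indel_blocks):
            start = block * stride + offset
            for c in range(start, start + config.indel_length):
                for member in groups.members(sp):
                    rows[id_index[member]][c] = "-"
                cols.append(c + 1)  # 1-based
            block += 1
        truth[sp] = cols
    out = AlignedLocus(locus.locus_name, list(locus.ids),
                       ["".join(r) for r in rows])
    return out, truth


def simulate_dataset(config: SimConfig) -> tuple[TruthSet, AlignedLocus]:
    """Tree + sequences (+ indels when configured) in one call."""
    truth = simulate_tree(config)
    locus = evolve_sequences(truth.tree, config)
    if config.indel_blocks:
        locus, cols = inject_indels(locus, truth.group_map(), config)
        truth.diagnostic_columns = cols
    return truth, locus


def write_dataset(truth: TruthSet, locus: AlignedLocus, directory) -> dict:
    """Write FASTA, newick, truth partition TSV and config JSON + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    fasta = directory / f"{locus.locus_name}.fasta"
    locus.write_fasta(fasta)
    files["fasta"] = fasta
    newick = directory / "truth_tree.nwk"
    truth.tree.write(path=str(newick), schema="newick",
                     suppress_rooting=True)
    files["tree"] = newick
    part = directory / "truth_partition.tsv"
    with open(part, "w") as fh:
        for tip in sorted(truth.partition):
            fh.write(f"{tip}\t{truth.partition[tip]}\n")
    files["partition"] = part
    cfg = directory / "sim_config.json"
    with open(cfg, "w") as fh:
        json.dump(asdict(truth.config), fh, indent=2, default=list)
    files["config"] = cfg
    manifest = {}
    for key, path in files.items():
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest[key] = {"path": path.name, "sha256": digest}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
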