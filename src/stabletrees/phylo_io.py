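"""Trees, trait tables, fossil handling and pseudo-outgroup grafting.

A :class:`TimeTree` is a rooted time-calibrated phylogeny (chronogram):
branch lengths are durations in Myr, tips carry ages in Myr before
present (0 for extant species, > 0 for fossil tips).  Newick and NEXUS
dialects are read and written through dendropy; the in-memory
representation is a flat parent-array form convenient for vectorized
likelihoods.

A :class:`TraitTable` maps species to body mass in kg; all model code
works on the log10-kg scale and reported quantities are back-transformed
with 10**x.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AGE_EPS",
    "DEGEN_EPS",
    "TimeTree",
    "TraitTable",
    "read_tree",
    "write_tree",
    "read_traits",
    "write_traits",
    "prune_to_tips",
    "prune_fossil_tips",
    "graft_outgroup",
]

#: A tip is treated as a fossil iff its age exceeds this (Myr); absorbs
#: float noise in published chronograms.
AGE_EPS = 1e-3

#: Internal edges shorter than this (Myr) are collapsed into polytomies;
#: pendant edges are exempt.  Zero-duration internal edges make the
#: branch-increment density degenerate.
DEGEN_EPS = 1e-8


class TimeTree:
    """Rooted chronogram in parent-array form.

    Parameters
    ----------
    parent : int array, -1 at the root; defines a connected acyclic graph.
    duration : float array, Myr; entry for the root is ignored (0).
    labels : per-node labels; tips must be uniquely labelled, internal
        labels optional.
    """

    def __init__(self, parent, duration, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.duration = np.asarray(duration, dtype=float)
        self.labels = list(labels)
        self.n_nodes = len(self.labels)
        if not (len(self.parent) == len(self.duration) == self.n_nodes):
            raise ValueError("parent, duration and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root; found {len(roots)}")
        self.root = int(roots[0])
        self.duration = self.duration.copy()
        self.duration[self.root] = 0.0
        if np.any(self.duration < 0):
            raise ValueError("negative branch durations are not allowed")

        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])

        # preorder via BFS-ish stack; also validates connectivity/acyclicity
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        if len(order) != self.n_nodes:
            raise ValueError("tree graph is not connected")
        self.preorder = np.array(order, dtype=np.int64)
        self.postorder = self.preorder[::-1].copy()
        self.edge_child = self.preorder[self.preorder != self.root]

        depth = np.zeros(self.n_nodes)
        for v in self.preorder:
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.duration[v]
        self.node_depth = depth
        self.root_age = float(depth[self.is_tip].max())
        self.node_age = self.root_age - depth

        tips = np.flatnonzero(self.is_tip)
        tip_labels = [self.labels[i] for i in tips]
        if len(set(tip_labels)) != len(tip_labels):
            dup = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        if any(l is None for l in tip_labels):
            raise ValueError("all tips must be labelled")
        self.tip_ages = {self.labels[i]: float(self.node_age[i]) for i in tips}

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in np.flatnonzero(self.is_tip)]

    def extant_tip_labels(self) -> list[str]:
        return [l for l, a in self.tip_ages.items() if a <= AGE_EPS]

    def fossil_tip_labels(self) -> list[str]:
        return [l for l, a in self.tip_ages.items() if a > AGE_EPS]

    def clade_tips(self, node: int) -> frozenset:
        """Labels of all tips descending from (and including) ``node``."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_tip[v]:
                out.append(self.labels[v])
            stack.extend(self.children[v])
        return frozenset(out)

    def clade_index(self) -> dict:
        """Tip-label set -> node index, for every node (clade lookup)."""
        return {self.clade_tips(v): int(v) for v in range(self.n_nodes)}

    def mrca(self, labels) -> int:
        """Most recent common ancestor of a set of tip labels."""
        want = set(labels)
        lab2idx = {self.labels[i]: i for i in np.flatnonzero(self.is_tip)}
        missing = want - lab2idx.keys()
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        paths = []
        for l in want:
            v, path = lab2idx[l], []
            while v >= 0:
                path.append(v)
                v = self.parent[v]
            paths.append(set(path))
        common = set.intersection(*paths)
        return int(max(common, key=lambda v: self.node_depth[v]))

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent.copy(), self.duration.copy(), list(self.labels))

    # ------------------------------------------------------------------
    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for v in self.preorder:
            nd = tree.seed_node if v == self.root else dendropy.Node()
            if v != self.root:
                nodes[self.parent[v]].add_child(nd)
                nd.edge.length = float(self.duration[v])
            if self.is_tip[v]:
                nd.taxon = taxa.new_taxon(label=self.labels[v])
            elif self.labels[v] is not None:
                nd.label = self.labels[v]
            nodes[v] = nd
        tree.is_rooted = True
        return tree

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, collapse_eps: float = DEGEN_EPS) -> "TimeTree":
        seed = dtree.seed_node
        idx, parent, duration, labels = {}, [], [], []
        for nd in dtree.preorder_node_iter():
            is_pendant = nd.is_leaf()
            if nd is not seed:
                if nd.edge.length is None:
                    name = nd.taxon.label if nd.taxon else (nd.label or "<unnamed>")
                    raise ValueError(f"missing branch length on the edge above {name!r}")
                if nd.edge.length < 0:
                    name = nd.taxon.label if nd.taxon else (nd.label or "<unnamed>")
                    raise ValueError(f"negative branch length above {name!r}")
                if (not is_pendant) and nd.edge.length < collapse_eps:
                    # collapse: children re-attach to this node's parent
                    idx[nd] = idx[nd.parent_node]
                    continue
            idx[nd] = len(labels)
            parent.append(-1 if nd is seed else idx[nd.parent_node])
            duration.append(0.0 if nd is seed else float(nd.edge.length))
            labels.append(nd.taxon.label if nd.taxon else nd.label)
        return cls(parent, duration, labels)


def read_tree(path, format: str = "newick") -> TimeTree:
    """Read a rooted chronogram from a Newick or NEXUS file.

    NEXUS translate tables are resolved; internal edges shorter than
    DEGEN_EPS are collapsed into polytomies (pendant edges exempt).
    Unrooted trees (explicit ``[&U]``) are rejected.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        dtree = dendropy.Tree.get(path=str(path), schema=format,
                                  suppress_internal_node_taxa=True)
    except dendropy.utility.error.DataParseError as e:
        msg = str(e)
        if "Multiple occurrences" in msg or "uplicate" in msg:
            raise ValueError(f"duplicate tip labels in tree file: {msg}") from e
        raise ValueError(f"could not parse tree file: {msg}") from e
    if dtree.is_rooted is False and format == "nexus":
        raise ValueError("tree is unrooted; root it before analysis")
    # newick without [&R] parses as unrooted: trust the file's shape but
    # reject an explicit unrooted flag
    if getattr(dtree, "is_rooted", None) is False and len(dtree.seed_node.child_nodes()) > 2:
        raise ValueError("tree appears unrooted (basal trifurcation, no [&R]); root it first")
    return TimeTree.from_dendropy(dtree)


def write_tree(tree: TimeTree, path, format: str = "newick") -> None:
    """Write a TimeTree in Newick or NEXUS (rooted, branch lengths kept)."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    tree.to_dendropy().write(path=str(path), schema=format)


# ----------------------------------------------------------------------
@dataclass
class TraitTable:
    """Species -> body mass (kg), with the log10 working scale."""

    records: dict = field(default_factory=dict)

    def __post_init__(self):
        for sp, m in self.records.items():
            if not (isinstance(m, (int, float)) and math.isfinite(m) and m > 0):
                raise ValueError(f"mass for {sp!r} must be a positive number; got {m!r}")
        self.records = {sp: float(m) for sp, m in self.records.items()}

    @property
    def working_values(self) -> dict:
        return {sp: math.log10(m) for sp, m in self.records.items()}

    @staticmethod
    def back_transform(x: float) -> float:
        """log10 kg -> kg."""
        return 10.0 ** x

    def subset(self, species) -> "TraitTable":
        missing = [s for s in species if s not in self.records]
        if missing:
            raise KeyError(f"species without mass records: {sorted(missing)}")
        return TraitTable({s: self.records[s] for s in species})

    def with_record(self, species: str, mass_kg: float) -> "TraitTable":
        rec = dict(self.records)
        rec[species] = mass_kg
        return TraitTable(rec)

    def bind(self, tree: TimeTree) -> None:
        """Check every tip of ``tree`` has exactly one mass record."""
        missing = [l for l in tree.tip_labels() if l not in self.records]
        if missing:
            raise KeyError(f"tips without mass records: {sorted(missing)}")


def read_traits(path) -> TraitTable:
    """Read a two-column species,mass_kg table (CSV or TSV; header optional)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#",
                     skip_blank_lines=True, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("trait table needs two columns: species, mass_kg")
    df = df.iloc[:, :2]
    first = str(df.iloc[0, 1]).strip()
    try:
        float(first)
        start = 0
    except ValueError:
        start = 1  # header row
    records = {}
    for row in range(start, len(df)):
        sp = str(df.iloc[row, 0]).strip()
        raw = str(df.iloc[row, 1]).strip()
        try:
            mass = float(raw)
        except ValueError:
            raise ValueError(f"row {row + 1}: non-numeric mass {raw!r} for {sp!r}")
        if not (math.isfinite(mass) and mass > 0):
            raise ValueError(f"row {row + 1}: non-positive mass {mass!r} for {sp!r}")
        if sp in records:
            raise ValueError(f"row {row + 1}: duplicate species {sp!r}")
        records[sp] = mass
    return TraitTable(records)


def write_traits(traits: TraitTable, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"species": list(traits.records), "mass_kg": list(traits.records.values())}
    ).to_csv(path, sep=sep, index=False)


# ----------------------------------------------------------------------
def prune_to_tips(tree: TimeTree, keep_tip, min_tips: int = 2,
                  keep_root: bool = True) -> TimeTree:
    """Restrict the tree to a subset of tips, suppressing degree-2 nodes.

    Durations of suppressed chains are summed, so root-to-tip path
    lengths of retained tips are conserved exactly.  With ``keep_root``
    (default) a root left with a single child keeps its stem edge, so
    the original root age is preserved; with ``keep_root=False`` such a
    root chain is suppressed and the new root is the MRCA of the kept
    tips.
    """
    keep_tip = set(keep_tip)
    unknown = keep_tip - set(tree.tip_labels())
    if unknown:
        raise KeyError(f"tips not in tree: {sorted(unknown)}")
    if len(keep_tip) < min_tips:
        raise ValueError(
            f"pruning would leave {len(keep_tip)} tips (< {min_tips})"
        )
    keep = np.zeros(tree.n_nodes, dtype=bool)
    for i in np.flatnonzero(tree.is_tip):
        if tree.labels[i] in keep_tip:
            v = i
            while v >= 0 and not keep[v]:
                keep[v] = True
                v = tree.parent[v]
    # suppress internal kept nodes with exactly one kept child (root exempt)
    n_kept_children = np.zeros(tree.n_nodes, dtype=int)
    for v in range(tree.n_nodes):
        if v != tree.root and keep[v]:
            n_kept_children[tree.parent[v]] += 1
    suppress = keep & ~tree.is_tip & (n_kept_children == 1)
    suppress[tree.root] = False
    if not keep_root:
        v = tree.root
        while not tree.is_tip[v] and n_kept_children[v] == 1:
            suppress[v] = True
            v = next(c for c in tree.children[v] if keep[c])

    new_idx, parent, duration, labels = {}, [], [], []
    for v in tree.preorder:
        if not keep[v] or suppress[v]:
            continue
        p, dur = tree.parent[v], tree.duration[v]
        while p >= 0 and suppress[p]:
            dur += tree.duration[p]
            p = tree.parent[p]
        new_idx[v] = len(labels)
        parent.append(-1 if p < 0 else new_idx[p])
        duration.append(0.0 if p < 0 else float(dur))
        labels.append(tree.labels[v])
    return TimeTree(parent, duration, labels)


def prune_fossil_tips(tree: TimeTree, min_tips: int = 3) -> TimeTree:
    """Remove all fossil tips (age > AGE_EPS); extant tip ages and the
    root age are conserved (see :func:`prune_to_tips`)."""
    return prune_to_tips(tree, tree.extant_tip_labels(), min_tips=min_tips)


def graft_outgroup(
    tree: TimeTree,
    traits: TraitTable,
    outgroup_mass: float,
    sep_total: float = 5.0,
    pendant: float = 0.01,
    sep_is_stem: bool = False,
    label: str = "pseudo_outgroup",
):
    """Graft a pseudo-outgroup tip of known mass above the focal root.

    Encodes prior knowledge of the ancestral mass: a new root is created
    whose children are the original (focal) root — on a stem of
    ``sep_total - pendant`` Myr (or ``sep_total`` if ``sep_is_stem``) —
    and a pendant fossil tip of duration ``pendant`` Myr carrying
    ``outgroup_mass``.  Defaults give a 5 Myr total separation with a
    0.01 Myr pendant edge.  Returns ``(tree, traits)`` with the focal
    root labelled ``focal_root`` if it had no label.
    """
    if outgroup_mass <= 0:
        raise ValueError("outgroup mass must be positive")
    if pendant <= 0:
        raise ValueError("pendant edge must be positive")
    stem = float(sep_total) if sep_is_stem else float(sep_total) - float(pendant)
    if stem <= 0:
        raise ValueError("separation must exceed the pendant edge length")
    if label in tree.tip_labels():
        raise ValueError(f"tree already has a tip named {label!r}")

    n = tree.n_nodes
    parent = np.concatenate([tree.parent, [n, -1]])
    parent[tree.root] = n + 1
    parent[n] = n + 1
    duration = np.concatenate([tree.duration, [pendant, 0.0]])
    duration[tree.root] = stem
    labels = list(tree.labels) + [label, None]
    if labels[tree.root] is None:
        labels[tree.root] = "focal_root"
    new_tree = TimeTree(parent, duration, labels)
    return new_tree, traits.with_record(label, outgroup_mass)
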