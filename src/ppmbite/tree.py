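"""Time-scaled phylogenies for paleontological comparative analyses.

Trees are rooted, with branch lengths in millions of years (Myr).  Ages are
expressed in Ma before present (present = 0); fossil tips terminate above the
present, so trees need not be ultrametric.  The module provides newick I/O,
FAD/LAD branch time-scaling, resolution of zero-length internal branches by
the "equal" time-sharing rule, and the Brownian-motion covariance matrix
(shared root-to-MRCA path lengths) that drives the regression engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeError",
    "TimeTree",
    "StratRange",
    "PhyloCovariance",
    "parse_newick",
    "read_newick",
    "write_newick",
    "read_strat_ranges",
    "timescale_fad_lad",
    "resolve_zero_branches_equal",
    "phylo_vcv",
]


class TreeError(ValueError):
    """Invalid tree structure, labels, or branch lengths."""


def _canon(label: str) -> str:
    """Canonical taxon label: trimmed, spaces folded to underscores."""
    return "_".join(str(label).strip().split())


@dataclass(frozen=True)
class StratRange:
    """Stratigraphic range of a fossil taxon (ages in Ma before present)."""

    taxon: str
    fad_ma: float
    lad_ma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.fad_ma) and math.isfinite(self.lad_ma)):
            raise TreeError(f"non-finite FAD/LAD for {self.taxon!r}")
        if not self.fad_ma >= self.lad_ma >= 0:
            raise TreeError(
                f"stratigraphic range for {self.taxon!r} must satisfy "
                f"FAD >= LAD >= 0 (got FAD={self.fad_ma}, LAD={self.lad_ma})"
            )


class TimeTree:
    """A rooted tree with unique tip labels and finite, non-negative branch
    lengths in Myr.

    Thin wrapper around a :class:`dendropy.Tree`; all mutating operations in
    this module return new instances.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._canonicalise()
        self._validate()

    # -- construction / IO ------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "TimeTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error classes
            raise TreeError(f"malformed newick: {exc}") from exc
        return cls(dtree)

    def as_newick(self) -> str:
        """Newick string with branch lengths at 9 significant digits."""
        s = self._tree.as_string(
            schema="newick",
            real_value_format_specifier=".9g",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip()

    def copy(self) -> "TimeTree":
        return TimeTree(self._tree.clone(depth=1))

    # -- validation -------------------------------------------------------

    def _canonicalise(self) -> None:
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise TreeError("tree has an unlabelled tip")
            leaf.taxon.label = _canon(leaf.taxon.label)
        self._tree.seed_node.edge.length = None  # no branch above the root

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            bl = node.edge.length
            if bl is None or not math.isfinite(bl):
                raise TreeError(
                    f"missing or non-finite branch length above "
                    f"{_node_name(node)!r}"
                )
            if bl < 0:
                raise TreeError(f"negative branch length above {_node_name(node)!r}")

    # -- queries ----------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def _depths(self) -> dict:
        """Root-to-node path length for every node (root depth 0)."""
        depths = {}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    @property
    def root_age(self) -> float:
        """Age of the root in Ma = maximum root-to-tip path length."""
        depths = self._depths()
        return max(depths[leaf] for leaf in self._tree.leaf_node_iter())

    def tip_depths(self) -> dict[str, float]:
        depths = self._depths()
        return {leaf.taxon.label: depths[leaf] for leaf in self._tree.leaf_node_iter()}

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = list(self.tip_depths().values())
        return max(d) - min(d) <= tol

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree(n_tips={self.n_tips}, root_age={self.root_age:.6g})"


def _node_name(node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return f"<internal node {id(node):#x}>"


def parse_newick(text: str) -> TimeTree:
    """Parse a single newick tree with branch lengths."""
    return TimeTree.from_newick(text)


def read_newick(path) -> TimeTree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: TimeTree, path=None) -> str:
    """Serialise to newick (9 significant digits); optionally write to file."""
    text = tree.as_newick() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_strat_ranges(path) -> list[StratRange]:
    """Read a stratigraphic-range table (CSV header ``taxon,fad_ma,lad_ma``)."""
    df = pd.read_csv(path, comment="#")
    required = {"taxon", "fad_ma", "lad_ma"}
    if not required.issubset(df.columns):
        raise TreeError(f"range table must have columns {sorted(required)}")
    return [
        StratRange(_canon(r.taxon), float(r.fad_ma), float(r.lad_ma))
        for r in df.itertuples()
    ]


# -- time-scaling ----------------------------------------------------------


def timescale_fad_lad(
    tree: TimeTree,
    ranges: Iterable[StratRange] | Mapping[str, tuple[float, float]],
    extant: Iterable[str] | None = None,
    root_age: float | None = None,
) -> TimeTree:
    """Extend fossil terminal branches to their last appearance dates.

    The input tree is assumed dated such that fossil tips terminate at their
    first appearance dates (FAD) and extant tips at the present; internal
    node ages follow from the branch lengths under that anchoring.  Each
    fossil terminal branch is then set to span from its divergence date down
    to the taxon's LAD, so the full FAD-LAD range is included in the terminal
    branch.  Extant tips are extended to 0 Ma.

    Parameters
    ----------
    ranges
        ``StratRange`` records (or a mapping taxon -> (fad, lad)) for every
        fossil tip.  Tips absent from ``ranges`` are treated as extant unless
        ``extant`` is given, in which case tips in neither set are an error.
    root_age
        Root calibration in Ma.  By default it is derived from the input
        anchoring (the maximum of root-to-tip path length plus tip age).
    """
    if isinstance(ranges, Mapping):
        range_map = {
            _canon(k): StratRange(_canon(k), float(v[0]), float(v[1]))
            for k, v in ranges.items()
        }
    else:
        range_map = {r.taxon: r for r in ranges}

    out = tree.copy()
    tips = set(out.tip_labels)
    unknown = sorted(set(range_map) - tips)
    if unknown:
        raise TreeError(f"range table lists taxa not in the tree: {unknown}")
    if extant is not None:
        extant_set = {_canon(t) for t in extant}
        missing = sorted(tips - set(range_map) - extant_set)
        if missing:
            raise TreeError(
                f"tips with no stratigraphic range and not declared extant: {missing}"
            )

    depths = out._depths()
    if root_age is None:
        # Anchor node ages: fossil tips sit at their FAD, extant tips at 0 Ma.
        root_age = 0.0
        for leaf in out._tree.leaf_node_iter():
            tip_age = range_map[leaf.taxon.label].fad_ma if leaf.taxon.label in range_map else 0.0
            root_age = max(root_age, depths[leaf] + tip_age)

    for leaf in out._tree.leaf_node_iter():
        parent_age = root_age - depths[leaf.parent_node]
        label = leaf.taxon.label
        if label in range_map:
            lad = range_map[label].lad_ma
            if lad > parent_age + 1e-9:
                raise TreeError(
                    f"LAD of {label!r} ({lad} Ma) is older than its divergence "
                    f"date ({parent_age:.6g} Ma)"
                )
            leaf.edge.length = max(parent_age - lad, 0.0)
        else:
            leaf.edge.length = parent_age
    return TimeTree(out._tree)


# -- zero-branch resolution ------------------------------------------------


def resolve_zero_branches_equal(tree: TimeTree, tol: float = 0.0) -> TimeTree:
    """Resolve zero-length internal branches by equal time-sharing.

    For each maximal run of consecutive zero-length internal branches, the
    nearest ancestral branch with positive duration donates its time: along
    every root-to-tip path through the run, the donor's duration is divided
    equally among the donor and the zero branches on that path.  Node ages
    outside the run are untouched, so every root-to-tip distance is
    preserved exactly.  Zero-length *terminal* branches (fossil tips whose
    LAD equals their divergence date) are left in place.
    """
    out = tree.copy()
    dtree = out._tree
    seed = dtree.seed_node
    depths = out._depths()
    root_age = max(depths[l] for l in dtree.leaf_node_iter())
    age = {n: root_age - d for n, d in depths.items()}

    def is_zero_internal(node) -> bool:
        return (
            node is not seed
            and not node.is_leaf()
            and node.edge.length is not None
            and node.edge.length <= tol
        )

    # Group zero internal branches into runs keyed by their donor branch
    # (identified by the donor's child node).
    runs: dict = {}  # donor child node -> {run node -> rank}
    for node in dtree.preorder_node_iter():
        if not is_zero_internal(node):
            continue
        # walk rootward to the nearest positive-length ancestor branch
        anc = node.parent_node
        rank = 0
        while anc is not seed and anc.edge.length is not None and anc.edge.length <= tol:
            if anc.is_leaf():  # cannot happen: leaves have no descendants
                break
            anc = anc.parent_node
            rank += 1
        if anc is seed:
            raise TreeError(
                "zero-length internal branch with no positive-length ancestral "
                "branch: cannot allocate time"
            )
        run = runs.setdefault(anc, {})
        run[node] = rank

    for donor_child, members in runs.items():
        t_top = age[donor_child.parent_node]
        t_bot = age[donor_child]
        d = t_top - t_bot
        members = dict(members)
        members[donor_child] = -1  # donor child participates, rank offset -1
        max_rank = max(members.values())
        depth_of_run = max_rank + 2  # donor branch + (max_rank+1) zero steps
        for node, rank in members.items():
            age[node] = t_top - (rank + 2) * d / depth_of_run

    # Rebuild branch lengths from (possibly updated) node ages.
    for node in dtree.preorder_node_iter():
        if node is seed:
            continue
        node.edge.length = max(age[node.parent_node] - age[node], 0.0)
    return TimeTree(dtree)


# -- Brownian covariance ---------------------------------------------------


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion covariance: shared root-to-MRCA path lengths (Myr)."""

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise TreeError("covariance matrix shape does not match taxa")


def phylo_vcv(tree: TimeTree, taxa: Sequence[str] | None = None) -> PhyloCovariance:
    """Phylogenetic variance-covariance matrix for the requested tips.

    Entry (i, j) is the path length from the root to the most recent common
    ancestor of tips i and j; the diagonal holds root-to-tip path lengths.
    The root of the *full* tree is the reference even when ``taxa`` is a
    subset, so sub-matrices of the full VCV are obtained by row/column
    selection.  Polytomies are handled natively.
    """
    dtree = tree._tree
    depths = tree._depths()
    if taxa is None:
        order = tree.tip_labels
    else:
        order = [_canon(t) for t in taxa]
    tips = set(tree.tip_labels)
    unknown = [t for t in order if t not in tips]
    if unknown:
        raise TreeError(f"taxa not found in tree: {unknown}")
    if len(order) != len(set(order)):
        raise TreeError("requested taxa contain duplicates")

    index = {label: i for i, label in enumerate(order)}
    n = len(order)
    vcv = np.zeros((n, n))

    # Postorder sweep: each node contributes its depth as the covariance of
    # every pair of requested tips whose MRCA it is.
    below: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label in index:
                i = index[label]
                vcv[i, i] = depths[node]
                below[node] = [i]
            else:
                below[node] = []
        else:
            groups = [below.pop(c, []) for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            vcv[i, j] = vcv[j, i] = d
            below[node] = [i for g in groups for i in g]
    return PhyloCovariance(taxa=tuple(order), matrix=vcv)
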