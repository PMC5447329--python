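"""Trees, chronograms, alignments and fossil-calibration tables.

The central container is :class:`Phylogeny`, a strictly binary rooted tree
whose branch lengths are expected substitutions per site.  Node ids are
preorder integers (root = 0, parents before children), so ascending id order
is a valid root-to-tip traversal and descending id order a valid tip-to-root
traversal.  All cross-module tables key on these ids.

Newick parsing and serialization are delegated to dendropy; this module adds
the strict validation the downstream analyses rely on (binary topology,
branch lengths on every non-root branch, unique tip labels) and the
round-trippable flat-array representation.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO


class PhyloError(ValueError):
    """Malformed tree, alignment or calibration input."""


ROOT = 0


@dataclass
class Phylogeny:
    """Rooted binary tree with branch lengths, preorder-indexed.

    Attributes
    ----------
    parent : (n,) int array, ``-1`` at the root.
    children : per-node tuple of child ids; ``()`` at tips.
    branch_length : (n,) float array, substitutions/site on the branch above
        each node; ``nan`` at the root.
    labels : per-node tip label (``None`` on internal nodes).
    """

    parent: np.ndarray
    children: list
    branch_length: np.ndarray
    labels: list

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.branch_length = np.asarray(self.branch_length, dtype=float)
        self._label_to_id = {
            lab: i for i, lab in enumerate(self.labels) if lab is not None
        }

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_ids(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.children) if not c], dtype=int)

    @property
    def internal_ids(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.children) if c], dtype=int)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    def preorder(self):
        return range(self.n_nodes)

    def postorder(self):
        # preorder ids guarantee parent < child, so descending order is
        # a children-first traversal
        return range(self.n_nodes - 1, -1, -1)

    def tip_id(self, label: str) -> int:
        try:
            return self._label_to_id[label]
        except KeyError:
            raise PhyloError(f"unknown tip {label}") from None

    def path_to_root(self, v: int) -> list:
        out = [v]
        while self.parent[out[-1]] >= 0:
            out.append(int(self.parent[out[-1]]))
        return out

    def validate(self) -> None:
        n = self.n_nodes
        if self.parent[ROOT] != -1 or np.sum(self.parent < 0) != 1:
            raise PhyloError("tree must have exactly one root with id 0")
        for v in range(1, n):
            if not (self.parent[v] < v):
                raise PhyloError("node ids must be preorder (parent < child)")
            b = self.branch_length[v]
            if not (math.isfinite(b) and b >= 0):
                raise PhyloError(f"branch length above node {v} must be finite and >= 0")
        for v, ch in enumerate(self.children):
            if ch and len(ch) != 2:
                raise PhyloError("unsupported multifurcation")
            if not ch and self.labels[v] is None:
                raise PhyloError(f"tip {v} has no label")
        labs = [l for l in self.labels if l is not None]
        if len(labs) != len(set(labs)):
            raise PhyloError("duplicate tip labels")

    def clade_tips(self, v: int) -> list:
        """Tip labels descending from node v, in preorder."""
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(self.labels[u])
            else:
                stack.extend(reversed(self.children[u]))
        return out

    def with_lengths(self, lengths: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), list(self.children),
                         np.asarray(lengths, float), list(self.labels))


@dataclass
class Chronogram:
    """Node ages on a Phylogeny: height above the present, tips at 0.

    Ages are in Myr (absolute mode) or dimensionless with root = 1
    (relative mode).
    """

    tree: Phylogeny
    ages: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)

    @property
    def root_age(self) -> float:
        return float(self.ages[ROOT])

    def durations(self) -> np.ndarray:
        """Per-node duration of the branch above (nan at the root)."""
        d = self.ages[self.tree.parent] - self.ages
        d[ROOT] = np.nan
        return d

    def validate(self, tip_tol: float = 0.0) -> None:
        t = self.tree
        for v in range(1, t.n_nodes):
            if not self.ages[t.parent[v]] > self.ages[v]:
                raise PhyloError(f"parent of node {v} is not older than it")
        if np.any(np.abs(self.ages[t.tip_ids]) > tip_tol):
            raise PhyloError("tips must be at age 0")

    def relative(self) -> "Chronogram":
        return Chronogram(self.tree, self.ages / self.root_age)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    seed = dtree.seed_node
    parent, children, blen, labels = [], [], [], []
    index = {}
    stack = [(seed, -1)]
    while stack:
        node, pid = stack.pop()
        vid = len(parent)
        index[id(node)] = vid
        parent.append(pid)
        kids = node.child_nodes()
        if len(kids) not in (0, 2):
            raise PhyloError("unsupported multifurcation")
        children.append(())
        if pid == -1:
            blen.append(math.nan)
        else:
            if node.edge.length is None:
                raise PhyloError("missing branch length on a non-root branch")
            blen.append(float(node.edge.length))
        if kids:
            labels.append(None)
        else:
            if node.taxon is None or node.taxon.label is None:
                raise PhyloError("tip without a label")
            labels.append(str(node.taxon.label))
        # push in reverse so preorder matches written child order
        for k in reversed(kids):
            stack.append((k, vid))
    # second pass: children tuples
    ch = [[] for _ in parent]
    for v, p in enumerate(parent):
        if p >= 0:
            ch[p].append(v)
    tree = Phylogeny(np.array(parent), [tuple(c) for c in ch],
                     np.array(blen), labels)
    tree.validate()
    return tree


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    The tree must be strictly binary (a polytomy is an error, never silently
    resolved) with a branch length on every non-root branch and unique tip
    labels.  Comments in ``[]`` are ignored; quoted labels are supported.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise PhyloError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def write_newick(tree: Phylogeny, lengths: np.ndarray | None = None) -> str:
    """Serialize to Newick (lengths to 12 significant digits)."""
    b = tree.branch_length if lengths is None else np.asarray(lengths, float)

    def rec(v: int) -> str:
        if tree.is_tip(v):
            core = _quote(tree.labels[v])
        else:
            core = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        if v == ROOT:
            return core
        return f"{core}:{_fmt(b[v])}"

    return rec(ROOT) + ";"


def _quote(label: str) -> str:
    if any(c in label for c in " ():;,[]'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def chronogram_to_newick(chron: Chronogram) -> str:
    """Write a chronogram as Newick with durations as branch lengths."""
    d = chron.durations()
    d[ROOT] = 0.0
    return write_newick(chron.tree, d)


# ---------------------------------------------------------------------------
# MRCA resolution
# ---------------------------------------------------------------------------

def resolve_mrca(tree: Phylogeny, tips) -> int:
    """Most recent common ancestor of a pair of tip labels (symmetric)."""
    a, b = tips
    pa = tree.path_to_root(tree.tip_id(a))
    pb = set(tree.path_to_root(tree.tip_id(b)))
    for v in pa:
        if v in pb:
            return v
    raise PhyloError("disconnected tree")  # pragma: no cover


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Equal-length sequence records, label -> string."""

    labels: list
    seqs: list

    def __post_init__(self):
        if len(set(len(s) for s in self.seqs)) > 1:
            raise PhyloError("alignment sequences differ in length")
        if len(self.labels) != len(set(self.labels)):
            raise PhyloError("duplicate sequence labels")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __getitem__(self, label: str) -> str:
        return self.seqs[self.labels.index(label)]


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Read FASTA or relaxed PHYLIP (``fmt="phylip"``) via Biopython."""
    bio_fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
    aln = AlignIO.read(str(path), bio_fmt)
    return Alignment([r.id for r in aln], [str(r.seq).upper() for r in aln])


def write_alignment(aln: Alignment, path, fmt: str = "fasta") -> None:
    with open(path, "w") as fh:
        if fmt == "fasta":
            for lab, s in zip(aln.labels, aln.seqs):
                fh.write(f">{lab}\n{s}\n")
        elif fmt == "phylip":
            fh.write(f" {len(aln.labels)} {aln.length}\n")
            for lab, s in zip(aln.labels, aln.seqs):
                fh.write(f"{lab}  {s}\n")
        else:
            raise ValueError(f"unknown alignment format {fmt}")


# ---------------------------------------------------------------------------
# Calibrations
# ---------------------------------------------------------------------------

_KINDS = ("min", "max", "min_max", "root_density")


@dataclass
class Calibration:
    """One fossil constraint: a clade (MRCA of two tips) with age bounds.

    ``tail_mass`` is the probability allowed outside a soft bound
    (0.05 = the conventional "soft bound 5%"); 0 makes the bound hard.
    For ``kind="min_max"`` each side carries ``tail_mass/2``.
    """

    clade: tuple | None
    kind: str
    t_min: float | None = None
    t_max: float | None = None
    density: tuple | None = None  # ("gamma", mean, sd) | ("exponential", mean)
    tail_mass: float = 0.05
    node: int | None = None  # filled by bind()

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise PhyloError(f"unknown calibration kind {self.kind}")
        if not (0 <= self.tail_mass < 0.5):
            raise PhyloError("tail_mass must lie in [0, 0.5)")
        if self.kind in ("min", "min_max") and self.t_min is None:
            raise PhyloError("min bound requires t_min")
        if self.kind in ("max", "min_max") and self.t_max is None:
            raise PhyloError("max bound requires t_max")
        if self.t_min is not None and self.t_max is not None:
            if not self.t_min < self.t_max:
                raise PhyloError("t_min must be < t_max")


@dataclass
class CalibrationSet:
    calibrations: list = field(default_factory=list)

    def __post_init__(self):
        n_root = sum(1 for c in self.calibrations if c.kind == "root_density")
        if n_root > 1:
            raise PhyloError("at most one root_density calibration")

    def __len__(self):
        return len(self.calibrations)

    def __iter__(self):
        return iter(self.calibrations)

    @property
    def root_density(self):
        for c in self.calibrations:
            if c.kind == "root_density":
                return c.density
        return None

    def bound(self) -> list:
        """Non-root calibrations (the age-bound constraints)."""
        return [c for c in self.calibrations if c.kind != "root_density"]

    def bind(self, tree: Phylogeny) -> "CalibrationSet":
        """Resolve every clade to a node id of ``tree`` (returns a copy)."""
        out = []
        for c in self.calibrations:
            if c.kind == "root_density" or c.clade is None:
                out.append(replace(c, node=ROOT))
            else:
                out.append(replace(c, node=resolve_mrca(tree, c.clade)))
        nodes = [c.node for c in out if c.kind != "root_density"]
        if len(nodes) != len(set(nodes)):
            raise PhyloError("two calibrations resolve to the same node")
        return CalibrationSet(out)


def parse_density(text: str) -> tuple | None:
    """Parse ``name:param[:param]`` density strings (``none`` -> None)."""
    if text in (".", "none", "", None):
        return None
    parts = text.split(":")
    name, params = parts[0], [float(p) for p in parts[1:]]
    if name == "gamma" and len(params) == 2:
        return ("gamma", params[0], params[1])
    if name == "exponential" and len(params) == 1:
        return ("exponential", params[0])
    raise PhyloError(f"cannot parse density {text!r}")


def format_density(density: tuple | None) -> str:
    if density is None:
        return "none"
    return ":".join([density[0]] + [format(p, ".12g") for p in density[1:]])


_CAL_COLS = ["clade_a", "clade_b", "kind", "t_min", "t_max", "density", "tail_mass"]


def read_calibrations(source) -> CalibrationSet:
    """Read a calibration TSV (``.`` for absent fields).

    Columns: clade_a, clade_b, kind, t_min, t_max, density, tail_mass.
    ``kind`` is min | max | min_max | root_density; ``clade_a`` may be
    ``root`` for a root-addressed row.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    missing = [c for c in _CAL_COLS if c not in df.columns]
    if missing:
        raise PhyloError(f"calibration table lacks columns {missing}")

    def opt(x):
        return None if (pd.isna(x) or x == ".") else float(x)

    cals = []
    for _, row in df.iterrows():
        a, b = row["clade_a"], row["clade_b"]
        clade = None if (a == "root" or b == ".") else (a, b)
        cals.append(Calibration(
            clade=clade,
            kind=row["kind"],
            t_min=opt(row["t_min"]),
            t_max=opt(row["t_max"]),
            density=parse_density(row["density"]),
            tail_mass=0.05 if row["tail_mass"] == "." else float(row["tail_mass"]),
        ))
    return CalibrationSet(cals)


def write_calibrations(calset: CalibrationSet, path) -> None:
    rows = []
    for c in calset:
        a, b = c.clade if c.clade else ("root", ".")
        rows.append({
            "clade_a": a, "clade_b": b, "kind": c.kind,
            "t_min": "." if c.t_min is None else format(c.t_min, ".12g"),
            "t_max": "." if c.t_max is None else format(c.t_max, ".12g"),
            "density": format_density(c.density),
            "tail_mass": format(c.tail_mass, ".12g"),
        })
    pd.DataFrame(rows, columns=_CAL_COLS).to_csv(path, sep="\t", index=False)


def smallest_two_tips(tree: Phylogeny, v: int) -> str:
    """Stable human-readable clade address: the two lexicographically
    smallest tip labels below the node."""
    tips = sorted(tree.clade_tips(v))
    return "|".join(tips[:2])
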