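"""Lineage parsing and the post-order lineage tree.

References carry an ordered taxonomic lineage (e.g. phylum → species) in
their FASTA header using the ``;tax=p:...,c:...,s:...;`` dialect. All
lineages of a database are merged into one multifurcating tree whose leaves
are the individual reference sequences, laid out in post-order. Every inner
node stores the half-open interval ``(a, b)`` of post-order leaf indices it
covers, so the confidence mass of any clade is a prefix-sum difference
``Ap[b] - Ap[a]`` — one subtraction per clade regardless of its size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("kmertax")


class LineageParseError(ValueError):
    """Raised when a reference header's taxonomy annotation is malformed."""


def parse_lineage(header: str) -> list[tuple[str, str]]:
    """Parse a ``tax=`` annotated FASTA header into (rank_label, taxon) pairs.

    The header (with or without the leading ``>``) must contain a
    ``tax=<label>:<name>,...`` field delimited by ``;``. Rank labels are the
    single-letter prefixes and must not repeat; taxa are returned in file
    order, highest rank first.
    """
    text = header.lstrip(">").strip()
    tax_field = None
    for part in text.split(";"):
        part = part.strip()
        if part.startswith("tax="):
            tax_field = part[len("tax=") :]
            break
    if tax_field is None:
        raise LineageParseError(f"no tax= field in header {header!r}")
    if not tax_field:
        raise LineageParseError(f"empty tax= field in header {header!r}")
    lineage: list[tuple[str, str]] = []
    seen: set[str] = set()
    for item in tax_field.split(","):
        item = item.strip()
        if not item:
            raise LineageParseError(f"empty lineage component in header {header!r}")
        label, sep, name = item.partition(":")
        if not sep or not name:
            raise LineageParseError(
                f"lineage component {item!r} is not label:name in header {header!r}"
            )
        if label in seen:
            raise LineageParseError(
                f"rank label {label!r} repeats in header {header!r}"
            )
        seen.add(label)
        lineage.append((label, name))
    return lineage


@dataclass
class TreeNode:
    """Inner node of the lineage tree (one taxon at one rank depth)."""

    taxon_name: str
    rank_label: str
    rank_depth: int
    children: list["TreeNode"] = field(default_factory=list)
    ref_ids: list[str] = field(default_factory=list)  # refs whose lineage ends here
    a: int = 0  # half-open post-order leaf interval [a, b)
    b: int = 0

    @property
    def leaf_count(self) -> int:
        return self.b - self.a


@dataclass
class LineageTree:
    """Multifurcating taxonomy over the references, leaves in post-order."""

    root: TreeNode
    leaf_ids: list[str]  # ref_ids in post-order

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def build_lineage_tree(
    lineages: list[tuple[str, list[tuple[str, str]]]],
) -> tuple[LineageTree, list[int]]:
    """Build the lineage tree and the input-order → post-order permutation.

    References with identical lineage prefixes share ancestor nodes; a
    reference hangs as a leaf under its deepest named taxon. Child taxa are
    ordered by name and leaf children by ref_id, so the layout is invariant
    to the input order of references. Lineages shorter than the deepest one
    are allowed (attached at their last rank) with a warning.
    """
    if not lineages:
        raise LineageParseError("no lineages to build a tree from")
    root = TreeNode("", "", -1)
    by_path: dict[tuple[tuple[str, str], ...], TreeNode] = {(): root}
    max_depth = max(len(lin) for _, lin in lineages)
    for ref_id, lin in lineages:
        if not lin:
            raise LineageParseError(f"reference {ref_id!r} has an empty lineage")
        if len(lin) < max_depth:
            logger.warning(
                "reference %s has a %d-rank lineage (deepest in database: %d); "
                "attached at its last rank",
                ref_id,
                len(lin),
                max_depth,
            )
        path: tuple[tuple[str, str], ...] = ()
        node = root
        for depth, (label, name) in enumerate(lin):
            path = path + ((label, name),)
            child = by_path.get(path)
            if child is None:
                child = TreeNode(name, label, depth)
                node.children.append(child)
                by_path[path] = child
            node = child
        node.ref_ids.append(ref_id)

    # canonical order + post-order leaf intervals
    leaf_ids: list[str] = []

    def layout(node: TreeNode) -> None:
        node.a = len(leaf_ids)
        for rid in sorted(node.ref_ids):
            leaf_ids.append(rid)
        node.children.sort(key=lambda c: c.taxon_name)
        for child in node.children:
            layout(child)
        node.b = len(leaf_ids)

    layout(root)
    pos = {rid: i for i, rid in enumerate(leaf_ids)}
    perm = [pos[ref_id] for ref_id, _ in lineages]
    return LineageTree(root, leaf_ids), perm


@dataclass(frozen=True)
class CladeScore:
    """Aggregated confidence of one clade at one rank."""

    taxon_name: str
    rank_label: str
    rank_depth: int
    score: float
    leaf_count: int


@dataclass(frozen=True)
class LineageResult:
    """One reported root-to-leaf (or root-to-pruned-frontier) lineage.

    ``clades`` runs from the highest named rank down to the terminal level;
    for a full lineage the terminal entry is the reference itself (rank
    label ``""``). ``truncated`` marks lineages whose descent stopped at a
    pruned frontier.
    """

    clades: tuple[CladeScore, ...]
    ref_id: str | None
    truncated: bool

    @property
    def terminal_score(self) -> float:
        return self.clades[-1].score

    def lineage_string(self, percent: bool = False) -> str:
        scale = 100.0 if percent else 1.0
        parts = [
            f"{c.rank_label}:{c.taxon_name}({c.score * scale:.4f})"
            for c in self.clades
            if c.rank_label  # terminal reference entry rendered separately
        ]
        if self.truncated:
            parts.append("*")
        return ",".join(parts)


def aggregate_confidences(
    tree: LineageTree,
    confidence: np.ndarray,
    prune_threshold: float = 0.005,
) -> list[LineageResult]:
    """Aggregate per-leaf confidences into per-rank clade scores.

    ``confidence`` is the L1-normalized per-reference vector in post-order
    leaf layout. Clade scores are read off the prefix sum of that vector;
    the depth-first descent stops at any node whose score falls below
    ``prune_threshold``, so only relevant lineages are reported. Results are
    sorted by terminal score descending, ties broken by lineage string.
    """
    n = tree.n_leaves
    confidence = np.asarray(confidence, dtype=np.float64)
    if confidence.shape != (n,):
        raise ValueError(
            f"confidence vector has shape {confidence.shape}, expected ({n},)"
        )
    prefix = np.concatenate([[0.0], np.cumsum(confidence)])

    def clade_mass(node: TreeNode) -> float:
        return float(prefix[node.b] - prefix[node.a])

    results: list[LineageResult] = []

    def descend(node: TreeNode, path: tuple[CladeScore, ...]) -> None:
        surviving: list[tuple[float, CladeScore, TreeNode | None, str | None]] = []
        for child in node.children:
            s = clade_mass(child)
            if s >= prune_threshold:
                cs = CladeScore(
                    child.taxon_name, child.rank_label, child.rank_depth, s,
                    child.leaf_count,
                )
                surviving.append((s, cs, child, None))
        # refs attached directly at this node occupy the first slots of its
        # interval, in sorted ref_id order (see build_lineage_tree layout)
        for j, rid in enumerate(sorted(node.ref_ids)):
            s = float(confidence[node.a + j])
            if s >= prune_threshold:
                cs = CladeScore(rid, "", node.rank_depth + 1, s, 1)
                surviving.append((s, cs, None, rid))
        if not surviving:
            if path:
                results.append(LineageResult(path, ref_id=None, truncated=True))
            return
        for _, cs, child, rid in surviving:
            if child is not None:
                descend(child, path + (cs,))
            else:
                results.append(LineageResult(path + (cs,), ref_id=rid, truncated=False))

    descend(tree.root, ())
    results.sort(key=lambda r: (-r.terminal_score, r.lineage_string()))
    return results
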