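"""Poisson-corrected protein distances and neighbor-joining tree building.

The phylogeny of CtrA homologs is built the classical way: align the protein
set (alignment itself is a prerequisite, not performed here), drop every
column containing a gap or missing character (complete deletion), compute
pairwise p-distances (fraction of differing sites), convert them with the
Poisson correction

    d = -ln(1 - p)

into expected substitutions per site, and run Saitou-Nei neighbor joining
with the Studier-Keppler Q-criterion.  Ties in the Q minimisation are broken
toward the lowest (i, j) index pair, so the tree is deterministic; negative
branch lengths are kept unless clamping is requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

#: Characters treated as gap or missing data during complete deletion
#: ('?' is missing, 'X' is an ambiguous residue).
GAP_MISSING = frozenset("-?X")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ProteinAlignment:
    """An aligned protein set: unique taxon ids and equal-length rows."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon ids are not unique")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise ValueError("alignment rows differ in length")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_alignment_fasta(path: str | Path) -> ProteinAlignment:
    """Read an aligned protein FASTA; unequal row lengths are rejected."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(
            f"{path} is not an alignment (row lengths {sorted(lengths)}); "
            "align the sequences first"
        )
    return ProteinAlignment(
        taxa=tuple(r.id for r in records),
        rows=tuple(str(r.seq).upper() for r in records),
    )


def complete_deletion(alignment: ProteinAlignment) -> ProteinAlignment:
    """Drop every column in which any row carries '-', '?' or 'X'."""
    if alignment.n_columns == 0:
        raise ValueError("empty alignment")
    cols = [
        j
        for j in range(alignment.n_columns)
        if all(row[j] not in GAP_MISSING for row in alignment.rows)
    ]
    if not cols:
        raise ValueError(
            "no columns without gaps or missing data remain: distances undefined"
        )
    rows = tuple("".join(row[j] for j in cols) for row in alignment.rows)
    return ProteinAlignment(taxa=alignment.taxa, rows=rows)


def p_distance(a: str, b: str) -> float:
    """Fraction of positions at which two gap-free sequences differ."""
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ ({len(a)} vs {len(b)})")
    if not a:
        raise ValueError("empty sequences")
    diff = sum(x != y for x, y in zip(a, b))
    return diff / len(a)


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance -ln(1-p), in substitutions per site."""
    if not 0 <= p < 1:
        raise ValueError(f"p-distance {p} is saturated or out of range [0, 1)")
    return float(-np.log1p(-p))


def poisson_distance_matrix(alignment: ProteinAlignment) -> DistanceMatrix:
    """Pairwise Poisson-corrected distances of a gap-free alignment."""
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(alignment.rows[i], alignment.rows[j])
            try:
                d[i, j] = d[j, i] = poisson_distance(p)
            except ValueError as exc:
                raise ValueError(
                    f"pair ({alignment.taxa[i]}, {alignment.taxa[j]}): {exc}"
                ) from exc
    return DistanceMatrix(d, ids=list(alignment.taxa))


def total_length(tree: TreeNode) -> float:
    """Sum of branch lengths over all edges of the tree."""
    return float(sum(n.length or 0.0 for n in tree.traverse(include_self=False)))


def nj_tree(d: DistanceMatrix, clamp_negative: bool = False) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Saitou-Nei agglomeration with the Studier-Keppler Q-criterion
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``; branch lengths from the standard
    two-point formulas.  Ties are broken toward the lowest (i, j) pair in the
    current node ordering.  The returned tree is unrooted, represented with a
    trifurcating seed node (for n >= 3); n == 2 yields a single leaf pair
    whose path length equals d(1,2).
    """
    mat = np.asarray(d.data, dtype=float)
    ids = list(d.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa for a tree")
    if not np.isfinite(mat).all():
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix is not symmetric")

    def _edge(length: float) -> float:
        return max(length, 0.0) if clamp_negative else length

    nodes = [TreeNode(name=name) for name in ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = mat.sum(axis=1)
        q = (m - 2) * mat - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) pair wins ties: scan upper triangle in index order
        best, bi, bj = np.inf, -1, -1
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best:
                    best, bi, bj = q[i, j], i, j
        dij = mat[bi, bj]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[bi].length = _edge(li)
        nodes[bj].length = _edge(lj)
        parent.extend([nodes[bi], nodes[bj]])
        new_row = 0.5 * (mat[bi] + mat[bj] - dij)
        keep = [k for k in range(m) if k not in (bi, bj)]
        mat = np.vstack([mat[keep][:, keep], new_row[keep][None, :]])
        mat = np.hstack([mat, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    root = TreeNode()
    if len(nodes) == 2:
        # degenerate pair: split the single edge between the two leaves
        half = mat[0, 1] / 2.0
        nodes[0].length = _edge(half)
        nodes[1].length = _edge(half)
        root.extend(nodes)
        return root
    # final three nodes: three-point formulas around the last internal node
    d01, d02, d12 = mat[0, 1], mat[0, 2], mat[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, length in zip(nodes, lengths):
        node.length = _edge(length)
    root.extend(nodes)
    return root


def pipeline_ctra_phylogeny(
    alignment: ProteinAlignment, clamp_negative: bool = False
) -> tuple[TreeNode, DistanceMatrix, dict]:
    """Complete deletion -> p-distance -> Poisson correction -> NJ.

    Returns the tree, the distance matrix, and a report dict with the taxon
    count, retained column count and total branch length.  Stage failures are
    re-raised with the failing stage named.
    """
    try:
        trimmed = complete_deletion(alignment)
    except ValueError as exc:
        raise ValueError(f"complete_deletion: {exc}") from exc
    try:
        dm = poisson_distance_matrix(trimmed)
    except ValueError as exc:
        raise ValueError(f"poisson_distance: {exc}") from exc
    try:
        tree = nj_tree(dm, clamp_negative=clamp_negative)
    except ValueError as exc:
        raise ValueError(f"nj_tree: {exc}") from exc
    report = {
        "n_taxa": alignment.n_taxa,
        "n_positions_input": alignment.n_columns,
        "n_positions_retained": trimmed.n_columns,
        "total_branch_length": total_length(tree),
    }
    logger.info(
        "phylogeny: %d taxa, %d/%d positions retained, total branch length %.6f",
        report["n_taxa"], report["n_positions_retained"],
        report["n_positions_input"], report["total_branch_length"],
    )
    return tree, dm, report


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_distance_matrix_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_data_frame().to_csv(path, sep="\t")
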