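"""Comparative analyses: pairwise identity matrices with within/between
clade summaries, neighbor-joining tree construction with outgroup-rooted
clade assignment, and TIR sequence-logo matrices.

Neighbor joining is implemented in full (agglomeration on the Q criterion
with three-point resolution of the final triple); it is exact on additive
distance matrices.  Distances fed to it by the pipeline are
(100 - percent identity) / 100 — an uncorrected similarity distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .seeding import make_protein_aligner


@dataclass(frozen=True)
class IdentityMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # percent identities, symmetric, diagonal 100
    clades: tuple[str, ...]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("identity matrix must be symmetric")


@dataclass(frozen=True)
class IdentitySummary:
    within_by_clade: dict[str, Optional[float]]
    within_mean: Optional[float]
    between_mean: Optional[float]


@dataclass(frozen=True)
class PhyloTree:
    newick: str
    labels: tuple[str, ...]
    negative_branches_clamped: int = 0

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick, schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )


@dataclass(frozen=True)
class TirLogo:
    frequencies: np.ndarray  # positions x 4 (A, C, G, T), rows sum to 1
    information_content: np.ndarray  # bits in [0, 2]
    n_sequences: int
    padded: bool

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.frequencies, axis=1))


# ---------------------------------------------------------------------------
# identities


def pairwise_identity(a: str, b: str, aligner=None) -> float:
    """Global-alignment identity: matches / alignment columns x 100."""
    if len(a) < 20 or len(b) < 20:
        raise ValueError("sequences must be >= 20 aa")
    if aligner is None:
        aligner = make_protein_aligner(mode="global")
    aln = aligner.align(a, b)[0]
    x, y = str(aln[0]), str(aln[1])
    matches = sum(1 for p, q in zip(x, y) if p == q and p != "-")
    return 100.0 * matches / len(x)


def identity_matrix(seqs: Sequence[str], labels: Sequence[str],
                    clades: Sequence[str]) -> IdentityMatrix:
    n = len(seqs)
    aligner = make_protein_aligner(mode="global")
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(seqs[i], seqs[j], aligner)
    return IdentityMatrix(labels=tuple(labels), matrix=m, clades=tuple(clades))


def identity_summary(mat: IdentityMatrix) -> IdentitySummary:
    """Mean identities within each clade (diagonal excluded) and over all
    between-clade pairs; absent (None) where undefined."""
    clades = sorted(set(mat.clades))
    within: dict[str, Optional[float]] = {}
    within_vals: list[float] = []
    for c in clades:
        idx = [i for i, x in enumerate(mat.clades) if x == c]
        vals = [mat.matrix[i, j] for i in idx for j in idx if i < j]
        within[c] = float(np.mean(vals)) if vals else None
        within_vals.extend(vals)
    between_vals = [
        mat.matrix[i, j]
        for i in range(len(mat.clades))
        for j in range(i + 1, len(mat.clades))
        if mat.clades[i] != mat.clades[j]
    ]
    return IdentitySummary(
        within_by_clade=within,
        within_mean=float(np.mean(within_vals)) if within_vals else None,
        between_mean=float(np.mean(between_vals)) if between_vals else None,
    )


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(distances: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Classic neighbor joining; exact on additive matrices.

    Negative branch lengths (possible on non-additive input) are clamped
    to zero and counted.  Raises on non-symmetric input.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix/labels size mismatch")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0) or np.any(d < -1e-12):
        raise ValueError("distances must be non-negative with zero diagonal")
    if n == 1:
        return PhyloTree(newick=f"({labels[0]}:0);", labels=tuple(labels))

    clamped = 0

    def edge(length: float) -> float:
        nonlocal clamped
        if length < 0:
            clamped += 1
            return 0.0
        return length

    nodes = [str(lbl) for lbl in labels]
    D = d.copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = edge(li), edge(lj)
        new_label = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        new_row = np.zeros(D.shape[0] + 1)
        for m_idx in active:
            if m_idx in (i, j):
                continue
            new_row[m_idx] = 0.5 * (D[i, m_idx] + D[j, m_idx] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(new_label)
        active = [m for m in active if m not in (i, j)] + [D.shape[0] - 1]

    if len(active) == 3:
        a, b, c = active
        la = edge(0.5 * (D[a, b] + D[a, c] - D[b, c]))
        lb = edge(0.5 * (D[a, b] + D[b, c] - D[a, c]))
        lc = edge(0.5 * (D[a, c] + D[b, c] - D[a, b]))
        newick = (f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},"
                  f"{nodes[c]}:{lc:.10g});")
    else:  # two nodes left
        a, b = active
        half = edge(D[a, b] / 2.0)
        newick = f"({nodes[a]}:{half:.10g},{nodes[b]}:{half:.10g});"
    return PhyloTree(newick=newick, labels=tuple(labels),
                     negative_branches_clamped=clamped)


def assign_clades(
    tree: PhyloTree,
    reference_labels: Mapping[str, str],
    outgroup: Sequence[str],
) -> dict[str, str]:
    """Assign each unlabeled (query) leaf the clade of the smallest rooted
    cluster containing it and references of exactly one clade.

    The tree is rooted on the outgroup before clustering; queries whose
    smallest reference-containing cluster mixes clades are "unassigned".
    """
    if not reference_labels:
        raise ValueError("no reference labels supplied")
    t = tree.to_dendropy()
    t.is_rooted = True
    og = [l for l in t.leaf_node_iter() if l.taxon.label in set(outgroup)]
    if og:
        if len(og) == 1:
            t.reroot_at_edge(og[0].edge, update_bipartitions=False)
        else:
            mrca = t.mrca(taxa=[l.taxon for l in og])
            if mrca.parent_node is not None:
                t.reroot_at_edge(mrca.edge, update_bipartitions=False)
    result: dict[str, str] = {}
    ref_ids = set(reference_labels)
    out_ids = set(outgroup)
    for leaf in t.leaf_node_iter():
        name = leaf.taxon.label
        if name in ref_ids or name in out_ids:
            continue
        node = leaf
        assigned = "unassigned"
        while node.parent_node is not None:
            node = node.parent_node
            members = {l.taxon.label for l in node.leaf_iter()}
            refs_in = members & ref_ids
            if refs_in:
                clades = {reference_labels[r] for r in refs_in}
                assigned = clades.pop() if len(clades) == 1 else "unassigned"
                break
        result[name] = assigned
    return result


# ---------------------------------------------------------------------------
# TIR logos


def tir_logo(tirs: Sequence[str]) -> TirLogo:
    """Position frequency matrix + information content for aligned TIRs.

    TIRs are left-anchored (position 0 is the element edge); shorter arms
    are right-padded and flagged.  IC per column is 2 + sum f*log2 f, over
    the sequences covering that column.
    """
    if len(tirs) < 2:
        raise ValueError("need at least 2 TIRs")
    width = max(len(t) for t in tirs)
    padded = any(len(t) != width for t in tirs)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((width, 4))
    for t in tirs:
        for p, ch in enumerate(t.upper()):
            if ch in base_idx:
                counts[p, base_idx[ch]] += 1
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a logo column has no unambiguous bases")
    freqs = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic = np.clip(ic, 0.0, 2.0)
    return TirLogo(frequencies=freqs, information_content=ic,
                   n_sequences=len(tirs), padded=padded)
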