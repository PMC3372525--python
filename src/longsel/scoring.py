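"""Mutation-rate-corrected BLOSUM similarity scores.

A fit column's regression response is the BLOSUM similarity of each
non-reference residue to the reference residue.  Fast-evolving lineages
accumulate low-similarity residues everywhere, trait or no trait, so each
species' scores are shifted by log10 of its substitution path length
relative to the reference (a species twice as diverged gets +log10(2) ≈
+0.3 back).  Corrected scores are clamped to the range of scores the
matrix can actually produce against that reference residue.

The substitution path lengths come from a substitution-scaled tree.  When
none is supplied, a simple internal estimator fits branch lengths on the
fixed input topology by least squares to Poisson-corrected pairwise
distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core import (
    AlignmentPanel,
    ColumnRecord,
    LongselError,
    PhylogeneticTree,
    SubstitutionMatrix,
    is_residue,
)


@dataclass
class MutationRates:
    """Per-species substitution path lengths and log-ratio corrections."""

    m: dict[str, float]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.m:
            raise LongselError(f"reference {self.reference!r} has no path length")
        bad = [s for s, v in self.m.items() if v <= 0]
        if bad:
            raise LongselError(f"non-positive substitution path length for {bad}")

    def correction(self, species: str) -> float:
        """log10(m_s / m_ref); 0 for the reference itself."""
        return math.log10(self.m[species] / self.m[self.reference])

    @classmethod
    def uniform(cls, species, reference: str) -> "MutationRates":
        """Equal path lengths: every correction is zero."""
        return cls({s: 1.0 for s in set(species) | {reference}}, reference)


def mutation_lengths_from_tree(
    subst_tree: PhylogeneticTree, reference: str
) -> MutationRates:
    """Root-to-tip path length of each species on the substitution tree."""
    if subst_tree.kind != "subst":
        raise LongselError("mutation rates need a substitution-scaled tree")
    depths = subst_tree.tip_depths()
    if reference not in depths:
        raise LongselError(f"reference {reference!r} not in substitution tree")
    return MutationRates(dict(depths), reference)


# ---------------------------------------------------------------------------
# Internal substitution-tree estimator
# ---------------------------------------------------------------------------

def pairwise_poisson_distances(
    panel: AlignmentPanel, species: list[str]
) -> np.ndarray:
    """d_ij = -ln(1 - p_ij), mismatch fraction over shared real-residue columns."""
    k = len(species)
    mism = np.zeros((k, k))
    shared = np.zeros((k, k))
    for _, msa in panel:
        present = [sp for sp in species if sp in msa]
        idx = {sp: species.index(sp) for sp in present}
        seqs = {sp: msa[sp] for sp in present}
        length = len(next(iter(msa.values())))
        for col in range(length):
            here = [sp for sp in present if is_residue(seqs[sp][col])]
            for a in range(len(here)):
                ia = idx[here[a]]
                ca = seqs[here[a]][col]
                for b in range(a + 1, len(here)):
                    ib = idx[here[b]]
                    shared[ia, ib] += 1
                    if ca != seqs[here[b]][col]:
                        mism[ia, ib] += 1
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if shared[i, j] == 0:
                raise LongselError(
                    f"no shared columns for {species[i]!r}/{species[j]!r}"
                )
            p = mism[i, j] / shared[i, j]
            if p >= 1.0:
                raise LongselError(
                    f"mismatch fraction 1 for {species[i]!r}/{species[j]!r}; "
                    "Poisson distance undefined"
                )
            d[i, j] = d[j, i] = -math.log1p(-p)
    return d


def estimate_substitution_tree(
    panel: AlignmentPanel, topology: PhylogeneticTree
) -> PhylogeneticTree:
    """Fit branch lengths on the given topology by least squares to
    Poisson-corrected pairwise distances; negative lengths truncated to 0.

    The minimum-norm solution is used where the rooted topology leaves a
    branch pair unidentifiable (the two edges meeting at the root).
    """
    species = sorted(topology.tip_labels())
    panel_species = {sp for _, msa in panel for sp in msa}
    missing = [s for s in panel_species if s not in species]
    if missing:
        raise LongselError(f"topology missing panel species: {missing}")
    d = pairwise_poisson_distances(panel, species)

    tree = topology.tree.clone(depth=1)
    edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None]
    edge_index = {id(e): i for i, e in enumerate(edges)}
    leaf_by_label = {l.taxon.label: l for l in tree.leaf_node_iter()}

    def path_edges(a: str, b: str) -> list[int]:
        chain_a, chain_b = [], []
        n = leaf_by_label[a]
        while n is not None:
            chain_a.append(n)
            n = n.parent_node
        n = leaf_by_label[b]
        while n is not None:
            chain_b.append(n)
            n = n.parent_node
        set_a = {id(x) for x in chain_a}
        mrca = next(x for x in chain_b if id(x) in set_a)
        out = []
        for chain in (chain_a, chain_b):
            for node in chain:
                if id(node) == id(mrca):
                    break
                out.append(edge_index[id(node.edge)])
        return out

    pairs = [(i, j) for i in range(len(species)) for j in range(i + 1, len(species))]
    A = np.zeros((len(pairs), len(edges)))
    b = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for e in path_edges(species[i], species[j]):
            A[row, e] = 1.0
        b[row] = d[i, j]
    lengths, *_ = np.linalg.lstsq(A, b, rcond=None)
    lengths = np.clip(lengths, 0.0, None)
    for e in edges:
        e.length = float(lengths[edge_index[id(e)]])
    return PhylogeneticTree(tree, "subst")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoredColumn:
    """A fit column with corrected, clamped similarity scores per species."""

    column: ColumnRecord
    scores: dict[str, float] = field(default_factory=dict)


def corrected_score(
    residue: str,
    ref_residue: str,
    matrix: SubstitutionMatrix,
    rates: MutationRates,
    species: str,
) -> float:
    """BLOSUM score + mutation-rate correction, clamped to the attainable
    score range of the reference residue's matrix row."""
    raw = matrix.score(residue, ref_residue)
    lo, hi = matrix.row_range(ref_residue)
    return float(min(max(raw + rates.correction(species), lo), hi))


def score_column(
    column: ColumnRecord,
    matrix: SubstitutionMatrix,
    rates: MutationRates,
    reference: str,
) -> ScoredColumn:
    """Score every non-reference residue of a fit column against the reference."""
    if column.klass != "fit":
        raise LongselError(f"can only score fit columns, got {column.klass!r}")
    if column.ref_residue is None:
        raise LongselError("fit column lacks a reference residue")
    scores = {
        sp: corrected_score(c, column.ref_residue, matrix, rates, sp)
        for sp, c in column.characters.items()
        if sp != reference
    }
    return ScoredColumn(column=column, scores=scores)
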