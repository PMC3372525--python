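"""Domain containers shared across the pipeline.

The scan operates on four kinds of external data: a panel of protein
multiple sequence alignments keyed by species, a species trait table
(maximum lifespan in years, adult body mass in grams), a rooted phylogeny
(either time-scaled/ultrametric or scaled in expected amino-acid
substitutions), and an amino-acid substitution matrix.  All of them are
validated at construction so downstream code can assume the invariants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

#: The 20 standard amino acids, alphabetical one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MASK = "X"
#: Ambiguity / rare codes that are masked on input rather than scored.
AMBIGUOUS_AA = "BZUO"

_ALLOWED = set(STANDARD_AA) | {GAP, MASK}


class LongselError(ValueError):
    """Base class for input-contract violations."""


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentPanel:
    """A set of species-keyed protein MSAs.

    ``alignments`` maps an alignment id to a mapping species-id -> aligned
    sequence.  Sequences are uppercase, drawn from the 20 standard amino
    acids plus ``-`` (gap) and ``X`` (masked).  Within one alignment all
    sequences have equal length.
    """

    alignments: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for aln_id, msa in self.alignments.items():
            if not msa:
                raise LongselError(f"alignment {aln_id!r} is empty")
            lengths = {len(s) for s in msa.values()}
            if len(lengths) != 1:
                raise LongselError(
                    f"ragged alignment {aln_id!r}: sequence lengths {sorted(lengths)}"
                )
            for sp, seq in msa.items():
                bad = set(seq) - _ALLOWED
                if bad:
                    pos = next(i for i, c in enumerate(seq) if c in bad)
                    raise LongselError(
                        f"illegal character {seq[pos]!r} at position {pos} "
                        f"in {aln_id!r}/{sp!r}"
                    )

    def length(self, aln_id: str) -> int:
        msa = self.alignments[aln_id]
        return len(next(iter(msa.values())))

    def species(self, aln_id: str) -> list[str]:
        return list(self.alignments[aln_id])

    def __iter__(self):
        return iter(self.alignments.items())


def is_residue(c: str) -> bool:
    """True for a real residue (not gap, not mask)."""
    return c != GAP and c != MASK


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Per-species maximum lifespan (years) and body mass (grams).

    ``reference`` names the long-lived reference species whose residues
    define the similarity axis of the scan (human in the original study).
    """

    data: pd.DataFrame  # index: species; columns: mls_years, mass_g
    reference: str

    def __post_init__(self) -> None:
        req = {"mls_years", "mass_g"}
        if not req <= set(self.data.columns):
            raise LongselError(f"trait table needs columns {sorted(req)}")
        if self.data.index.has_duplicates:
            raise LongselError("duplicate species in trait table")
        if (self.data[["mls_years", "mass_g"]] <= 0).any().any():
            bad = self.data.index[(self.data[["mls_years", "mass_g"]] <= 0).any(axis=1)]
            raise LongselError(f"non-positive trait values for {list(bad)}")
        if self.reference not in self.data.index:
            raise LongselError(f"reference {self.reference!r} not in trait table")
        self.data = self.data.rename_axis("species")

    @classmethod
    def from_dict(
        cls, rows: Mapping[str, tuple[float, float]], reference: str | None = None
    ) -> "TraitTable":
        df = pd.DataFrame.from_dict(
            {sp: {"mls_years": m, "mass_g": g} for sp, (m, g) in rows.items()},
            orient="index",
        )
        if reference is None:
            reference = df["mls_years"].idxmax()
        return cls(df, reference)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def mls(self, sp: str) -> float:
        return float(self.data.at[sp, "mls_years"])

    def mass(self, sp: str) -> float:
        return float(self.data.at[sp, "mass_g"])


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class PhylogeneticTree:
    """A rooted phylogeny over species ids.

    ``kind`` is ``"time"`` for an ultrametric, time-scaled tree (the source
    of the Brownian covariance) or ``"subst"`` for a tree whose branch
    lengths are expected amino-acid substitutions (the source of per-species
    mutation path lengths).  Time-scaled trees are checked for
    ultrametricity at construction.
    """

    tree: dendropy.Tree
    kind: str  # "time" | "subst"
    ultrametric_rtol: float = 1e-6

    def __post_init__(self) -> None:
        if self.kind not in ("time", "subst"):
            raise LongselError(f"unknown tree kind {self.kind!r}")
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            raise LongselError("duplicate tip labels in tree")
        self._depths: dict[str, float] | None = None
        if self.kind == "time":
            depths = self.tip_depths()
            lo, hi = min(depths.values()), max(depths.values())
            if hi > 0 and (hi - lo) / hi > self.ultrametric_rtol:
                raise LongselError(
                    f"tree is not ultrametric: root-to-tip spread {hi - lo:.6g} "
                    f"over depth {hi:.6g}"
                )

    @classmethod
    def from_newick(cls, newick: str, kind: str) -> "PhylogeneticTree":
        t = dendropy.Tree.get(data=newick, schema="newick")
        return cls(t, kind)

    def tip_labels(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    def tip_depths(self) -> dict[str, float]:
        if self._depths is None:
            out = {}
            for leaf in self.tree.leaf_node_iter():
                d = 0.0
                n = leaf
                while n.parent_node is not None:
                    d += n.edge.length or 0.0
                    n = n.parent_node
                out[leaf.taxon.label] = d
            self._depths = out
        return self._depths

    def depth(self) -> float:
        return max(self.tip_depths().values())

    def mrca_depths(self, species: list[str]) -> np.ndarray:
        """Matrix of root-to-MRCA path lengths for each pair (diag = tip depth)."""
        node_depth: dict[int, float] = {}

        def _depth(node) -> float:
            key = id(node)
            if key not in node_depth:
                d = 0.0
                n = node
                while n.parent_node is not None:
                    d += n.edge.length or 0.0
                    n = n.parent_node
                node_depth[key] = d
            return node_depth[key]

        taxa = {t.label: t for t in self.tree.taxon_namespace}
        missing = [s for s in species if s not in taxa]
        if missing:
            raise LongselError(f"species not in tree: {missing}")
        # ancestor sets per tip for MRCA lookup
        leaf_by_label = {l.taxon.label: l for l in self.tree.leaf_node_iter()}
        anc: dict[str, list] = {}
        for s in species:
            chain = []
            n = leaf_by_label[s]
            while n is not None:
                chain.append(n)
                n = n.parent_node
            anc[s] = chain
        k = len(species)
        out = np.zeros((k, k))
        for i, a in enumerate(species):
            out[i, i] = _depth(anc[a][0])
            set_a = {id(n) for n in anc[a]}
            for j in range(i + 1, k):
                mrca = next(n for n in anc[species[j]] if id(n) in set_a)
                out[i, j] = out[j, i] = _depth(mrca)
        return out

    def relabel_tips(self, mapping: Mapping[str, str]) -> "PhylogeneticTree":
        """Return a copy with tip labels renamed per ``mapping`` (old -> new)."""
        t = self.tree.clone(depth=1)
        t.taxon_namespace = dendropy.TaxonNamespace()
        for leaf in t.leaf_node_iter():
            old = leaf.taxon.label
            leaf.taxon = t.taxon_namespace.new_taxon(mapping.get(old, old))
        return PhylogeneticTree(t, self.kind)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Substitution matrix
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionMatrix:
    """A symmetric amino-acid similarity matrix (BLOSUM-style, integer scores).

    Scores over the 20 standard residues drive the scan; any extra columns
    present in the source file (B, Z, X, ``*``) are retained but flagged
    non-standard and never scored.
    """

    name: str
    scores: dict[tuple[str, str], float]
    nonstandard: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for a in STANDARD_AA:
            for b in STANDARD_AA:
                if (a, b) not in self.scores:
                    raise LongselError(f"matrix {self.name}: missing pair ({a},{b})")
                if self.scores[a, b] != self.scores[b, a]:
                    raise LongselError(
                        f"matrix {self.name}: asymmetric entry ({a},{b})"
                    )
        self._row_range: dict[str, tuple[float, float]] = {}
        for a in STANDARD_AA:
            row = [self.scores[a, b] for b in STANDARD_AA]
            self._row_range[a] = (min(row), max(row))

    def score(self, a: str, b: str) -> float:
        if a not in STANDARD_AA or b not in STANDARD_AA:
            raise LongselError(f"non-standard residue in score lookup: {a!r},{b!r}")
        return self.scores[a, b]

    def row_range(self, ref: str) -> tuple[float, float]:
        """(min, max) score attainable against ``ref`` over standard residues."""
        if ref not in STANDARD_AA:
            raise LongselError(f"non-standard reference residue {ref!r}")
        return self._row_range[ref]


# ---------------------------------------------------------------------------
# Per-column records and fits
# ---------------------------------------------------------------------------

@dataclass
class ColumnRecord:
    """One alignment column after masking and classification.

    ``characters`` holds only real residues (no gaps, no masks).  ``ref_pos``
    is the 1-based position in the ungapped reference sequence, or None when
    the reference has a gap in this column.
    """

    alignment_id: str
    column: int  # 0-based
    characters: dict[str, str]
    ref_residue: str | None
    klass: str  # "excluded" | "conserved" | "fit"
    ref_pos: int | None = None

    @property
    def n_chars(self) -> int:
        return len(self.characters)


@dataclass
class ColumnFit:
    """Slopes and p-values from one column's PGLS fit."""

    b_mls: float
    p_mls: float
    b_mass: float
    p_mass: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        for p in (self.p_mls, self.p_mass):
            if not (0.0 <= p <= 1.0 or np.isnan(p)):
                raise LongselError(f"p-value out of [0,1]: {p}")


#: Convention for conserved columns: no divergence to regress, so a flat fit.
CONSERVED_FIT = ColumnFit(b_mls=0.0, p_mls=1.0, b_mass=0.0, p_mass=1.0, n=0,
                          degenerate=True)


@dataclass
class MaskReport:
    """Masked intervals per (alignment, species), 0-based half-open, aligned
    coordinates, sorted and non-overlapping."""

    intervals: dict[tuple[str, str], list[tuple[int, int]]] = field(
        default_factory=dict
    )

    def total_masked(self) -> int:
        return sum(e - s for iv in self.intervals.values() for s, e in iv)


@dataclass
class DomainAnnotation:
    """A named region of the reference sequence, 1-based inclusive coords."""

    protein_id: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise LongselError(
                f"domain {self.name!r}: bad coordinates {self.start}..{self.end}"
            )


@dataclass
class SecondaryStructureTrack:
    """Per-residue 3-class secondary structure (H/E/C) of the reference."""

    protein_id: str
    classes: str  # one of H/E/C per ungapped reference residue

    def __post_init__(self) -> None:
        bad = set(self.classes) - set("HEC")
        if bad:
            raise LongselError(f"unknown secondary-structure classes {bad}")
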