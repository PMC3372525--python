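"""Readers and writers for every external format the pipeline touches.

FASTA alignments are read with Biopython, trees with DendroPy, substitution
matrices with Biopython's NCBI flat-format reader, and the tab-separated
tables (traits, domains, secondary structure, scan results) with pandas.
All readers validate on the way in: ragged alignments, asymmetric matrices
and non-ultrametric time trees are hard errors, never silent coercions.
"""

from __future__ import annotations

import os
import re
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .core import (
    AMBIGUOUS_AA,
    GAP,
    MASK,
    STANDARD_AA,
    AlignmentPanel,
    ColumnFit,
    ColumnRecord,
    DomainAnnotation,
    LongselError,
    MaskReport,
    PhylogeneticTree,
    SecondaryStructureTrack,
    SubstitutionMatrix,
    TraitTable,
)

_ALLOWED = set(STANDARD_AA) | {GAP, MASK}


def _species_id(header: str, id_regex: str | None) -> str:
    if id_regex is None:
        return header.split()[0]
    m = re.search(id_regex, header)
    if m is None:
        raise LongselError(f"header {header!r} does not match id regex {id_regex!r}")
    return m.group(1) if m.groups() else m.group(0)


def _normalize_seq(seq: str, where: str) -> str:
    """Uppercase; ambiguity codes B/Z/U/O masked; anything else illegal."""
    seq = seq.upper()
    if any(c in seq for c in AMBIGUOUS_AA):
        warnings.warn(f"{where}: ambiguity codes masked to '{MASK}'")
        seq = re.sub(f"[{AMBIGUOUS_AA}]", MASK, seq)
    for i, c in enumerate(seq):
        if c not in _ALLOWED:
            raise LongselError(f"{where}: illegal character {c!r} at position {i}")
    return seq


def read_alignment_panel(
    paths: Sequence[str | os.PathLike], id_regex: str | None = None
) -> AlignmentPanel:
    """Read one FASTA alignment per path into a panel.

    The alignment id is the file stem.  The species id is the first
    whitespace-delimited header token unless ``id_regex`` is given, in which
    case its first group (or whole match) is used.
    """
    alignments: dict[str, dict[str, str]] = {}
    for path in paths:
        path = Path(path)
        aln_id = path.stem
        msa: dict[str, str] = {}
        length = None
        for rec in SeqIO.parse(str(path), "fasta"):
            sp = _species_id(rec.description, id_regex)
            if sp in msa:
                raise LongselError(f"{path}: duplicate species {sp!r}")
            seq = _normalize_seq(str(rec.seq), f"{path}:{sp}")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise LongselError(
                    f"{path}: ragged alignment — {sp!r} has length {len(seq)}, "
                    f"expected {length}"
                )
            msa[sp] = seq
        if not msa:
            raise LongselError(f"{path}: no sequences")
        alignments[aln_id] = msa
    return AlignmentPanel(alignments)


def write_alignment_panel(panel: AlignmentPanel, outdir: str | os.PathLike) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for aln_id, msa in panel:
        p = outdir / f"{aln_id}.fasta"
        with open(p, "w") as fh:
            for sp, seq in msa.items():
                fh.write(f">{sp}\n{seq}\n")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------

def read_substitution_matrix(path: str | os.PathLike) -> SubstitutionMatrix:
    """Read an NCBI flat-format matrix ('#' comments, residue header row)."""
    arr = substitution_matrices.read(str(path))
    letters = list(arr.alphabet)
    scores: dict[tuple[str, str], float] = {}
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            if arr[i, j] != arr[j, i]:
                raise LongselError(f"{path}: asymmetric entry ({a},{b})")
            scores[a, b] = float(arr[i, j])
    missing = [a for a in STANDARD_AA if a not in letters]
    if missing:
        raise LongselError(f"{path}: missing residue rows {missing}")
    nonstandard = frozenset(l for l in letters if l not in STANDARD_AA)
    return SubstitutionMatrix(
        name=Path(path).stem, scores=scores, nonstandard=nonstandard
    )


def load_builtin_matrix(name: str = "BLOSUM80") -> SubstitutionMatrix:
    """Load a packaged matrix (BLOSUM80 or BLOSUM62, half-bit units)."""
    ref = resources.files("longsel.data") / f"{name}.txt"
    with resources.as_file(ref) as path:
        return read_substitution_matrix(path)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path: str | os.PathLike, kind: str) -> PhylogeneticTree:
    """Read a rooted newick tree; ``kind`` is 'time' or 'subst'."""
    with open(path) as fh:
        newick = fh.read()
    return PhylogeneticTree.from_newick(newick, kind)


def write_tree(tree: PhylogeneticTree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# Tab-separated tables
# ---------------------------------------------------------------------------

def read_traits(
    path: str | os.PathLike, reference: str | None = None
) -> TraitTable:
    """Read a TSV with columns species, mls_years, mass_g.

    The reference species defaults to the longest-lived one.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    for col in ("species", "mls_years", "mass_g"):
        if col not in df.columns:
            raise LongselError(f"{path}: missing column {col!r}")
    df = df.set_index("species")
    if reference is None:
        reference = df["mls_years"].idxmax()
    return TraitTable(df[["mls_years", "mass_g"]], reference)


def write_traits(traits: TraitTable, path: str | os.PathLike) -> None:
    df = traits.data.reset_index(names="species")
    df.to_csv(path, sep="\t", index=False)


def read_domains(path: str | os.PathLike) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "name": str})
    for col in ("protein", "start", "end", "name"):
        if col not in df.columns:
            raise LongselError(f"{path}: missing column {col!r}")
    return [
        DomainAnnotation(r.protein, int(r.start), int(r.end), r.name)
        for r in df.itertuples()
    ]


def read_secondary_structure(path: str | os.PathLike) -> dict[str, SecondaryStructureTrack]:
    """TSV with columns protein, position (1-based), class (H/E/C)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "class": str})
    for col in ("protein", "position", "class"):
        if col not in df.columns:
            raise LongselError(f"{path}: missing column {col!r}")
    tracks = {}
    for prot, grp in df.groupby("protein"):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise LongselError(f"{path}: positions for {prot!r} not 1..n")
        tracks[prot] = SecondaryStructureTrack(prot, "".join(grp["class"]))
    return tracks


# ---------------------------------------------------------------------------
# Scan results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "alignment",
    "column",  # 1-based in the file
    "ref_pos",
    "ref_residue",
    "class",
    "n",
    "b_mls",
    "p_mls",
    "b_mass",
    "p_mass",
]


def scan_frame(records: Iterable[ColumnRecord],
               fits: dict[tuple[str, int], ColumnFit]) -> pd.DataFrame:
    """Tabulate selected columns (fit + conserved) as a DataFrame."""
    rows = []
    for rec in records:
        if rec.klass == "excluded":
            continue
        fit = fits[(rec.alignment_id, rec.column)]
        rows.append(
            {
                "alignment": rec.alignment_id,
                "column": rec.column + 1,
                "ref_pos": rec.ref_pos,
                "ref_residue": rec.ref_residue,
                "class": rec.klass,
                "n": fit.n,
                "b_mls": fit.b_mls,
                "p_mls": fit.p_mls,
                "b_mass": fit.b_mass,
                "p_mass": fit.p_mass,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df.sort_values(["alignment", "column"], kind="stable").reset_index(drop=True)


def write_scan_results(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the selected-column table; floats at full precision so a
    round-trip read reproduces every value."""
    out = df.copy()
    for col in ("b_mls", "p_mls", "b_mass", "p_mass"):
        out[col] = out[col].map(lambda v: repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


def read_scan_results(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"alignment": str, "ref_residue": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise LongselError(f"{path}: missing result columns {missing}")
    return df


def write_mask_report(report: MaskReport, path: str | os.PathLike) -> None:
    rows = [
        {"alignment": a, "species": s, "start": start, "end": end}
        for (a, s), ivs in sorted(report.intervals.items())
        for start, end in ivs
    ]
    pd.DataFrame(rows, columns=["alignment", "species", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )
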