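"""Masking of divergent subsequences and column classification.

Low-coverage genome assemblies leave mistranslated or misassembled
stretches in ortholog alignments.  Before any fitting, each sequence is
screened with a sliding-window rule: a stretch is masked (replaced by 'X')
when every 10-residue window inside it contains at least four residues
that agree with fewer than 30% of the other residues in their column.

Columns are then partitioned into three classes:

* ``excluded`` — fewer than ``min_chars`` real residues, or missing the
  reference or a required anchor species;
* ``fit``       — selected, with at least ``min_diff`` non-reference
  residues differing from the reference residue (enough divergence to
  regress);
* ``conserved`` — selected but not fit.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

from .core import (
    GAP,
    MASK,
    AlignmentPanel,
    ColumnRecord,
    LongselError,
    MaskReport,
    TraitTable,
    is_residue,
)


def residue_column_identity(msa: dict[str, str], species: str, column: int) -> float:
    """Fraction of other species whose residue at ``column`` matches this one.

    Only real residues count; returns 0 when no other species has a residue.
    """
    c = msa[species][column]
    if not is_residue(c):
        raise LongselError(
            f"species {species!r} has no real residue at column {column}"
        )
    others = [s[column] for sp, s in msa.items()
              if sp != species and is_residue(s[column])]
    if not others:
        return 0.0
    return sum(o == c for o in others) / len(others)


def _column_identities(msa: dict[str, str]) -> dict[str, np.ndarray]:
    """Vectorized residue_column_identity for every (species, column).

    Returns, per species, an array with the identity fraction at each of its
    real-residue columns and NaN elsewhere.
    """
    species = list(msa)
    arr = np.array([list(msa[sp]) for sp in species])  # (n_sp, n_col) of chars
    real = (arr != GAP) & (arr != MASK)
    n_col = arr.shape[1]
    # per column: counts of each residue among real residues
    out = {}
    n_real = real.sum(axis=0)
    match_counts = np.zeros_like(arr, dtype=float)
    # count, for each cell, how many real residues in its column equal it
    for col in range(n_col):
        vals, counts = np.unique(arr[real[:, col], col], return_counts=True)
        lut = dict(zip(vals.tolist(), counts.tolist()))
        for i in range(arr.shape[0]):
            if real[i, col]:
                match_counts[i, col] = lut[arr[i, col]]
    for i, sp in enumerate(species):
        ident = np.full(n_col, np.nan)
        for col in range(n_col):
            if real[i, col]:
                denom = n_real[col] - 1
                ident[col] = (match_counts[i, col] - 1) / denom if denom > 0 else 0.0
        out[sp] = ident
    return out


def mask_divergent_subsequences(
    panel: AlignmentPanel,
    window: int = 10,
    min_divergent: int = 4,
    identity_threshold: float = 0.30,
    min_run: int = 10,
) -> tuple[AlignmentPanel, MaskReport]:
    """Mask divergent stretches of each sequence with 'X'.

    Windows run over each sequence's real residues (gaps are skipped when
    counting the ``window`` residues).  A window qualifies when at least
    ``min_divergent`` of its residues have column identity below
    ``identity_threshold``; the union of residues covered by qualifying
    windows, in maximal runs of at least ``min_run`` residues, is masked.
    Identities are computed on the unmasked input, each sequence
    independently (no cascade).
    """
    report = MaskReport()
    new_alignments: dict[str, dict[str, str]] = {}
    for aln_id, msa in panel:
        length = len(next(iter(msa.values())))
        if length < window:
            warnings.warn(
                f"{aln_id}: alignment shorter than window ({length} < {window}); "
                "nothing masked"
            )
            new_alignments[aln_id] = dict(msa)
            continue
        idents = _column_identities(msa)
        new_msa = {}
        for sp, seq in msa.items():
            positions = [i for i, c in enumerate(seq) if is_residue(c)]
            k = len(positions)
            divergent = np.array(
                [idents[sp][p] < identity_threshold for p in positions], dtype=int
            )
            masked_idx: set[int] = set()
            if k >= window:
                run_sums = np.convolve(divergent, np.ones(window, dtype=int), "valid")
                for i, s in enumerate(run_sums):
                    if s >= min_divergent:
                        masked_idx.update(range(i, i + window))
            # group into runs of consecutive residue indices, trim each run
            # to its outermost divergent residues (windows overhang into the
            # agreeing flanks, which are not part of the bad stretch), then
            # enforce min_run
            intervals: list[tuple[int, int]] = []
            chars = list(seq)
            if masked_idx:
                idx = sorted(masked_idx)
                runs: list[list[int]] = [[idx[0]]]
                for j in idx[1:]:
                    if j == runs[-1][-1] + 1:
                        runs[-1].append(j)
                    else:
                        runs.append([j])
                for run in runs:
                    div_in_run = [j for j in run if divergent[j]]
                    if not div_in_run:
                        continue
                    trimmed = list(range(div_in_run[0], div_in_run[-1] + 1))
                    if len(trimmed) < min_run:
                        continue
                    for j in trimmed:
                        chars[positions[j]] = MASK
                    intervals.append(
                        (positions[trimmed[0]], positions[trimmed[-1]] + 1)
                    )
            if intervals:
                report.intervals[(aln_id, sp)] = intervals
            new_msa[sp] = "".join(chars)
        new_alignments[aln_id] = new_msa
    return AlignmentPanel(new_alignments), report


def default_required_species(traits: TraitTable) -> list[str]:
    """The shortest-lived non-reference species: the anchor that guarantees
    every selected column spans the full lifespan range."""
    ranked = traits.data["mls_years"].drop(traits.reference).sort_values()
    return [ranked.index[0]]


def classify_columns(
    panel: AlignmentPanel,
    traits: TraitTable,
    required_species: Sequence[str] | None = None,
    min_chars: int = 10,
    min_diff: int = 3,
) -> list[ColumnRecord]:
    """Partition every column of every alignment into excluded / conserved / fit.

    A column is *selected* when it has at least ``min_chars`` real residues
    including one for the reference and one for every required species.
    Selected columns with at least ``min_diff`` non-reference residues
    differing from the reference residue are *fit*; the rest *conserved*.
    """
    if required_species is None:
        required_species = default_required_species(traits)
    missing = [s for s in required_species if s not in traits.data.index]
    if missing:
        raise LongselError(f"required species not in trait table: {missing}")
    reference = traits.reference
    records: list[ColumnRecord] = []
    for aln_id, msa in panel:
        length = len(next(iter(msa.values())))
        if reference not in msa:
            warnings.warn(f"{aln_id}: reference {reference!r} absent; all columns excluded")
            for col in range(length):
                chars = {sp: s[col] for sp, s in msa.items() if is_residue(s[col])}
                records.append(ColumnRecord(aln_id, col, chars, None, "excluded"))
            continue
        ref_seq = msa[reference]
        ref_pos = 0  # 1-based ungapped reference coordinate (counts 'X' too)
        for col in range(length):
            if ref_seq[col] != GAP:
                ref_pos += 1
            chars = {sp: s[col] for sp, s in msa.items() if is_residue(s[col])}
            ref_res = chars.get(reference)
            pos = ref_pos if ref_seq[col] != GAP else None
            selected = (
                len(chars) >= min_chars
                and ref_res is not None
                and all(sp in chars for sp in required_species)
            )
            if not selected:
                records.append(
                    ColumnRecord(aln_id, col, chars, ref_res, "excluded", pos)
                )
                continue
            n_diff = sum(
                1 for sp, c in chars.items() if sp != reference and c != ref_res
            )
            klass = "fit" if n_diff >= min_diff else "conserved"
            records.append(ColumnRecord(aln_id, col, chars, ref_res, klass, pos))
    return records
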