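"""Orchestration of the per-column scan and the randomized control.

``run_scan`` applies the pipeline in order — mask, classify, score, fit —
and collects one record per column.  Fit columns carry a PGLS fit;
conserved columns carry the flat convention (b_MLS = 0, p_MLS = 1): with
fewer than three divergent residues there is nothing to regress, and a
fully conserved column is by definition uninformative about lifespan.

``randomize_traits`` builds the empirical null: each non-reference species
swaps its lifespan, mass and tree position with a randomly chosen partner,
while every alignment stays untouched, so exactly the same columns are fit
in the control as in the real scan.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CONSERVED_FIT,
    GAP,
    AlignmentPanel,
    ColumnFit,
    ColumnRecord,
    LongselError,
    PhylogeneticTree,
    SubstitutionMatrix,
    TraitTable,
)
from .pgls import brownian_covariance, column_species, fit_column
from .preprocess import classify_columns, mask_divergent_subsequences
from .scoring import MutationRates, score_column


@dataclass
class ScanConfig:
    """All tunables of the scan, with the study defaults."""

    alpha: float = 0.01
    min_chars: int = 10
    min_diff: int = 3
    lam: float = 1.0
    log_traits: bool = True
    min_fit_species: int = 4
    required_species: tuple[str, ...] | None = None
    mask_window: int = 10
    mask_min_divergent: int = 4
    mask_identity_threshold: float = 0.30
    mask_min_run: int = 10
    apply_mask: bool = True
    matrix_name: str = "BLOSUM80"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise LongselError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass
class ScanResult:
    """Every column's classification plus the fits of selected columns."""

    records: list[ColumnRecord]
    fits: dict[tuple[str, int], ColumnFit]
    ref_lengths: dict[str, int]
    config: ScanConfig
    provenance: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        by_class = {"excluded": 0, "conserved": 0, "fit": 0}
        for r in self.records:
            by_class[r.klass] += 1
        ls, ms = call_positions(self, self.config.alpha)
        return {
            "columns": len(self.records),
            "selected": by_class["conserved"] + by_class["fit"],
            "fit": by_class["fit"],
            "conserved": by_class["conserved"],
            "excluded": by_class["excluded"],
            "longevity_selected": len(ls),
            "mass_selected": len(ms),
        }

    def to_frame(self) -> pd.DataFrame:
        from .io import scan_frame

        return scan_frame(self.records, self.fits)

    def fit_records(self) -> list[tuple[ColumnRecord, ColumnFit]]:
        return [
            (r, self.fits[(r.alignment_id, r.column)])
            for r in self.records
            if r.klass == "fit"
        ]


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_scan(
    panel: AlignmentPanel,
    traits: TraitTable,
    time_tree: PhylogeneticTree,
    matrix: SubstitutionMatrix,
    rates: MutationRates,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Mask, classify, score and fit every column of the panel."""
    config = config or ScanConfig()
    if config.apply_mask:
        masked, _report = mask_divergent_subsequences(
            panel,
            window=config.mask_window,
            min_divergent=config.mask_min_divergent,
            identity_threshold=config.mask_identity_threshold,
            min_run=config.mask_min_run,
        )
    else:
        masked = panel
    required = list(config.required_species) if config.required_species else None
    records = classify_columns(
        masked,
        traits,
        required_species=required,
        min_chars=config.min_chars,
        min_diff=config.min_diff,
    )
    ref_lengths = {
        aln_id: sum(1 for c in msa[traits.reference] if c != GAP)
        for aln_id, msa in masked
        if traits.reference in msa
    }
    fits: dict[tuple[str, int], ColumnFit] = {}
    cov_cache: dict[tuple[str, ...], object] = {}
    for rec in records:
        key = (rec.alignment_id, rec.column)
        if rec.klass == "conserved":
            fits[key] = dataclasses.replace(CONSERVED_FIT, n=rec.n_chars - 1)
        elif rec.klass == "fit":
            scored = score_column(rec, matrix, rates, traits.reference)
            species = column_species(scored, traits, time_tree)
            cov = None
            if len(species) >= config.min_fit_species:
                ck = tuple(species)
                cov = cov_cache.get(ck)
                if cov is None:
                    cov = brownian_covariance(time_tree, species, config.lam)
                    cov_cache[ck] = cov
            fits[key] = fit_column(
                scored,
                traits,
                time_tree,
                lam=config.lam,
                log_traits=config.log_traits,
                min_species=config.min_fit_species,
                cov=cov,
            )
    provenance = {
        "config": _digest(json.dumps(dataclasses.asdict(config), sort_keys=True)),
        "matrix": matrix.name,
        "tree": _digest(time_tree.as_newick()),
        "reference": traits.reference,
    }
    return ScanResult(records, fits, ref_lengths, config, provenance)


def call_positions(
    result: ScanResult, alpha: float = 0.01
) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """Longevity-selected and mass-selected position sets.

    A position is longevity-selected when b_MLS > 0 and p_MLS < alpha,
    mass-selected when b_mass > 0 and p_mass < alpha.
    """
    longevity, mass = set(), set()
    for rec, fit in result.fit_records():
        key = (rec.alignment_id, rec.column)
        if fit.b_mls > 0 and fit.p_mls < alpha:
            longevity.add(key)
        if fit.b_mass > 0 and fit.p_mass < alpha:
            mass.add(key)
    return longevity, mass


def randomize_traits(
    traits: TraitTable, seed: int
) -> tuple[TraitTable, dict[str, str]]:
    """Permute (MLS, mass, tip label) jointly among non-reference species.

    Returns the permuted trait table and a tip-relabel map (old label ->
    new label) to apply to the time tree with ``tree.relabel_tips``.  After
    both are applied, species A carries the traits *and* the tree position
    of its randomly chosen partner pi(A); the reference is a fixed point.
    Fixed points elsewhere are allowed (a uniformly random permutation).
    """
    others = [sp for sp in traits.species if sp != traits.reference]
    if len(others) < 2:
        raise LongselError("need at least two non-reference species to randomize")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(others))
    pi = {a: others[perm[i]] for i, a in enumerate(others)}  # A takes pi(A)'s slot
    new = traits.data.copy()
    for a, b in pi.items():
        new.loc[a, ["mls_years", "mass_g"]] = traits.data.loc[
            b, ["mls_years", "mass_g"]
        ]
    # tip formerly labelled pi(A) is now occupied by A
    relabel = {b: a for a, b in pi.items()}
    return TraitTable(new, traits.reference), relabel


def ref_to_column(msa: dict[str, str], reference: str) -> dict[int, int]:
    """Map 1-based ungapped reference positions to 0-based column indices.

    Masked ('X') reference residues still occupy a sequence position, so
    they are counted; only gaps are skipped.
    """
    if reference not in msa:
        raise LongselError(f"reference {reference!r} not in alignment")
    out = {}
    pos = 0
    for col, c in enumerate(msa[reference]):
        if c != GAP:
            pos += 1
            out[pos] = col
    return out
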