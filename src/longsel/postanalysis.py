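"""Downstream summaries of a scan.

These are the proteome-level diagnostics of the method: the density of
p_MLS values among positively sloped fit columns (flat when nothing but
phylogeny drives the scores, top-heavy when longevity-coupled positions
exist), Pearson chi-square tests of secondary-structure composition,
aggregation of hits into annotated domains, rolling-window medians of
p_MLS along a protein, and a region-level PGLS of residue counts (e.g.
cysteines in a cysteine-rich tail) on lifespan and mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    AlignmentPanel,
    DomainAnnotation,
    LongselError,
    PhylogeneticTree,
    SecondaryStructureTrack,
    TraitTable,
    is_residue,
)
from .pgls import GlsFit, brownian_covariance, gls_fit
from .scan import ScanResult, call_positions


# ---------------------------------------------------------------------------
# p-value density
# ---------------------------------------------------------------------------

def pvalue_histogram(
    result: ScanResult, bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Density histogram over [0, 1] of p_MLS for fit columns with b_MLS > 0."""
    p = np.array(
        [f.p_mls for _, f in result.fit_records() if f.b_mls > 0], dtype=float
    )
    if p.size == 0:
        raise LongselError("no fit columns with positive MLS slope")
    dens, edges = np.histogram(p, bins=bins, range=(0.0, 1.0), density=True)
    return dens, edges


# ---------------------------------------------------------------------------
# Secondary-structure composition
# ---------------------------------------------------------------------------

@dataclass
class CompositionTable:
    """Counts of alpha-helix / beta-strand / random-coil positions."""

    helix: int
    strand: int
    coil: int

    def __post_init__(self) -> None:
        if min(self.helix, self.strand, self.coil) < 0:
            raise LongselError("negative composition count")

    @property
    def total(self) -> int:
        return self.helix + self.strand + self.coil

    def as_array(self) -> np.ndarray:
        return np.array([self.helix, self.strand, self.coil], dtype=float)

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise LongselError("empty composition table")
        return self.as_array() / self.total


def composition_chisq_gof(
    observed: CompositionTable,
    reference: CompositionTable,
    method: str = "gof",
) -> tuple[float, int, float]:
    """Pearson chi-square of a composition against a reference.

    ``gof`` (default) tests the observed counts against expected counts
    formed from the reference class proportions at the observed total
    (df = 2, n = observed.total).  ``contingency`` instead tests the 2x3
    table of both count rows for independence (also df = 2).
    """
    if observed.total == 0:
        raise LongselError("observed composition is empty")
    if method == "gof":
        props = reference.proportions()
        if np.any(props == 0):
            raise LongselError("reference class with zero count: expected cell is 0")
        expected = observed.total * props
        stat, p = stats.chisquare(observed.as_array(), f_exp=expected)
        return float(stat), 2, float(p)
    if method == "contingency":
        table = np.vstack([observed.as_array(), reference.as_array()])
        stat, p, df, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), int(df), float(p)
    raise LongselError(f"unknown chi-square method {method!r}")


def composition_of_positions(
    positions: set[tuple[str, int]],
    result: ScanResult,
    tracks: dict[str, "SecondaryStructureTrack"],
) -> CompositionTable:
    """Tally H/E/C classes of a position set via reference coordinates."""
    by_key = {(r.alignment_id, r.column): r for r in result.records}
    counts = {"H": 0, "E": 0, "C": 0}
    for key in positions:
        rec = by_key[key]
        if rec.ref_pos is None:
            continue
        track = tracks.get(rec.alignment_id)
        if track is None:
            continue
        counts[track.classes[rec.ref_pos - 1]] += 1
    return CompositionTable(helix=counts["H"], strand=counts["E"], coil=counts["C"])


# ---------------------------------------------------------------------------
# Domain aggregation
# ---------------------------------------------------------------------------

@dataclass
class DomainSummary:
    """A domain with its longevity-selected positions."""

    name: str
    protein_id: str
    start: int
    end: int
    n_positions: int
    positions: list[int]  # 1-based reference coordinates


def _aggregate_domains(
    hits_by_protein: dict[str, list[int]],
    domains: list[DomainAnnotation],
    min_positions: int,
    ref_lengths: dict[str, int] | None,
) -> list[DomainSummary]:
    out = []
    for dom in domains:
        if ref_lengths is not None:
            ref_len = ref_lengths.get(dom.protein_id)
            if ref_len is None:
                raise LongselError(
                    f"domain {dom.name!r}: unknown protein {dom.protein_id!r}"
                )
            if dom.end > ref_len:
                raise LongselError(
                    f"domain {dom.name!r} ends at {dom.end}, beyond reference "
                    f"length {ref_len}"
                )
        pos = sorted(
            p for p in hits_by_protein.get(dom.protein_id, [])
            if dom.start <= p <= dom.end
        )
        if len(pos) >= min_positions:
            out.append(
                DomainSummary(dom.name, dom.protein_id, dom.start, dom.end,
                              len(pos), pos)
            )
    return sorted(out, key=lambda d: (-d.n_positions, d.name))


def domain_summary(
    result: ScanResult,
    domains: list[DomainAnnotation],
    min_positions: int = 2,
    alpha: float | None = None,
) -> list[DomainSummary]:
    """Domains holding at least ``min_positions`` longevity-selected
    positions, sorted by count descending then name."""
    alpha = result.config.alpha if alpha is None else alpha
    longevity, _ = call_positions(result, alpha)
    by_key = {(r.alignment_id, r.column): r for r in result.records}
    hits_by_protein: dict[str, list[int]] = {}
    for key in longevity:
        rec = by_key[key]
        if rec.ref_pos is not None:
            hits_by_protein.setdefault(rec.alignment_id, []).append(rec.ref_pos)
    return _aggregate_domains(hits_by_protein, domains, min_positions,
                              result.ref_lengths)


def domain_summary_frame(
    df,
    domains: list[DomainAnnotation],
    min_positions: int = 2,
    alpha: float = 0.01,
) -> list[DomainSummary]:
    """Like :func:`domain_summary` but from a written results table (no
    reference-length validation, which the table does not carry)."""
    sig = df[(df["class"] == "fit") & (df.b_mls > 0) & (df.p_mls < alpha)]
    hits_by_protein = {
        aln: [int(p) for p in grp.ref_pos.dropna()]
        for aln, grp in sig.groupby("alignment")
    }
    return _aggregate_domains(hits_by_protein, domains, min_positions, None)


# ---------------------------------------------------------------------------
# Rolling-window median p
# ---------------------------------------------------------------------------

def _window_medians(
    cols: list[int], pvals: dict[int, float], window: int
) -> list[tuple[int, float]]:
    out: list[tuple[int, float]] = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if len(run) < window:
            return
        for i in range(len(run) - window + 1):
            w = run[i : i + window]
            out.append((w[0], float(np.median([pvals[c] for c in w]))))

    for c in cols:
        if run and c != run[-1] + 1:
            flush(run)
            run = []
        run.append(c)
    flush(run)
    return out


def rolling_median_p(
    result: ScanResult, alignment_id: str, window: int = 10
) -> list[tuple[int, float]]:
    """Median p_MLS in sliding windows over runs of consecutive selected
    positions.

    Only contiguous blocks of at least ``window`` selected positions yield
    windows; an excluded position breaks the run.  Conserved positions
    contribute p = 1.  Returns (0-based start column, median) pairs.
    """
    cols = sorted(
        r.column for r in result.records
        if r.alignment_id == alignment_id and r.klass != "excluded"
    )
    pvals = {c: result.fits[(alignment_id, c)].p_mls for c in cols}
    return _window_medians(cols, pvals, window)


def rolling_median_p_frame(
    df, alignment_id: str, window: int = 10
) -> list[tuple[int, float]]:
    """Like :func:`rolling_median_p` but from a written results table
    (which stores 1-based columns; output stays 0-based)."""
    sub = df[df.alignment == alignment_id]
    cols = sorted(int(c) - 1 for c in sub.column)
    pvals = {int(r.column) - 1: float(r.p_mls) for r in sub.itertuples()}
    return _window_medians(cols, pvals, window)


# ---------------------------------------------------------------------------
# Region residue-count PGLS
# ---------------------------------------------------------------------------

def region_residue_count_pgls(
    panel: AlignmentPanel,
    alignment_id: str,
    columns: tuple[int, int],
    residue: str,
    traits: TraitTable,
    tree: PhylogeneticTree,
    lam: float = 1.0,
) -> GlsFit:
    """PGLS of per-species counts of ``residue`` over a column range
    (0-based half-open) on log10 lifespan and log10 mass.

    Unlike the column scan, the response here is a plain count, not a
    similarity to the reference, so the reference species is included.
    """
    msa = panel.alignments[alignment_id]
    start, end = columns
    if not (0 <= start < end <= panel.length(alignment_id)):
        raise LongselError(f"bad column range {columns}")
    tips = set(tree.tip_labels())
    species = sorted(
        sp for sp in msa if sp in traits.data.index and sp in tips
    )
    if len(species) < 4:
        raise LongselError(f"need >= 4 species with traits and tips, got {len(species)}")
    y = np.array(
        [msa[sp][start:end].count(residue) for sp in species], dtype=float
    )
    X = np.column_stack(
        [
            np.log10([traits.mls(sp) for sp in species]),
            np.log10([traits.mass(sp) for sp in species]),
        ]
    )
    cov = brownian_covariance(tree, species, lam)
    return gls_fit(y, X, cov)
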