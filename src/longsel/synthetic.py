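"""Synthetic fixtures with the statistical structure the scan assumes.

Real inputs are ortholog alignments over a few dozen mammals with
lifespans spanning 3–90 years.  The generator emulates exactly the three
ingredients the method rests on: an ultrametric species tree (coalescent
topology), lifespan and mass evolving as correlated Brownian motion in
log10 space, and alignment columns of three kinds —

* ``conserved``: one residue across all species;
* ``null``: the similarity of each species' residue to the reference
  residue is Brownian noise on the tree around a flat target (this is the
  error model PGLS assumes, realized in residue space);
* ``planted``: the target additionally climbs with log10 lifespan at
  ``effect_size`` score units per log10 year — the pattern the scan is
  built to detect.

Residues are drawn by a Gaussian-kernel softmax over BLOSUM similarity to
the reference residue, centred on the per-species target score, so the
realized scores are the targets quantized to the attainable score set.
Truth labels ship with every panel.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core import (
    STANDARD_AA,
    AlignmentPanel,
    LongselError,
    PhylogeneticTree,
    SubstitutionMatrix,
    TraitTable,
)


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic data set.

    Trait defaults mimic the mammalian panel the method was designed for:
    root lifespan 10 y with tip log10-MLS variance 0.12 (tips span roughly
    3–90 y), root mass ~3 kg with wide variance, and a 0.5 correlation
    between log lifespan and log mass.  ``effect_size`` is in score units
    per log10 year; ``noise_sd`` is the tip-level standard deviation of the
    score noise in score units.
    """

    n_species: int = 33
    depth: float = 1.0
    pendant_frac: float = 0.2
    root_log10_mls: float = 1.0
    root_log10_mass: float = 3.5
    bm_var_mls: float = 0.12
    bm_var_mass: float = 2.25
    trait_corr: float = 0.5
    n_conserved: int = 240
    n_null: int = 60
    n_planted: int = 20
    effect_size: float = 3.0
    noise_sd: float = 1.5
    score_kernel: float = 0.3
    rate_multipliers: dict[str, float] | None = None
    subst_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_conserved, self.n_null, self.n_planted) < 0:
            raise LongselError("column counts must be non-negative")
        if not np.isfinite(self.effect_size):
            raise LongselError("effect size must be finite")


def simulate_tree(
    n_species: int, depth: float, seed: int, pendant_frac: float = 0.2
) -> PhylogeneticTree:
    """A random coalescent (hence ultrametric) topology, rescaled so every
    tip sits at ``depth``.

    ``pendant_frac`` of the depth is added to every terminal branch (the
    coalescent part is squeezed into the remaining fraction, keeping the
    tree ultrametric).  Mammal-scale ortholog panels sample species spread
    across orders, so terminal branches are typically long relative to
    total depth — a pure Kingman tree's near-zero cherry branches are not
    representative of them.
    """
    if n_species < 3:
        raise LongselError("need at least 3 species")
    if not 0.0 <= pendant_frac < 1.0:
        raise LongselError("pendant_frac must be in [0, 1)")
    tns = dendropy.TaxonNamespace(
        [f"sp{i+1:02d}" for i in range(n_species)]
    )
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=1.0, rng=random.Random(seed)
    )
    # rescale the coalescent part, then extend every pendant edge
    t = PhylogeneticTree(tree, "time")
    factor = depth * (1.0 - pendant_frac) / t.depth()
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= factor
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + pendant_frac * depth
    return PhylogeneticTree(tree, "time")


def _branch_rate(spec: SimulationSpec, edge) -> float:
    """Pendant branches may carry a species-specific rate multiplier."""
    if spec.rate_multipliers and edge.head_node.is_leaf():
        return spec.rate_multipliers.get(edge.head_node.taxon.label, 1.0)
    return 1.0


def simulate_traits(
    tree: PhylogeneticTree, spec: SimulationSpec, rng: np.random.Generator
) -> TraitTable:
    """Correlated Brownian motion of (log10 MLS, log10 mass) down the tree.

    The longest-lived tip becomes the reference species.
    """
    c = spec.trait_corr * np.sqrt(spec.bm_var_mls * spec.bm_var_mass)
    sigma = np.array([[spec.bm_var_mls, c], [c, spec.bm_var_mass]])
    root_val = np.array([spec.root_log10_mls, spec.root_log10_mass])
    values: dict[int, np.ndarray] = {id(tree.tree.seed_node): root_val}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        blen = node.edge.length or 0.0
        step = (
            rng.multivariate_normal(np.zeros(2), sigma * blen)
            if blen > 0
            else np.zeros(2)
        )
        values[id(node)] = values[id(node.parent_node)] + step
    rows = {}
    for leaf in tree.tree.leaf_node_iter():
        x = values[id(leaf)]
        rows[leaf.taxon.label] = (10.0 ** x[0], 10.0 ** x[1])
    return TraitTable.from_dict(rows)


def _simulate_bm_noise(
    tree: PhylogeneticTree, spec: SimulationSpec, rng: np.random.Generator,
    n_columns: int,
) -> dict[str, np.ndarray]:
    """Brownian score noise per species for many columns at once; tip-level
    variance is noise_sd**2 (rate multipliers scale pendant branches)."""
    per_time = spec.noise_sd**2 / spec.depth
    values: dict[int, np.ndarray] = {
        id(tree.tree.seed_node): np.zeros(n_columns)
    }
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        blen = (node.edge.length or 0.0) * _branch_rate(spec, node.edge)
        step = rng.normal(0.0, np.sqrt(per_time * blen), size=n_columns)
        values[id(node)] = values[id(node.parent_node)] + step
    return {
        l.taxon.label: values[id(l)] for l in tree.tree.leaf_node_iter()
    }


def _interleaved_classes(spec: SimulationSpec, rng: np.random.Generator) -> list[str]:
    """Spread non-conserved columns as evenly as possible among conserved
    ones, so divergent columns stay too sparse to trip the masking rule."""
    divergent = ["null"] * spec.n_null + ["planted"] * spec.n_planted
    rng.shuffle(divergent)
    total = spec.n_conserved + len(divergent)
    if not divergent:
        return ["conserved"] * total
    slots = np.linspace(0, total - 1, num=len(divergent)).round().astype(int)
    classes = ["conserved"] * total
    for s, cls in zip(slots, divergent):
        classes[s] = cls
    return classes


def simulate_panel(
    tree: PhylogeneticTree,
    traits: TraitTable,
    spec: SimulationSpec,
    matrix: SubstitutionMatrix,
    rng: np.random.Generator | None = None,
) -> tuple[AlignmentPanel, list[str]]:
    """One gapless alignment plus per-column truth labels.

    The reference species always carries the column's reference residue;
    other species' residues realize the target-score model described in
    the module docstring.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    species = sorted(tree.tip_labels())
    ref = traits.reference
    classes = _interleaved_classes(spec, rng)
    n_total = len(classes)
    n_div = sum(c != "conserved" for c in classes)
    noise = _simulate_bm_noise(tree, spec, rng, n_div) if n_div else {}
    log_mls = {sp: np.log10(traits.mls(sp)) for sp in species}
    mean_log_mls = float(np.mean(list(log_mls.values())))
    aa = np.array(list(STANDARD_AA))

    columns: dict[str, list[str]] = {sp: [] for sp in species}
    div_idx = 0
    for cls in classes:
        r = str(rng.choice(aa))
        if cls == "conserved":
            for sp in species:
                columns[sp].append(r)
            continue
        # centre the target among the off-diagonal scores: a divergent
        # column's residues sit below the self-score, and the self-score is
        # typically far above the rest of the row
        off = [matrix.score(a, r) for a in STANDARD_AA if a != r]
        base = 0.5 * (min(off) + max(off))
        row = np.array([matrix.score(a, r) for a in STANDARD_AA])
        effect = spec.effect_size if cls == "planted" else 0.0
        for sp in species:
            if sp == ref:
                columns[sp].append(r)
                continue
            target = (
                base
                + effect * (log_mls[sp] - mean_log_mls)
                + noise[sp][div_idx]
            )
            logw = -((row - target) ** 2) / (2.0 * spec.score_kernel**2)
            w = np.exp(logw - logw.max())
            columns[sp].append(str(rng.choice(aa, p=w / w.sum())))
        div_idx += 1
    panel = AlignmentPanel(
        {"synthetic": {sp: "".join(columns[sp]) for sp in species}}
    )
    return panel, classes


def substitution_tree(
    time_tree: PhylogeneticTree, spec: SimulationSpec
) -> PhylogeneticTree:
    """The generator's true substitution-scaled tree: the time tree scaled
    by ``subst_rate`` with pendant branches times the rate multipliers."""
    t = time_tree.tree.clone(depth=1)
    for e in t.preorder_edge_iter():
        if e.length is not None:
            e.length *= spec.subst_rate * _branch_rate(spec, e)
    return PhylogeneticTree(t, "subst")


def simulate_all(
    spec: SimulationSpec, matrix: SubstitutionMatrix
) -> tuple[PhylogeneticTree, TraitTable, AlignmentPanel, list[str]]:
    """Tree, traits, panel and truth labels from one seed."""
    tree = simulate_tree(spec.n_species, spec.depth, spec.seed, spec.pendant_frac)
    rng = np.random.default_rng(spec.seed + 1)
    traits = simulate_traits(tree, spec, rng)
    panel, labels = simulate_panel(tree, traits, spec, matrix, rng)
    return tree, traits, panel, labels
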