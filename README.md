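# longsel

Scan protein ortholog alignments for **longevity-selected positions** —
alignment columns conserved in long-lived but not short-lived mammals.

Comparative gerontology predicts that proteins important for long lifespan
accumulate fewer damaging substitutions in long-lived lineages. `longsel`
turns that prediction into a per-column regression scan: for each column
of each ortholog alignment, it asks whether the biochemical similarity of
every species' residue to the residue of a long-lived reference species
(human, in the motivating data) *increases* with that species' maximum
lifespan (MLS), after accounting for body mass, species-specific mutation
rate, and shared phylogeny.

## The model

For a *fit* column (one with enough divergence to regress), the response
for non-reference species *s* is the mutation-rate-corrected BLOSUM80
similarity to the reference residue *r*:

```
B80mut(s) = clamp( B80(a_s, r) + log10(m_s / m_ref),  min B80(., r), max B80(., r) )
```

where `a_s` is species *s*'s residue and `m_s` its root-to-tip path length
on a substitution-scaled tree (fast lineages get credit back, slow ones
are penalized). The per-column model is a phylogenetic generalized least
squares (PGLS) regression under Brownian motion on the time-scaled
phylogeny, with Pagel's λ fixed at 1:

```
B80mut ~ intercept + b_MLS * log10(MLS) + b_mass * log10(mass),   Cov[ε] = σ² V
```

with `V_ij` the root-to-MRCA path length of species *i* and *j*. A column
is **longevity-selected** when `b_MLS > 0` and `p_MLS < 0.01`; mass-selected
analogously. Columns with fewer than three residues differing from the
reference are *conserved* and assigned `(b_MLS, p_MLS) = (0, 1)`.
An empirical null comes from a **randomized control**: each non-reference
species swaps lifespan, mass and tree position with a random partner while
alignments stay fixed, so exactly the same columns are refit.

Before any fitting, divergent stretches (mistranslations, wrong isoforms,
assembly errors) are masked by a sliding-window rule, and columns are
selected only if they carry at least 10 residues including the reference
and a short-lived anchor species.

## Worked example

Everything runs from one CLI. Simulate a mammal-like panel (33 species,
coalescent tree, correlated Brownian log-lifespan/log-mass, 240 conserved +
60 null + 20 lifespan-coupled columns), scan it, and run the control:

```
$ longsel simulate --seed 7 --out-dir demo
$ longsel scan -a demo/synthetic.fasta --traits demo/traits.tsv \
    --tree demo/time_tree.nwk --subst-tree demo/subst_tree.nwk \
    --out demo/results.tsv
{"columns": 320, "selected": 320, "fit": 80, "conserved": 240,
 "excluded": 0, "longevity_selected": 15, "mass_selected": 0}
$ longsel control -a demo/synthetic.fasta --traits demo/traits.tsv \
    --tree demo/time_tree.nwk --subst-tree demo/subst_tree.nwk \
    --seed 1 --out demo/control.tsv
{"columns": 320, "selected": 320, "fit": 80, "conserved": 240,
 "excluded": 0, "longevity_selected": 1, "mass_selected": 0}
```

The real scan calls 15 longevity-selected positions — all of them among
the 20 columns the generator actually coupled to lifespan (`demo/truth.tsv`)
— while the trait-swapped control calls 1, consistent with the 1% false
positive rate the `p < 0.01` threshold implies. `demo/results.tsv` holds
one row per selected column:

```
alignment  column  ref_pos  ref_residue  class      n   b_mls   p_mls   ...
synthetic  1       1        Y            fit        32  0.583   0.748
synthetic  2       2        E            conserved  32  0.0     1.0
```

Downstream summaries: `longsel report` (p-value density histogram,
secondary-structure composition χ²), `longsel domains` (domains with ≥ 2
longevity-selected positions), `longsel window` (rolling median `p_MLS`
over runs of selected positions), `longsel region-count` (PGLS of
per-species residue counts in a region, e.g. cysteines in a C-terminal
tail, on log10 MLS and mass). `longsel mask`, `classify`, and `rates`
expose the pipeline stages individually. The same functionality is
available as a library (`import longsel`).

## Layout

- `src/longsel/io.py` — FASTA/newick/NCBI-matrix/TSV readers and writers
- `src/longsel/preprocess.py` — divergence masking, column classification
- `src/longsel/scoring.py` — mutation rates, substitution-tree estimation,
  corrected BLOSUM scores
- `src/longsel/pgls.py` — Brownian covariance and GLS engine
- `src/longsel/scan.py` — scan orchestration, significance calls,
  randomized control
- `src/longsel/postanalysis.py` — histograms, composition χ², domain and
  window summaries, region residue-count PGLS
- `src/longsel/synthetic.py` — synthetic tree/trait/alignment generator
- `src/longsel/cli.py` — the `longsel` command

See `docs/methods.md` for modelling choices, defaults, and limitations.
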