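# paleoenrich

Ancestral protein sequence reconstruction and structural
substitution-enrichment analysis on phylogenies.

`paleoenrich` is for molecular evolutionists who want to ask *where on a
protein structure, and when in a protein family's history, did amino-acid
substitutions concentrate?* It was built around the analysis of an ancient
carbon-fixation enzyme family (Rubisco and Rubisco-like proteins), whose
catalytic dimer carries oxygen-sensitive interfaces and an active-site
barrel, but every stage is generic: any gapped protein alignment, rooted
tree, and dimer coordinates will do.

## What it computes

**1. Ancestral reconstruction.** On a fixed rooted topology, under an
empirical substitution model with discrete-gamma rate heterogeneity
(WAG+Γ₄ by default), branch lengths are fitted by maximum likelihood and
each internal node receives a posterior matrix *p*, where *p(i, j)* is the
probability of amino acid *i* at site *j* (the marginal, empirical-Bayes
reconstruction). The ML ancestral sequence takes the argmax per site.
Insertion/deletion characters are reconstructed separately by Fitch
parsimony, one column at a time; a site reconstructed absent emits a gap.
Diagnostics include per-node posterior binning (10% bins), posterior-sampled
alternate ancestors, AIC model comparison, and approximate likelihood-ratio
(aLR) branch support via nearest-neighbour interchanges.

**2. Region annotation.** Nine regions of the catalytic dimer are derived
from coordinates: interfaces by the strict rule *any non-hydrogen atom
within < 5 Å of the opposite side* (measured against reference assemblies
for the cross-form interfaces after Kabsch superposition), and subdomains
(barrel strands, loop 6, N-/C-termini, near-barrel neighbourhood) by
nearest-Cα transfer from a reference structure. Regions are expressed as
alignment columns.

**3. Enrichment scan.** For each phylogenetic window (path between two
named ancestors, resolved as MRCAs) the ML sequences at the endpoints are
compared and each site classified into

|              | in region | out of region |
|--------------|-----------|---------------|
| substituted  | a         | c             |
| conserved    | b         | d             |

Fisher's exact test gives a p-value per (region, window); a cell is flagged
significant when its odds ratio `(a·d)/(b·c)` exceeds **1.5** and
**p < .05** (both strict). Sites gapped at either endpoint are excluded
(policy configurable).

The library follows a model/results idiom:
`AncestralReconstructionModel(alignment, tree, "WAG").fit()` returns an
`AncestralReconstructionResults` carrying the fitted tree, log-likelihood,
posteriors, ML sequences and a `summary()`; `enrichment_scan(...)` turns
results + windows + regions into a tidy table.

## Worked example

Everything below is synthetic and generated on the fly — the package ships
a simulator that produces alignments evolved under WAG+Γ along a known
tree, plus toy dimer coordinate files whose interface contacts are placed
by construction just inside the 5 Å cutoff.

```bash
paleo-enrich simulate --out demo --seed 5        # fixture bundle + config
paleo-enrich run --config demo/run_config.json   # full analysis
```

or equivalently in Python:

```python
from paleoenrich import SimulationConfig, gen_fixture_bundle, RunConfig, run_pipeline

gen_fixture_bundle(SimulationConfig(n_leaves=8, seq_length=60, seed=5), "demo")
report = run_pipeline(RunConfig.from_json("demo/run_config.json"))
```

`demo/pipeline_out/summary.txt` then contains:

```
Ancestral reconstruction results
========================================
model:            WAG+G4 (alpha=1)
taxa / sites:     8 / 60
log-likelihood:   -571.1920
branch lengths:   optimized
indel changes:    3 (Fitch parsimony)
internal nodes:   7

node          present  mean maxP   P>=0.9
N1                 60     0.9826    0.950
N2                 60     1.0000    1.000
...
```

i.e. seven ancestors were reconstructed, each site flagged present by the
indel step, with mean maximum posteriors of 0.79–1.00 per node. The
enrichment table `demo/pipeline_out/enrichment_results.tsv` holds one row
per (window, region) — 5 windows × 9 regions = 45 rows — for example:

```
window      region                a  b  c  d   excluded  odds_ratio  p_value   significant
AncA->AncB  FormIII_LL_interface  1  2  1  56  0         28.0        0.098305  False
```

one substitution fell inside the three-column Form III interface on the
root-side window (odds ratio 28) but a single site is not evidence — the
exact test keeps p at 0.098 and the cell is, correctly, not flagged. With
the null simulation settings none of the 45 cells is significant.

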