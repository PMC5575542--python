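# Methods

This note documents the statistical and geometric machinery in
`paleoenrich`: what is modelled, the defaults and why, what the synthetic
data emulate, and the numerical choices that affect results.

## Overview

The package implements a three-stage analysis of protein-family history:

1. **Ancestral sequence reconstruction (ASR).** Given a fixed rooted
   topology with branch lengths, a gapped amino-acid alignment, and an
   empirical substitution model, branch lengths are re-optimized by maximum
   likelihood and marginal (empirical-Bayes) posteriors over the twenty
   amino acids are computed for every site of every internal node.
2. **Structural region annotation.** Nine functional regions of a catalytic
   dimer — three cross-assembly interfaces, the within-dimer interface, the
   α/β-barrel strands and their neighbourhood, mobile loop 6, and the N- and
   C-terminal domains — are derived from coordinates by distance rules and
   nearest-Cα transfer, then expressed as alignment columns.
3. **Enrichment scan.** For each *phylogenetic window* (the path between two
   named ancestors) and each region, sites are classified into a 2×2 table
   (substituted × in-region) by comparing the ML ancestral sequences at the
   window's endpoints; enrichment is tested with Fisher's exact test and a
   cell is flagged when its odds ratio exceeds 1.5 **and** p < .05 (both
   strict inequalities).

## Substitution model

The rate matrix is built from a symmetric exchangeability matrix S and
stationary frequencies π as `Q_ij = S_ij·π_j` (i ≠ j), diagonal set so rows
sum to zero, rescaled so `−Σ π_i Q_ii = 1`; branch lengths are therefore
expected substitutions per site. Two models are provided:

- **WAG** — the published empirical exchangeabilities and frequencies,
  embedded as constants in `_wag.py` in alphabetical one-letter order.
- **Poisson** — equal exchangeabilities, uniform frequencies. Its
  transition probabilities have the closed form
  `P_ii(t) = 1/20 + (19/20)·e^(−20t/19)`, which several tests exploit.

Site-rate heterogeneity uses the discrete-gamma construction: K
equal-probability categories (default **K = 4**, shape **α = 1**) whose
rates are the exact means of Gamma(α, α) over its quantile bands, normalized
to average one. The rate-class approximation sometimes used for tree search
is intentionally not reproduced; discrete gamma is the reproducible common
denominator for reconstruction. Note that at finite α the extreme category
means deviate from 1 by ≈1.27/√α, so even α = 10⁶ leaves ~1.3 × 10⁻³
deviations — this is exact behaviour, not error.

Transition matrices are computed by symmetric eigendecomposition of
`D^{1/2} Q D^{-1/2}` (D = diag π), cached per model; entries are clamped to
[0, 1] and rows renormalized against round-off.

## Likelihood and marginal posteriors

The pruning algorithm runs over unique column patterns with per-node
max-scaling and log accumulators, so deep or long trees do not underflow.
Gaps (and `X`/`?`) are missing data: their leaf partials are all-ones.
Site presence at ancestors is decided *solely* by the indel step below —
the likelihood machinery never interprets a gap as a 21st state.

Marginal posteriors combine the "below" partial F and "above" partial B at
each node: within each rate category the posterior is `F⊙B` normalized per
site; categories are mixed with weights proportional to the per-site
category likelihoods. On all trees with ≤ 4 leaves and ≤ 3 sites the
implementation is tested to agree with exhaustive enumeration over all
internal-state assignments to 10⁻⁸ in probability. Likelihood invariance
under root placement (the pulley principle) is also verified.

The **ML ancestral sequence** takes the argmax of each posterior column;
exact ties break alphabetically by one-letter code (the state order makes
`argmax`'s lowest-index rule implement this). Sites reconstructed absent
emit `-`. Posterior support is summarized by binning per-site maximum
posteriors into ten 10%-wide bins over present sites, and alternate
ancestors are drawn site-independently from the posterior columns
(default 5 per node, seeded).

## Branch lengths, model choice, branch support

Branch lengths are optimized coordinate-wise with bounded scalar search on
[10⁻⁸, 20], repeated until the log-likelihood improves by less than 10⁻⁶
(default; at most 20 sweeps, with a warning and best-found result on
non-convergence). The bounds and tolerance are numerical-stability choices,
not biological claims. Model fit is compared by AIC = 2k − 2 lnL with k =
branch count + model free parameters (the gamma shape counts as one when
rates vary). Topology inference is out of scope — the tree is an input.

Branch support is the approximate likelihood ratio (aLR): for an internal
branch, the likelihood of the input resolution against the better of its
two nearest-neighbour-interchange alternatives, with the five branch
lengths adjacent to the rearrangement locally re-optimized for each
resolution. When the tested branch's parent is the root, the unrooted edge
spans the root, so the exchange partners are the *children* of the sibling;
testing a branch whose unrooted counterpart is pendant is an error. Ratios
are reported both raw (clamped to the floating range) and as log₁₀.

## Indel reconstruction

Each alignment column's presence/absence pattern (gap = absent) is treated
as an independent binary character and reconstructed by Fitch parsimony:
set-intersection up-pass (union on empty intersection, counting one
change), then a down-pass that keeps the parent state whenever a node's
state set is ambiguous. An ambiguous root resolves to **present** by
default (configurable); the up-pass union count equals the parsimony
minimum, verified against brute force. The symmetric gain/loss choice in
the simulator (below) matches the independence assumption but is a
stand-in: nothing in the reconstruction depends on it.

## Structural regions

All distance rules use **non-hydrogen atoms on both sides** and a strict
`< cutoff` inequality with cutoff 5.0 Å by default (chosen to include
nonpolar contacts). Specifics:

- *Interfaces within a model* — residue r of side A is at the interface iff
  any of its heavy atoms is strictly within the cutoff of a heavy atom of
  side B.
- *Cross-model interfaces* — the query dimer is superimposed (least-squares
  Kabsch on paired Cα atoms, reflections excluded; the pairing defaults to
  position-by-position correspondence of the dimer chains) onto the
  reference assembly's dimer, then tested against the reference's partner
  chains (e.g. small subunits, neighbouring large subunits).
- *Subdomain transfer* — each reference subdomain residue selects the query
  residue with the nearest Cα after superposition; ties break to the lower
  (chain, index) key. Subdomain residue lists (barrel strands, loop 6,
  termini) must be supplied in reference numbering; they are not derivable
  from geometry alone.
- *near-barrel* — heavy-atom proximity to the barrel-strand residues,
  excluding the strand residues themselves (configurable).

Reading coordinates keeps ATOM records, drops HETATM ligands/ions/solvent,
and renames a small configurable set of modified residues to their parents
(e.g. carboxylated lysine → lysine, selenomethionine → methionine).
Structure residues map to alignment columns through the reference taxon's
row; the ungapped row must match the structure sequence up to a configurable
mismatch fraction (default 5%, mismatches mapped but flagged). Homology
modelling is out of scope: any query coordinates (a real model, a reference
structure, or a toy fixture) are accepted.

All nine region outputs are invariant under rigid motions of the query and
non-decreasing in the cutoff; both properties are tested.

## Enrichment testing

Windows are defined by resolving named ancestors as MRCAs of taxon sets and
joining consecutive ancestors along a root-to-tip path; non-nested requests
are errors. Only the window's *endpoints* are compared (not per-branch sums
along the path). Sites where either endpoint is reconstructed absent are
excluded from the table by default (`count-as-substitution` is available);
excluded counts are reported and `a+b+c+d+excluded` always equals the
alignment length.

Fisher's exact test is computed from the hypergeometric distribution of the
a-cell given fixed margins; the two-sided p sums all tables whose point
probability is at most the observed one (with 1 + 10⁻⁷ relative slack
against round-off), matching the convention of the standard
implementations. It is tested against exact rational enumeration for every
table with total ≤ 60 (10⁻¹² relative) and cross-checked against an
independent library implementation. The odds ratio is the sample ratio
`(a·d)/(b·c)` with `+inf` when only the denominator vanishes and undefined
(NaN) when both products do; a Haldane +0.5 correction is available behind
a flag but is off by default. Two-sided testing is the default, one-sided
"greater" is a flag. No multiple-testing correction enters the significance
rule; a Benjamini–Hochberg column is reported alongside for context.

Each region is tested against its complement (which may contain other,
overlapping regions) — regions are not mutually exclusive.

## Synthetic data

The simulator generates the conditions the analysis assumes: a root
sequence drawn from the model's stationary frequencies evolves down a
rooted tree (Yule-like random joins, ladder, or balanced shapes;
exponential branch lengths); each site keeps one gamma-category rate for
its whole history; a configurable multiplier m scales the rate on named
branches at named region columns only (m = 1 is the null). A fraction of
columns (default 5%) carries a symmetric binary gain/loss presence
character rooted at "present" (rate 0.3/unit branch length — a modest
turnover chosen so fixtures contain informative but not overwhelming gap
patterns). True states and presence are recorded at every node.

Toy dimer structures place Cα/pseudo-side-chain atoms on two straight
chains (4.5 Å spacing, 18 Å separation) and create exact contacts: each
requested interface pair receives atoms at cutoff − 0.1 Å across chains
while every other cross-chain heavy-atom distance exceeds cutoff + 1 Å
(construction is self-checked and refuses infeasible geometry).
Hydrogen-only contacts can be added to verify the heavy-atom rule. Partner
chains for cross-model interfaces approach designated residues
perpendicular to the dimer plane. The fixture bundle writes an alignment,
tree, structures, a region truth table, and a pipeline config whose nested
ladder clades define six ancestors and hence five windows.

What the toys do **not** emulate: realistic protein geometry (bond lengths,
secondary structure, packing), alignment error, affine indels, structure
evolution, or rate variation beyond the site-constant gamma. Passing tests
therefore demonstrate correctness of the rules and calibration of the
statistics under the assumed generating process, not robustness to
real-data violations of it.

## Calibration and power (simulation studies)

`paleoenrich.calibration` runs the replicated study used by the acceptance
checks: an 8-leaf ladder tree, 400 columns, nine regions (the implant
region covers 20% of columns, the others 10% each), five windows, and a
0.4-substitutions/site implant branch. Replicates are reconstructed by
marginal ASR with the true tree and branch lengths — per-replicate
branch-length re-optimization is deliberately skipped, since the studied
property is the calibration of the scan given a reconstruction, and the
study sizes (500 null, 200 power replicates) were chosen so the whole suite
runs at desk scale. Under the null, no (region, window) cell rejects at
p < .05 in more than 7% of replicates (Fisher is conservative; typical cell
rates are 2–5%); with m = 5 the implanted cell is flagged by the compound
rule in ≥ 80% of replicates (empirically ≈100%).

## Known limitations

- Joint (max-sum) reconstruction is not implemented; posteriors are
  marginal per site.
- The gamma shape α is not estimated by default (a 1-D optimizer flag
  exists for branch lengths only); model choice is by AIC over fixed
  candidates.
- The superposition pairing defaults to ordinal correspondence, which is
  correct for the package's threaded/equal-length use case but not a
  general structure aligner.
- aLR values can exceed the floating range; use the log₁₀ field for
  comparison across branches.
- Enrichment p-values treat sites as independent; correlated substitution
  processes would require a different null.
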