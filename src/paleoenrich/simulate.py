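"""Synthetic data generation: trees, alignments, and toy dimer structures.

The simulator emulates the evolutionary process the reconstruction stack
assumes: a root sequence drawn from the substitution model's stationary
frequencies evolves down a rooted tree with discrete-gamma site rates, and a
configurable region x branch rate multiplier implants a substitution-
enrichment signal (``m = 1`` is the null).  A fraction of columns carry an
independent binary presence/absence (indel) character evolved as a symmetric
gain/loss process.  True ancestral states are recorded at every node so
downstream stages can be scored against ground truth.

Toy dimer structures place pseudo-atoms so that designated residue pairs sit
just inside a distance cutoff across chains and everything else sits well
outside it, giving exact expected answers for the interface geometry rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import dendropy
import numpy as np

from .alphabet import N_STATES, THREE_LETTER, decode
from .containers import ProteinAlignment
from .structures import Atom, Residue, StructureModel, write_pdb
from .substitution import build_model
from .trees import TreeIndex, name_internal_nodes, parse_newick, to_newick

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "gen_tree",
    "evolve_alignment",
    "gen_toy_dimer",
    "gen_toy_complex",
    "gen_fixture_bundle",
]


class FixtureError(RuntimeError):
    """Geometric placement infeasible for the requested toy structure."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    ``rate_multiplier`` scales the substitution rate on ``multiplier_branches``
    (named by the node below each branch) at ``region_columns`` only;
    ``m = 1`` is the null of no implanted enrichment.
    """

    n_leaves: int = 8
    seq_length: int = 400
    model_name: str = "WAG"
    gamma_shape: float = 1.0
    n_rate_categories: int = 4
    region_columns: frozenset[int] = frozenset()
    multiplier_branches: frozenset[str] = frozenset()
    rate_multiplier: float = 1.0
    indel_column_fraction: float = 0.05
    indel_rate: float = 0.3
    tree_mode: str = "ladder"
    mean_branch_length: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be at least 2")
        if self.seq_length < 1:
            raise ValueError("seq_length must be positive")
        if self.rate_multiplier <= 0:
            raise ValueError("rate multiplier m must be positive")
        if not 0 <= self.indel_column_fraction <= 1:
            raise ValueError("indel_column_fraction must lie in [0, 1]")
        bad = [c for c in self.region_columns if not 0 <= c < self.seq_length]
        if bad:
            raise ValueError(f"region columns outside the alignment: {sorted(bad)}")
        object.__setattr__(self, "region_columns", frozenset(self.region_columns))
        object.__setattr__(self, "multiplier_branches", frozenset(self.multiplier_branches))

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulatedDataset:
    """A simulated tree/alignment with recorded ancestral truth."""

    tree: dendropy.Tree
    alignment: ProteinAlignment
    true_states: dict[str, np.ndarray]
    true_presence: dict[str, np.ndarray]
    config: SimulationConfig

    def true_sequence(self, node: str, gapped: bool = True) -> str:
        """True sequence at any node; gaps where the site is absent."""
        return decode(
            self.true_states[node], self.true_presence[node] if gapped else None
        )

    @property
    def internal_nodes(self) -> list[str]:
        leaves = set(self.alignment.taxa)
        return [n for n in self.true_states if n not in leaves]


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def gen_tree(
    n_leaves: int,
    mode: str = "yule",
    mean_branch_length: float = 0.1,
    seed: int = 0,
) -> dendropy.Tree:
    """Random rooted binary tree with exponential branch lengths.

    Modes: ``yule`` (random sequential joins), ``ladder`` (fully pectinate,
    convenient for nested ancestor windows) and ``balanced`` (as balanced as
    ``n_leaves`` allows).  Leaves are named L1..Ln; internal nodes are named
    deterministically in postorder.
    """
    if n_leaves < 2:
        raise ValueError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"L{i + 1}" for i in range(n_leaves)]

    def newick_topology() -> str:
        if mode == "ladder":
            s = f"({labels[0]},{labels[1]})"
            for lab in labels[2:]:
                s = f"({s},{lab})"
            return s
        if mode == "balanced":
            def build(items):
                if len(items) == 1:
                    return items[0]
                half = len(items) // 2
                return f"({build(items[:half])},{build(items[half:])})"
            return build(labels)
        if mode == "yule":
            groups = list(labels)
            while len(groups) > 1:
                i, j = sorted(rng.choice(len(groups), size=2, replace=False))
                merged = f"({groups[i]},{groups[j]})"
                groups = [g for k, g in enumerate(groups) if k not in (i, j)]
                groups.append(merged)
            return groups[0]
        raise ValueError(f"unknown tree mode {mode!r}")

    tree = parse_newick(newick_topology() + ";")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            length = float(rng.exponential(mean_branch_length))
            node.edge.length = max(length, 1e-6)
    return name_internal_nodes(tree)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _sample_states(P: np.ndarray, parents: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw child states given parent states and one transition matrix."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parents.shape[0])
    return (u[:, None] > cum[parents]).sum(axis=1)


def evolve_alignment(tree: dendropy.Tree, config: SimulationConfig) -> SimulatedDataset:
    """Simulate sequences down ``tree`` under the configured model.

    Site rates combine the site's gamma-category rate with the configured
    region x branch multiplier; indel columns carry an independent symmetric
    binary gain/loss character rooted at "present".
    """
    rng = np.random.default_rng(config.seed)
    model = build_model(
        config.model_name, alpha=config.gamma_shape, K=config.n_rate_categories
    )
    tree = name_internal_nodes(tree.clone(depth=1))
    ti = TreeIndex(tree)
    L = config.seq_length
    cats = rng.integers(0, model.n_categories, size=L)
    in_region = np.zeros(L, dtype=bool)
    in_region[sorted(config.region_columns)] = True

    n_indel = int(round(config.indel_column_fraction * L))
    indel_cols = rng.choice(L, size=n_indel, replace=False) if n_indel else np.array([], int)

    states = np.empty((ti.n_nodes, L), dtype=np.int64)
    presence = np.ones((ti.n_nodes, L), dtype=bool)
    states[ti.root] = _sample_states(
        np.tile(model.frequencies, (N_STATES, 1)), np.zeros(L, dtype=np.int64), rng
    )
    for i in range(ti.n_nodes - 2, -1, -1):
        parent = ti.parent[i]
        t = ti.lengths[i]
        boosted = in_region if ti.labels[i] in config.multiplier_branches else np.zeros(L, bool)
        child = np.empty(L, dtype=np.int64)
        for k, r in enumerate(model.category_rates):
            for region_flag in (False, True):
                mask = (cats == k) & (boosted == region_flag)
                if not mask.any():
                    continue
                rate = r * (config.rate_multiplier if region_flag else 1.0)
                P = model.transition_probs(t, rate)
                child[mask] = _sample_states(P, states[parent][mask], rng)
        states[i] = child
        # symmetric two-state gain/loss process on indel columns
        presence[i] = presence[parent]
        if indel_cols.size:
            p_flip = 0.5 * (1.0 - np.exp(-2.0 * config.indel_rate * t))
            flips = rng.random(indel_cols.size) < p_flip
            cols = indel_cols[flips]
            presence[i, cols] = ~presence[parent, cols]

    rows = []
    for i in range(ti.n_nodes):
        if ti.is_leaf[i]:
            rows.append((ti.labels[i], decode(states[i], presence[i])))
    alignment = ProteinAlignment(rows)
    true_states = {ti.labels[i]: states[i] for i in range(ti.n_nodes)}
    true_presence = {ti.labels[i]: presence[i] for i in range(ti.n_nodes)}
    return SimulatedDataset(tree, alignment, true_states, true_presence, config)


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

_DEF_SPACING = 4.5      # A between consecutive residues along a chain
_DEF_SEPARATION = 18.0  # A between the two chain axes


def _chain_residues(
    chain_id: str,
    n: int,
    origin: np.ndarray,
    sequence: str | None,
    side_sign: float,
    spacing: float,
) -> list[Residue]:
    residues = []
    for i in range(n):
        name = "ALA" if sequence is None else THREE_LETTER[sequence[i]]
        ca = origin + np.array([i * spacing, 0.0, 0.0])
        cb = ca + np.array([0.0, 1.5 * side_sign, 0.0])
        residues.append(
            Residue(
                chain_id=chain_id,
                index=i + 1,
                name=name,
                atoms=[Atom("CA", "C", ca), Atom("CB", "C", cb)],
            )
        )
    return residues


def gen_toy_dimer(
    n_residues_per_chain: int,
    interface_pairs: list[tuple[int, int]],
    cutoff: float = 5.0,
    seed: int = 0,
    hydrogen_pairs: list[tuple[int, int]] | None = None,
    sequence: str | None = None,
    spacing: float = _DEF_SPACING,
    separation: float = _DEF_SEPARATION,
    path: str | Path | None = None,
) -> StructureModel:
    """Two-chain toy structure with exact constructed interface contacts.

    Residues listed in ``interface_pairs`` (1-based, chain A index x chain B
    index) receive a pseudo side-chain atom pair at ``cutoff - 0.1`` A across
    the chains; every other cross-chain heavy-atom distance exceeds
    ``cutoff + 1``.  ``hydrogen_pairs`` get hydrogen-only contacts at
    ``cutoff - 0.1`` A, which the heavy-atom interface rule must ignore.
    """
    del seed  # placement is deterministic; kept for interface symmetry
    n = n_residues_per_chain
    if sequence is not None and len(sequence) != n:
        raise FixtureError("sequence length must match residue count")
    for i, j in list(interface_pairs) + list(hydrogen_pairs or []):
        if not (1 <= i <= n and 1 <= j <= n):
            raise FixtureError(f"residue pair ({i},{j}) outside chain length {n}")
    # non-contact guarantees: contact atoms sit on the midline at
    # separation/2 +- (cutoff-0.1)/2, so the nearest regular atom of the
    # opposite chain is separation/2 + 0.95 away; distinct contact pairs are
    # spacing apart horizontally and cutoff-0.1 vertically.
    if separation / 2 + 0.95 <= cutoff + 1.0 or separation - 3.0 <= cutoff + 1.0:
        raise FixtureError("chains too close for the non-contact guarantee")
    if spacing**2 <= (cutoff + 1.0) ** 2 - (cutoff - 0.1) ** 2:
        raise FixtureError("residue spacing too small for the non-contact guarantee")

    chain_a = _chain_residues("A", n, np.array([0.0, 0.0, 0.0]), sequence, +1.0, spacing)
    chain_b = _chain_residues("B", n, np.array([0.0, separation, 0.0]), sequence, -1.0, spacing)
    contact = cutoff - 0.1
    mid = separation / 2.0
    for i, j in interface_pairs:
        x = 0.5 * (chain_a[i - 1].atoms[0].xyz[0] + chain_b[j - 1].atoms[0].xyz[0])
        chain_a[i - 1].atoms.append(Atom("CG", "C", np.array([x, mid - contact / 2, 0.0])))
        chain_b[j - 1].atoms.append(Atom("CG", "C", np.array([x, mid + contact / 2, 0.0])))
    for i, j in hydrogen_pairs or []:
        x = 0.5 * (chain_a[i - 1].atoms[0].xyz[0] + chain_b[j - 1].atoms[0].xyz[0])
        chain_a[i - 1].atoms.append(Atom("H1", "H", np.array([x, mid - contact / 2, 3.0])))
        chain_b[j - 1].atoms.append(Atom("H1", "H", np.array([x, mid + contact / 2, 3.0])))

    model = StructureModel({"A": chain_a, "B": chain_b})
    _verify_dimer(model, interface_pairs, cutoff)
    if path is not None:
        write_pdb(model, path)
    return model


def _verify_dimer(model: StructureModel, pairs, cutoff: float) -> None:
    """Construction self-check: exactly the requested contacts exist."""
    from .structures import interface_residues

    expected_a = {("A", i) for i, _ in pairs}
    got = interface_residues(
        model, model.residue_keys("A"), model.residue_keys("B"), cutoff
    )
    if got != expected_a:
        raise FixtureError(f"constructed interface {got} != requested {expected_a}")


def gen_toy_complex(
    dimer: StructureModel,
    partner_specs: dict[str, list[tuple[str, int]]],
    cutoff: float = 5.0,
    partner_length: int = 4,
    path: str | Path | None = None,
) -> StructureModel:
    """Add far-away partner chains touching designated dimer residues.

    ``partner_specs`` maps a new chain id to the list of dimer residues
    (``(chain_id, residue_index)``) that must be detected at the partner
    interface: each gets one partner pseudo-atom at ``cutoff - 0.1`` A from
    its CA, approaching perpendicular to the dimer plane so no other residue
    comes within ``cutoff``.
    """
    chains = {cid: [Residue(r.chain_id, r.index, r.name, [Atom(a.name, a.element, a.xyz.copy()) for a in r.atoms]) for r in residues] for cid, residues in dimer.chains.items()}
    z_far = 18.0
    for offset, (chain_id, contacts) in enumerate(partner_specs.items()):
        if chain_id in chains:
            raise FixtureError(f"partner chain id {chain_id!r} already used")
        sign = 1.0 if offset % 2 == 0 else -1.0
        z0 = sign * (z_far + 6.0 * (offset // 2))
        residues = [
            Residue(chain_id, i + 1, "GLY",
                    [Atom("CA", "C", np.array([i * _DEF_SPACING, 0.0, z0]))])
            for i in range(max(partner_length, len(contacts)))
        ]
        for k, key in enumerate(contacts):
            res = dimer.residue(key)
            ca = res.atoms[0].xyz
            contact_xyz = ca + np.array([0.0, 0.0, sign * (cutoff - 0.1)])
            residues[k].atoms.append(Atom("CX", "C", contact_xyz))
        chains[chain_id] = residues
    model = StructureModel(chains)
    if path is not None:
        write_pdb(model, path)
    return model


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def gen_fixture_bundle(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a complete, internally consistent fixture set and its manifest.

    Produces an alignment (FASTA), tree (Newick), truth tables (TSV), toy
    query dimer plus reference complexes (PDB), a region-truth table, and a
    JSON manifest.  The structures are built from the first leaf's ungapped
    sequence so residue-to-column mapping is exact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = gen_tree(config.n_leaves, config.tree_mode, config.mean_branch_length, config.seed)
    data = evolve_alignment(tree, config)

    files: dict[str, str] = {}
    aln_path = out / "alignment.fasta"
    data.alignment.to_fasta(aln_path)
    files["alignment"] = aln_path.name
    tree_path = out / "tree.nwk"
    tree_path.write_text(to_newick(data.tree) + "\n")
    files["tree"] = tree_path.name

    truth = out / "true_ancestors.tsv"
    with open(truth, "w") as fh:
        fh.write("node\tsequence\n")
        for node in sorted(data.true_states):
            fh.write(f"{node}\t{data.true_sequence(node)}\n")
    files["true_ancestors"] = truth.name

    reference_taxon = data.alignment.taxa[0]
    ungapped = data.alignment.ungapped(reference_taxon)
    n_res = len(ungapped)
    rng = np.random.default_rng(config.seed + 1)
    picks = rng.permutation(n_res)[: min(n_res, 14)] + 1  # 1-based residues
    dimer_pairs = [(int(p), int(p)) for p in sorted(picks[0:3])]
    ll_contacts = [("A", int(p)) for p in sorted(picks[3:6])]
    ls_contacts = [("A", int(p)) for p in sorted(picks[6:9])]
    f3_contacts = [("A", int(p)) for p in sorted(picks[9:12])]
    barrel = sorted(int(p) for p in picks[12:14])

    query = gen_toy_dimer(n_res, dimer_pairs, sequence=ungapped,
                          path=out / "query_dimer.pdb")
    files["query_dimer"] = "query_dimer.pdb"
    gen_toy_complex(query, {"C": ll_contacts, "S": ls_contacts},
                    path=out / "form1_reference.pdb")
    files["form1_reference"] = "form1_reference.pdb"
    gen_toy_complex(query, {"D": f3_contacts}, path=out / "form3_reference.pdb")
    files["form3_reference"] = "form3_reference.pdb"
    write_pdb(query, out / "subdomain_reference.pdb")
    files["subdomain_reference"] = "subdomain_reference.pdb"

    subdomains = {
        "barrel_strands": barrel,
        "loop6": [max(1, n_res // 2)],
        "N_terminal": list(range(1, min(3, n_res) + 1)),
        "C_terminal": list(range(max(1, n_res - 2), n_res + 1)),
    }
    region_truth = {
        "dimer_interface": sorted({i for i, _ in dimer_pairs}),
        "FormI_LL_interface": sorted(i for _, i in ll_contacts),
        "FormI_LS_interface": sorted(i for _, i in ls_contacts),
        "FormIII_LL_interface": sorted(i for _, i in f3_contacts),
        **{k: sorted(v) for k, v in subdomains.items()},
    }
    # near_barrel: immediate chain neighbours of barrel members (spacing puts
    # only adjacent residues inside the 5 A cutoff), excluding members
    near = set()
    for b in barrel:
        near.update({b - 1, b + 1})
    region_truth["near_barrel"] = sorted(
        n for n in near if 1 <= n <= n_res and n not in barrel
    )
    truth_path = out / "region_truth_residues.tsv"
    with open(truth_path, "w") as fh:
        fh.write("region\tresidues\n")
        for k in sorted(region_truth):
            fh.write(f"{k}\t{','.join(map(str, region_truth[k]))}\n")
    files["region_truth"] = truth_path.name

    # a ready pipeline config: nested ancestors along the ladder backbone
    # give up to five phylogenetic windows between six named ancestors
    leaves = [f"L{i + 1}" for i in range(config.n_leaves)]
    n_anc = min(6, config.n_leaves - 1)
    ancestors = {
        f"Anc{chr(ord('A') + k)}": leaves[: config.n_leaves - k]
        for k in range(n_anc)
    }
    run_config = {
        "alignment": files["alignment"],
        "tree": files["tree"],
        "out_dir": "pipeline_out",
        "query_structure": files["query_dimer"],
        "form1_reference": files["form1_reference"],
        "form3_reference": files["form3_reference"],
        "subdomain_reference": files["subdomain_reference"],
        "reference_taxon": reference_taxon,
        "model_name": config.model_name,
        "alpha": config.gamma_shape,
        "K": config.n_rate_categories,
        "ancestors": ancestors,
        "region_config": {
            "barrel_strand_residues": subdomains["barrel_strands"],
            "loop6_residues": subdomains["loop6"],
            "n_terminal_residues": subdomains["N_terminal"],
            "c_terminal_residues": subdomains["C_terminal"],
        },
        "seed": config.seed,
    }
    with open(out / "run_config.json", "w") as fh:
        json.dump(run_config, fh, indent=2, sort_keys=True)
    files["run_config"] = "run_config.json"

    manifest = {
        "seed": config.seed,
        "reference_taxon": reference_taxon,
        "n_residues": n_res,
        "subdomains": subdomains,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["path"] = str(out)
    return manifest
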