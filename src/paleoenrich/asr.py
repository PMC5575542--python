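"""Ancestral sequence reconstruction under empirical substitution models.

The central objects follow the model/results idiom: an
:class:`AncestralReconstructionModel` couples a gapped protein alignment, a
rooted tree and a substitution model; its :meth:`~AncestralReconstructionModel.fit`
optimizes branch lengths by maximum likelihood and returns an
:class:`AncestralReconstructionResults` holding, for every internal node, the
marginal (empirical-Bayes) posterior matrix p(i, j) — the probability of
amino acid i at site j — the maximum-likelihood ancestral sequence, and the
site presence/absence states placed by Fitch parsimony on the gap pattern.

Indel characters are handled separately from amino-acid states: gaps are
missing data in the likelihood, and a site is reported at an ancestor only
where the parsimony reconstruction marks it present.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._engine import PruningEngine
from .alphabet import AMINO_ACIDS, decode
from .containers import ProteinAlignment
from .substitution import SubstitutionModel, build_model
from .trees import TreeIndex, name_internal_nodes, to_newick

__all__ = [
    "AncestralReconstructionModel",
    "AncestralReconstructionResults",
    "BranchSupport",
    "tree_log_likelihood",
    "optimize_branch_lengths",
    "aic_compare",
    "marginal_ancestral_posteriors",
    "fitch_indel_reconstruction",
    "branch_aLR",
]

BRANCH_LENGTH_BOUNDS = (1e-8, 20.0)

_PRESENT, _ABSENT, _BOTH = 1, 2, 3


# ---------------------------------------------------------------------------
# Fitch parsimony on binary presence/absence characters
# ---------------------------------------------------------------------------

def fitch_indel_reconstruction(
    tree: dendropy.Tree,
    presence: dict[str, np.ndarray],
    root_ambiguous_present: bool = True,
) -> tuple[dict[str, np.ndarray], int]:
    """Minimum-change ancestral presence/absence states, per column.

    Each column is treated as an independent binary character.  The up-pass
    uses set intersection (else union, counting one change); the down-pass
    keeps the parent's state whenever the node's state set is ambiguous.  An
    ambiguous root resolves to "present" by default.

    Parameters
    ----------
    presence : map leaf label -> boolean vector (True = residue present).

    Returns
    -------
    states : map node label -> boolean vector for every node (leaves echoed).
    changes : total parsimony change count over all columns.
    """
    ti = TreeIndex(tree)
    L = len(next(iter(presence.values())))
    masks = np.empty((ti.n_nodes, L), dtype=np.int8)
    changes = 0
    for i in range(ti.n_nodes):
        if ti.is_leaf[i]:
            vec = np.asarray(presence[ti.labels[i]], dtype=bool)
            masks[i] = np.where(vec, _PRESENT, _ABSENT)
        else:
            acc = np.full(L, _BOTH, dtype=np.int8)
            union = np.zeros(L, dtype=np.int8)
            for c in ti.children[i]:
                acc &= masks[c]
                union |= masks[c]
            empty = acc == 0
            changes += int(empty.sum())
            masks[i] = np.where(empty, union, acc)

    final = np.empty_like(masks)
    root_choice = _PRESENT if root_ambiguous_present else _ABSENT
    final[ti.root] = np.where(masks[ti.root] == _BOTH, root_choice, masks[ti.root])
    for i in range(ti.n_nodes - 2, -1, -1):
        parent_state = final[ti.parent[i]]
        keep_parent = (masks[i] & parent_state) > 0
        final[i] = np.where(keep_parent, parent_state, masks[i])

    states = {ti.labels[i]: final[i] == _PRESENT for i in range(ti.n_nodes)}
    return states, changes


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------

@dataclass
class BranchSupport:
    """Approximate likelihood-ratio support for an internal branch."""

    branch: str
    aLR: float
    log10_aLR: float
    log_likelihoods: tuple[float, float, float]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BranchSupport(branch={self.branch!r}, aLR={self.aLR:.4g})"


class AncestralReconstructionResults:
    """Fitted ancestral reconstruction.

    Carries the (possibly branch-length-optimized) tree, the total
    log-likelihood, per-internal-node posterior matrices, Fitch
    presence/absence states, and derived quantities (ML sequences, posterior
    bins, sampled alternate ancestors).
    """

    def __init__(
        self,
        model: "AncestralReconstructionModel",
        tree: dendropy.Tree,
        log_likelihood: float,
        posteriors: dict[str, np.ndarray],
        presence: dict[str, np.ndarray],
        indel_changes: int,
        optimized: bool,
    ):
        self.model = model
        self.tree = tree
        self.log_likelihood = log_likelihood
        self.posteriors = posteriors
        self.presence = presence
        self.indel_changes = indel_changes
        self.optimized = optimized

    # -- per-node views ----------------------------------------------------
    @property
    def node_names(self) -> list[str]:
        return sorted(self.posteriors)

    @property
    def alignment_length(self) -> int:
        return self.model.alignment.length

    def _check_node(self, node: str) -> None:
        if node not in self.posteriors:
            raise KeyError(f"no reconstruction for node {node!r}")

    def ml_states(self, node: str) -> np.ndarray:
        self._check_node(node)
        # np.argmax returns the lowest index on ties => alphabetical tie-break
        return np.argmax(self.posteriors[node], axis=1)

    def ml_sequence(self, node: str) -> str:
        """ML ancestral sequence; sites reconstructed absent emit a gap."""
        self._check_node(node)
        return decode(self.ml_states(node), self.presence[node])

    def max_posterior(self, node: str) -> np.ndarray:
        self._check_node(node)
        return self.posteriors[node].max(axis=1)

    def bin_posteriors(self, node: str, bin_width: float = 0.1) -> np.ndarray:
        """Proportion of present sites per max-posterior bin.

        Bins are [0, w), [w, 2w), ..., [1-w, 1]; proportions sum to one over
        the sites reconstructed as present.
        """
        self._check_node(node)
        n_bins = int(round(1.0 / bin_width))
        mp = self.max_posterior(node)[self.presence[node]]
        if mp.size == 0:
            return np.zeros(n_bins)
        idx = np.minimum((mp / bin_width).astype(int), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        return counts / counts.sum()

    def sample_ancestors(self, node: str, n: int = 5, seed: int | None = None) -> list[str]:
        """Alternate ancestors drawn site-wise from the posterior columns."""
        self._check_node(node)
        rng = np.random.default_rng(seed)
        post = self.posteriors[node]
        L = post.shape[0]
        cum = np.cumsum(post, axis=1)
        cum /= cum[:, -1:]
        out = []
        for _ in range(n):
            u = rng.random(L)
            states = (u[:, None] > cum).sum(axis=1)
            out.append(decode(states, self.presence[node]))
        return out

    # -- reporting ---------------------------------------------------------
    def node_table(self, node: str) -> pd.DataFrame:
        """Per-site reconstruction table for one node (1-based sites)."""
        self._check_node(node)
        post = self.posteriors[node]
        df = pd.DataFrame(
            {
                "site": np.arange(1, post.shape[0] + 1),
                "present": self.presence[node].astype(int),
                "ml_state": list(self.ml_sequence(node)),
                "max_posterior": self.max_posterior(node),
            }
        )
        for i, aa in enumerate(AMINO_ACIDS):
            df[f"p_{aa}"] = post[:, i]
        return df

    def to_directory(self, out_dir: str | Path) -> list[Path]:
        """Write per-node TSVs, newick and a bin table; returns paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for node in self.node_names:
            p = out_dir / f"ancestor_{node}.tsv"
            self.node_table(node).to_csv(p, sep="\t", index=False, float_format="%.6g")
            written.append(p)
        bins = pd.DataFrame(
            {node: self.bin_posteriors(node) for node in self.node_names},
            index=[f"[{i / 10:.1f},{(i + 1) / 10:.1f})" for i in range(10)],
        )
        p = out_dir / "posterior_bins.tsv"
        bins.to_csv(p, sep="\t", float_format="%.6g")
        written.append(p)
        p = out_dir / "tree_fitted.nwk"
        p.write_text(to_newick(self.tree) + "\n")
        written.append(p)
        return written

    def summary(self) -> str:
        lines = [
            "Ancestral reconstruction results",
            "=" * 40,
            f"model:            {self.model.substitution_model.name}"
            f"+G{self.model.substitution_model.n_categories}"
            f" (alpha={self.model.substitution_model.alpha:g})",
            f"taxa / sites:     {self.model.alignment.n_taxa} / {self.alignment_length}",
            f"log-likelihood:   {self.log_likelihood:.4f}",
            f"branch lengths:   {'optimized' if self.optimized else 'as input'}",
            f"indel changes:    {self.indel_changes} (Fitch parsimony)",
            f"internal nodes:   {len(self.node_names)}",
            "",
            f"{'node':<12}{'present':>9}{'mean maxP':>11}{'P>=0.9':>9}",
        ]
        for node in self.node_names:
            mp = self.max_posterior(node)[self.presence[node]]
            frac = float((mp >= 0.9).mean()) if mp.size else float("nan")
            lines.append(
                f"{node:<12}{int(self.presence[node].sum()):>9}"
                f"{float(mp.mean()) if mp.size else float('nan'):>11.4f}{frac:>9.3f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

class AncestralReconstructionModel:
    """Maximum-likelihood ancestral reconstruction on a fixed topology.

    Parameters
    ----------
    alignment : gapped protein alignment whose taxa cover the tree's leaves.
    tree : rooted tree with branch lengths (substitutions/site).  Internal
        nodes are auto-named deterministically if unlabeled.
    substitution_model : a :class:`SubstitutionModel` or a model name
        (``"WAG"`` / ``"Poisson"``); names are built with the given
        ``alpha`` / ``K``.
    """

    def __init__(
        self,
        alignment: ProteinAlignment,
        tree: dendropy.Tree,
        substitution_model: SubstitutionModel | str = "WAG",
        *,
        alpha: float = 1.0,
        K: int = 4,
    ):
        if isinstance(substitution_model, str):
            substitution_model = build_model(substitution_model, alpha=alpha, K=K)
        self.alignment = alignment
        self.tree = name_internal_nodes(tree)
        self.substitution_model = substitution_model
        missing = set(l.taxon.label for l in tree.leaf_node_iter()) - set(alignment.taxa)
        if missing:
            raise ValueError(f"tree leaves missing from alignment: {sorted(missing)}")
        self._encoded = np.stack([alignment.encoded(t) for t in alignment.taxa])
        self._rows = {t: i for i, t in enumerate(alignment.taxa)}

    @classmethod
    def from_files(
        cls, alignment_path, tree_path, substitution_model="WAG", **kwargs
    ) -> "AncestralReconstructionModel":
        from .trees import load_tree

        return cls(
            ProteinAlignment.from_fasta(alignment_path),
            load_tree(tree_path),
            substitution_model,
            **kwargs,
        )

    # -- likelihood --------------------------------------------------------
    def _engine(self, tree: dendropy.Tree | None = None) -> PruningEngine:
        ti = TreeIndex(tree if tree is not None else self.tree)
        return PruningEngine(ti, self._encoded, self._rows, self.substitution_model)

    def loglike(self, tree: dendropy.Tree | None = None) -> float:
        """Pruning log-likelihood of the alignment on the (given) tree."""
        return self._engine(tree).log_likelihood()

    # -- branch length optimization ---------------------------------------
    def _optimize_lengths_inplace(
        self,
        tree: dendropy.Tree,
        tol: float,
        max_rounds: int,
        edges: list[dendropy.Node] | None = None,
    ) -> float:
        """Coordinate-wise bounded 1-D optimization of branch lengths."""
        engine = self._engine(tree)
        ti = engine.ti
        lengths = ti.lengths.copy()
        if edges is None:
            targets = list(range(ti.n_nodes - 1))
        else:
            wanted = {id(n) for n in edges}
            targets = [i for i, n in enumerate(ti.nodes) if id(n) in wanted and i != ti.root]
        current = engine.log_likelihood(lengths)
        lo, hi = BRANCH_LENGTH_BOUNDS
        for _ in range(max_rounds):
            previous = current
            for i in targets:
                def neg(x: float, i=i) -> float:
                    trial = lengths.copy()
                    trial[i] = x
                    return -engine.log_likelihood(trial)

                res = minimize_scalar(
                    neg, bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-8},
                )
                if -res.fun > current:
                    lengths[i] = float(res.x)
                    current = -res.fun
            if current - previous < tol:
                break
        else:
            warnings.warn("branch-length optimization did not converge", RuntimeWarning)
        for i, node in enumerate(ti.nodes):
            if i != ti.root:
                node.edge.length = float(lengths[i])
        return current

    def optimize_branch_lengths(
        self, tol: float = 1e-6, max_rounds: int = 20
    ) -> tuple[dendropy.Tree, float]:
        """Return a copy of the tree with ML branch lengths and its lnL."""
        tree = copy.deepcopy(self.tree)
        lnl = self._optimize_lengths_inplace(tree, tol, max_rounds)
        return tree, lnl

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        optimize_branch_lengths: bool = True,
        tol: float = 1e-6,
        max_rounds: int = 20,
        root_ambiguous_present: bool = True,
    ) -> AncestralReconstructionResults:
        """Fit branch lengths (optionally) and reconstruct every ancestor."""
        if optimize_branch_lengths:
            tree, _ = self.optimize_branch_lengths(tol=tol, max_rounds=max_rounds)
        else:
            tree = copy.deepcopy(self.tree)
        engine = self._engine(tree)
        post_by_index, lnl = engine.marginal_posteriors()
        posteriors = {
            engine.ti.labels[i]: p
            for i, p in post_by_index.items()
            if engine.ti.labels[i]
        }
        presence_leaves = {
            t: self.alignment.presence_matrix()[self._rows[t]]
            for t in (l.taxon.label for l in tree.leaf_node_iter())
        }
        presence, changes = fitch_indel_reconstruction(
            tree, presence_leaves, root_ambiguous_present=root_ambiguous_present
        )
        return AncestralReconstructionResults(
            model=self,
            tree=tree,
            log_likelihood=lnl,
            posteriors=posteriors,
            presence=presence,
            indel_changes=changes,
            optimized=optimize_branch_lengths,
        )

    # -- branch support ----------------------------------------------------
    def branch_support(
        self, branch: str, tol: float = 1e-4, max_rounds: int = 5
    ) -> BranchSupport:
        """Approximate likelihood-ratio (aLR) support for an internal branch.

        The branch is named by the internal node below it.  The two
        nearest-neighbor-interchange alternatives are evaluated with the five
        adjacent branch lengths locally re-optimized; the aLR is the ratio of
        the input resolution's likelihood to the better alternative's.
        """
        lnls = []
        for resolution in range(3):
            tree = copy.deepcopy(self.tree)
            node = next(
                (n for n in tree.preorder_internal_node_iter() if n.label == branch),
                None,
            )
            if node is None:
                raise ValueError(f"no internal node labeled {branch!r}")
            parent = node.parent_node
            if parent is None:
                raise ValueError("the root has no branch above it")
            kids = node.child_nodes()
            if len(kids) != 2:
                raise ValueError("NNI requires a binary internal node")
            sibling = next(c for c in parent.child_nodes() if c is not node)
            if parent.parent_node is None:
                # the unrooted edge is node--sibling: NNI exchanges one child
                # of the node with one child of the sibling
                partner_parent = sibling
                sib_kids = sibling.child_nodes()
                if len(sib_kids) != 2:
                    raise ValueError(
                        "branch is pendant in the unrooted tree; aLR undefined"
                    )
                partner = sib_kids[0]
            else:
                # NNI exchanges one child of the node with its sibling subtree
                partner_parent = parent
                partner = sibling
            if resolution:
                moved = kids[resolution - 1]
                partner_parent.remove_child(partner)
                node.remove_child(moved)
                partner_parent.add_child(moved)
                node.add_child(partner)
            # branches adjacent to the rearranged edge
            local = [node, *node.child_nodes()]
            if parent.parent_node is None:
                local += [sibling, *sibling.child_nodes()]
            else:
                local += [sibling, parent]
            lnls.append(self._optimize_lengths_inplace(tree, tol, max_rounds, edges=local))
        log_ratio = lnls[0] - max(lnls[1], lnls[2])
        return BranchSupport(
            branch=branch,
            aLR=float(np.exp(np.clip(log_ratio, -700, 700))),
            log10_aLR=float(log_ratio / np.log(10.0)),
            log_likelihoods=tuple(lnls),
        )


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def tree_log_likelihood(
    tree: dendropy.Tree, alignment: ProteinAlignment, model: SubstitutionModel
) -> float:
    return AncestralReconstructionModel(alignment, tree, model).loglike()


def optimize_branch_lengths(
    tree: dendropy.Tree,
    alignment: ProteinAlignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
) -> tuple[dendropy.Tree, float]:
    return AncestralReconstructionModel(alignment, tree, model).optimize_branch_lengths(tol=tol)


def marginal_ancestral_posteriors(
    tree: dendropy.Tree, alignment: ProteinAlignment, model: SubstitutionModel
) -> AncestralReconstructionResults:
    return AncestralReconstructionModel(alignment, tree, model).fit(
        optimize_branch_lengths=False
    )


def branch_aLR(
    tree: dendropy.Tree,
    alignment: ProteinAlignment,
    model: SubstitutionModel,
    branch: str,
) -> BranchSupport:
    return AncestralReconstructionModel(alignment, tree, model).branch_support(branch)


def aic_compare(
    alignment: ProteinAlignment,
    tree: dendropy.Tree,
    candidate_models: list[SubstitutionModel],
    optimize: bool = True,
) -> pd.DataFrame:
    """Rank candidate substitution models by AIC = 2k - 2 lnL.

    ``k`` counts one parameter per branch plus the model's free parameters
    (the gamma shape counts as one when rates vary).  Branch lengths are
    re-optimized for each candidate unless ``optimize`` is False.
    """
    if not candidate_models:
        raise ValueError("need at least one candidate model")
    rows = []
    n_branches = TreeIndex(tree).n_branches
    for m in candidate_models:
        arm = AncestralReconstructionModel(alignment, tree, m)
        lnl = arm.optimize_branch_lengths()[1] if optimize else arm.loglike()
        k = n_branches + m.n_free_parameters
        rows.append(
            {
                "model": f"{m.name}+G{m.n_categories}" if m.n_categories > 1 else m.name,
                "lnL": lnl,
                "k_params": k,
                "AIC": 2 * k - 2 * lnl,
            }
        )
    table = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    table["best"] = False
    table.loc[0, "best"] = True
    return table
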