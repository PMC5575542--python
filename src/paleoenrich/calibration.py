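"""Simulation studies of the enrichment scan: null calibration and power.

Both studies share one design: a ladder phylogeny whose nested clades define
six named ancestors (five windows), nine region column sets, and replicated
alignments simulated under the substitution model.  Each replicate is
reconstructed by marginal ancestral-state inference on the true tree (branch
lengths are not re-estimated per replicate; the scan consumes the
reconstruction, not the optimizer) and scanned for enrichment.

Under the null (rate multiplier m = 1) the per-cell rejection rate at
p < .05 measures calibration; Fisher's exact test is conservative, so the
rate sits below the nominal level.  With an implanted multiplier (m > 1 on
one branch within one region) the recovery rate of the implanted
(region, window) cell measures power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asr import AncestralReconstructionModel
from .enrichment import PhylogeneticWindow, define_windows, enrichment_scan
from .regions import REGION_LABELS, RegionMap
from .simulate import SimulationConfig, evolve_alignment, gen_tree

__all__ = ["EnrichmentStudy", "null_rejection_rate", "signal_recovery_rate"]

IMPLANT_REGION = "barrel_strands"
IMPLANT_WINDOW_INDEX = 0  # root-side window: the single branch below the root


@dataclass
class StudyResult:
    """Aggregate of one replicated enrichment study."""

    rejection_rates: pd.DataFrame  # per (window, region): p<.05 rate and flag rate
    n_replicates: int
    implant_cell: tuple[str, str] | None

    @property
    def max_p_rejection_rate(self) -> float:
        return float(self.rejection_rates["p_reject_rate"].max())

    @property
    def implant_recovery_rate(self) -> float:
        if self.implant_cell is None:
            raise ValueError("study had no implanted signal")
        window, region = self.implant_cell
        row = self.rejection_rates[
            (self.rejection_rates["window"] == window)
            & (self.rejection_rates["region"] == region)
        ]
        return float(row["significant_rate"].iloc[0])


class EnrichmentStudy:
    """Replicated simulate -> reconstruct -> scan experiment."""

    def __init__(
        self,
        n_leaves: int = 8,
        seq_length: int = 400,
        region_fraction: float = 0.2,
        multiplier: float = 1.0,
        multiplier_branch_length: float = 0.4,
        mean_branch_length: float = 0.15,
        alpha: float = 1.0,
        K: int = 4,
        seed: int = 0,
    ):
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.tree = gen_tree(n_leaves, "ladder", mean_branch_length, seed)
        leaves = [f"L{i + 1}" for i in range(n_leaves)]
        n_anc = min(6, n_leaves - 1)
        self.ancestor_specs = {
            f"Anc{chr(ord('A') + k)}": leaves[: n_leaves - k] for k in range(n_anc)
        }
        self.windows: list[PhylogeneticWindow] = define_windows(
            self.tree, self.ancestor_specs
        )
        # the implant branch is the single branch of the root-side window
        implant_end = self.windows[IMPLANT_WINDOW_INDEX].end
        self._implant_branch = implant_end
        for node in self.tree.preorder_node_iter():
            if node.label == implant_end:
                node.edge.length = multiplier_branch_length

        L = seq_length
        n_region_cols = max(1, int(round(region_fraction * L)))
        region_cols: dict[str, np.ndarray] = {}
        for label in REGION_LABELS:
            size = n_region_cols if label == IMPLANT_REGION else max(1, L // 10)
            region_cols[label] = rng.choice(L, size=size, replace=False)
        self.region_map = RegionMap(
            {label: set(map(int, cols)) for label, cols in region_cols.items()},
            provenance={"synthetic": True, "seed": seed},
        )
        self.base_config = SimulationConfig(
            n_leaves=n_leaves,
            seq_length=L,
            gamma_shape=alpha,
            n_rate_categories=K,
            region_columns=frozenset(map(int, region_cols[IMPLANT_REGION])),
            multiplier_branches=frozenset({implant_end} if multiplier != 1.0 else ()),
            rate_multiplier=multiplier,
            indel_column_fraction=0.0,
            seed=seed,
        )
        self.multiplier = multiplier

    @property
    def implant_cell(self) -> tuple[str, str] | None:
        if self.multiplier == 1.0:
            return None
        return (self.windows[IMPLANT_WINDOW_INDEX].name, IMPLANT_REGION)

    def run_replicate(self, replicate: int) -> pd.DataFrame:
        cfg = self.base_config.replace(seed=(self.seed + 7919 * (replicate + 1)) % 2**31)
        data = evolve_alignment(self.tree, cfg)
        arm = AncestralReconstructionModel(
            data.alignment, data.tree, self.base_config.model_name,
            alpha=self.base_config.gamma_shape, K=self.base_config.n_rate_categories,
        )
        results = arm.fit(optimize_branch_lengths=False)
        return enrichment_scan(results, self.windows, self.region_map)

    def run(self, n_replicates: int, p_threshold: float = 0.05) -> StudyResult:
        p_reject = None
        sig = None
        for r in range(n_replicates):
            df = self.run_replicate(r)
            hit_p = (df["p_value"] < p_threshold).to_numpy(dtype=float)
            hit_sig = df["significant"].to_numpy(dtype=float)
            if p_reject is None:
                p_reject = hit_p
                sig = hit_sig
                index = df[["window", "region"]]
            else:
                p_reject += hit_p
                sig += hit_sig
        rates = index.copy()
        rates["p_reject_rate"] = p_reject / n_replicates
        rates["significant_rate"] = sig / n_replicates
        return StudyResult(
            rejection_rates=rates,
            n_replicates=n_replicates,
            implant_cell=self.implant_cell,
        )


def null_rejection_rate(
    n_replicates: int = 500, seed: int = 0, **study_kwargs
) -> StudyResult:
    """Type-I calibration of the scan under m = 1 (no implanted signal)."""
    study = EnrichmentStudy(multiplier=1.0, seed=seed, **study_kwargs)
    return study.run(n_replicates)


def signal_recovery_rate(
    n_replicates: int = 200, multiplier: float = 5.0, seed: int = 0, **study_kwargs
) -> StudyResult:
    """Power of the scan to flag an implanted region x branch enrichment."""
    study = EnrichmentStudy(multiplier=multiplier, seed=seed, **study_kwargs)
    return study.run(n_replicates)
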