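"""End-to-end orchestration: inputs -> ASR -> region map -> enrichment report.

A single JSON :class:`RunConfig` drives the whole run so the report can embed
it verbatim; every stage records success or failure and downstream stages
that depend on a failed stage are skipped rather than aborting the whole
run.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from .asr import AncestralReconstructionModel
from .containers import ProteinAlignment
from .enrichment import define_windows, enrichment_scan
from .regions import RegionConfig, build_region_map
from .structures import read_structure
from .trees import load_tree, root_with_outgroup, to_newick

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_config"]

logger = logging.getLogger("paleoenrich")


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    alignment: str
    tree: str
    out_dir: str
    query_structure: str | None = None
    form1_reference: str | None = None
    form3_reference: str | None = None
    subdomain_reference: str | None = None
    reference_taxon: str | None = None
    model_name: str = "WAG"
    alpha: float = 1.0
    K: int = 4
    outgroup: list[str] = dc_field(default_factory=list)
    ancestors: dict[str, list[str]] = dc_field(default_factory=dict)
    region_config: dict = dc_field(default_factory=dict)
    or_threshold: float = 1.5
    p_threshold: float = 0.05
    gap_policy: str = "exclude"
    alternative: str = "two-sided"
    n_alternate_ancestors: int = 5
    optimize_branch_lengths: bool = True
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        base = Path(path).parent
        cfg = cls(**payload)
        # resolve relative paths against the config file location
        for attr in ("alignment", "tree", "query_structure", "form1_reference",
                     "form3_reference", "subdomain_reference", "out_dir"):
            value = getattr(cfg, attr)
            if value is not None and not Path(value).is_absolute():
                setattr(cfg, attr, str(base / value))
        return cfg

    def to_dict(self) -> dict:
        return {k: (sorted(v) if isinstance(v, (set, frozenset)) else v)
                for k, v in self.__dict__.items()}


@dataclass
class RunReport:
    """Per-stage status plus enough metadata to reproduce the run."""

    config: dict
    stages: dict = dc_field(default_factory=dict)
    checksums: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)
    outputs: dict = dc_field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages.values()
                   if s["status"] != "skipped")

    @property
    def failed_stages(self) -> list[str]:
        return [n for n, s in self.stages.items() if s["status"] == "failed"]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True,
                                         default=str))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable problems (empty iff valid)."""
    problems: list[str] = []
    for attr in ("alignment", "tree", "query_structure", "form1_reference",
                 "form3_reference", "subdomain_reference"):
        value = getattr(config, attr)
        if value is not None and not Path(value).exists():
            problems.append(f"{attr}: path does not exist: {value}")
    if config.or_threshold <= 0:
        problems.append("or_threshold: must be positive")
    if not 0 < config.p_threshold <= 1:
        problems.append("p_threshold: must lie in (0, 1]")
    if config.gap_policy not in ("exclude", "count-as-substitution"):
        problems.append(f"gap_policy: unknown policy {config.gap_policy!r}")
    if config.alternative not in ("two-sided", "greater"):
        problems.append(f"alternative: unknown sidedness {config.alternative!r}")
    if config.alpha <= 0:
        problems.append("alpha: gamma shape must be positive")
    if config.K < 1:
        problems.append("K: need at least one rate category")
    cutoff = config.region_config.get("cutoff", 5.0)
    if cutoff <= 0:
        problems.append("region_config.cutoff: must be positive")
    if Path(config.alignment).exists() and Path(config.tree).exists():
        try:
            aln = ProteinAlignment.from_fasta(config.alignment)
            tree = load_tree(config.tree)
            leaves = {l.taxon.label for l in tree.leaf_node_iter()}
            missing = leaves - set(aln.taxa)
            if missing:
                problems.append(f"tree: leaves missing from alignment: {sorted(missing)}")
            for name, taxa in config.ancestors.items():
                unknown = set(taxa) - leaves
                for t in sorted(unknown):
                    problems.append(f"ancestors.{name}: unknown taxon {t!r}")
            unknown_og = set(config.outgroup) - leaves
            for t in sorted(unknown_og):
                problems.append(f"outgroup: unknown taxon {t!r}")
        except Exception as exc:
            problems.append(f"inputs: failed to parse alignment/tree: {exc}")
    if config.reference_taxon and Path(config.alignment).exists():
        try:
            aln = ProteinAlignment.from_fasta(config.alignment)
            if config.reference_taxon not in aln:
                problems.append(
                    f"reference_taxon: {config.reference_taxon!r} not in alignment")
        except Exception:
            pass
    return problems


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and write all artifacts.

    Stage order: inputs -> rooting -> branch-length fit + ancestral
    reconstruction -> region map -> windows -> enrichment scan -> report.
    A failed stage is recorded and its dependents are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    state: dict = {}

    def stage(name: str, fn, requires: tuple[str, ...] = ()):
        for req in requires:
            if report.stages.get(req, {}).get("status") != "ok":
                report.stages[name] = {"status": "skipped",
                                       "error": f"requires stage {req!r}"}
                logger.info("stage %s skipped (requires %s)", name, req)
                return
        try:
            fn()
            report.stages[name] = {"status": "ok", "error": ""}
            logger.info("stage %s ok", name)
        except Exception as exc:
            report.stages[name] = {"status": "failed", "error": str(exc)}
            report.warnings.append(f"{name}: {traceback.format_exc(limit=2)}")
            logger.error("stage %s failed: %s", name, exc)

    def load_inputs():
        state["alignment"] = ProteinAlignment.from_fasta(config.alignment)
        state["tree"] = load_tree(config.tree)
        for attr in ("alignment", "tree"):
            report.checksums[attr] = _sha256(getattr(config, attr))
        for attr in ("query_structure", "form1_reference", "form3_reference",
                     "subdomain_reference"):
            value = getattr(config, attr)
            if value is not None and Path(value).exists():
                report.checksums[attr] = _sha256(value)
            elif value is not None:
                # only the region stage consumes structures; record and go on
                report.warnings.append(f"inputs: structure path missing: {value}")

    def rooting():
        if config.outgroup:
            state["tree"] = root_with_outgroup(state["tree"], config.outgroup)
        (out / "tree_rooted.nwk").write_text(to_newick(state["tree"]) + "\n")

    def asr():
        arm = AncestralReconstructionModel(
            state["alignment"], state["tree"], config.model_name,
            alpha=config.alpha, K=config.K,
        )
        results = arm.fit(optimize_branch_lengths=config.optimize_branch_lengths)
        state["results"] = results
        written = results.to_directory(out / "asr")
        report.outputs["asr"] = [str(p) for p in written]
        if config.n_alternate_ancestors > 0:
            with open(out / "asr" / "alternate_ancestors.fasta", "w") as fh:
                for node in results.node_names:
                    samples = results.sample_ancestors(
                        node, n=config.n_alternate_ancestors, seed=config.seed
                    )
                    for i, seq in enumerate(samples, 1):
                        fh.write(f">{node}|alt{i}\n{seq}\n")
        (out / "summary.txt").write_text(results.summary() + "\n")

    def regionmap():
        if config.query_structure is None:
            raise ValueError("no query structure configured")
        rc = RegionConfig.from_dict(config.region_config)
        query = read_structure(config.query_structure)
        form1 = read_structure(config.form1_reference)
        form3 = read_structure(config.form3_reference)
        subref = read_structure(config.subdomain_reference)
        reference_taxon = config.reference_taxon or state["alignment"].taxa[0]
        rmap = build_region_map(rc, query, form1, form3, subref,
                                state["alignment"], reference_taxon)
        state["region_map"] = rmap
        rmap.to_tsv(out / "region_map.tsv", state["alignment"].length)
        rmap.to_json(out / "region_map.json")

    def windows():
        state["windows"] = define_windows(state["tree"], config.ancestors)
        (out / "windows.json").write_text(json.dumps(
            [w.__dict__ for w in state["windows"]], indent=2))

    def scan():
        df = enrichment_scan(
            state["results"], state["windows"], state["region_map"],
            or_threshold=config.or_threshold, p_threshold=config.p_threshold,
            gap_policy=config.gap_policy, alternative=config.alternative,
        )
        state["scan"] = df
        df.to_csv(out / "enrichment_results.tsv", sep="\t", index=False,
                  float_format="%.6g")
        meta = {
            "thresholds": {"odds_ratio": config.or_threshold,
                           "p_value": config.p_threshold},
            "gap_policy": config.gap_policy,
            "alternative": config.alternative,
            "rows": int(len(df)),
            "significant": int(df.get("significant", pd.Series(dtype=bool)).sum()),
        }
        (out / "enrichment_results.json").write_text(json.dumps({
            "metadata": meta,
            "results": json.loads(df.to_json(orient="records")),
        }, indent=2))

    stage("inputs", load_inputs)
    stage("rooting", rooting, requires=("inputs",))
    stage("asr", asr, requires=("rooting",))
    stage("regions", regionmap, requires=("inputs",))
    stage("windows", windows, requires=("rooting",))
    stage("scan", scan, requires=("asr", "regions", "windows"))
    report.outputs["out_dir"] = str(out)
    report.to_json(out / "report.json")
    return report
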