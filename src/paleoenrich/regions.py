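"""The nine structural region labels of the catalytic dimer, as alignment columns.

The region vocabulary covers three cross-assembly interfaces (measured
against reference structures of the octameric Form I and the dimeric/array
Form III enzymes), the interface within the catalytic dimer itself, the
strands of the alpha/beta barrel that caps the active site plus the residues
near it, mobile loop 6 which closes over the substrate, and the N- and
C-terminal domains.  Interfaces use the strict ``< cutoff`` heavy-atom rule;
subdomains transfer from a reference structure by nearest CA after
superposition.  Every region is finally expressed as a set of alignment
columns through the reference taxon's row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .containers import ProteinAlignment
from .structures import (
    ResidueKey,
    StructureModel,
    cross_model_interface,
    interface_residues,
    map_residues_to_alignment,
    near_set,
    ordinal_pairing,
    subdomain_by_nearest_ca,
)

__all__ = ["REGION_LABELS", "RegionConfig", "RegionMap", "build_region_map"]

REGION_LABELS = (
    "FormI_LL_interface",
    "FormI_LS_interface",
    "FormIII_LL_interface",
    "dimer_interface",
    "barrel_strands",
    "near_barrel",
    "loop6",
    "N_terminal",
    "C_terminal",
)


class RegionError(RuntimeError):
    """A region computation failed; carries the region name."""


@dataclass
class RegionConfig:
    """Geometry parameters and reference selections for region building.

    Subdomain residue lists are 1-based indices in the numbering of the
    subdomain reference structure and are applied to both chains of its
    dimer.  Chain pairs name the catalytic dimer within each reference.
    """

    cutoff: float = 5.0
    query_chains: tuple[str, str] = ("A", "B")
    form1_dimer_chains: tuple[str, str] = ("A", "B")
    form1_large_partner_chains: frozenset[str] = frozenset({"C"})
    form1_small_partner_chains: frozenset[str] = frozenset({"S"})
    form3_dimer_chains: tuple[str, str] = ("A", "B")
    form3_partner_chains: frozenset[str] = frozenset({"D"})
    subdomain_chains: tuple[str, str] = ("A", "B")
    barrel_strand_residues: list[int] = field(default_factory=list)
    loop6_residues: list[int] = field(default_factory=list)
    n_terminal_residues: list[int] = field(default_factory=list)
    c_terminal_residues: list[int] = field(default_factory=list)
    near_barrel_excludes_core: bool = True
    max_mismatch_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("interface cutoff must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RegionConfig":
        kwargs = dict(d)
        for key in ("form1_large_partner_chains", "form1_small_partner_chains",
                    "form3_partner_chains"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        for key in ("query_chains", "form1_dimer_chains", "form3_dimer_chains",
                    "subdomain_chains"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


class RegionMap:
    """Alignment-column sets for each of the nine region labels."""

    def __init__(self, regions: dict[str, set[int]], provenance: dict | None = None):
        unknown = set(regions) - set(REGION_LABELS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")
        self.regions = {label: frozenset(regions.get(label, ())) for label in REGION_LABELS}
        self.provenance = provenance or {}

    def __getitem__(self, label: str) -> frozenset[int]:
        return self.regions[label]

    def labels_for_column(self, column: int) -> set[str]:
        return {label for label, cols in self.regions.items() if column in cols}

    def items(self):
        return self.regions.items()

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path, alignment_length: int | None = None) -> None:
        """Column table (1-based columns, comma-separated labels)."""
        columns = sorted({c for cols in self.regions.values() for c in cols})
        if alignment_length is not None:
            columns = list(range(alignment_length))
        with open(path, "w") as fh:
            for key, value in sorted(self.provenance.items()):
                fh.write(f"# {key}: {value}\n")
            fh.write("column\tregions\n")
            for c in columns:
                labels = sorted(self.labels_for_column(c))
                fh.write(f"{c + 1}\t{','.join(labels)}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "provenance": self.provenance,
            "regions": {label: sorted(cols) for label, cols in self.regions.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionMap":
        payload = json.loads(Path(path).read_text())
        return cls(
            {label: set(cols) for label, cols in payload["regions"].items()},
            provenance=payload.get("provenance", {}),
        )


def _keys_to_columns(
    keys: set[ResidueKey],
    column_maps: dict[str, dict[int, int]],
) -> set[int]:
    out = set()
    for chain_id, index in keys:
        cmap = column_maps.get(chain_id)
        if cmap is not None and index in cmap:
            out.add(cmap[index])
    return out


def build_region_map(
    config: RegionConfig,
    query: StructureModel,
    form1_reference: StructureModel,
    form3_reference: StructureModel,
    subdomain_reference: StructureModel,
    alignment: ProteinAlignment,
    reference_row: str,
) -> RegionMap:
    """Compute all nine region column sets for the query dimer.

    ``reference_row`` names the alignment taxon whose (ungapped) sequence
    matches the query structure; both query chains map onto that row.
    """
    if reference_row not in alignment:
        raise ValueError(f"reference taxon {reference_row!r} not in alignment")
    row = alignment.sequence(reference_row)
    column_maps: dict[str, dict[int, int]] = {}
    for cid in config.query_chains:
        cmap, _ = map_residues_to_alignment(
            query.sequence(cid), row, config.max_mismatch_fraction
        )
        column_maps[cid] = cmap

    qa, qb = config.query_chains
    residue_sets: dict[str, set[ResidueKey]] = {}

    def run(label: str, fn):
        try:
            residue_sets[label] = fn()
        except Exception as exc:  # propagate with the region name attached
            raise RegionError(f"region {label!r}: {exc}") from exc

    run("FormI_LL_interface", lambda: cross_model_interface(
        query, form1_reference, set(config.form1_large_partner_chains),
        ordinal_pairing(query, form1_reference, config.query_chains,
                        config.form1_dimer_chains),
        config.cutoff))
    run("FormI_LS_interface", lambda: cross_model_interface(
        query, form1_reference, set(config.form1_small_partner_chains),
        ordinal_pairing(query, form1_reference, config.query_chains,
                        config.form1_dimer_chains),
        config.cutoff))
    run("FormIII_LL_interface", lambda: cross_model_interface(
        query, form3_reference, set(config.form3_partner_chains),
        ordinal_pairing(query, form3_reference, config.query_chains,
                        config.form3_dimer_chains),
        config.cutoff))
    run("dimer_interface", lambda: (
        interface_residues(query, query.residue_keys(qa), query.residue_keys(qb),
                           config.cutoff)
        | interface_residues(query, query.residue_keys(qb), query.residue_keys(qa),
                             config.cutoff)))

    sub_pairing = ordinal_pairing(
        query, subdomain_reference, config.query_chains, config.subdomain_chains
    )

    def subdomain(residues: list[int]) -> set[ResidueKey]:
        if not residues:
            return set()
        ref_keys = {
            (cid, i) for cid in config.subdomain_chains for i in residues
            if (cid, i) in subdomain_reference.residue_keys()
        }
        return subdomain_by_nearest_ca(query, subdomain_reference, ref_keys, sub_pairing)

    run("barrel_strands", lambda: subdomain(config.barrel_strand_residues))
    run("loop6", lambda: subdomain(config.loop6_residues))
    run("N_terminal", lambda: subdomain(config.n_terminal_residues))
    run("C_terminal", lambda: subdomain(config.c_terminal_residues))

    def near_barrel() -> set[ResidueKey]:
        core = residue_sets["barrel_strands"]
        if not core:
            return set()
        near = near_set(query, core, config.cutoff)
        if not config.near_barrel_excludes_core:
            near |= core
        return near

    run("near_barrel", near_barrel)

    regions = {label: _keys_to_columns(keys, column_maps)
               for label, keys in residue_sets.items()}
    provenance = {
        "cutoff_A": config.cutoff,
        "reference_row": reference_row,
        "query_chains": "".join(config.query_chains),
    }
    return RegionMap(regions, provenance)
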