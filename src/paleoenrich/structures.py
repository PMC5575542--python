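"""Structure models, superposition, and interface geometry.

Coordinates are read from PDB files via gemmi into a light residue/atom
container.  All distance rules operate on non-hydrogen ("heavy") atoms, with
a strict ``< cutoff`` inequality, matching the convention of defining
interface residues to include nonpolar contacts at 5 A.

Rigid-body superposition is the least-squares Kabsch solution (reflections
excluded), computed via :func:`scipy.spatial.transform.Rotation.align_vectors`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .alphabet import GAP, ONE_LETTER

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "SuperpositionResult",
    "read_structure",
    "write_pdb",
    "extract_dimer",
    "superimpose",
    "apply_transform",
    "interface_residues",
    "cross_model_interface",
    "subdomain_by_nearest_ca",
    "near_set",
    "map_residues_to_alignment",
    "ordinal_pairing",
    "MODIFIED_RESIDUE_PARENTS",
]

ResidueKey = tuple[str, int]

#: default modified-residue -> parent renames applied on reading
MODIFIED_RESIDUE_PARENTS: dict[str, str] = {
    "KCX": "LYS",  # carboxylated lysine (carbamate at the activated site)
    "MSE": "MET",  # selenomethionine
    "CSO": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
}

_HYDROGENS = {"H", "D"}


class FormatError(ValueError):
    """Unparseable coordinate file."""


class GeometryError(ValueError):
    """Superposition impossible (too few or collinear anchor points)."""


class MappingError(ValueError):
    """Structure sequence cannot be reconciled with the alignment row."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGENS


@dataclass
class Residue:
    chain_id: str
    index: int
    name: str
    atoms: list[Atom]

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.index)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.xyz for a in self.atoms if a.is_heavy]
        return np.array(pts) if pts else np.empty((0, 3))


class StructureModel:
    """Chains of residues with 3-D coordinates (Angstrom)."""

    def __init__(self, chains: dict[str, list[Residue]]):
        self.chains = chains
        self._index: dict[ResidueKey, Residue] = {}
        for cid, residues in chains.items():
            seen = set()
            for r in residues:
                if r.index in seen:
                    raise FormatError(f"duplicate residue {r.index} in chain {cid}")
                seen.add(r.index)
                self._index[(cid, r.index)] = r

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residue(self, key: ResidueKey) -> Residue:
        return self._index[key]

    def residue_keys(self, chain_id: str | None = None) -> set[ResidueKey]:
        if chain_id is None:
            return set(self._index)
        return {(chain_id, r.index) for r in self.chains[chain_id]}

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain; unknown residues become 'X'."""
        return "".join(
            ONE_LETTER.get(r.name, "X")
            for r in sorted(self.chains[chain_id], key=lambda r: r.index)
        )

    def heavy_atom_table(self, keys: set[ResidueKey]) -> tuple[np.ndarray, list[ResidueKey]]:
        """Stacked heavy-atom coordinates and the owning key of each row."""
        coords, owners = [], []
        for key in sorted(keys):
            pts = self._index[key].heavy_coords()
            coords.append(pts)
            owners.extend([key] * len(pts))
        stacked = np.vstack(coords) if coords else np.empty((0, 3))
        return stacked, owners

    def copy(self) -> "StructureModel":
        return StructureModel(
            {
                cid: [
                    Residue(r.chain_id, r.index, r.name,
                            [Atom(a.name, a.element, a.xyz.copy()) for a in r.atoms])
                    for r in residues
                ]
                for cid, residues in self.chains.items()
            }
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path,
    modified_parents: dict[str, str] | None = None,
) -> StructureModel:
    """Load the first model of a PDB file.

    HETATM ligands, ions and solvent are dropped, except residues listed in
    the modified-residue table, which are renamed to their parent residue and
    kept.
    """
    table = MODIFIED_RESIDUE_PARENTS if modified_parents is None else modified_parents
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    chains: dict[str, list[Residue]] = {}
    for chain in st[0]:
        residues = []
        for res in chain:
            is_atom_record = res.het_flag != "H"
            name = res.name
            if not is_atom_record:
                if name not in table:
                    continue  # ligand / ion / solvent
            name = table.get(name, name)
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in res
            ]
            residues.append(Residue(chain.name, res.seqid.num, name, atoms))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise FormatError(f"no polymer ATOM records in {path}")
    return StructureModel(chains)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    st = gemmi.Structure()
    st.name = "toy"
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.index, " ")
            res.het_flag = "A"
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*map(float, a.xyz))
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    doc_path = str(path)
    st.write_pdb(doc_path)


def extract_dimer(model: StructureModel, chain_ids: tuple[str, str]) -> StructureModel:
    """Restrict the model to the two named chains."""
    missing = [c for c in chain_ids if c not in model.chains]
    if missing:
        raise ValueError(f"chains not in structure: {missing}")
    return StructureModel({c: model.chains[c] for c in chain_ids}).copy()


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Rigid transform (x -> R x + t) minimizing CA RMSD over a pairing."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def transform(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def ordinal_pairing(
    mobile: StructureModel,
    reference: StructureModel,
    mobile_chains: tuple[str, str] | None = None,
    reference_chains: tuple[str, str] | None = None,
) -> list[tuple[ResidueKey, ResidueKey]]:
    """Position-by-position residue pairing between corresponding chains."""
    mc = mobile_chains or tuple(mobile.chain_ids[:2])
    rc = reference_chains or tuple(reference.chain_ids[:2])
    pairing = []
    for cm, cr in zip(mc, rc):
        a = sorted(mobile.chains[cm], key=lambda r: r.index)
        b = sorted(reference.chains[cr], key=lambda r: r.index)
        pairing.extend((ra.key, rb.key) for ra, rb in zip(a, b))
    return pairing


def superimpose(
    mobile: StructureModel,
    reference: StructureModel,
    residue_pairing: list[tuple[ResidueKey, ResidueKey]],
) -> SuperpositionResult:
    """Least-squares rigid superposition over paired CA atoms."""
    mob_pts, ref_pts = [], []
    for mk, rk in residue_pairing:
        ca_m = mobile.residue(mk).atom("CA")
        ca_r = reference.residue(rk).atom("CA")
        if ca_m is None or ca_r is None:
            continue
        mob_pts.append(ca_m.xyz)
        ref_pts.append(ca_r.xyz)
    if len(mob_pts) < 3:
        raise GeometryError("need at least 3 paired CA atoms")
    mob = np.array(mob_pts)
    ref = np.array(ref_pts)
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise GeometryError("anchor points are collinear")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=len(mob_pts))


def apply_transform(model: StructureModel, sup: SuperpositionResult) -> StructureModel:
    out = model.copy()
    for residues in out.chains.values():
        for r in residues:
            for a in r.atoms:
                a.xyz = sup.transform(a.xyz)
    return out


# ---------------------------------------------------------------------------
# distance rules
# ---------------------------------------------------------------------------

def _close_owners(
    model_a: StructureModel,
    keys_a: set[ResidueKey],
    model_b: StructureModel,
    keys_b: set[ResidueKey],
    cutoff: float,
) -> set[ResidueKey]:
    """Residues of side A with any heavy atom strictly within cutoff of side B."""
    pts_a, owners_a = model_a.heavy_atom_table(keys_a)
    pts_b, _ = model_b.heavy_atom_table(keys_b)
    if pts_a.size == 0 or pts_b.size == 0 or cutoff <= 0:
        return set()
    d2 = np.sum((pts_a[:, None, :] - pts_b[None, :, :]) ** 2, axis=2)
    near_rows = np.flatnonzero((d2 < cutoff**2).any(axis=1))
    return {owners_a[i] for i in near_rows}


def interface_residues(
    model: StructureModel,
    side_a: set[ResidueKey],
    side_b: set[ResidueKey],
    cutoff: float = 5.0,
) -> set[ResidueKey]:
    """Residues of ``side_a`` at the interface with ``side_b``.

    A residue qualifies iff any of its non-hydrogen atoms lies strictly
    within ``cutoff`` Angstrom of a non-hydrogen atom of the opposite side.
    """
    if side_a & side_b:
        raise ValueError("interface sides must be disjoint")
    return _close_owners(model, side_a, model, side_b, cutoff)


def cross_model_interface(
    query_dimer: StructureModel,
    reference_complex: StructureModel,
    reference_partner_chains: set[str],
    pairing: list[tuple[ResidueKey, ResidueKey]],
    cutoff: float = 5.0,
) -> set[ResidueKey]:
    """Query residues near partner chains of a reference complex.

    The query dimer is superimposed onto the reference's corresponding dimer
    (via the CA pairing), then its residues are tested against heavy atoms of
    the named partner chains of the reference (for example the small subunits
    or the neighboring large subunits of a larger assembly).
    """
    if not reference_partner_chains:
        return set()
    sup = superimpose(query_dimer, reference_complex, pairing)
    moved = apply_transform(query_dimer, sup)
    partner_keys = set()
    for cid in reference_partner_chains:
        partner_keys |= reference_complex.residue_keys(cid)
    return _close_owners(moved, moved.residue_keys(), reference_complex, partner_keys, cutoff)


def subdomain_by_nearest_ca(
    query: StructureModel,
    reference: StructureModel,
    reference_subdomain: set[ResidueKey],
    pairing: list[tuple[ResidueKey, ResidueKey]],
) -> set[ResidueKey]:
    """Transfer a reference subdomain to the query by nearest CA.

    After superposition, each reference subdomain residue selects the query
    residue with the closest CA; ties break to the lower (chain, index) key.
    Reference residues without a CA atom are skipped.
    """
    sup = superimpose(query, reference, pairing)
    moved = apply_transform(query, sup)
    q_keys = sorted(moved.residue_keys())
    q_ca = []
    q_valid = []
    for key in q_keys:
        ca = moved.residue(key).atom("CA")
        if ca is not None:
            q_ca.append(ca.xyz)
            q_valid.append(key)
    if not q_ca:
        raise GeometryError("query has no CA atoms")
    q_ca = np.array(q_ca)
    out: set[ResidueKey] = set()
    for key in sorted(reference_subdomain):
        res = reference.residue(key)
        ca = res.atom("CA")
        if ca is None:
            continue
        d2 = np.sum((q_ca - ca.xyz) ** 2, axis=1)
        # argmin returns the first (lowest sorted key) index on exact ties
        out.add(q_valid[int(np.argmin(d2))])
    return out


def near_set(
    model: StructureModel,
    core_residues: set[ResidueKey],
    cutoff: float = 5.0,
) -> set[ResidueKey]:
    """Residues (excluding the core itself) near the core by the heavy-atom rule."""
    if not core_residues:
        raise ValueError("core residue set is empty")
    others = model.residue_keys() - set(core_residues)
    return _close_owners(model, others, model, set(core_residues), cutoff)


# ---------------------------------------------------------------------------
# sequence <-> alignment mapping
# ---------------------------------------------------------------------------

def map_residues_to_alignment(
    structure_sequence: str,
    alignment_row: str,
    max_mismatch_fraction: float = 0.05,
) -> tuple[dict[int, int], list[int]]:
    """Map structure residue indices (1-based) to alignment columns (0-based).

    The ungapped alignment row must equal the structure sequence up to the
    allowed mismatch fraction.  Returns the mapping and the list of
    mismatched residue indices (mapped but flagged).
    """
    columns = [j for j, ch in enumerate(alignment_row) if ch != GAP]
    if not columns:
        raise MappingError("alignment row is all gaps")
    if len(columns) != len(structure_sequence):
        raise MappingError(
            f"structure has {len(structure_sequence)} residues but the row has "
            f"{len(columns)} non-gap columns"
        )
    mismatches = [
        i + 1
        for i, (s, a) in enumerate(
            zip(structure_sequence.upper(), (alignment_row[j].upper() for j in columns))
        )
        if s != a
    ]
    if len(mismatches) > max_mismatch_fraction * len(structure_sequence):
        raise MappingError(
            f"{len(mismatches)} mismatches exceed the allowed fraction "
            f"{max_mismatch_fraction:g}"
        )
    return {i + 1: col for i, col in enumerate(columns)}, mismatches
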