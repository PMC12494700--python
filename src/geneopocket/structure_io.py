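"""PDB complex parsing and per-atom physicochemical parameter assignment.

The reader implements a deliberately narrow dialect suited to prepared
single-model structures: fixed columns, ``ATOM``/``HETATM`` records, first
``MODEL`` only, waters dropped, alternate locations collapsed to the
highest-occupancy variant.  Each atom is then decorated with the scalars the
interaction-field channels consume: van der Waals radius, mass, partial
charge, signed lipophilic coefficient, polarity indicator, and hydrogen-bond
role with Lennard-Jones-style well parameters.  Bonds are inferred from
covalent radii so that donors know their hydrogens and antecedent heavy
atoms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .errors import (
    EmptyStructureError,
    NoChainNearLigandError,
    PDBParseError,
    UnknownElementError,
    UnknownLigandError,
)

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})

#: Residues never chosen as the ligand by AUTO selection: ions, buffer and
#: cryo-protectant molecules commonly co-crystallized with proteins.
ION_BUFFER_RESIDUES = frozenset({
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "CD",
    "SO4", "PO4", "GOL", "EDO", "PEG", "PG4", "ACT", "DMS", "MPD", "BME",
    "TRS", "FMT", "NO3", "IOD", "BR", "MES", "EPE", "CIT", "TLA", "ACE",
})

_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
}
_BOND_TOLERANCE = 0.4  # Å added to the covalent-radius sum


@dataclass(frozen=True)
class RawAtom:
    """One ATOM/HETATM record after dialect normalization."""

    record_kind: str          # "ATOM" or "HETATM"
    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: np.ndarray        # (3,) float64, Å
    element: str
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise PDBParseError(f"non-finite coordinates for atom serial {self.serial}")
        if not self.element:
            raise PDBParseError(f"empty element for atom serial {self.serial}")


@dataclass
class ParameterizedAtom:
    """Atom with every scalar the channel computations need."""

    coords: np.ndarray
    element: str
    vdw_radius: float
    mass: float
    charge: float
    lipo_coeff: float         # signed; negative part feeds the lipophilic channel
    polar: int                # 0/1
    hb_role: str              # none | acceptor | donor | both
    hb_eps: float
    hb_rmin: float
    donor_hydrogens: list[np.ndarray] = field(default_factory=list)
    antecedent: np.ndarray | None = None
    name: str = ""
    chain_id: str = ""
    residue_seq: int = 0
    residue_name: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_acceptor(self) -> bool:
        return self.hb_role in ("acceptor", "both")

    @property
    def is_donor(self) -> bool:
        return self.hb_role in ("donor", "both")


@dataclass
class ParameterizedStructure:
    """A protein/ligand pair ready for voxelization."""

    protein_atoms: list[ParameterizedAtom]
    ligand_atoms: list[ParameterizedAtom]
    provenance: dict = field(default_factory=dict)

    @property
    def ligand_heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms if not a.is_hydrogen],
                        dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _infer_element(name: str) -> str:
    # PDB atom-name columns 13-16: element is right-justified in 13-14.
    stripped = name.strip()
    if not stripped:
        return ""
    two = name[:2].strip().upper()
    if two in _COVALENT_RADII and not two.isdigit() and len(two) == 2 and two not in ("CA", "CD", "CE", "CZ", "CB", "CG", "NE", "ND", "NZ", "NH", "OD", "OE", "OG", "OH", "SD", "SG"):
        return two
    head = stripped.lstrip("0123456789")
    return head[:1].upper()


def parse_pdb(text: str) -> list[RawAtom]:
    """Read the first model's ATOM/HETATM records.

    Waters are dropped and alternate locations collapsed to the
    highest-occupancy variant (ties broken by file order).

    Raises
    ------
    PDBParseError
        On a malformed numeric field; the message names the line number.
    EmptyStructureError
        If no atoms survive.
    """
    atoms: list[RawAtom] = []
    in_model = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
            continue
        if rec == "ENDMDL":
            break
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated {rec} record")
        try:
            serial = int(line[6:11])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed numeric field ({exc})") from exc
        name = line[12:16]
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        try:
            resseq = int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed residue number") from exc
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(name)
        if not element:
            raise PDBParseError(f"line {lineno}: cannot infer element from name {name!r}")
        if resname in WATER_RESIDUES:
            continue
        atoms.append(RawAtom(rec, serial, name.strip(), resname, chain_id, resseq,
                             np.array([x, y, z]), element, occupancy, altloc))

    atoms = _collapse_altlocs(atoms)
    if not atoms:
        raise EmptyStructureError("no ATOM/HETATM records left after filtering")
    return atoms


def _collapse_altlocs(atoms: list[RawAtom]) -> list[RawAtom]:
    best: dict[tuple, int] = {}
    order: list[tuple] = []
    for i, a in enumerate(atoms):
        key = (a.chain_id, a.residue_seq, a.residue_name, a.name)
        if key not in best:
            best[key] = i
            order.append(key)
        elif atoms[i].occupancy > atoms[best[key]].occupancy:
            best[key] = i
    return [replace(atoms[best[k]], altloc="") for k in order]


def write_pdb(protein_atoms: Sequence, ligand_atoms: Sequence = (),
              ligand_resname: str = "LIG") -> str:
    """Serialize atoms back to fixed-column PDB text.

    Accepts RawAtom or ParameterizedAtom sequences; coordinates are written
    with the format's native 3-decimal precision.
    """
    out = io.StringIO()
    serial = 0

    def _emit(rec: str, a, resname: str, chain: str, resseq: int) -> None:
        nonlocal serial
        serial += 1
        name = getattr(a, "name", "") or a.element
        name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
        x, y, z = a.coords
        elem = a.element.rjust(2)
        out.write(f"{rec:<6s}{serial:>5d} {name_f}"
                  f" {resname:<3s} {chain}{resseq:>4d}    "
                  f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                  f"          {elem}\n")

    for a in protein_atoms:
        _emit("ATOM", a,
              getattr(a, "residue_name", "") or "GLY",
              getattr(a, "chain_id", "") or "A",
              getattr(a, "residue_seq", 0) or 1)
    if protein_atoms:
        out.write("TER\n")
    for a in ligand_atoms:
        _emit("HETATM", a,
              getattr(a, "residue_name", "") or ligand_resname,
              getattr(a, "chain_id", "") or "A",
              getattr(a, "residue_seq", 0) or 900)
    out.write("END\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Complex splitting and chain filtering
# ---------------------------------------------------------------------------

def split_complex(atoms: Sequence[RawAtom], ligand_selector: str = "AUTO",
                  ) -> tuple[list[RawAtom], list[RawAtom]]:
    """Partition a parsed complex into protein and ligand atoms.

    ``AUTO`` picks the HETATM residue instance with the most heavy atoms,
    skipping common ions/buffers.  An explicit residue name selects every
    residue with that name.
    """
    protein = [a for a in atoms if a.record_kind == "ATOM"]
    het = [a for a in atoms if a.record_kind == "HETATM"]

    if ligand_selector != "AUTO":
        ligand = [a for a in het if a.residue_name == ligand_selector]
        if not ligand:
            raise UnknownLigandError(f"no HETATM residue named {ligand_selector!r}")
        return protein, ligand

    groups: dict[tuple, list[RawAtom]] = {}
    order: list[tuple] = []
    for a in het:
        key = (a.chain_id, a.residue_seq, a.residue_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)

    best_key = None
    best_count = -1
    for key in order:
        if key[2] in ION_BUFFER_RESIDUES:
            continue
        heavy = sum(1 for a in groups[key] if a.element != "H")
        if heavy > best_count:
            best_count = heavy
            best_key = key
    if best_key is None:
        raise UnknownLigandError("AUTO ligand selection found no candidate HETATM residue")
    return protein, groups[best_key]


def filter_chains_near_ligand(protein_atoms: Sequence, ligand_atoms: Sequence,
                              cutoff: float = 10.0) -> list:
    """Keep exactly the chains with at least one atom within ``cutoff`` Å of
    any ligand atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not protein_atoms or not ligand_atoms:
        raise EmptyStructureError("need protein and ligand atoms for chain filtering")
    lig_xyz = np.array([a.coords for a in ligand_atoms])
    tree = cKDTree(lig_xyz)
    dmin, _ = tree.query(np.array([a.coords for a in protein_atoms]))
    kept_chains = {a.chain_id for a, d in zip(protein_atoms, dmin) if d <= cutoff}
    if not kept_chains:
        raise NoChainNearLigandError(
            f"no protein chain within {cutoff} Å of the ligand")
    return [a for a in protein_atoms if a.chain_id in kept_chains]


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

_REQUIRED_ELEMENTS = ("H", "C", "N", "O", "S", "P", "F", "CL", "BR", "I")

#: element -> (vdw radius Å, mass u, default charge e, lipophilic coefficient,
#:             HB role, epsilon, R_min Å)
_DEFAULT_TABLE: dict[str, tuple] = {
    "H":  (1.20, 1.008,   +0.15,  0.0, "none",     0.0, 0.0),
    "C":  (1.70, 12.011,   0.00, -1.0, "none",     0.0, 0.0),
    "N":  (1.55, 14.007,  -0.30, +1.0, "both",     1.0, 2.0),
    "O":  (1.52, 15.999,  -0.40, +1.0, "both",     1.0, 1.9),
    "S":  (1.80, 32.06,   -0.10, -1.0, "acceptor", 1.0, 2.0),
    "P":  (1.80, 30.974,  +0.20, +0.5, "none",     0.0, 0.0),
    "F":  (1.47, 18.998,  -0.10, -1.0, "none",     0.0, 0.0),
    "CL": (1.75, 35.45,   -0.10, -1.0, "none",     0.0, 0.0),
    "BR": (1.85, 79.904,  -0.10, -1.0, "none",     0.0, 0.0),
    "I":  (1.98, 126.904, -0.10, -1.0, "none",     0.0, 0.0),
    "SE": (1.90, 78.971,  -0.10, -1.0, "acceptor", 1.0, 2.2),
}


@dataclass(frozen=True)
class ElementParams:
    vdw_radius: float
    mass: float
    charge: float
    lipo_coeff: float
    hb_role: str
    hb_eps: float
    hb_rmin: float


class AtomParameterTable:
    """Per-element physicochemical parameters.

    The magnitudes are largely conventional: the per-protein min-max
    normalization of every channel removes any global scale, so only signs
    (lipophilic vs hydrophilic) and relative orderings matter.
    """

    def __init__(self, entries: Mapping[str, ElementParams]):
        entries = {k.upper(): v for k, v in entries.items()}
        missing = [e for e in _REQUIRED_ELEMENTS if e not in entries]
        if missing:
            raise UnknownElementError(
                f"parameter table missing required elements: {missing}")
        self._entries = dict(entries)

    def __contains__(self, element: str) -> bool:
        return element.upper() in self._entries

    def __getitem__(self, element: str) -> ElementParams:
        try:
            return self._entries[element.upper()]
        except KeyError:
            raise UnknownElementError(f"element {element!r} not in parameter table")

    @classmethod
    def default(cls) -> "AtomParameterTable":
        return cls({el: ElementParams(*vals) for el, vals in _DEFAULT_TABLE.items()})

    @classmethod
    def from_yaml(cls, source: str | Path) -> "AtomParameterTable":
        """Load a table from YAML: ``{EL: {vdw_radius: .., mass: .., ...}}``."""
        text = Path(source).read_text() if isinstance(source, Path) else source
        data = yaml.safe_load(text)
        entries = {}
        for el, row in data.items():
            entries[el.upper()] = ElementParams(
                vdw_radius=float(row["vdw_radius"]), mass=float(row["mass"]),
                charge=float(row.get("charge", 0.0)),
                lipo_coeff=float(row.get("lipo_coeff", 0.0)),
                hb_role=str(row.get("hb_role", "none")),
                hb_eps=float(row.get("hb_eps", 0.0)),
                hb_rmin=float(row.get("hb_rmin", 0.0)))
        return cls(entries)


def read_pqr_charges(text: str) -> dict[int, float]:
    """Parse a PQR-style sidecar, returning ``{serial: charge}``.

    PQR uses whitespace-separated columns with charge and radius replacing
    occupancy/B-factor.
    """
    charges: dict[int, float] = {}
    for line in text.splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        parts = line.split()
        charges[int(parts[1])] = float(parts[-2])
    return charges


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

def _infer_bonds(atoms: Sequence[RawAtom]) -> list[list[int]]:
    """Adjacency lists from covalent-radius sums + 0.4 Å tolerance."""
    n = len(atoms)
    adj: list[list[int]] = [[] for _ in range(n)]
    if n < 2:
        return adj
    xyz = np.array([a.coords for a in atoms])
    radii = np.array([_COVALENT_RADII.get(a.element.upper(), 0.8) for a in atoms])
    tree = cKDTree(xyz)
    max_bond = 2 * radii.max() + _BOND_TOLERANCE
    for i, j in tree.query_pairs(max_bond):
        d = np.linalg.norm(xyz[i] - xyz[j])
        if d <= radii[i] + radii[j] + _BOND_TOLERANCE and d > 1e-6:
            adj[i].append(j)
            adj[j].append(i)
    return adj


def assign_parameters(atoms: Sequence[RawAtom],
                      table: AtomParameterTable | None = None,
                      charges: Mapping[int, float] | None = None,
                      ) -> list[ParameterizedAtom]:
    """Decorate raw atoms with channel parameters.

    Bonds are inferred to locate donor hydrogens and antecedents; donors
    without a bonded hydrogen are demoted (both -> acceptor, donor -> none).
    Hydrogens inherit the lipophilic sign of their bonded heavy atom.
    Polarity is 1 for N and O, and for S carrying a hydrogen.

    ``charges`` (e.g. from a PQR sidecar, keyed by serial) override the
    table's per-element defaults.
    """
    if table is None:
        table = AtomParameterTable.default()
    unknown = [a.serial for a in atoms if a.element not in table]
    if unknown:
        raise UnknownElementError(
            f"elements not in parameter table for atom serials {unknown}")

    adj = _infer_bonds(atoms)
    out: list[ParameterizedAtom] = []
    for i, a in enumerate(atoms):
        p = table[a.element]
        elem = a.element.upper()
        neighbors = adj[i]
        h_neighbors = [j for j in neighbors if atoms[j].element.upper() == "H"]
        heavy_neighbors = [j for j in neighbors if atoms[j].element.upper() != "H"]

        lipo = p.lipo_coeff
        if elem == "H" and heavy_neighbors:
            j = min(heavy_neighbors,
                    key=lambda j: np.linalg.norm(atoms[j].coords - a.coords))
            lipo = table[atoms[j].element].lipo_coeff

        polar = 1 if elem in ("N", "O") or (elem == "S" and h_neighbors) else 0

        role = p.hb_role
        if role in ("donor", "both") and not h_neighbors:
            role = "acceptor" if role == "both" else "none"

        antecedent = None
        if heavy_neighbors:
            j = min(heavy_neighbors,
                    key=lambda j: np.linalg.norm(atoms[j].coords - a.coords))
            antecedent = atoms[j].coords.copy()

        charge = p.charge
        if charges is not None and a.serial in charges:
            charge = charges[a.serial]

        out.append(ParameterizedAtom(
            coords=a.coords.copy(), element=elem, vdw_radius=p.vdw_radius,
            mass=p.mass, charge=charge, lipo_coeff=lipo, polar=polar,
            hb_role=role, hb_eps=p.hb_eps, hb_rmin=p.hb_rmin,
            donor_hydrogens=[atoms[j].coords.copy() for j in h_neighbors],
            antecedent=antecedent, name=a.name, chain_id=a.chain_id,
            residue_seq=a.residue_seq, residue_name=a.residue_name))
    return out


def read_complex(source: str | Path, ligand: str = "AUTO",
                 chain_cutoff: float | None = 10.0,
                 table: AtomParameterTable | None = None,
                 pqr: str | None = None) -> ParameterizedStructure:
    """One-call pipeline: parse, split, optionally filter chains, assign
    parameters.

    ``source`` may be a path or PDB text; ``chain_cutoff=None`` disables the
    near-ligand chain filter.
    """
    path = None
    if isinstance(source, Path) or (len(str(source)) < 4096 and "\n" not in str(source)
                                    and Path(source).exists()):
        path = Path(source)
        text = path.read_text()
    else:
        text = str(source)
    atoms = parse_pdb(text)
    protein_raw, ligand_raw = split_complex(atoms, ligand)
    if chain_cutoff is not None and protein_raw and ligand_raw:
        protein_raw = filter_chains_near_ligand(protein_raw, ligand_raw, chain_cutoff)
    charges = read_pqr_charges(pqr) if pqr else None
    return ParameterizedStructure(
        protein_atoms=assign_parameters(protein_raw, table, charges),
        ligand_atoms=assign_parameters(ligand_raw, table, charges),
        provenance={"source": str(path) if path else "<text>",
                    "ligand": ligand_raw[0].residue_name if ligand_raw else None})
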