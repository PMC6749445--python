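"""Coordinate file I/O: PDB and mmCIF readers, a PDB writer, and the
hierarchical structure model (structure -> chain -> residue -> atom) used by
every analysis module.

Anisotropic displacement records (``ANISOU`` / ``atom_site_anisotrop``) are
attached to their atoms as symmetric 3x3 tensors in A^2. Deuterium is treated
as hydrogen throughout (element ``D`` == ``H``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueView",
    "StructureModel",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "select_class",
    "STANDARD_AMINO_ACIDS",
    "WATER_NAMES",
]

#: Residue names classified as polymer (standard amino acids + common variants).
STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "MSE", "SEC", "PYL",
    }
)

#: Residue names classified as solvent (including heavy water).
WATER_NAMES = frozenset({"HOH", "DOD", "WAT", "H2O", "D2O"})

#: Maximum C(i)-N(i+1) distance for a peptide link, in Angstrom.
PEPTIDE_BOND_CUTOFF = 2.0

_EIGHT_PI_SQ_OVER_3 = 8.0 * math.pi**2 / 3.0


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class AtomRecord:
    """One atom: identity, coordinates, occupancy, B factor, optional ADP."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0
    altloc: str = ""
    uij: Optional[np.ndarray] = None  # symmetric 3x3, A^2
    source: str = "observed"  # "observed" | "placed" (riding hydrogens)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_iso < 0.0:
            raise ValueError(f"negative b_iso {self.b_iso}")
        if self.uij is not None:
            self.uij = np.asarray(self.uij, dtype=float)
            if self.uij.shape != (3, 3):
                raise ValueError("uij must be a 3x3 tensor")
            b_eq = _EIGHT_PI_SQ_OVER_3 * float(np.trace(self.uij))
            if self.b_iso > 1e-6 and abs(b_eq - self.b_iso) > 0.01 * self.b_iso:
                warnings.warn(
                    f"B_eq from uij ({b_eq:.2f}) differs from b_iso "
                    f"({self.b_iso:.2f}) by >1% for atom {self.atom_name} "
                    f"{self.residue_name} {self.chain_id}{self.residue_number}",
                    stacklevel=2,
                )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def b_eq(self) -> Optional[float]:
        if self.uij is None:
            return None
        return _EIGHT_PI_SQ_OVER_3 * float(np.trace(self.uij))


@dataclass
class ResidueView:
    """Grouped atoms of one residue with name-based lookup and chain links."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    category: str = "ligand"  # polymer | ligand | solvent
    prev: Optional["ResidueView"] = field(default=None, repr=False)
    next: Optional["ResidueView"] = field(default=None, repr=False)

    @property
    def label(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}{icode}"

    def get(self, atom_name: str, altloc: Optional[str] = None) -> Optional[AtomRecord]:
        """First atom with *atom_name* (optionally restricted to one altloc)."""
        for atom in self.atoms:
            if atom.atom_name == atom_name:
                if altloc is None or atom.altloc in ("", altloc):
                    return atom
        return None

    def altlocs(self) -> list[str]:
        return sorted({a.altloc for a in self.atoms if a.altloc})

    def preferred_altloc(self) -> str:
        """Highest-total-occupancy altloc (ties broken lexicographically)."""
        locs = self.altlocs()
        if not locs:
            return ""
        totals = {
            loc: sum(a.occupancy for a in self.atoms if a.altloc == loc)
            for loc in locs
        }
        best = max(totals.values())
        return min(loc for loc, tot in totals.items() if tot >= best - 1e-9)

    def conformer(self, altloc: Optional[str] = None) -> dict[str, AtomRecord]:
        """Single-conformer atom map: blank-altloc atoms plus one altloc.

        The altloc defaults to the highest-occupancy one, implementing the
        one-conformer policy used by all geometry metrics.
        """
        if altloc is None:
            altloc = self.preferred_altloc()
        out: dict[str, AtomRecord] = {}
        for atom in self.atoms:
            if atom.altloc in ("", altloc) and atom.atom_name not in out:
                out[atom.atom_name] = atom
        return out

    def add_atom(self, atom: AtomRecord) -> None:
        self.atoms.append(atom)


@dataclass
class StructureModel:
    """A parsed structure: ordered chains of residues, classified by type."""

    entry_id: str
    chains: dict[str, list[ResidueView]] = field(default_factory=dict)

    def residues(self, category: Optional[str] = None) -> Iterator[ResidueView]:
        for residues in self.chains.values():
            for res in residues:
                if category is None or res.category == category:
                    yield res

    def atoms(self, category: Optional[str] = None) -> Iterator[AtomRecord]:
        for res in self.residues(category):
            yield from res.atoms

    def polymer_chains(self) -> dict[str, list[ResidueView]]:
        out: dict[str, list[ResidueView]] = {}
        for chain_id, residues in self.chains.items():
            polymer = [r for r in residues if r.category == "polymer"]
            if polymer:
                out[chain_id] = polymer
        return out

    def find_residue(
        self, chain_id: str, residue_number: int, insertion_code: str = ""
    ) -> Optional[ResidueView]:
        for res in self.chains.get(chain_id, []):
            if res.residue_number == residue_number and res.insertion_code == insertion_code:
                return res
        return None


def _classify(residue: ResidueView) -> str:
    name = residue.residue_name.upper()
    if name in WATER_NAMES:
        return "solvent"
    if name in STANDARD_AMINO_ACIDS:
        return "polymer"
    return "ligand"


def _link_polymer(model: StructureModel) -> None:
    """Set prev/next links where C(i)-N(i+1) <= 2.0 A."""
    for residues in model.chains.values():
        polymer = [r for r in residues if r.category == "polymer"]
        for left, right in zip(polymer, polymer[1:]):
            c = left.conformer().get("C")
            n = right.conformer().get("N")
            if c is None or n is None:
                continue
            if np.linalg.norm(c.position - n.position) <= PEPTIDE_BOND_CUTOFF:
                left.next = right
                right.prev = left


def _finalize(model: StructureModel) -> StructureModel:
    for res in model.residues():
        res.category = _classify(res)
    _link_polymer(model)
    return model


def _guess_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip()
    if residue_name.upper() in STANDARD_AMINO_ACIDS | WATER_NAMES:
        for char in name:
            if char.isalpha():
                return char.upper()
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


# ---------------------------------------------------------------------------
# PDB format
# ---------------------------------------------------------------------------

def _read_pdb(path: Path) -> StructureModel:
    model = StructureModel(entry_id=path.stem.upper())
    atom_index: dict[tuple, AtomRecord] = {}
    residue_index: dict[tuple, ResidueView] = {}

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6]
            if record == "HEADER" and len(line) >= 66:
                entry = line[62:66].strip()
                if entry:
                    model.entry_id = entry.upper()
            if record == "ENDMDL":
                break  # first model only
            if record not in ("ATOM  ", "HETATM", "ANISOU"):
                continue
            try:
                serial = line[6:11].strip()
                atom_name = line[12:16].strip()
                altloc = line[16].strip()
                residue_name = line[17:20].strip()
                chain_id = line[21].strip() or "A"
                residue_number = int(line[22:26])
                insertion_code = line[26].strip()
            except (ValueError, IndexError) as exc:
                raise StructureParseError(
                    f"{path}: malformed {record.strip()} record at line {lineno}"
                ) from exc
            key = (serial, atom_name, altloc, chain_id, residue_number, insertion_code)

            if record == "ANISOU":
                atom = atom_index.get(key)
                if atom is None:
                    warnings.warn(
                        f"{path}: ANISOU without matching ATOM at line {lineno}; dropped",
                        stacklevel=2,
                    )
                    continue
                try:
                    u = [float(line[28 + 7 * i : 35 + 7 * i]) * 1e-4 for i in range(6)]
                except ValueError as exc:
                    raise StructureParseError(
                        f"{path}: malformed ANISOU record at line {lineno}"
                    ) from exc
                atom.uij = _uij_matrix(u)
                continue

            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
                b_iso = float(line[60:66]) if line[60:66].strip() else 0.0
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}: malformed coordinate fields at line {lineno}"
                ) from exc
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _guess_element(atom_name, residue_name)

            atom = AtomRecord(
                chain_id=chain_id,
                residue_number=residue_number,
                insertion_code=insertion_code,
                residue_name=residue_name,
                atom_name=atom_name,
                element=element,
                position=np.array([x, y, z]),
                occupancy=min(max(occupancy, 0.0), 1.0),
                b_iso=max(b_iso, 0.0),
                altloc=altloc,
            )
            atom_index[key] = atom
            res_key = (chain_id, residue_number, insertion_code, residue_name)
            residue = residue_index.get(res_key)
            if residue is None:
                residue = ResidueView(chain_id, residue_number, insertion_code, residue_name)
                residue_index[res_key] = residue
                model.chains.setdefault(chain_id, []).append(residue)
            residue.add_atom(atom)

    if not residue_index:
        raise StructureParseError(f"{path}: no ATOM/HETATM records found")
    return _finalize(model)


def _uij_matrix(u6) -> np.ndarray:
    """Symmetric tensor from (U11, U22, U33, U12, U13, U23)."""
    u11, u22, u33, u12, u13, u23 = (float(v) for v in u6)
    return np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])


# ---------------------------------------------------------------------------
# mmCIF format (category parsing delegated to biotite's CIF reader)
# ---------------------------------------------------------------------------

def _cif_str_column(category, name: str, n: int, default: str = "") -> np.ndarray:
    if name not in category:
        return np.full(n, default, dtype=object)
    values = category[name].as_array(str)
    values = np.asarray(values, dtype=object)
    values[(values == "?") | (values == ".")] = default
    return values


def _read_mmcif(path: Path) -> StructureModel:
    from biotite.structure.io.pdbx import CIFFile

    try:
        cif = CIFFile.read(str(path))
    except Exception as exc:  # biotite raises several parse error types
        raise StructureParseError(f"{path}: mmCIF parse failure: {exc}") from exc
    block = next(iter(cif.values()), None)
    if block is None or "atom_site" not in block:
        raise StructureParseError(f"{path}: no atom_site category found")
    entry_id = next(iter(cif.keys()), path.stem).upper()

    site = block["atom_site"]
    n = site.row_count
    atom_id = _cif_str_column(site, "id", n)
    type_symbol = _cif_str_column(site, "type_symbol", n)
    atom_name = _cif_str_column(site, "auth_atom_id", n)
    if not atom_name.any():
        atom_name = _cif_str_column(site, "label_atom_id", n)
    altloc = _cif_str_column(site, "label_alt_id", n)
    residue_name = _cif_str_column(site, "auth_comp_id", n)
    if not residue_name.any():
        residue_name = _cif_str_column(site, "label_comp_id", n)
    chain_id = _cif_str_column(site, "auth_asym_id", n)
    if not chain_id.any():
        chain_id = _cif_str_column(site, "label_asym_id", n)
    seq_id = _cif_str_column(site, "auth_seq_id", n)
    if not seq_id.any():
        seq_id = _cif_str_column(site, "label_seq_id", n)
    icode = _cif_str_column(site, "pdbx_PDB_ins_code", n)
    xs = site["Cartn_x"].as_array(float)
    ys = site["Cartn_y"].as_array(float)
    zs = site["Cartn_z"].as_array(float)
    occ = (
        site["occupancy"].as_array(float)
        if "occupancy" in site
        else np.ones(n)
    )
    b_iso = (
        site["B_iso_or_equiv"].as_array(float)
        if "B_iso_or_equiv" in site
        else np.zeros(n)
    )
    model_num = _cif_str_column(site, "pdbx_PDB_model_num", n, default="1")
    first_model = model_num[0] if n else "1"

    aniso_by_id: dict[str, np.ndarray] = {}
    if "atom_site_anisotrop" in block:
        aniso = block["atom_site_anisotrop"]
        m = aniso.row_count
        ids = _cif_str_column(aniso, "id", m)
        comps = {}
        for label in ("U[1][1]", "U[2][2]", "U[3][3]", "U[1][2]", "U[1][3]", "U[2][3]"):
            if label in aniso:
                comps[label] = aniso[label].as_array(float)
        if len(comps) == 6:
            for i in range(m):
                aniso_by_id[str(ids[i])] = _uij_matrix(
                    [
                        comps["U[1][1]"][i],
                        comps["U[2][2]"][i],
                        comps["U[3][3]"][i],
                        comps["U[1][2]"][i],
                        comps["U[1][3]"][i],
                        comps["U[2][3]"][i],
                    ]
                )

    model = StructureModel(entry_id=entry_id)
    residue_index: dict[tuple, ResidueView] = {}
    matched_aniso = 0
    for i in range(n):
        if model_num[i] != first_model:
            continue
        name = str(residue_name[i])
        try:
            resnum = int(seq_id[i]) if seq_id[i] else 0
        except ValueError as exc:
            raise StructureParseError(
                f"{path}: non-integer auth_seq_id {seq_id[i]!r} in atom_site row {i + 1}"
            ) from exc
        atom = AtomRecord(
            chain_id=str(chain_id[i]) or "A",
            residue_number=resnum,
            insertion_code=str(icode[i]),
            residue_name=name,
            atom_name=str(atom_name[i]),
            element=str(type_symbol[i]).upper() or _guess_element(str(atom_name[i]), name),
            position=np.array([xs[i], ys[i], zs[i]]),
            occupancy=min(max(float(occ[i]), 0.0), 1.0),
            b_iso=max(float(b_iso[i]), 0.0),
            altloc=str(altloc[i]),
        )
        uij = aniso_by_id.get(str(atom_id[i]))
        if uij is not None:
            atom.uij = uij
            matched_aniso += 1
        res_key = (atom.chain_id, atom.residue_number, atom.insertion_code, name)
        residue = residue_index.get(res_key)
        if residue is None:
            residue = ResidueView(atom.chain_id, atom.residue_number, atom.insertion_code, name)
            residue_index[res_key] = residue
            model.chains.setdefault(atom.chain_id, []).append(residue)
        residue.add_atom(atom)

    if aniso_by_id and matched_aniso < len(aniso_by_id):
        warnings.warn(
            f"{path}: {len(aniso_by_id) - matched_aniso} atom_site_anisotrop rows "
            "without a matching atom_site id; dropped",
            stacklevel=2,
        )
    if not residue_index:
        raise StructureParseError(f"{path}: no atoms in first model")
    return _finalize(model)


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path : path to the coordinate file.
    format : ``pdb``, ``mmcif`` or ``auto`` (by file extension, falling back
        to content sniffing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".cif", ".mmcif"):
            fmt = "mmcif"
        elif suffix in (".pdb", ".ent"):
            fmt = "pdb"
        else:
            with open(path) as handle:
                head = handle.read(4096)
            fmt = "mmcif" if head.lstrip().startswith("data_") or "_atom_site." in head else "pdb"
    if fmt == "mmcif":
        return _read_mmcif(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unknown format {format!r}; use 'pdb', 'mmcif' or 'auto'")


def _pdb_atom_name(atom: AtomRecord) -> str:
    name = atom.atom_name
    if len(name) >= 4:
        return name[:4]
    if len(atom.element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def write_structure(model: StructureModel, path) -> None:
    """Write *model* as a PDB file, including ANISOU records where present."""
    lines: list[str] = []
    serial = 0
    for chain_id, residues in model.chains.items():
        for res in residues:
            record = "ATOM  " if res.category == "polymer" else "HETATM"
            for atom in res.atoms:
                serial += 1
                name = _pdb_atom_name(atom)
                lines.append(
                    f"{record}{serial:>5} {name}{atom.altloc or ' ':1}"
                    f"{atom.residue_name:>3} {chain_id:1}{atom.residue_number:>4}"
                    f"{atom.insertion_code or ' ':1}   "
                    f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.b_iso:6.2f}          "
                    f"{atom.element:>2}"
                )
                if atom.uij is not None:
                    u = atom.uij
                    vals = [u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2]]
                    fields = "".join(f"{int(round(v * 1e4)):>7}" for v in vals)
                    lines.append(
                        f"ANISOU{serial:>5} {name}{atom.altloc or ' ':1}"
                        f"{atom.residue_name:>3} {chain_id:1}{atom.residue_number:>4}"
                        f"{atom.insertion_code or ' ':1} {fields}      "
                        f"{atom.element:>2}"
                    )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def select_class(
    model: StructureModel, category: str, exclude_hydrogen: bool = True
) -> list[AtomRecord]:
    """Atoms of one class (``polymer``/``ligand``/``solvent``).

    Hydrogen *and* deuterium are excluded when *exclude_hydrogen* is true.
    ``protein`` is accepted as an alias for ``polymer``.
    """
    if category == "protein":
        category = "polymer"
    if category not in ("polymer", "ligand", "solvent"):
        raise ValueError(f"unknown class {category!r}")
    out = []
    for atom in model.atoms(category):
        if exclude_hydrogen and atom.is_hydrogen:
            continue
        out.append(atom)
    return out
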