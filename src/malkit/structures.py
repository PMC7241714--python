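"""Macromolecular structures and docked ligand poses.

A deliberately small coordinate model: an :class:`Atom` carries PDB v3
addressing (chain, residue number, atom name) plus Cartesian coordinates
in Å, a :class:`Structure` is an ordered collection of atoms, and a
:class:`LigandPose` is one docked (or crystallographic) conformation of a
small molecule in the *receptor frame* — poses are never re-superposed.

PDB content is parsed through :mod:`gemmi`; the multi-model pose, mol2 and
LeDock ``.dok`` dialects produced by docking programs are handled by thin
block readers on top of it (docking dialects bend the formats enough that
coordinates and scores are the only reliable payload).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import (
    AmbiguousAtomError,
    EmptyInputError,
    FormatError,
    MissingAtomError,
    MissingLigandError,
    UsageError,
)

__all__ = [
    "Atom",
    "Structure",
    "LigandPose",
    "read_structure",
    "get_atom",
    "extract_ligand",
    "read_poses",
    "write_structure",
    "write_poses",
]

#: Atom-name aliases seen across PDB-era files (``MG``/``MG2`` for the
#: divalent magnesium, deprotonated Nζ variants).
ATOM_NAME_ALIASES: dict[str, tuple[str, ...]] = {
    "MG": ("MG", "MG2"),
    "MG2": ("MG2", "MG"),
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class Atom:
    """One atom with PDB v3 addressing and coordinates in Å."""

    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    het: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        object.__setattr__(self, "position", pos)

    @property
    def address(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.name)


@dataclass
class Structure:
    """Ordered atom collection with unique (chain, resnum, name) addresses."""

    atoms: list[Atom]
    identifier: str = ""
    _index: dict[tuple[str, int, str], int] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self._index = {}
        for i, atom in enumerate(self.atoms):
            key = atom.address
            if key in self._index:
                raise AmbiguousAtomError(
                    f"duplicate atom address {key!r} in structure {self.identifier!r}"
                )
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass
class LigandPose:
    """One posed ligand conformation, in the receptor coordinate frame."""

    pose_id: int
    ligand_name: str
    atoms: list[Atom]
    docking_score: float | None = None

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError(
                f"pose {self.pose_id} of {self.ligand_name!r}: atom names not unique"
            )

    def atom(self, name: str) -> Atom:
        for candidate in ATOM_NAME_ALIASES.get(name, (name,)):
            for a in self.atoms:
                if a.name == candidate:
                    return a
        raise MissingAtomError(
            f"pose {self.pose_id} of {self.ligand_name!r} has no atom {name!r}"
        )

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def translated(self, shift) -> "LigandPose":
        shift = np.asarray(shift, dtype=float)
        return replace(
            self,
            atoms=[replace(a, position=a.position + shift) for a in self.atoms],
        )


def _check_coordinate_fields(text: str) -> None:
    # gemmi is forgiving about mangled coordinate columns; enforce the
    # fixed-width contract up front so errors carry a line number.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fragment = line[lo:hi].strip()
                try:
                    value = float(fragment)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: unparseable coordinate field {fragment!r}"
                    ) from None
                if not math.isfinite(value):
                    raise FormatError(f"line {lineno}: non-finite coordinate {fragment!r}")


def _atoms_from_gemmi_model(model: gemmi.Model) -> list[Atom]:
    atoms: list[Atom] = []
    seen: set[tuple[str, int, str]] = set()
    for chain in model:
        for residue in chain:
            for a in residue:
                if a.altloc not in ("\x00", "", "A"):
                    continue
                key = (chain.name, residue.seqid.num, a.name)
                if key in seen:  # first altloc wins
                    continue
                seen.add(key)
                element = a.element.name if a.element.name != "X" else a.name[:1]
                atoms.append(
                    Atom(
                        name=a.name,
                        element=element.upper(),
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        het=residue.het_flag == "H",
                    )
                )
    return atoms


def read_structure(text: str, identifier: str = "") -> Structure:
    """Parse PDB-format content into a :class:`Structure`.

    Only altloc blank/'A' atoms are kept (first occurrence wins); insertion
    codes are tolerated. Raises :class:`FormatError` naming the offending
    line for a malformed coordinate field and :class:`EmptyInputError` when
    no ATOM/HETATM record survives parsing.
    """
    _check_coordinate_fields(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"PDB parse failure: {exc}") from exc
    if len(st) == 0:
        raise EmptyInputError("no ATOM/HETATM records in input")
    atoms = _atoms_from_gemmi_model(st[0])
    if not atoms:
        raise EmptyInputError("no ATOM/HETATM records in input")
    return Structure(atoms=atoms, identifier=identifier or st.name or "")


def get_atom(structure: Structure, chain: str, residue_number: int, atom_name: str) -> Atom:
    """Return the unique atom at (chain, residue_number, atom_name).

    The small alias table in :data:`ATOM_NAME_ALIASES` absorbs common
    naming variants (``MG`` vs ``MG2``). Raises :class:`MissingAtomError`
    naming the full address when nothing matches.
    """
    for candidate in ATOM_NAME_ALIASES.get(atom_name, (atom_name,)):
        idx = structure._index.get((chain, residue_number, candidate))
        if idx is not None:
            return structure.atoms[idx]
    raise MissingAtomError(
        f"no atom {atom_name!r} in residue {residue_number} of chain {chain!r}"
        f" (structure {structure.identifier!r})"
    )


def extract_ligand(structure: Structure, residue_name: str, chain: str | None = None) -> LigandPose:
    """Isolate a HETATM residue as a :class:`LigandPose` (receptor untouched).

    Water residues are never returned. When the residue occurs in several
    chains, ``chain`` selects the copy.
    """
    if residue_name.upper() in _WATER_NAMES:
        raise MissingLigandError(f"{residue_name!r} is a water residue, not a ligand")
    matches = [
        a
        for a in structure.atoms
        if a.residue_name == residue_name
        and a.het
        and (chain is None or a.chain_id == chain)
    ]
    if not matches:
        where = f" in chain {chain!r}" if chain else ""
        raise MissingLigandError(
            f"no HETATM residue {residue_name!r}{where} in structure"
            f" {structure.identifier!r}"
        )
    chains = {a.chain_id for a in matches}
    if len(chains) > 1:
        raise AmbiguousAtomError(
            f"residue {residue_name!r} occurs in chains {sorted(chains)}; pass chain="
        )
    return LigandPose(pose_id=0, ligand_name=residue_name, atoms=matches)


# --- pose-file dialects -----------------------------------------------------

_SCORE_RE = re.compile(
    r"(?:score|affinity|vina\s+result)\s*[:=]?\s*(-?\d+(?:\.\d+)?)", re.IGNORECASE
)


def _score_from_lines(lines: list[str]) -> float | None:
    for line in lines:
        m = _SCORE_RE.search(line)
        if m:
            return float(m.group(1))
    return None


def _pose_from_pdb_block(
    block: list[str], pose_id: int, ligand_name: str | None
) -> LigandPose:
    body = "\n".join(block) + "\nEND\n"
    st = read_structure(body)
    name = ligand_name or st.atoms[0].residue_name
    return LigandPose(
        pose_id=pose_id,
        ligand_name=name,
        atoms=list(st.atoms),
        docking_score=_score_from_lines(block),
    )


def _read_pdb_multi_model(text: str) -> list[LigandPose]:
    poses: list[LigandPose] = []
    block: list[str] = []
    model_no: int | None = None
    saw_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            block, model_no = [], int(line.split()[1])
        elif rec == "ENDMDL":
            if block:
                poses.append(_pose_from_pdb_block(block, model_no or len(poses) + 1, None))
            block = []
        elif rec in ("ATOM", "HETATM", "REMARK"):
            block.append(line)
    if block and not saw_model:  # single-model file without MODEL cards
        poses.append(_pose_from_pdb_block(block, 1, None))
    return poses


def _read_mol2(text: str) -> list[LigandPose]:
    poses: list[LigandPose] = []
    blocks = re.split(r"@<TRIPOS>MOLECULE", text)[1:]
    for i, block in enumerate(blocks, start=1):
        lines = block.splitlines()
        header = [ln for ln in lines if not ln.startswith("@<TRIPOS>")]
        mol_name = header[1].strip() if len(header) > 1 and header[1].strip() else f"LIG"
        atoms: list[Atom] = []
        in_atoms = False
        for lineno, line in enumerate(lines):
            if line.startswith("@<TRIPOS>ATOM"):
                in_atoms = True
                continue
            if line.startswith("@<TRIPOS>"):
                in_atoms = False
                continue
            if in_atoms and line.strip():
                parts = line.split()
                if len(parts) < 6:
                    raise FormatError(f"mol2 ATOM line too short: {line!r}")
                try:
                    xyz = [float(parts[2]), float(parts[3]), float(parts[4])]
                except ValueError:
                    raise FormatError(
                        f"mol2 block {i}: unparseable coordinate in {line!r}"
                    ) from None
                sybyl = parts[5]
                atoms.append(
                    Atom(
                        name=parts[1],
                        element=sybyl.split(".")[0].upper(),
                        residue_name=(parts[7] if len(parts) > 7 else mol_name)[:3].upper(),
                        residue_number=int(parts[6]) if len(parts) > 6 else 1,
                        chain_id="X",
                        position=np.array(xyz),
                        het=True,
                    )
                )
        if atoms:
            poses.append(
                LigandPose(
                    pose_id=i,
                    ligand_name=mol_name.split()[0],
                    atoms=atoms,
                    docking_score=_score_from_lines(header[:2] + header[2:4]),
                )
            )
    return poses


def _read_dok(text: str) -> list[LigandPose]:
    """LeDock .dok output: PDB-ish ATOM blocks separated by END, score in REMARK."""
    poses: list[LigandPose] = []
    block: list[str] = []
    for line in text.splitlines():
        if line.startswith("END"):
            if any(ln.startswith(("ATOM", "HETATM")) for ln in block):
                poses.append(_pose_from_pdb_block(block, len(poses) + 1, None))
            block = []
        else:
            block.append(line)
    if any(ln.startswith(("ATOM", "HETATM")) for ln in block):
        poses.append(_pose_from_pdb_block(block, len(poses) + 1, None))
    return poses


_DIALECTS = {
    "pdb-multi-model": _read_pdb_multi_model,
    "mol2": _read_mol2,
    "dok": _read_dok,
}


def read_poses(text: str, dialect: str) -> list[LigandPose]:
    """Read a docking pose file in an explicitly declared dialect.

    Dialects: ``pdb-multi-model`` (MODEL/ENDMDL blocks), ``mol2``
    (@<TRIPOS>MOLECULE blocks), ``dok`` (LeDock output). There is no
    format sniffing. Scores are captured from block headers/REMARKs when
    present, otherwise left unset.
    """
    try:
        reader = _DIALECTS[dialect]
    except KeyError:
        raise UsageError(
            f"unknown pose dialect {dialect!r}; choose from {sorted(_DIALECTS)}"
        ) from None
    poses = reader(text)
    if not poses:
        raise EmptyInputError(f"no poses parsed from {dialect} input")
    return poses


# --- writers ----------------------------------------------------------------

def _pdb_atom_line(serial: int, atom: Atom) -> str:
    record = "HETATM" if atom.het else "ATOM  "
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    x, y, z = atom.position
    return (
        f"{record}{serial:>5d} {name:<4s}{atom.residue_name:>4s} "
        f"{atom.chain_id:1s}{atom.residue_number:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}"
    )


def write_structure(structure: Structure) -> str:
    """Serialize to PDB text (fixed-width, coordinates to 3 decimals)."""
    lines = [_pdb_atom_line(i, a) for i, a in enumerate(structure.atoms, start=1)]
    return "\n".join(lines) + "\nEND\n"


def write_poses(poses: list[LigandPose]) -> str:
    """Serialize poses as a multi-model PDB with scores in REMARK lines."""
    lines: list[str] = []
    for pose in poses:
        lines.append(f"MODEL {pose.pose_id:>8d}")
        if pose.docking_score is not None:
            lines.append(f"REMARK SCORE: {pose.docking_score:.3f}")
        lines.extend(_pdb_atom_line(i, a) for i, a in enumerate(pose.atoms, start=1))
        lines.append("ENDMDL")
    return "\n".join(lines) + "\nEND\n"
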