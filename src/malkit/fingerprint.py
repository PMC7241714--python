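"""Simplified protein–ligand interaction fingerprints.

Atomic contacts between pocket residues and a ligand pose are classified
into a reduced category set — hydrogen bond, ionic, hydrophobic, proximal
— by distance (and, when explicit hydrogens are present, a donor angle
term). This is a deliberately coarse scheme in the spirit of richer
contact-typing tools: categories are mutually exclusive per atom pair with
precedence hydrogen_bond > ionic > hydrophobic > proximal, and a
fingerprint is the *set* of (residue, category) pairs, so repeated
contacts of one kind with one residue collapse to a single entry.

Charge assignment is a residue/atom-name lookup (Asp/Glu carboxylates and
ligand carboxylates negative; Lys Nζ, Arg guanidinium, ligand amino groups
and the catalytic Mg²⁺ positive; His ε/δ nitrogens positive behind an
optional flag) — there is no pKa model. Water-mediated contacts are out of
scope; a residue that only touches the ligand through water shows up as
proximal at best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .structures import Atom, LigandPose, Structure
from .templates import LigandTemplate

__all__ = [
    "ContactRule",
    "ContactRules",
    "Fingerprint",
    "FingerprintComparison",
    "compute_fingerprint",
    "compare_fingerprints",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}

_NEGATIVE_RECEPTOR = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_POSITIVE_RECEPTOR = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
}
_HIS_NITROGEN = {("HIS", "ND1"), ("HIS", "NE2")}
# carbons that belong to polar/charged groups and never count as apolar
_POLAR_CARBONS = {
    ("ASP", "CG"), ("GLU", "CD"), ("ASN", "CG"), ("GLN", "CD"), ("ARG", "CZ"),
}


@dataclass(frozen=True)
class ContactRule:
    """One contact category with its geometric thresholds."""

    category: str
    distance_max: float
    angle_min: float | None = None  # degrees; hydrogen bonds only

    def __post_init__(self) -> None:
        if self.distance_max <= 0:
            raise ConfigError(f"{self.category}: distance_max must be positive")


@dataclass(frozen=True)
class ContactRules:
    """The rule set, in precedence order. Defaults are package-defined."""

    hydrogen_bond: ContactRule = ContactRule("hydrogen_bond", 3.5, angle_min=120.0)
    ionic: ContactRule = ContactRule("ionic", 4.0)
    hydrophobic: ContactRule = ContactRule("hydrophobic", 4.5)
    proximal: ContactRule = ContactRule("proximal", 5.0)
    his_charged: bool = False

    @property
    def max_distance(self) -> float:
        return max(
            r.distance_max
            for r in (self.hydrogen_bond, self.ionic, self.hydrophobic, self.proximal)
        )


@dataclass(frozen=True)
class Fingerprint:
    """Set of (residue label, category) pairs plus per-contact distances."""

    contacts: frozenset[tuple[str, str]]
    min_distances: dict = field(default_factory=dict, hash=False, compare=False)

    def __contains__(self, item) -> bool:
        return item in self.contacts

    def __len__(self) -> int:
        return len(self.contacts)

    def residues(self) -> set[str]:
        return {res for res, _ in self.contacts}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"residue": res, "category": cat, "min_distance": self.min_distances.get((res, cat))}
            for res, cat in sorted(self.contacts)
        ]
        return pd.DataFrame(rows, columns=["residue", "category", "min_distance"])


@dataclass(frozen=True)
class FingerprintComparison:
    shared: frozenset[tuple[str, str]]
    only_a: frozenset[tuple[str, str]]
    only_b: frozenset[tuple[str, str]]
    jaccard: float

    def to_dict(self) -> dict:
        return {
            "shared": sorted(map(list, self.shared)),
            "only_a": sorted(map(list, self.only_a)),
            "only_b": sorted(map(list, self.only_b)),
            "jaccard": self.jaccard,
        }


def _residue_label(atom: Atom) -> str:
    one = _THREE_TO_ONE.get(atom.residue_name)
    if one is None:
        return f"{atom.residue_name}{atom.residue_number}"
    return f"{one}{atom.residue_number}"


def _is_polar(atom: Atom) -> bool:
    return atom.element in ("N", "O")


def _receptor_charge(atom: Atom, rules: ContactRules) -> int:
    key = (atom.residue_name, atom.name)
    if key in _NEGATIVE_RECEPTOR:
        return -1
    if key in _POSITIVE_RECEPTOR:
        return +1
    if rules.his_charged and key in _HIS_NITROGEN:
        return +1
    if atom.element == "MG":
        return +2
    return 0


def _receptor_apolar_carbon(atom: Atom) -> bool:
    if atom.element != "C" or atom.name == "C":  # backbone carbonyl excluded
        return False
    return (atom.residue_name, atom.name) not in _POLAR_CARBONS


def _ligand_classes(template: LigandTemplate | None):
    carboxyl_c: set[str] = set()
    carboxyl_o: set[str] = set()
    amino_n: set[str] = set()
    apolar: set[str] = set()
    if template is not None:
        for g in template.carboxyl_groups:
            carboxyl_c.add(g.carbon)
            carboxyl_o.update((g.oxygen1, g.oxygen2))
        amino_n.update(template.amino_nitrogens)
        apolar.update(template.hydrophobic_carbons)
    return carboxyl_c, carboxyl_o, amino_n, apolar


def _hydrogens_near(atoms: list[Atom], donor: Atom, limit: float = 1.3) -> list[Atom]:
    return [
        h
        for h in atoms
        if h.element == "H"
        and np.linalg.norm(h.position - donor.position) <= limit
    ]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b (degrees) of the a–b–c triple."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def compute_fingerprint(
    receptor: Structure,
    pose: LigandPose,
    pocket_residues: list[tuple[str, int]],
    template: LigandTemplate | None = None,
    rules: ContactRules | None = None,
) -> Fingerprint:
    """Classify pocket-residue/ligand contacts into the reduced categories.

    ``pocket_residues`` is a list of (chain, residue number) addresses; the
    catalytic Mg²⁺ may be included as a pocket "residue". For every atom
    pair within the largest rule distance the highest-precedence satisfied
    rule contributes one (residue, category) pair. Hydrogen bonds use the
    D–H…A angle when explicit hydrogens ride the donor, and fall back to a
    distance-only criterion otherwise. Raises :class:`ConfigError` for a
    pocket address that resolves to nothing.
    """
    rules = rules or ContactRules()
    carboxyl_c, carboxyl_o, amino_n, apolar_lig = _ligand_classes(template)

    by_residue: dict[tuple[str, int], list[Atom]] = {}
    for atom in receptor.atoms:
        by_residue.setdefault((atom.chain_id, atom.residue_number), []).append(atom)
    for address in pocket_residues:
        if tuple(address) not in by_residue:
            raise ConfigError(f"pocket residue {address!r} not found in receptor")

    contacts: dict[tuple[str, str], float] = {}
    lig_atoms = [a for a in pose.atoms if a.element != "H"]
    for address in pocket_residues:
        res_atoms = by_residue[tuple(address)]
        heavy = [a for a in res_atoms if a.element != "H"]
        for ra in heavy:
            for la in lig_atoms:
                d = float(np.linalg.norm(ra.position - la.position))
                if d > rules.max_distance:
                    continue
                category = _classify_pair(
                    ra, la, d, res_atoms, pose.atoms, rules,
                    carboxyl_o, amino_n, apolar_lig,
                )
                if category is None:
                    continue
                key = (_residue_label(ra), category)
                if key not in contacts or d < contacts[key]:
                    contacts[key] = d
    return Fingerprint(contacts=frozenset(contacts), min_distances=dict(contacts))


def _classify_pair(
    ra: Atom,
    la: Atom,
    d: float,
    res_atoms: list[Atom],
    pose_atoms: list[Atom],
    rules: ContactRules,
    carboxyl_o: set[str],
    amino_n: set[str],
    apolar_lig: set[str],
) -> str | None:
    # hydrogen bond: N/O on both sides
    if d <= rules.hydrogen_bond.distance_max and _is_polar(ra) and _is_polar(la):
        if _hbond_geometry_ok(ra, la, res_atoms, pose_atoms, rules):
            return "hydrogen_bond"
    # ionic: oppositely charged group atoms
    if d <= rules.ionic.distance_max:
        rq = _receptor_charge(ra, rules)
        lq = (-1 if la.name in carboxyl_o else 0) + (+1 if la.name in amino_n else 0)
        if rq * lq < 0:
            return "ionic"
    # hydrophobic: apolar carbons on both sides
    if (
        d <= rules.hydrophobic.distance_max
        and _receptor_apolar_carbon(ra)
        and la.name in apolar_lig
    ):
        return "hydrophobic"
    if d <= rules.proximal.distance_max:
        return "proximal"
    return None


def _hbond_geometry_ok(
    ra: Atom, la: Atom, res_atoms: list[Atom], pose_atoms: list[Atom], rules: ContactRules
) -> bool:
    if rules.hydrogen_bond.angle_min is None:
        return True
    hydrogens = _hydrogens_near(res_atoms, ra) + _hydrogens_near(list(pose_atoms), la)
    if not hydrogens:
        return True  # no explicit hydrogens: distance-only criterion
    donors = [(ra, la, h) for h in _hydrogens_near(res_atoms, ra)] + [
        (la, ra, h) for h in _hydrogens_near(list(pose_atoms), la)
    ]
    if not donors:
        return True
    return any(
        _angle(donor.position, h.position, acceptor.position)
        >= rules.hydrogen_bond.angle_min
        for donor, acceptor, h in donors
    )


def compare_fingerprints(a: Fingerprint, b: Fingerprint) -> FingerprintComparison:
    """Exact set algebra between two fingerprints.

    The Jaccard index is |a∩b| / |a∪b|, defined as 1.0 when both
    fingerprints are empty.
    """
    sa, sb = set(a.contacts), set(b.contacts)
    union = sa | sb
    shared = sa & sb
    jaccard = 1.0 if not union else len(shared) / len(union)
    return FingerprintComparison(
        shared=frozenset(shared),
        only_a=frozenset(sa - sb),
        only_b=frozenset(sb - sa),
        jaccard=jaccard,
    )
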