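"""Two-criterion docking-pose triage in the MAL catalytic pocket.

A pose is judged first by four anchor distances measured against catalytic
residues of the receptor — the Nζ of the catalytic lysine (K331) to the
proton-abstraction carbon, and the Mg-oriented carboxylate oxygens to the
glutamine amide nitrogen (Q329), the histidine ε-nitrogen (H194) and the
catalytic Mg²⁺ — and second by the positional RMSD of a six-atom common
scaffold against the crystallographic natural-substrate pose.

Conventions that matter:

* Carboxylate oxygens are chemically equivalent, so each oxygen-based
  distance is the minimum over the two oxygens, and the scaffold RMSD is
  minimized over the in-group oxygen swap and (for dicarboxylic ligands)
  over which carboxylate plays the Mg-oriented role.
* A pose is "inside the pocket" when at least ``min_pass`` (default 3) of
  the four distances are strictly below ``cutoff`` (default 4 Å). With the
  reference geometry (4.16, 3.08, 2.75, 2.2 Å) the crystal substrate
  itself scores 3 of 4 — the lysine distance sits just above the cutoff —
  which is exactly why the rule demands three, not four.
* RMSD is positional: poses and reference share the receptor frame and are
  never superposed before comparison.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import MissingAtomError, UsageError
from .structures import Atom, LigandPose, Structure, get_atom
from .templates import LigandTemplate

__all__ = [
    "PocketAnchors",
    "DistanceSet",
    "TriageResult",
    "TriageReport",
    "anchors_from_structure",
    "measure_distances",
    "pose_in_pocket",
    "scaffold_rmsd",
    "select_pose",
    "percent_in_pocket",
    "triage_ligand",
]

#: Anchor distances of the crystal substrate in the reference structure, Å:
#: K331 Nζ–C3, Q329 amide N–O, H194 εN–O, Mg–O.
REFERENCE_DISTANCES = (4.16, 3.08, 2.75, 2.2)


@dataclass(frozen=True)
class PocketAnchors:
    """The four pocket anchor atoms plus the pass/fail policy."""

    k331_nz: Atom
    q329_amide_n: Atom
    h194_eps_n: Atom
    mg: Atom
    cutoff: float = 4.0
    min_pass: int = 3
    reference_distances: tuple[float, float, float, float] = REFERENCE_DISTANCES

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise UsageError("cutoff must be positive")
        if not 1 <= self.min_pass <= 4:
            raise UsageError("min_pass must be between 1 and 4")


@dataclass(frozen=True)
class DistanceSet:
    """The four measured anchor distances (Å) for one pose."""

    d_k331_c3: float
    d_q329_o: float
    d_h194_o: float
    d_mg_o: float
    carboxyl_choice: int = 0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.d_k331_c3, self.d_q329_o, self.d_h194_o, self.d_mg_o)


@dataclass(frozen=True)
class TriageResult:
    pose_id: int
    distances: DistanceSet
    n_below_cutoff: int
    in_pocket: bool
    scaffold_rmsd: float
    mapping_used: dict
    docking_score: float | None = None


@dataclass
class TriageReport:
    """All per-pose results plus the selection and pocket statistics."""

    ligand_name: str
    results: list[TriageResult]
    selected: TriageResult | None
    percent_in_pocket: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            d = r.distances
            rows.append(
                {
                    "pose_id": r.pose_id,
                    "d_k331_c3": d.d_k331_c3,
                    "d_q329_o": d.d_q329_o,
                    "d_h194_o": d.d_h194_o,
                    "d_mg_o": d.d_mg_o,
                    "carboxyl_choice": d.carboxyl_choice,
                    "n_below_cutoff": r.n_below_cutoff,
                    "in_pocket": r.in_pocket,
                    "scaffold_rmsd": r.scaffold_rmsd,
                    "mapping": json.dumps(r.mapping_used, sort_keys=True),
                    "docking_score": r.docking_score,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "ligand": self.ligand_name,
            "n_poses": len(self.results),
            "percent_in_pocket": self.percent_in_pocket,
            "selected_pose_id": None if self.selected is None else self.selected.pose_id,
            "selected_rmsd": None if self.selected is None else self.selected.scaffold_rmsd,
        }


def anchors_from_structure(
    receptor: Structure,
    chain: str = "B",
    lys_residue: int = 331,
    gln_residue: int = 329,
    his_residue: int = 194,
    mg_chain: str | None = None,
    cutoff: float = 4.0,
    min_pass: int = 3,
) -> PocketAnchors:
    """Resolve the four anchors on a receptor by their canonical addresses.

    The Mg²⁺ ion rarely keeps a predictable residue number across files,
    so it is located as the first magnesium HETATM in the requested chain.
    """
    k = get_atom(receptor, chain, lys_residue, "NZ")
    q = get_atom(receptor, chain, gln_residue, "NE2")
    h = get_atom(receptor, chain, his_residue, "NE2")
    mg_chain = mg_chain or chain
    mg = next(
        (a for a in receptor.atoms if a.element == "MG" and a.chain_id == mg_chain),
        None,
    )
    if mg is None:
        raise MissingAtomError(f"no magnesium ion in chain {mg_chain!r}")
    return PocketAnchors(k, q, h, mg, cutoff=cutoff, min_pass=min_pass)


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def measure_distances(
    pose: LigandPose, template: LigandTemplate, anchors: PocketAnchors
) -> DistanceSet:
    """Measure the four anchor distances for one pose.

    Each oxygen-based distance takes the shorter of the two carboxylate
    oxygens; for dicarboxylic ligands the carboxylate whose carbon lies
    nearer the Mg²⁺ anchor supplies the oxygens and the abstraction carbon,
    and the choice is recorded.
    """
    mg_pos = anchors.mg.position
    carbons = template.resolve(
        pose, tuple(g.carbon for g in template.carboxyl_groups)
    )
    choice = min(
        range(len(carbons)), key=lambda i: _dist(carbons[i].position, mg_pos)
    )
    group = template.carboxyl_groups[choice]
    o1, o2 = template.resolve(pose, (group.oxygen1, group.oxygen2))
    c3 = template.resolve(pose, (template.abstraction_carbons[choice],))[0]

    def min_o(anchor: Atom) -> float:
        return min(_dist(o1.position, anchor.position), _dist(o2.position, anchor.position))

    return DistanceSet(
        d_k331_c3=_dist(c3.position, anchors.k331_nz.position),
        d_q329_o=min_o(anchors.q329_amide_n),
        d_h194_o=min_o(anchors.h194_eps_n),
        d_mg_o=min_o(anchors.mg),
        carboxyl_choice=choice,
    )


def pose_in_pocket(distances: DistanceSet, anchors: PocketAnchors) -> tuple[int, bool]:
    """Count distances strictly below the cutoff and apply the ≥min_pass rule."""
    n = sum(1 for d in distances.as_tuple() if d < anchors.cutoff)
    return n, n >= anchors.min_pass


def scaffold_rmsd(
    pose: LigandPose,
    reference: LigandPose,
    template: LigandTemplate,
    reference_template: LigandTemplate | None = None,
) -> tuple[float, dict]:
    """Symmetry-aware positional RMSD over the six common scaffold atoms.

    No superposition is performed. The RMSD is minimized over the pose's
    and the reference's carboxylate choices and over the oxygen-pair
    permutation within the matched carboxylates; the minimizing mapping is
    returned as a descriptor.
    """
    ref_template = reference_template or template
    best: tuple[float, dict] | None = None
    for pc in range(len(template.carboxyl_groups)):
        pose_xyz = np.array(
            [a.position for a in template.resolve(pose, template.scaffold_labels(pc))]
        )
        for rc in range(len(ref_template.carboxyl_groups)):
            ref_xyz = np.array(
                [
                    a.position
                    for a in ref_template.resolve(
                        reference, ref_template.scaffold_labels(rc)
                    )
                ]
            )
            for swap in (False, True):
                p = pose_xyz.copy()
                if swap:
                    p[[1, 2]] = p[[2, 1]]
                rmsd = float(np.sqrt(np.mean(np.sum((p - ref_xyz) ** 2, axis=1))))
                mapping = {
                    "pose_carboxyl": pc,
                    "reference_carboxyl": rc,
                    "oxygen_swap": swap,
                }
                if best is None or rmsd < best[0]:
                    best = (rmsd, mapping)
    assert best is not None
    return best


def select_pose(results: list[TriageResult]) -> TriageResult | None:
    """Pick the in-pocket pose with the lowest scaffold RMSD.

    Ties go to the better (lower) docking score, then the lower pose id.
    Returns ``None`` — an explicit no-selection outcome, not an error —
    when no pose is inside the pocket.
    """
    if not results:
        raise UsageError("select_pose needs at least one triage result")
    candidates = [r for r in results if r.in_pocket]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda r: (
            r.scaffold_rmsd,
            r.docking_score if r.docking_score is not None else float("inf"),
            r.pose_id,
        ),
    )


def percent_in_pocket(results: list[TriageResult]) -> float:
    """Fraction of poses inside the pocket, in [0, 1]."""
    if not results:
        raise UsageError("percent_in_pocket needs at least one triage result")
    return sum(r.in_pocket for r in results) / len(results)


def triage_ligand(
    receptor: Structure,
    poses: list[LigandPose],
    template: LigandTemplate,
    anchors: PocketAnchors,
    reference: LigandPose,
    reference_template: LigandTemplate | None = None,
) -> TriageReport:
    """Run the full two-criterion triage for one ligand's pose set."""
    if not poses:
        raise UsageError("no poses to triage")
    results = []
    for pose in poses:
        dists = measure_distances(pose, template, anchors)
        n, inside = pose_in_pocket(dists, anchors)
        rmsd, mapping = scaffold_rmsd(pose, reference, template, reference_template)
        results.append(
            TriageResult(
                pose_id=pose.pose_id,
                distances=dists,
                n_below_cutoff=n,
                in_pocket=inside,
                scaffold_rmsd=rmsd,
                mapping_used=mapping,
                docking_score=pose.docking_score,
            )
        )
    return TriageReport(
        ligand_name=template.ligand_name,
        results=results,
        selected=select_pose(results),
        percent_in_pocket=percent_in_pocket(results),
    )
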