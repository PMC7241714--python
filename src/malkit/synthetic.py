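"""Ground-truth synthetic data for every pipeline stage.

Everything here is a pure function of its configuration, including the
seed, and writes only through the package's own readers' formats, so the
generated inputs round-trip losslessly.

The pocket fixture is *analytic*: the reference ligand is laid out with
realistic bond geometry and the four anchor atoms are then placed by
construction so that the measured anchor distances equal the reference
values 4.16, 3.08, 2.75 and 2.2 Å exactly (machine precision), the way
they are measured — shortest-oxygen convention included. It stands in for
the crystal-structure pocket in download-free runs; it is a synthetic
stand-in, not crystallographic coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError
from .kinetics import competitive_rate, michaelis_menten, noncompetitive_rate
from .structures import Atom, LigandPose, Structure
from .templates import LigandTemplate, get_template
from .triage import PocketAnchors, REFERENCE_DISTANCES, measure_distances, pose_in_pocket

__all__ = [
    "PoseSimConfig",
    "KineticSimConfig",
    "PoseSet",
    "make_pocket_fixture",
    "fixture_pocket_residues",
    "generate_poses",
    "generate_kinetics",
    "generate_ddg_table",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


# --- analytic pocket fixture ------------------------------------------------

# Ligand atom positions (Å), receptor frame. C4 is the Mg-oriented
# carboxyl carbon at the origin; C3 carries the methyl (CM) and the
# abstractable proton; C1 is the distal carboxylate.
_LIGAND_XYZ = {
    "C4": (0.0, 0.0, 0.0),
    "O41": (0.63, 1.08, 0.0),
    "O42": (0.63, -1.08, 0.0),
    "C3": (-1.52, 0.0, 0.0),
    "CM": (-2.02, -1.1, 0.9),
    "C2": (-2.22, 1.2, 0.5),
    "N2": (-2.02, 2.2, -0.5),
    "C1": (-3.42, 1.0, 1.4),
    "O11": (-4.42, 1.7, 1.6),
    "O12": (-3.72, -0.1, 1.9),
}

# Extra pocket atoms for the extended fixture: a hydrophobic leucine
# side-chain carbon 4.0 Å from the methyl group, and the threonine/cysteine
# partners of the distal carboxylate.
_EXTENDED_XYZ = [
    ("CD1", "C", "LEU", 384, (-2.02, -4.3, 3.3)),
    ("OG1", "O", "THR", 360, (-5.72, -1.8, 3.1)),
    ("N", "N", "CYS", 361, (-6.02, 3.3, -0.3)),
]


def make_pocket_fixture(
    extended: bool = False, chain: str = "B"
) -> tuple[Structure, LigandPose]:
    """Build the analytic pocket (anchors + Mg) and the reference pose.

    Deterministic, no randomness. ``measure_distances`` on the returned
    pose reproduces the reference distances (4.16, 3.08, 2.75, 2.2 Å) to
    machine precision. ``extended=True`` adds three more pocket atoms
    (L384 CD1, T360 OG1, C361 N) so interaction fingerprints have
    hydrophobic and hydrogen-bond partners beyond the anchors.
    """
    d_k, d_q, d_h, d_mg = REFERENCE_DISTANCES
    xyz = {k: np.array(v) for k, v in _LIGAND_XYZ.items()}
    oy = xyz["O41"][1]  # oxygen offset from the carboxyl axis
    anchors_xyz = {
        # Mg on the carboxyl bisector: equidistant d_mg from both oxygens
        "MG": np.array([xyz["O41"][0] + math.sqrt(d_mg**2 - oy**2), 0.0, 0.0]),
        # amide N straight above O41, ε-N straight below O42
        "Q329": xyz["O41"] + np.array([0.0, d_q, 0.0]),
        "H194": xyz["O42"] + np.array([0.0, -d_h, 0.0]),
        # lysine Nζ perpendicular over the abstraction carbon
        "K331": xyz["C3"] + np.array([0.0, 0.0, d_k]),
    }

    def atom(name, element, resname, resnum, pos, het=False):
        return Atom(
            name=name, element=element, residue_name=resname,
            residue_number=resnum, chain_id=chain, position=np.asarray(pos, float),
            het=het,
        )

    receptor_atoms = [
        atom("NE2", "N", "HIS", 194, anchors_xyz["H194"]),
        atom("NE2", "N", "GLN", 329, anchors_xyz["Q329"]),
        atom("NZ", "N", "LYS", 331, anchors_xyz["K331"]),
        atom("MG", "MG", "MG", 601, anchors_xyz["MG"], het=True),
    ]
    if extended:
        receptor_atoms.extend(
            atom(name, element, resname, resnum, pos)
            for name, element, resname, resnum, pos in _EXTENDED_XYZ
        )
    receptor = Structure(atoms=receptor_atoms, identifier="synthetic-pocket")

    element = {"N2": "N"}
    ligand_atoms = [
        atom(
            name,
            element.get(name, name[0]),
            "MAA",
            501,
            pos,
            het=True,
        )
        for name, pos in _LIGAND_XYZ.items()
    ]
    reference = LigandPose(pose_id=0, ligand_name="3-methylaspartate", atoms=ligand_atoms)
    return receptor, reference


def fixture_pocket_residues(extended: bool = False, chain: str = "B") -> list[tuple[str, int]]:
    """Pocket addresses matching :func:`make_pocket_fixture`."""
    base = [(chain, 194), (chain, 329), (chain, 331), (chain, 601)]
    if extended:
        base += [(chain, 384), (chain, 360), (chain, 361)]
    return base


# --- labelled pose clouds ---------------------------------------------------

@dataclass(frozen=True)
class PoseSimConfig:
    """Pose-cloud simulation: rigid in-pocket jitter plus displaced decoys."""

    n_in_pocket: int = 40
    n_decoys: int = 60
    rotation_max: float = 8.0  # degrees
    translation_sigma: float = 0.25  # Å
    decoy_offset: float = 20.0  # Å; beyond cutoff + max reference distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_in_pocket < 0 or self.n_decoys < 0:
            raise UsageError("pose counts must be nonnegative")
        if self.decoy_offset <= 4.0 + max(REFERENCE_DISTANCES):
            raise UsageError(
                "decoy_offset must exceed cutoff + max reference distance"
            )


@dataclass
class PoseSet:
    """Generated poses with ground-truth labels and applied transforms."""

    poses: list[LigandPose]
    labels: list[bool]  # True = generated in-pocket
    transforms: list[dict]
    config: PoseSimConfig

    def truth_fraction_in_pocket(self) -> float:
        return sum(self.labels) / len(self.labels) if self.labels else 0.0


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    if max_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0.0, max_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _transform_pose(
    pose: LigandPose, rot: np.ndarray, center: np.ndarray, shift: np.ndarray, pose_id: int
) -> LigandPose:
    from dataclasses import replace

    atoms = [
        replace(a, position=rot @ (a.position - center) + center + shift)
        for a in pose.atoms
    ]
    return replace(pose, pose_id=pose_id, atoms=atoms)


def generate_poses(
    reference: LigandPose,
    config: PoseSimConfig,
    template: LigandTemplate | None = None,
    anchors: PocketAnchors | None = None,
) -> PoseSet:
    """Generate a labelled pose cloud around a reference pose.

    In-pocket poses are rigid perturbations of the reference (rotation up
    to ``rotation_max`` about the scaffold centroid, isotropic Gaussian
    translation); when a template and anchors are supplied, each in-pocket
    draw is checked against the pocket criterion and redrawn if the jitter
    pushed it out, so labels are correct by construction. Decoys are
    displaced by ``decoy_offset`` in a random direction, far beyond any
    passing geometry. Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    if template is None:
        template = get_template(reference.ligand_name)
    scaffold = template.scaffold_labels(0)
    center = np.mean([reference.atom(n).position for n in scaffold], axis=0)

    entries: list[tuple[LigandPose, bool, dict]] = []
    for i in range(config.n_in_pocket):
        for attempt in range(1000):
            rot = _random_rotation(rng, config.rotation_max)
            shift = rng.normal(scale=config.translation_sigma, size=3)
            pose = _transform_pose(reference, rot, center, shift, pose_id=0)
            if anchors is None:
                break
            dists = measure_distances(pose, template, anchors)
            if pose_in_pocket(dists, anchors)[1]:
                break
        else:
            raise UsageError(
                "could not draw an in-pocket pose; jitter settings too aggressive"
            )
        entries.append(
            (pose, True, {"rotation": rot.tolist(), "translation": shift.tolist()})
        )
    for i in range(config.n_decoys):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rot = _random_rotation(rng, config.rotation_max)
        shift = config.decoy_offset * direction
        pose = _transform_pose(reference, rot, center, shift, pose_id=0)
        entries.append(
            (pose, False, {"rotation": rot.tolist(), "translation": shift.tolist()})
        )

    order = rng.permutation(len(entries))
    poses, labels, transforms = [], [], []
    for new_id, idx in enumerate(order, start=1):
        pose, label, tf = entries[idx]
        from dataclasses import replace

        poses.append(replace(pose, pose_id=new_id))
        labels.append(label)
        transforms.append(tf)
    return PoseSet(poses=poses, labels=labels, transforms=transforms, config=config)


# --- kinetic datasets -------------------------------------------------------

@dataclass(frozen=True)
class KineticSimConfig:
    """Initial-velocity simulation under one rate law.

    Defaults follow the reference assay: substrate grid spanning
    1.25–15 mM, three replicates, 2% multiplicative Gaussian noise.
    """

    model: str = "mm"  # mm | competitive | noncompetitive
    kcat: float = 17.6  # s⁻¹
    Km: float = 1.0  # mM
    Ki: float | None = None  # mM
    S_grid: tuple[float, ...] = (1.25, 2.5, 5.0, 7.5, 10.0, 15.0)
    I_levels: tuple[float, ...] = (0.0,)
    replicates: int = 3
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("mm", "competitive", "noncompetitive"):
            raise UsageError(f"unknown kinetic model {self.model!r}")
        if self.kcat <= 0 or self.Km <= 0:
            raise UsageError("kcat and Km must be positive")
        if self.model != "mm" and (self.Ki is None or self.Ki <= 0):
            raise UsageError(f"{self.model} model needs a positive Ki")
        if 0.0 not in self.I_levels:
            raise UsageError("inhibitor levels must include 0")
        if any(s <= 0 for s in self.S_grid):
            raise UsageError("substrate grid must be positive")
        if self.replicates < 1 or self.noise_cv < 0:
            raise UsageError("replicates ≥ 1 and noise_cv ≥ 0 required")


def _true_rate(config: KineticSimConfig, S, I):
    if config.model == "mm":
        return michaelis_menten(S, config.kcat, config.Km)
    if config.model == "competitive":
        return competitive_rate(S, I, config.kcat, config.Km, config.Ki)
    return noncompetitive_rate(S, I, config.kcat, config.Km, config.Ki)


def generate_kinetics(config: KineticSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate initial velocities y = model(S, I; θ)·(1 + ε), ε ~ N(0, cv²).

    Returns the measurement table (columns substrate_mM, inhibitor_mM,
    velocity, replicate) and a truth record carrying θ.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for I in config.I_levels:
        for S in config.S_grid:
            v_true = float(_true_rate(config, S, I))
            for rep in range(1, config.replicates + 1):
                noise = rng.normal(0.0, config.noise_cv) if config.noise_cv else 0.0
                rows.append(
                    {
                        "substrate_mM": S,
                        "inhibitor_mM": I,
                        "velocity": v_true * (1.0 + noise),
                        "replicate": rep,
                    }
                )
    truth = {
        "model": config.model,
        "kcat": config.kcat,
        "Km": config.Km,
        "Ki": config.Ki,
        "noise_cv": config.noise_cv,
        "seed": config.seed,
    }
    return pd.DataFrame(rows), truth


# --- ΔΔG tables -------------------------------------------------------------

def generate_ddg_table(
    positions,
    runs: int = 5,
    run_sd: float = 0.8,
    planted_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a saturation-scan ΔΔG table with known labels.

    Per position all 19 substitutions of a randomly drawn wild type are
    generated. True effects come from a declared two-component mixture —
    neutral ~ N(0, 0.5²), destabilizing ~ N(3, 1²) with probability
    ``planted_fraction`` — and each replicate run adds N(0, run_sd²)
    prediction noise (0.8 kcal/mol mirrors the predictor's typical error).
    Returns the run table and a truth table with the planted component per
    mutation.
    """
    if runs < 1:
        raise UsageError("need at least one run")
    if not 0.0 <= planted_fraction <= 1.0:
        raise UsageError("planted_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for pos in positions:
        wt = _AA20[rng.integers(len(_AA20))]
        for mut in _AA20:
            if mut == wt:
                continue
            destabilizing = bool(rng.random() < planted_fraction)
            true_ddg = (
                rng.normal(3.0, 1.0) if destabilizing else rng.normal(0.0, 0.5)
            )
            run_values = true_ddg + rng.normal(0.0, run_sd, size=runs)
            row = {"position": pos, "wild_type": wt, "mutant": mut}
            row.update({f"run{j + 1}": float(v) for j, v in enumerate(run_values)})
            rows.append(row)
            truth_rows.append(
                {
                    "position": pos,
                    "wild_type": wt,
                    "mutant": mut,
                    "true_ddg": float(true_ddg),
                    "true_label": "destabilizing" if destabilizing else "neutral",
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
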