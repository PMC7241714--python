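"""Per-ligand scaffold declarations.

The triage geometry never perceives bonds: each ligand ships an explicit
:class:`LigandTemplate` naming (i) its carboxylate group(s) — the carboxyl
carbon and its two oxygens, (ii) for each carboxylate choice the three
backbone carbons that follow the carboxyl carbon along the chain, and
(iii) the proton-abstraction carbon (the carbon deprotonated by the
catalytic lysine; the first backbone carbon unless declared otherwise).
The six scaffold atoms used for positional RMSD are the carboxyl carbon,
its two oxygens and the three following backbone carbons.

For a dicarboxylic ligand both carboxylates are listed; distance
measurement picks the one nearer the catalytic Mg²⁺, while scaffold RMSD
minimizes over both choices and the in-group oxygen swap (the carboxylate
oxygens are chemically indistinguishable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import TemplateError, UsageError
from .structures import LigandPose

__all__ = ["CarboxylGroup", "LigandTemplate", "get_template", "list_templates"]


@dataclass(frozen=True)
class CarboxylGroup:
    carbon: str
    oxygen1: str
    oxygen2: str


@dataclass(frozen=True)
class LigandTemplate:
    """Atom-label declaration of a ligand's common scaffold and groups."""

    ligand_name: str
    carboxyl_groups: tuple[CarboxylGroup, ...]
    #: per carboxyl choice, the ordered 3 carbons following the carboxyl C
    backbone_carbons: tuple[tuple[str, str, str], ...]
    #: per carboxyl choice, the proton-abstraction carbon
    abstraction_carbons: tuple[str, ...]
    amino_nitrogens: tuple[str, ...] = ()
    #: apolar carbons eligible for hydrophobic contacts
    hydrophobic_carbons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.carboxyl_groups)
        if n not in (1, 2):
            raise UsageError(f"{self.ligand_name}: need 1 or 2 carboxyl groups, got {n}")
        if len(self.backbone_carbons) != n or len(self.abstraction_carbons) != n:
            raise UsageError(
                f"{self.ligand_name}: backbone_carbons and abstraction_carbons must"
                f" give one entry per carboxyl choice"
            )
        for trio in self.backbone_carbons:
            if len(trio) != 3:
                raise UsageError(
                    f"{self.ligand_name}: each carboxyl choice needs exactly 3 backbone carbons"
                )

    def scaffold_labels(self, choice: int) -> tuple[str, ...]:
        """The 6 scaffold atom labels for one carboxyl choice."""
        g = self.carboxyl_groups[choice]
        return (g.carbon, g.oxygen1, g.oxygen2) + self.backbone_carbons[choice]

    def resolve(self, pose: LigandPose, labels) -> list:
        try:
            return [pose.atom(label) for label in labels]
        except Exception as exc:
            raise TemplateError(
                f"template {self.ligand_name!r} does not resolve on pose"
                f" {pose.pose_id}: {exc}"
            ) from exc


def _t(name, carboxyls, backbones, abstraction=None, amino=(), hydrophobic=()):
    groups = tuple(CarboxylGroup(*c) for c in carboxyls)
    if abstraction is None:
        abstraction = tuple(b[0] for b in backbones)
    return LigandTemplate(
        ligand_name=name,
        carboxyl_groups=groups,
        backbone_carbons=tuple(tuple(b) for b in backbones),
        abstraction_carbons=tuple(abstraction),
        amino_nitrogens=tuple(amino),
        hydrophobic_carbons=tuple(hydrophobic),
    )


# Carbon numbering follows the carboxylic-acid convention (C1 = the
# carboxyl carbon of the parent acid). The natural substrate's reactive
# carboxylate is C4 (the one coordinating Mg²⁺); its abstraction carbon is
# C3, which also bears the methyl group.
_SHIPPED: dict[str, LigandTemplate] = {
    t.ligand_name: t
    for t in [
        _t(
            "3-methylaspartate",
            [("C4", "O41", "O42"), ("C1", "O11", "O12")],
            [("C3", "C2", "C1"), ("C2", "C3", "C4")],
            amino=("N2",),
            hydrophobic=("CM", "C3"),
        ),
        _t(
            "aspartate",
            [("C4", "O41", "O42"), ("C1", "O11", "O12")],
            [("C3", "C2", "C1"), ("C2", "C3", "C4")],
            amino=("N2",),
            hydrophobic=("C3",),
        ),
        _t(
            "beta-lysine",
            [("C1", "O11", "O12")],
            [("C2", "C3", "C4")],
            amino=("N3", "N6"),
            hydrophobic=("C2", "C4", "C5"),
        ),
        _t(
            "lysine",
            [("C1", "O11", "O12")],
            [("C2", "C3", "C4")],
            amino=("N2", "NZ"),
            hydrophobic=("C3", "C4", "C5"),
        ),
        _t(
            "beta-glutamate",
            [("C1", "O11", "O12"), ("C5", "O51", "O52")],
            [("C2", "C3", "C4"), ("C4", "C3", "C2")],
            amino=("N3",),
            hydrophobic=("C2", "C4"),
        ),
        _t(
            "3-aminobutanoate",
            [("C1", "O11", "O12")],
            [("C2", "C3", "C4")],
            amino=("N3",),
            hydrophobic=("C2", "C4"),
        ),
        _t(
            "2-aminoadipate",
            [("C1", "O11", "O12"), ("C6", "O61", "O62")],
            [("C2", "C3", "C4"), ("C5", "C4", "C3")],
            amino=("N2",),
            hydrophobic=("C3", "C4", "C5"),
        ),
    ]
}


def get_template(name: str) -> LigandTemplate:
    """Look up a shipped ligand template by name."""
    try:
        return _SHIPPED[name]
    except KeyError:
        raise UsageError(
            f"no shipped template {name!r}; available: {sorted(_SHIPPED)}"
        ) from None


def list_templates() -> list[str]:
    return sorted(_SHIPPED)
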