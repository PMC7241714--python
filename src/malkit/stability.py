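"""Saturation-mutagenesis ΔΔG post-processing.

Consumes tabular output of a stability predictor run several times per
mutation (five runs is the expected protocol; any count is accepted),
averages the runs and classifies each mutation against a fixed threshold:
mean ΔΔG strictly above 1.6 kcal/mol — twice the predictor's typical
error of 0.8 kcal/mol — is destabilizing, anything else neutral. A value
of exactly 1.6 is therefore neutral. An optional third class flags
clearly stabilizing mutations (mean ≤ −threshold); it is an annotation
beyond the two-class scheme, off by default.

The energy function itself is never executed here; only its tables are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError

__all__ = [
    "DDG_THRESHOLD",
    "MutationDdg",
    "aggregate_runs",
    "classify_mutation",
    "read_ddg_table",
    "scan_summary",
]

#: Destabilizing/neutral boundary, kcal/mol (twice the typical 0.8 kcal/mol
#: prediction error of the stability predictor).
DDG_THRESHOLD = 1.6

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MutationDdg:
    """One mutation with its replicate ΔΔG values (kcal/mol)."""

    position: int
    wild_type: str
    mutant: str
    run_ddg: tuple[float, ...]
    mean_ddg: float
    sd_ddg: float
    classification: str

    def __post_init__(self) -> None:
        if self.mutant == self.wild_type:
            raise UsageError(
                f"position {self.position}: mutant equals wild type {self.wild_type!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"


def aggregate_runs(run_ddg) -> tuple[float, float]:
    """Arithmetic mean and (population) standard deviation over runs."""
    values = np.asarray(list(run_ddg), dtype=float)
    if values.size == 0:
        raise UsageError("aggregate_runs needs at least one value")
    return float(values.mean()), float(values.std())


def classify_mutation(
    mean_ddg: float, threshold: float = DDG_THRESHOLD, annotate_stabilizing: bool = False
) -> str:
    """Two-class rule: destabilizing iff mean ΔΔG > threshold, else neutral.

    With ``annotate_stabilizing`` a mean ≤ −threshold returns
    "stabilizing" instead of "neutral" (annotation beyond the canonical
    two-class scheme).
    """
    if threshold <= 0:
        raise UsageError("threshold must be positive")
    if mean_ddg > threshold:
        return "destabilizing"
    if annotate_stabilizing and mean_ddg <= -threshold:
        return "stabilizing"
    return "neutral"


def read_ddg_table(
    source,
    threshold: float = DDG_THRESHOLD,
    annotate_stabilizing: bool = False,
) -> list[MutationDdg]:
    """Load a (position, wild_type, mutant, run1..runN) delimited table.

    ``source`` is a path/file-like or an already-loaded DataFrame. Run
    columns are every column named ``run*`` (any count ≥ 1).
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    run_cols = [c for c in df.columns if str(c).lower().startswith("run")]
    needed = {"position", "wild_type", "mutant"}
    if not needed.issubset(df.columns) or not run_cols:
        raise UsageError(
            "ΔΔG table needs columns position, wild_type, mutant and run1..runN"
        )
    out = []
    for row in df.itertuples(index=False):
        runs = tuple(float(getattr(row, c)) for c in run_cols)
        mean, sd = aggregate_runs(runs)
        out.append(
            MutationDdg(
                position=int(row.position),
                wild_type=str(row.wild_type),
                mutant=str(row.mutant),
                run_ddg=runs,
                mean_ddg=mean,
                sd_ddg=sd,
                classification=classify_mutation(mean, threshold, annotate_stabilizing),
            )
        )
    return out


def scan_summary(
    mutations: list[MutationDdg],
    positions: list[int] | None = None,
    highlight: list[str] | None = None,
) -> pd.DataFrame:
    """Per-position counts of destabilizing/neutral mutations.

    A full saturation scan contributes 19 mutations per position. A
    requested position absent from the table triggers a warning, not a
    failure. ``highlight`` flags named variants (e.g. ``T360A``) in the
    output.
    """
    by_position: dict[int, list[MutationDdg]] = {}
    for m in mutations:
        by_position.setdefault(m.position, []).append(m)
    wanted = positions if positions is not None else sorted(by_position)
    highlight = set(highlight or [])
    rows = []
    for pos in wanted:
        muts = by_position.get(pos)
        if muts is None:
            warnings.warn(f"position {pos} absent from ΔΔG table", stacklevel=2)
            continue
        classes = [m.classification for m in muts]
        rows.append(
            {
                "position": pos,
                "wild_type": muts[0].wild_type,
                "n_mutations": len(muts),
                "n_destabilizing": classes.count("destabilizing"),
                "n_neutral": classes.count("neutral"),
                "n_stabilizing": classes.count("stabilizing"),
                "highlighted": ",".join(
                    sorted(m.label for m in muts if m.label in highlight)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position", "wild_type", "n_mutations", "n_destabilizing",
            "n_neutral", "n_stabilizing", "highlighted",
        ],
    )
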