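"""Steady-state enzyme kinetics: rate conversion, model fits, inhibition.

Initial velocities measured spectrophotometrically are converted through
the Beer–Lambert law, fitted to the Michaelis–Menten model

    v = kcat·S / (Km + S)

and, in the presence of an inhibitor at concentration I, globally to the
competitive

    v = kcat·S / (Km·(1 + I/Ki) + S)

or non-competitive

    v = kcat·S / ((1 + I/Ki)·(Km + S))

rate laws, with a single (kcat, Km, Ki) shared across all inhibitor
series. Model discrimination uses the small-sample Akaike criterion
(AICc): an inhibition model must beat the plain Michaelis–Menten fit by
more than 2 AICc units, otherwise "none" is declared. Lineweaver–Burk
(double-reciprocal) series are provided as the classical visual
diagnostic: competitive series share a y-intercept (1/kcat), purely
non-competitive series share an x-intercept (−1/Km).

Substrate and inhibitor concentrations are mM throughout; velocities are
whatever unit the caller supplies (kcat inherits it; with per-enzyme
turnover input, s⁻¹).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, UsageError

__all__ = [
    "AssaySpec",
    "Velocity",
    "MMFit",
    "InhibitionFit",
    "LineweaverBurk",
    "rate_from_absorbance",
    "extinction_from_spectrum",
    "michaelis_menten",
    "competitive_rate",
    "noncompetitive_rate",
    "fit_michaelis_menten",
    "fit_inhibition",
    "classify_inhibition",
    "lineweaver_burk",
    "efficiency",
    "fold_change",
    "read_kinetics_table",
]

REQUIRED_COLUMNS = ("substrate_mM", "inhibitor_mM", "velocity")


@dataclass(frozen=True)
class AssaySpec:
    """Spectrophotometric assay constants for Beer–Lambert conversion."""

    extinction_coefficient: float  # M⁻¹ cm⁻¹
    wavelength: float | None = None  # nm, provenance only
    path_length: float = 1.0  # cm
    enzyme_concentration: float | None = None  # M

    def __post_init__(self) -> None:
        if self.extinction_coefficient <= 0:
            raise UsageError("extinction coefficient must be positive")
        if self.path_length <= 0:
            raise UsageError("path length must be positive")


@dataclass(frozen=True)
class Velocity:
    """One converted initial velocity."""

    M_per_min: float
    mM_per_min: float
    per_enzyme_s: float | None = None  # turnover, s⁻¹


@dataclass(frozen=True)
class MMFit:
    kcat: float
    kcat_se: float
    Km: float
    Km_se: float
    r_squared: float
    n: int
    converged: bool = True
    valid: bool = True

    def predict(self, S):
        return michaelis_menten(np.asarray(S, dtype=float), self.kcat, self.Km)


@dataclass(frozen=True)
class InhibitionFit:
    model: str  # competitive | noncompetitive | none
    kcat: float
    kcat_se: float
    Km: float
    Km_se: float
    Ki: float | None
    Ki_se: float | None
    global_r_squared: float
    aicc: dict = field(default_factory=dict)
    n: int = 0
    converged: bool = True
    valid: bool = True
    ki_identifiable: bool = True
    no_inhibition_indicated: bool = False


# --- Beer–Lambert -----------------------------------------------------------

def rate_from_absorbance(slope: float, assay: AssaySpec) -> Velocity:
    """Convert an absorbance slope (A·min⁻¹) to an initial velocity.

    v = slope / (ε·l) in M·min⁻¹; divided by the enzyme concentration and
    by 60 into a per-enzyme turnover (s⁻¹) when the spec provides one.
    """
    v_m = slope / (assay.extinction_coefficient * assay.path_length)
    per_enzyme = None
    if assay.enzyme_concentration is not None:
        if assay.enzyme_concentration <= 0:
            raise UsageError("enzyme concentration must be positive")
        per_enzyme = v_m / assay.enzyme_concentration / 60.0
    return Velocity(M_per_min=v_m, mM_per_min=v_m * 1e3, per_enzyme_s=per_enzyme)


def extinction_from_spectrum(absorbance: float, concentration: float, path_length: float = 1.0) -> float:
    """ε = A / (c·l), M⁻¹ cm⁻¹, from a known-concentration spectrum point."""
    if concentration <= 0:
        raise UsageError("concentration must be positive")
    if path_length <= 0:
        raise UsageError("path length must be positive")
    return absorbance / (concentration * path_length)


# --- rate laws --------------------------------------------------------------

def michaelis_menten(S, kcat, Km):
    S = np.asarray(S, dtype=float)
    return kcat * S / (Km + S)


def competitive_rate(S, I, kcat, Km, Ki):
    S, I = np.asarray(S, dtype=float), np.asarray(I, dtype=float)
    return kcat * S / (Km * (1.0 + I / Ki) + S)


def noncompetitive_rate(S, I, kcat, Km, Ki):
    S, I = np.asarray(S, dtype=float), np.asarray(I, dtype=float)
    return kcat * S / ((1.0 + I / Ki) * (Km + S))


_MODELS = {"competitive": competitive_rate, "noncompetitive": noncompetitive_rate}


# --- table handling ---------------------------------------------------------

def read_kinetics_table(source) -> pd.DataFrame:
    """Load a (substrate_mM, inhibitor_mM, velocity[, replicate]) table.

    ``source`` is a path or file-like accepted by :func:`pandas.read_csv`;
    the delimiter is inferred between comma and tab.
    """
    df = pd.read_csv(source, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"kinetics table lacks required columns: {missing}")
    if "replicate" not in df.columns:
        df = df.assign(replicate=1)
    return df


def _validate(df: pd.DataFrame, need_inhibitor: bool) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"kinetics data lacks required columns: {missing}")
    if (df["substrate_mM"] <= 0).any():
        raise UsageError("substrate concentrations must be positive")
    if (df["inhibitor_mM"] < 0).any():
        raise UsageError("inhibitor concentrations must be nonnegative")
    if df["substrate_mM"].nunique() < 4:
        raise UsageError("need at least 4 distinct substrate concentrations")
    if need_inhibitor and 0.0 not in df["inhibitor_mM"].values:
        raise UsageError("inhibition data must include an uninhibited (I=0) series")
    return df


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _aicc(y, yhat, n_params: int) -> float:
    n = len(y)
    ss_res = float(np.sum((y - yhat) ** 2))
    k = n_params + 1  # + residual variance
    if n - k - 1 <= 0:
        return float("inf")
    ss_res = max(ss_res, 1e-300)
    return n * np.log(ss_res / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# --- fits -------------------------------------------------------------------

def fit_michaelis_menten(data: pd.DataFrame) -> MMFit:
    """Nonlinear least-squares Michaelis–Menten fit of an I=0 dataset.

    Initial guesses: Km = median substrate, kcat = 1.2 × max velocity.
    Standard errors come from the Jacobian-based parameter covariance.
    A negative parameter at the optimum is flagged invalid rather than
    silently clipped.
    """
    df = _validate(data, need_inhibitor=False)
    if (df["inhibitor_mM"] > 0).any():
        raise UsageError("fit_michaelis_menten expects inhibitor-free data")
    S = df["substrate_mM"].to_numpy(dtype=float)
    y = df["velocity"].to_numpy(dtype=float)
    p0 = (float(np.max(y)) * 1.2, float(np.median(S)))
    try:
        popt, pcov = curve_fit(michaelis_menten, S, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    kcat, Km = popt
    return MMFit(
        kcat=float(kcat),
        kcat_se=float(se[0]),
        Km=float(Km),
        Km_se=float(se[1]),
        r_squared=_r_squared(y, michaelis_menten(S, *popt)),
        n=len(y),
        valid=bool(kcat > 0 and Km > 0),
    )


def fit_inhibition(data: pd.DataFrame, model: str) -> InhibitionFit:
    """Single global fit of (S, I, v) data to one inhibition rate law.

    All inhibitor series share one (kcat, Km, Ki). When the data carry no
    positive inhibitor level the Ki is unidentifiable: the fit degrades to
    plain Michaelis–Menten and is flagged. A fitted Ki far above the
    probed inhibitor range is reported as a no-inhibition indication.
    """
    if model not in _MODELS:
        raise UsageError(f"unknown inhibition model {model!r}")
    df = _validate(data, need_inhibitor=True)
    S = df["substrate_mM"].to_numpy(dtype=float)
    I = df["inhibitor_mM"].to_numpy(dtype=float)
    y = df["velocity"].to_numpy(dtype=float)
    rate = _MODELS[model]

    if not (I > 0).any():
        mm = fit_michaelis_menten(df)
        return InhibitionFit(
            model=model,
            kcat=mm.kcat, kcat_se=mm.kcat_se, Km=mm.Km, Km_se=mm.Km_se,
            Ki=None, Ki_se=None,
            global_r_squared=mm.r_squared, n=mm.n,
            valid=mm.valid, ki_identifiable=False,
        )

    def f(x, kcat, Km, Ki):
        return rate(x[0], x[1], kcat, Km, Ki)

    p0 = (
        float(np.max(y[I == 0])) * 1.2,
        float(np.median(np.unique(S))),
        float(np.median(np.unique(I[I > 0]))),
    )
    try:
        popt, pcov = curve_fit(f, np.vstack([S, I]), y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"{model} global fit did not converge: {exc}") from exc
    kcat, Km, Ki = (float(v) for v in popt)
    se = np.sqrt(np.diag(pcov))
    yhat = rate(S, I, *popt)
    return InhibitionFit(
        model=model,
        kcat=kcat, kcat_se=float(se[0]),
        Km=Km, Km_se=float(se[1]),
        Ki=Ki, Ki_se=float(se[2]),
        global_r_squared=_r_squared(y, yhat),
        aicc={model: _aicc(y, yhat, 3)},
        n=len(y),
        valid=bool(kcat > 0 and Km > 0 and Ki > 0),
        no_inhibition_indicated=bool(Ki > 100.0 * float(np.max(I))),
    )


def classify_inhibition(data: pd.DataFrame, aicc_margin: float = 2.0) -> InhibitionFit:
    """Fit both inhibition models plus an inhibitor-blind Michaelis–Menten
    fit and choose by smallest AICc.

    "none" is declared when neither inhibition model improves on the plain
    Michaelis–Menten fit by more than ``aicc_margin`` AICc units (i.e. the
    inhibitor has no resolvable effect), or when the best fit itself
    indicates an effectively infinite Ki.
    """
    df = _validate(data, need_inhibitor=True)
    S = df["substrate_mM"].to_numpy(dtype=float)
    y = df["velocity"].to_numpy(dtype=float)
    # inhibitor-blind fit: one MM curve through all points
    p0 = (float(np.max(y)) * 1.2, float(np.median(np.unique(S))))
    try:
        popt_mm, pcov_mm = curve_fit(michaelis_menten, S, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"baseline Michaelis–Menten fit did not converge: {exc}") from exc
    aicc = {"none": _aicc(y, michaelis_menten(S, *popt_mm), 2)}

    fits: dict[str, InhibitionFit] = {}
    for model in _MODELS:
        fit = fit_inhibition(df, model)
        fits[model] = fit
        aicc[model] = fit.aicc[model]

    best_model = min(_MODELS, key=lambda m: aicc[m])
    best = fits[best_model]
    if aicc["none"] - aicc[best_model] <= aicc_margin or best.no_inhibition_indicated:
        se_mm = np.sqrt(np.diag(pcov_mm))
        return InhibitionFit(
            model="none",
            kcat=float(popt_mm[0]), kcat_se=float(se_mm[0]),
            Km=float(popt_mm[1]), Km_se=float(se_mm[1]),
            Ki=None, Ki_se=None,
            global_r_squared=_r_squared(y, michaelis_menten(S, *popt_mm)),
            aicc=aicc, n=len(y),
        )
    return InhibitionFit(
        model=best_model,
        kcat=best.kcat, kcat_se=best.kcat_se,
        Km=best.Km, Km_se=best.Km_se,
        Ki=best.Ki, Ki_se=best.Ki_se,
        global_r_squared=best.global_r_squared,
        aicc=aicc, n=best.n, valid=best.valid,
    )


# --- diagnostics & derived quantities --------------------------------------

@dataclass(frozen=True)
class LineweaverBurk:
    """Per-inhibitor-level double-reciprocal series with linear fits."""

    series: pd.DataFrame  # columns: inhibitor_mM, slope, y_intercept, x_intercept
    points: pd.DataFrame  # columns: inhibitor_mM, inv_S, inv_v
    pattern: str  # competitive-pattern | noncompetitive-pattern | indeterminate


def lineweaver_burk(data: pd.DataFrame, pattern_rtol: float = 1e-6) -> LineweaverBurk:
    """Build Lineweaver–Burk series and diagnose the intercept pattern.

    Non-positive velocities cannot be reciprocated; they are excluded with
    a warning. A common y-intercept across inhibitor levels (relative
    spread ≤ ``pattern_rtol``) labels the set competitive-pattern, a
    common x-intercept non-competitive-pattern.
    """
    df = _validate(data, need_inhibitor=False)
    bad = df["velocity"] <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} non-positive velocities from the"
            " double-reciprocal plot",
            stacklevel=2,
        )
        df = df[~bad]
    points = pd.DataFrame(
        {
            "inhibitor_mM": df["inhibitor_mM"].to_numpy(),
            "inv_S": 1.0 / df["substrate_mM"].to_numpy(dtype=float),
            "inv_v": 1.0 / df["velocity"].to_numpy(dtype=float),
        }
    )
    rows = []
    for level, grp in points.groupby("inhibitor_mM"):
        slope, intercept = np.polyfit(grp["inv_S"], grp["inv_v"], 1)
        rows.append(
            {
                "inhibitor_mM": level,
                "slope": float(slope),
                "y_intercept": float(intercept),
                "x_intercept": float(-intercept / slope) if slope != 0 else float("nan"),
            }
        )
    series = pd.DataFrame(rows).sort_values("inhibitor_mM", ignore_index=True)

    def _common(values) -> bool:
        values = np.asarray(values, dtype=float)
        scale = np.max(np.abs(values))
        return bool(scale == 0 or (np.ptp(values) / scale) <= pattern_rtol)

    if len(series) > 1 and _common(series["y_intercept"]):
        pattern = "competitive-pattern"
    elif len(series) > 1 and _common(series["x_intercept"]):
        pattern = "noncompetitive-pattern"
    else:
        pattern = "indeterminate"
    return LineweaverBurk(series=series, points=points, pattern=pattern)


def efficiency(fit_or_kcat, Km: float | None = None) -> float:
    """Catalytic efficiency kcat/Km (s⁻¹·mM⁻¹).

    Accepts either a fitted :class:`MMFit` or an explicit (kcat, Km) pair.
    The raw ratio is returned; round to 3 significant figures for display.
    """
    if isinstance(fit_or_kcat, MMFit):
        return fit_or_kcat.kcat / fit_or_kcat.Km
    if Km is None:
        raise UsageError("efficiency needs either an MMFit or both kcat and Km")
    return fit_or_kcat / Km


def fold_change(a: float, b: float) -> float:
    """Ratio a/b, for the fold comparisons between kinetic constants."""
    if b == 0:
        raise UsageError("fold_change denominator is zero")
    return a / b
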