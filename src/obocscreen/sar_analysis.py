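"""Structure-activity statistics and dose-response fitting.

Two kinds of summary mirror the screen's read-outs.  Composition tables
give, for each compound group, the percentage of each randomised residue
over all variable positions of the member sequences (the parent alone is
67% L / 33% V; group A in the published screen is 57% L / 43% V with no
T/N').  Percent-active counts a compound as active when at least one of
its wells inhibited bacterial growth.

Quantitative potencies come from the Hill (four-parameter logistic)
model

    response(c) = bottom + (top - bottom) / (1 + (EC50 / c)^h)

fit by bounded nonlinear least squares on log-concentration with a
deterministic grid initialiser (no random restarts).  Responses are on %
scales, so bottom/top default to 0/100 with a free-top variant by flag.
EC50, the inverse (effect_concentration) and HC10 (10% hemolysis) follow
from the fitted curve; MIC comes from a twofold microdilution series as
the lowest concentration with no growth.  Censored measurements (">1000")
are carried as explicit (value, censor) pairs and never silently compared.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .library_design import PeptideSequence, variable_composition
from .screening_classify import CompoundRecord, PotencyCode

__all__ = [
    "CensoredValue",
    "DoseResponseFit",
    "ActivityProfile",
    "group_composition",
    "percent_active",
    "fit_hill",
    "hill_response",
    "effect_concentration",
    "hc10_from_curve",
    "mic_from_dilutions",
    "fold_change",
    "profile_table",
    "HEATMAP_BOUNDS",
]

#: Colour-scale bounds (nM) used for the activity heat-map metadata:
#: (most potent shown red, least potent shown blue).
HEATMAP_BOUNDS: Mapping[str, tuple[float, float]] = {
    "ec50_transport": (1.3, 1000.0),
    "ic50_p388": (4.1, 1000.0),
    "hc10": (160.0, 3000.0),
    "mic": (8.0, 33000.0),
}


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).to_integral_value(rounding=ROUND_HALF_UP))


def _round_sig2(x: float) -> float:
    if x == 0:
        return 0.0
    d = Decimal(repr(abs(x)))
    shift = 1 - int(d.log10().to_integral_value(rounding="ROUND_FLOOR"))
    q = d.scaleb(shift).to_integral_value(rounding=ROUND_HALF_UP)
    return math.copysign(float(q.scaleb(-shift)), x)


@dataclass(frozen=True)
class CensoredValue:
    """A measurement that may be a bound rather than a point value.

    ``censor`` is None for a measured value, 'gt' for ">x" (activity not
    reached at the highest concentration tested), 'le' for "<=x", or
    'lt' for "<x" (used by censored fold changes).
    """

    value: float
    censor: str | None = None

    def __post_init__(self) -> None:
        if self.censor not in (None, "gt", "lt", "le"):
            raise ValueError(f"unknown censor flag {self.censor!r}")

    @property
    def is_censored(self) -> bool:
        return self.censor is not None

    @classmethod
    def parse(cls, text: str | float) -> "CensoredValue":
        if isinstance(text, (int, float)):
            return cls(float(text))
        s = str(text).strip()
        for prefix, flag in ((">", "gt"), ("<=", "le"), ("<", "lt")):
            if s.startswith(prefix):
                return cls(float(s[len(prefix):]), flag)
        return cls(float(s))

    def __str__(self) -> str:
        prefix = {None: "", "gt": ">", "lt": "<", "le": "<="}[self.censor]
        return f"{prefix}{self.value:g}"


def _as_censored(x) -> CensoredValue:
    return x if isinstance(x, CensoredValue) else CensoredValue(float(x))


# ---- composition / percent-active ------------------------------------------


def group_composition(
    groups: Mapping[str, Sequence[PeptideSequence]],
    exact: bool = False,
) -> pd.DataFrame:
    """Residue distribution (%) over variable positions, per group.

    One row per group: percentage of each alphabet residue across all
    variable positions of all member sequences (6 x n_compounds slots),
    plus ``n_compounds``.  Percentages are rounded half-up to integers
    unless ``exact``.  Empty groups give an all-zero row.
    """
    rows = {}
    alphabet: list[str] = []
    for label, seqs in groups.items():
        counts: dict[str, float] = {}
        slots = 0
        for s in seqs:
            comp = variable_composition(s)
            for c, n in comp.counts.items():
                counts[c] = counts.get(c, 0) + n
                if c not in alphabet:
                    alphabet.append(c)
            slots += comp.total()
        row = {}
        for c in alphabet:
            pct = 100.0 * counts.get(c, 0) / slots if slots else 0.0
            row[c] = pct if exact else _round_half_up(pct)
        row["n_compounds"] = len(seqs)
        rows[label] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    cols = [c for c in alphabet] + ["n_compounds"]
    return df.reindex(columns=cols).fillna(0 if not exact else 0.0)


def percent_active(records: Sequence[CompoundRecord]) -> int | None:
    """Percent of compounds with >= 1 antibacterially active well.

    Rounded half-up to an integer; ``None`` for an empty input.
    """
    if not records:
        return None
    active = sum(1 for r in records if r.n_abx_active_wells >= 1)
    return _round_half_up(100.0 * active / len(records))


# ---- Hill dose-response -----------------------------------------------------


@dataclass(frozen=True)
class DoseResponseFit:
    ec50: float
    hill_slope: float
    top: float
    bottom: float
    rss: float
    converged: bool
    n_points: int = 0
    message: str = ""


def hill_response(c, ec50: float, hill_slope: float, top: float = 100.0, bottom: float = 0.0):
    """Hill curve response at concentration(s) ``c``."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill_slope)


def fit_hill(
    concentrations: Sequence[float],
    responses: Sequence[float],
    fixed_bottom: float = 0.0,
    fixed_top: float = 100.0,
    free_top: bool = False,
) -> DoseResponseFit:
    """Least-squares Hill fit with a deterministic grid initialiser.

    Concentrations must be positive and span the transition (>= 4 points).
    EC50 is parameterised as log10(EC50) and the slope bounded in
    [0.05, 10].  With ``free_top`` the plateau is fit as a third
    parameter (bounded by twice the largest response).  Constant
    responses cannot constrain the model and return ``converged=False``.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape or c.size < 4:
        raise ValueError("need >= 4 matched concentration/response points")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if float(np.ptp(r)) < 1e-9:
        return DoseResponseFit(
            ec50=float("nan"), hill_slope=float("nan"), top=fixed_top,
            bottom=fixed_bottom, rss=float("nan"), converged=False,
            n_points=int(c.size), message="degenerate data: constant response",
        )

    logc = np.log10(c)
    bottom = fixed_bottom

    def residuals(theta):
        log_ec50, slope = theta[0], theta[1]
        top = theta[2] if free_top else fixed_top
        pred = bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (log_ec50 - logc)))
        return pred - r

    # Deterministic grid over plausible EC50 (data range +- 1 decade) and slope.
    grid_ec50 = np.linspace(logc.min() - 1.0, logc.max() + 1.0, 13)
    grid_slope = (0.5, 1.0, 2.0, 4.0)
    top0 = max(float(r.max()), bottom + 1.0)
    best, best_sse = None, np.inf
    for le in grid_ec50:
        for hs in grid_slope:
            theta = [le, hs, top0] if free_top else [le, hs]
            sse = float(np.sum(residuals(theta) ** 2))
            if sse < best_sse:
                best, best_sse = theta, sse

    lo = [logc.min() - 4.0, 0.05] + ([bottom + 1e-6] if free_top else [])
    hi = [logc.max() + 4.0, 10.0] + ([2.0 * top0] if free_top else [])
    sol = least_squares(residuals, best, bounds=(lo, hi), method="trf")
    top = float(sol.x[2]) if free_top else fixed_top
    return DoseResponseFit(
        ec50=float(10.0 ** sol.x[0]),
        hill_slope=float(sol.x[1]),
        top=top,
        bottom=bottom,
        rss=float(np.sum(sol.fun ** 2)),
        converged=bool(sol.success),
        n_points=int(c.size),
        message=sol.message,
    )


def effect_concentration(fit: DoseResponseFit, percent_effect: float) -> float:
    """Invert the Hill curve: concentration producing the given % effect.

    ``percent_effect`` must lie strictly between bottom and top;
    effect_concentration(fit, 50) equals the fitted EC50 when bottom/top
    are 0/100.
    """
    if not fit.converged:
        raise ValueError("cannot invert a non-converged fit")
    if not (fit.bottom < percent_effect < fit.top):
        raise ValueError(
            f"percent effect {percent_effect} outside the open interval "
            f"({fit.bottom}, {fit.top})"
        )
    f = (percent_effect - fit.bottom) / (fit.top - percent_effect)
    return fit.ec50 * f ** (1.0 / fit.hill_slope)


def hc10_from_curve(fit: DoseResponseFit) -> float:
    """Concentration causing 10% effect (hemolysis convention)."""
    return effect_concentration(fit, 10.0)


# ---- MIC --------------------------------------------------------------------


def mic_from_dilutions(series: Sequence[tuple[float, bool]]) -> CensoredValue:
    """MIC from a strictly decreasing dilution series of (conc, growth).

    The MIC is the lowest concentration showing no growth above the
    highest growing concentration.  Growth everywhere is censored '>max';
    no growth anywhere is censored '<=min'.  A no-growth well below a
    growing one is a non-monotone pattern; it is skipped with a warning.
    """
    if len(series) < 1:
        raise ValueError("empty dilution series")
    concs = [c for c, _ in series]
    if any(b >= a for a, b in zip(concs, concs[1:])):
        raise ValueError("concentrations must be strictly decreasing")
    growth_concs = [c for c, g in series if g]
    if not growth_concs:
        return CensoredValue(min(concs), "le")
    highest_growth = max(growth_concs)
    no_growth_above = [c for c, g in series if not g and c > highest_growth]
    if any(c < highest_growth for c, g in series if not g):
        warnings.warn(
            "non-monotone growth pattern; MIC taken above the highest "
            "growing concentration",
            UserWarning,
            stacklevel=2,
        )
    if not no_growth_above:
        return CensoredValue(max(concs), "gt")
    return CensoredValue(min(no_growth_above))


# ---- fold changes -----------------------------------------------------------


def fold_change(
    numerator: float | CensoredValue,
    denominator: float | CensoredValue,
    rounding: str | None = "int",
):
    """numerator / denominator with an explicit rounding rule.

    ``rounding``: 'int' (nearest integer, half up), '2sig' (two
    significant figures, for sub-unity folds such as 0.29), or None (raw
    float).  A censored operand propagates to a censored fold with the
    appropriate direction flag; two censored operands are indeterminate.
    """
    num, den = _as_censored(numerator), _as_censored(denominator)
    if den.value <= 0:
        raise ValueError("denominator must be > 0")
    if num.is_censored and den.is_censored:
        raise ValueError("fold change of two censored values is indeterminate")
    ratio = num.value / den.value
    if num.is_censored or den.is_censored:
        if num.censor == "gt" or den.censor in ("lt", "le"):
            direction = "gt"
        else:
            direction = "lt"
        return CensoredValue(ratio, direction)
    if rounding == "int":
        return _round_half_up(ratio)
    if rounding == "2sig":
        return _round_sig2(ratio)
    if rounding is None:
        return ratio
    raise ValueError(f"unknown rounding rule {rounding!r}")


# ---- activity profiles ------------------------------------------------------


@dataclass
class ActivityProfile:
    """Resynthesis-scale potency summary of one compound (all in nM)."""

    compound_id: str
    group: str  # 'A', 'B0', 'B1', 'B2' or 'parent'
    ec50_transport: CensoredValue
    ic50_p388: CensoredValue
    hc10: CensoredValue
    mic: Mapping[str, CensoredValue] = field(default_factory=dict)


_GROUP_ORDER = {"parent": 0, "A": 1, "B0": 2, "B1": 3, "B2": 4}


def profile_table(profiles: Sequence[ActivityProfile]) -> pd.DataFrame:
    """Ranked potency table: groups in order parent, A, B0, B1, B2; within
    a group ascending IC50 with censored values last.  Heat-map colour
    bounds are attached as ``df.attrs['heatmap_bounds']``."""

    def sort_key(p: ActivityProfile):
        ic = p.ic50_p388
        return (
            _GROUP_ORDER.get(p.group, 99),
            1 if ic.is_censored else 0,
            ic.value,
        )

    rows = []
    for p in sorted(profiles, key=sort_key):
        row = {
            "compound_id": p.compound_id,
            "group": p.group,
            "ec50_transport_nM": str(p.ec50_transport),
            "ic50_p388_nM": str(p.ic50_p388),
            "hc10_nM": str(p.hc10),
        }
        for strain, v in p.mic.items():
            row[f"mic_{strain}_nM"] = str(v)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["heatmap_bounds"] = dict(HEATMAP_BOUNDS)
    return df


def render_profile_summary(df: pd.DataFrame) -> str:
    """Plain-text rendering of a profile table, one block per group."""
    lines = []
    for group, sub in df.groupby("group", sort=False):
        lines.append(f"[{group}]")
        for _, row in sub.iterrows():
            vals = ", ".join(
                f"{k.removesuffix('_nM')}={row[k]}" for k in df.columns if k.endswith("_nM")
            )
            lines.append(f"  {row['compound_id']}: {vals}")
    return "\n".join(lines)
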