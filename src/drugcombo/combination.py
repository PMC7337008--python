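"""Fixed-ratio combination design, combination index, Fa-CI curves, verdicts.

The combination index at fraction affected ``fa`` for component doses
``d_j`` given in the mixture is

    CI = sum_j d_j / Dx_j(fa)

where ``Dx_j(fa)`` is the dose of drug ``j`` alone producing the same
``fa`` (the inverse median-effect curve).  CI < 1 indicates synergism,
CI = 1 Loewe additivity, CI > 1 antagonism; finer verdict bands follow the
standard classification grid.
"""

from __future__ import annotations

import bisect
import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import InvalidArgumentError, OutOfDomainError, SchemaError, UnitMismatchError
from .median_effect import (
    DoseResponsePoint,
    MedianEffectParams,
    dose_for_fa,
    fit_median_effect,
)

__all__ = [
    "FixedRatioDesign",
    "CombinationObservation",
    "CIRecord",
    "SynergyVerdict",
    "design_fixed_ratio",
    "combination_index",
    "fit_combination_as_single",
    "fa_ci_curve",
    "classify_ci",
    "ci_records_from_observations",
    "default_fa_grid",
    "read_combination_csv",
    "write_combination_csv",
]


@dataclass(frozen=True)
class FixedRatioDesign:
    """Component weights and serial-dilution ladder for a mixture treated as one drug.

    ``weights`` are dose fractions summing to 1; every level keeps the same
    component proportions.  Level ``k`` has total dose
    ``top_total_dose / dilution_factor**k``.
    """

    components: tuple[str, ...]
    weights: tuple[float, ...]
    dilution_factor: float
    top_total_dose: float
    n_levels: int
    unit: str

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights):
            raise InvalidArgumentError("components and weights must have equal length")
        if any(w <= 0 for w in self.weights):
            raise InvalidArgumentError("all weights must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise InvalidArgumentError(f"weights must sum to 1, got {sum(self.weights)!r}")
        if self.dilution_factor <= 1.0:
            raise InvalidArgumentError("dilution_factor must be > 1")
        if self.top_total_dose <= 0:
            raise InvalidArgumentError("top_total_dose must be positive")
        if self.n_levels < 2:
            raise InvalidArgumentError("n_levels must be >= 2")

    def total_doses(self) -> list[float]:
        """Strictly decreasing total-dose ladder, top first."""
        return [self.top_total_dose / self.dilution_factor**k for k in range(self.n_levels)]

    def component_doses(self, total_dose: float) -> tuple[float, ...]:
        return tuple(w * total_dose for w in self.weights)


@dataclass(frozen=True)
class CombinationObservation:
    """Observed (component doses, fa) for one mixture dose level."""

    component_doses: tuple[float, ...]
    fa: float

    @property
    def total_dose(self) -> float:
        return float(sum(self.component_doses))


@dataclass(frozen=True)
class SynergyVerdict:
    label: str
    ci_interval: tuple[float, float]  # half-open [lo, hi); lo = 0 is exclusive


@dataclass(frozen=True)
class CIRecord:
    """One combination dose level: component doses, observed fa, CI, verdict."""

    component_doses: tuple[float, ...]
    fa_observed: float
    ci: float
    verdict: SynergyVerdict


# Half-open, lower-inclusive bands tiling (0, inf).  The printed grid
# [0.1,0.3) strong synergism ... [0.90,1.10) nearly additive is extended to
# cover the whole line following the standard convention.
_BAND_EDGES = (0.10, 0.30, 0.70, 0.85, 0.90, 1.10, 1.20, 3.30, math.inf)
_BAND_LABELS = (
    "very strong synergism",
    "strong synergism",
    "synergism",
    "moderate synergism",
    "slight synergism",
    "nearly additive",
    "slight antagonism",
    "antagonism",
    "strong antagonism",
)


def classify_ci(ci: float) -> SynergyVerdict:
    """Deterministic band lookup on half-open, lower-inclusive CI intervals."""
    if not (isinstance(ci, (int, float)) and ci > 0 and math.isfinite(ci)):
        raise InvalidArgumentError(f"ci must be positive and finite, got {ci!r}")
    idx = bisect.bisect_right(_BAND_EDGES, ci)
    lo = 0.0 if idx == 0 else _BAND_EDGES[idx - 1]
    return SynergyVerdict(label=_BAND_LABELS[idx], ci_interval=(lo, _BAND_EDGES[idx]))


def _check_one_unit(params: Sequence[MedianEffectParams]) -> str:
    units = {p.unit for p in params}
    if len(units) != 1:
        raise UnitMismatchError(f"parameter sets mix units {sorted(units)}")
    return units.pop()


def design_fixed_ratio(
    single_params: Sequence[MedianEffectParams],
    dilution_factor: float = 1.5,
    n_levels: int = 8,
    top_total_dose: float | None = None,
    components: Sequence[str] | None = None,
) -> FixedRatioDesign:
    """Build a fixed-ratio design with Dm-proportional weights.

    ``w_j = Dm_j / sum(Dm)``, so the level whose total equals ``sum(Dm)``
    gives every drug exactly its own median-effect dose.  When
    ``top_total_dose`` is omitted the ladder is centred so that ``sum(Dm)``
    is an interior level (the middle one, rounding down).
    """
    if not single_params:
        raise InvalidArgumentError("need at least one drug")
    unit = _check_one_unit(single_params)
    if dilution_factor <= 1.0:
        raise InvalidArgumentError("dilution_factor must be > 1")
    dm_sum = sum(p.dm for p in single_params)
    weights = tuple(p.dm / dm_sum for p in single_params)
    if top_total_dose is None:
        mid = (n_levels - 1) // 2
        if n_levels >= 3:
            mid = min(max(mid, 1), n_levels - 2)
        top_total_dose = dm_sum * dilution_factor**mid
    if components is None:
        components = tuple(f"drug{i + 1}" for i in range(len(single_params)))
    return FixedRatioDesign(
        components=tuple(components),
        weights=weights,
        dilution_factor=float(dilution_factor),
        top_total_dose=float(top_total_dose),
        n_levels=int(n_levels),
        unit=unit,
    )


def combination_index(
    single_params: Sequence[MedianEffectParams],
    component_doses: Sequence[float],
    fa_observed: float,
) -> float:
    """CI = sum_j d_j / Dx_j(fa_observed); linear in the dose vector at fixed fa."""
    if len(single_params) != len(component_doses):
        raise InvalidArgumentError(
            f"{len(component_doses)} doses for {len(single_params)} parameter sets"
        )
    _check_one_unit(single_params)
    if any(d <= 0 for d in component_doses):
        raise InvalidArgumentError("all component doses must be positive")
    if not (0.0 < fa_observed < 1.0):
        raise OutOfDomainError(f"fa must lie strictly in (0, 1), got {fa_observed!r}")
    return float(
        sum(d / dose_for_fa(p, fa_observed) for p, d in zip(single_params, component_doses))
    )


def fit_combination_as_single(
    observations: Sequence[tuple[float, float] | CombinationObservation],
    unit: str | None = None,
) -> MedianEffectParams:
    """Fit the mixture as one agent on TOTAL dose.

    ``observations`` are (total_dose, fa) pairs or
    :class:`CombinationObservation` rows; boundary fa values are excluded by
    the underlying median-effect fit.
    """
    points = []
    for obs in observations:
        if isinstance(obs, CombinationObservation):
            total, fa = obs.total_dose, obs.fa
        else:
            total, fa = obs
        kwargs = {"unit": unit} if unit is not None else {}
        points.append(DoseResponsePoint(dose=total, fa=fa, **kwargs))
    return fit_median_effect(points)


def default_fa_grid(start: float = 0.05, stop: float = 0.95, step: float = 0.05) -> list[float]:
    """fa grid 0.05 .. 0.95 by 0.05: avoids the undefined boundaries."""
    n = int(round((stop - start) / step)) + 1
    return [round(start + k * step, 10) for k in range(n)]


def fa_ci_curve(
    single_params: Sequence[MedianEffectParams],
    combo_params: MedianEffectParams,
    design: FixedRatioDesign,
    fa_grid: Sequence[float] | None = None,
) -> list[tuple[float, float]]:
    """Fa-CI curve from the FITTED combination curve.

    For each fa: total dose = dose_for_fa(combo curve, fa), component doses
    = weights * total, CI from the single-drug parameters.
    """
    if fa_grid is None:
        fa_grid = default_fa_grid()
    out = []
    for fa in fa_grid:
        if not (0.0 < fa < 1.0):
            raise OutOfDomainError(f"fa grid values must lie strictly in (0, 1), got {fa!r}")
        total = dose_for_fa(combo_params, fa)
        doses = design.component_doses(total)
        out.append((float(fa), combination_index(single_params, doses, fa)))
    return out


def ci_records_from_observations(
    single_params: Sequence[MedianEffectParams],
    observations: Sequence[CombinationObservation],
) -> list[CIRecord]:
    """Table-style CI: one record per dose level using the OBSERVED fa."""
    records = []
    for obs in observations:
        if not (0.0 < obs.fa < 1.0):
            continue  # boundary fa has no defined CI
        ci = combination_index(single_params, obs.component_doses, obs.fa)
        records.append(
            CIRecord(
                component_doses=obs.component_doses,
                fa_observed=obs.fa,
                ci=ci,
                verdict=classify_ci(ci),
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV interface: one dose column per component + fa
# ---------------------------------------------------------------------------


def read_combination_csv(
    path: str | Path, components: Sequence[str] | None = None
) -> tuple[list[str], list[CombinationObservation]]:
    """Read combination observations.

    Columns: one dose column per component plus ``fa``.  If ``components``
    is None, every non-``fa`` column is taken as a component, in file order.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = list(reader.fieldnames or [])
        if "fa" not in fields:
            raise SchemaError(f"{path}: missing column(s) ['fa']")
        if components is None:
            components = [c for c in fields if c != "fa"]
        else:
            missing = set(components) - set(fields)
            if missing:
                raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
        if not components:
            raise SchemaError(f"{path}: no component dose columns")
        observations = []
        for i, row in enumerate(reader, start=2):
            try:
                doses = tuple(float(row[c]) for c in components)
                fa = float(row["fa"])
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}:{i}: {exc}") from exc
            observations.append(CombinationObservation(component_doses=doses, fa=fa))
    return list(components), observations


def write_combination_csv(
    path: str | Path, components: Sequence[str], observations: Sequence[CombinationObservation]
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([*components, "fa"])
        for obs in observations:
            writer.writerow([*(repr(d) for d in obs.component_doses), repr(obs.fa)])
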