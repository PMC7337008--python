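"""Median-effect dose-response model.

The model relates dose ``D`` and fraction affected ``fa`` through

    fa / fu = (D / Dm) ** m,        fu = 1 - fa

where ``Dm`` is the median-effect dose (the dose producing fa = 0.5,
playing the role of an IC50) and ``m`` is a dimensionless shape exponent
(m = 1 hyperbolic, m > 1 sigmoidal).  Taking base-10 logs linearizes the
model,

    log10(fa / fu) = m * log10(D) - m * log10(Dm),

so ordinary least squares of ``y = log10(fa/fu)`` on ``x = log10(D)``
yields the slope ``m`` and, from the intercept, ``Dm``.  The Pearson
correlation ``r`` of the (x, y) pairs is reported as the fit quality.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
    NonMonotoneDataError,
    OutOfDomainError,
    SchemaError,
    UnitMismatchError,
)

logger = logging.getLogger(__name__)

DEFAULT_UNIT = "uM"

__all__ = [
    "DoseResponsePoint",
    "MedianEffectParams",
    "fa_from_dose",
    "dose_for_fa",
    "fit_median_effect",
    "read_points_csv",
    "write_points_csv",
]


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (dose, fraction affected) observation for a drug or a mixture.

    Parameters
    ----------
    dose:
        Strictly positive dose in the declared concentration unit.
    fa:
        Fraction affected in [0, 1].  The unaffected fraction ``fu = 1 - fa``
        is implicit and never stored.
    unit:
        Concentration-unit tag; must be uniform within one curve.
    """

    dose: float
    fa: float
    unit: str = DEFAULT_UNIT

    def __post_init__(self) -> None:
        if not (self.dose > 0 and math.isfinite(self.dose)):
            raise InvalidArgumentError(f"dose must be positive and finite, got {self.dose!r}")
        if not (0.0 <= self.fa <= 1.0):
            raise InvalidArgumentError(f"fa must lie in [0, 1], got {self.fa!r}")


@dataclass(frozen=True)
class MedianEffectParams:
    """Fitted median-effect parameters (Dm, m, r).

    ``r`` is the Pearson correlation coefficient of the median-effect plot;
    it is ``None`` for parameter sets constructed directly rather than
    obtained from :func:`fit_median_effect`.  ``n_used`` counts the points
    retained by the fit (boundary fa values are excluded, not clamped).
    """

    dm: float
    m: float
    r: float | None = None
    unit: str = DEFAULT_UNIT
    n_used: int = 2
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (self.dm > 0 and math.isfinite(self.dm)):
            raise InvalidArgumentError(f"dm must be positive and finite, got {self.dm!r}")
        if not (self.m > 0 and math.isfinite(self.m)):
            raise InvalidArgumentError(f"m must be positive and finite, got {self.m!r}")
        if self.r is not None and not (-1.0 - 1e-9 <= self.r <= 1.0 + 1e-9):
            raise InvalidArgumentError(f"r must lie in [-1, 1], got {self.r!r}")
        if self.n_used < 2:
            raise InvalidArgumentError(f"n_used must be >= 2, got {self.n_used!r}")


def fa_from_dose(params: MedianEffectParams, dose: float) -> float:
    """Forward median-effect curve: fraction affected at ``dose``.

    Computed as ``fa = 1 / (1 + (Dm/D)**m)``, evaluated in log space via the
    logistic function for numerical robustness at extreme doses.  Strictly
    increasing in dose, with fa -> 0 as dose -> 0 and fa -> 1 as dose -> inf.
    """
    if not (isinstance(dose, (int, float)) and dose > 0 and math.isfinite(dose)):
        raise InvalidArgumentError(f"dose must be positive and finite, got {dose!r}")
    # fa = 1/(1 + exp(m * ln(Dm/D))) = expit(m * ln(D/Dm))
    return float(expit(params.m * (math.log(dose) - math.log(params.dm))))


def dose_for_fa(params: MedianEffectParams, fa: float) -> float:
    """Inverse median-effect curve: the dose producing fraction affected ``fa``.

    ``Dx = Dm * (fa / (1 - fa)) ** (1/m)``.  This ``Dx`` is the single-drug
    denominator used by the combination index.  Raises
    :class:`OutOfDomainError` at the boundaries fa = 0 (dose 0, excluded) and
    fa = 1 (dose infinite).
    """
    if not (isinstance(fa, (int, float)) and math.isfinite(fa)):
        raise InvalidArgumentError(f"fa must be a finite number, got {fa!r}")
    if not (0.0 < fa < 1.0):
        raise OutOfDomainError(f"fa must lie strictly in (0, 1), got {fa!r}")
    return float(params.dm * (fa / (1.0 - fa)) ** (1.0 / params.m))


def _usable(points: Sequence[DoseResponsePoint]) -> list[DoseResponsePoint]:
    return [p for p in points if 0.0 < p.fa < 1.0]


def fit_median_effect(
    points: Sequence[DoseResponsePoint],
    *,
    r_warn_threshold: float = 0.9,
) -> MedianEffectParams:
    """Fit (Dm, m, r) by unweighted OLS on the median-effect plot.

    Points with fa equal to 0 or 1 are excluded (the log transform is
    undefined there); exclusions are logged and reported through
    ``n_excluded``.  A warning is logged when ``|r| < r_warn_threshold``;
    no fit-quality cutoff is enforced.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 usable points remain after exclusion.
    UnitMismatchError
        Points carry different unit tags.
    DegenerateDesignError
        All retained doses are identical.
    NonMonotoneDataError
        The fitted slope is not positive.
    """
    points = list(points)
    units = {p.unit for p in points}
    if len(units) > 1:
        raise UnitMismatchError(f"points mix units {sorted(units)}; one curve, one unit")
    usable = _usable(points)
    n_excluded = len(points) - len(usable)
    if n_excluded:
        logger.info("excluded %d boundary-fa point(s) from median-effect fit", n_excluded)
    if len(usable) < 2:
        raise InsufficientDataError(
            f"need >= 2 points with fa strictly in (0, 1); got {len(usable)}"
        )

    x = np.log10([p.dose for p in usable])
    y = np.log10([p.fa / (1.0 - p.fa) for p in usable])
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("all doses identical; slope is undefined")

    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise NonMonotoneDataError(
            f"fitted slope m = {slope:.6g} is not positive; "
            "effect does not increase with dose on the median-effect plot"
        )
    dm = 10.0 ** (-intercept / slope)
    with np.errstate(invalid="ignore"):
        r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) < r_warn_threshold:
        logger.warning("median-effect fit quality low: |r| = %.4f < %.2f", abs(r), r_warn_threshold)

    unit = units.pop() if units else DEFAULT_UNIT
    return MedianEffectParams(
        dm=float(dm),
        m=float(slope),
        r=r,
        unit=unit,
        n_used=len(usable),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# CSV interface: columns drug,dose,unit,fa (header required, dot decimal)
# ---------------------------------------------------------------------------

POINTS_COLUMNS = ("drug", "dose", "unit", "fa")


def read_points_csv(path: str | Path) -> dict[str, list[DoseResponsePoint]]:
    """Read dose-response points grouped by drug label.

    Expects a UTF-8 CSV with header ``drug,dose,unit,fa``.
    """
    path = Path(path)
    groups: dict[str, list[DoseResponsePoint]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(POINTS_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                point = DoseResponsePoint(
                    dose=float(row["dose"]), fa=float(row["fa"]), unit=row["unit"]
                )
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}:{i}: {exc}") from exc
            groups.setdefault(row["drug"], []).append(point)
    return groups


def write_points_csv(path: str | Path, groups: dict[str, Iterable[DoseResponsePoint]]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(POINTS_COLUMNS)
        for drug, points in groups.items():
            for p in points:
                writer.writerow([drug, repr(p.dose), p.unit, repr(p.fa)])
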