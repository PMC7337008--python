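"""MTT plate processing: OD490 readings to viability %, inhibition %, and fa.

Viability is ``(A_sample - A_blank) / (A_control - A_blank) * 100``.
Controls and blanks are pooled by mean within a plate group before the
formula is applied; sample replicates are then converted individually and
summarised as mean +/- SD (sample SD, n-1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import InvalidArgumentError, InvalidPlateError, SchemaError

ROLES = ("sample", "control", "blank")

__all__ = [
    "PlateMeasurement",
    "ViabilityTable",
    "viability_percent",
    "inhibition_rate",
    "aggregate_replicates",
    "read_plate_csv",
]


@dataclass(frozen=True)
class PlateMeasurement:
    """One well reading.  ``dose`` is ignored for control and blank rows."""

    drug: str
    dose: float
    unit: str
    replicate: int
    role: str
    od490: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InvalidArgumentError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.od490 < 0 or not math.isfinite(self.od490):
            raise InvalidArgumentError(f"od490 must be >= 0, got {self.od490!r}")
        if self.replicate < 1:
            raise InvalidArgumentError(f"replicate must be >= 1, got {self.replicate!r}")
        if self.role == "sample" and self.dose < 0:
            raise InvalidArgumentError(f"dose must be >= 0, got {self.dose!r}")


@dataclass(frozen=True)
class ViabilityTable:
    """Per-(drug, dose) viability summary.

    ``data`` columns: drug, dose, unit, n, viability_mean_raw (audit copy,
    may leave [0, 100]), viability_mean (truncated), viability_sd,
    inhibition_mean, fa.
    """

    data: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def viability_percent(a_sample: float, a_control: float, a_blank: float) -> float:
    """Raw viability %; may exceed [0, 100] on noisy plates (truncation is downstream)."""
    if a_control <= a_blank:
        raise InvalidPlateError(
            f"no signal window: control OD {a_control!r} <= blank OD {a_blank!r}"
        )
    return (a_sample - a_blank) / (a_control - a_blank) * 100.0


def inhibition_rate(viability: float) -> float:
    """Complement of viability, truncated to [0, 100]."""
    return min(max(100.0 - viability, 0.0), 100.0)


def aggregate_replicates(rows: Sequence[PlateMeasurement]) -> ViabilityTable:
    """Summarise plate rows into a per-(drug, dose) viability table.

    Within each plate group (one drug label), control and blank ODs are
    averaged first; each sample replicate is then converted to viability %
    and summarised per dose.  Viability is truncated to [0, 100] before the
    fa conversion ``fa = 1 - viability/100``; the raw mean is retained for
    audit.
    """
    if not rows:
        raise InvalidPlateError("empty plate")
    df = pd.DataFrame(
        {
            "drug": [r.drug for r in rows],
            "dose": [r.dose for r in rows],
            "unit": [r.unit for r in rows],
            "replicate": [r.replicate for r in rows],
            "role": [r.role for r in rows],
            "od490": [r.od490 for r in rows],
        }
    )
    out_records = []
    for drug, group in df.groupby("drug", sort=True):
        controls = group.loc[group["role"] == "control", "od490"]
        blanks = group.loc[group["role"] == "blank", "od490"]
        if controls.empty or blanks.empty:
            raise InvalidPlateError(f"plate group {drug!r}: missing control or blank rows")
        a_control = controls.mean()
        a_blank = blanks.mean()
        samples = group[group["role"] == "sample"]
        for (dose, unit), sub in samples.groupby(["dose", "unit"], sort=True):
            viab = sub["od490"].map(lambda od: viability_percent(od, a_control, a_blank))
            mean_raw = float(viab.mean())
            sd = float(viab.std(ddof=1)) if len(viab) > 1 else 0.0
            mean_trunc = min(max(mean_raw, 0.0), 100.0)
            out_records.append(
                {
                    "drug": drug,
                    "dose": float(dose),
                    "unit": unit,
                    "n": int(len(viab)),
                    "viability_mean_raw": mean_raw,
                    "viability_mean": mean_trunc,
                    "viability_sd": sd,
                    "inhibition_mean": inhibition_rate(mean_raw),
                    "fa": 1.0 - mean_trunc / 100.0,
                }
            )
    return ViabilityTable(pd.DataFrame(out_records))


PLATE_COLUMNS = ("drug", "dose", "unit", "replicate", "role", "od490")


def read_plate_csv(path: str | Path) -> list[PlateMeasurement]:
    """Read plate rows from CSV with header ``drug,dose,unit,replicate,role,od490``."""
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            PlateMeasurement(
                drug=str(rec.drug),
                dose=float(rec.dose),
                unit=str(rec.unit),
                replicate=int(rec.replicate),
                role=str(rec.role),
                od490=float(rec.od490),
            )
        )
    return rows
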