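"""Synthetic dose-response and protein tables with known ground truth.

Single-drug curves are drawn directly from the median-effect model.  A
fixed-ratio mixture with a prescribed true combination-index profile
``kappa`` is constructed from Loewe additivity: the additive total dose at
fraction affected fa is

    D_add(fa) = ( sum_j w_j / Dx_j(fa) ) ** -1

and the generated mixture reaches fa at total dose ``kappa(fa) * D_add(fa)``.
For a requested total-dose grid, fa is obtained by monotone root finding on
that relation.  Running the combination pipeline on the output therefore
recovers CI ~= kappa by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import bisect

from .combination import CombinationObservation
from .errors import InvalidArgumentError, NumericalError
from .median_effect import DoseResponsePoint, MedianEffectParams, dose_for_fa, fa_from_dose
from .screen import ProteinQuant
from .viability import PlateMeasurement

__all__ = [
    "DrugTruth",
    "SimulationConfig",
    "ProteinTableTruth",
    "simulate_single_drug",
    "simulate_combination",
    "simulate_protein_table",
    "points_to_plate_rows",
    "loewe_additive_dose",
]

_FA_BRACKET = (1e-6, 1.0 - 1e-6)


@dataclass(frozen=True)
class DrugTruth:
    """Ground-truth (name, Dm, m) for one simulated drug."""

    name: str
    dm: float
    m: float

    def params(self, unit: str = "uM") -> MedianEffectParams:
        return MedianEffectParams(dm=self.dm, m=self.m, unit=unit)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for one simulation; ``seed`` fixes every source of randomness.

    ``true_ci`` is either a positive constant kappa or a sequence of
    (fa, kappa) pairs interpolated linearly in fa.  ``weights`` default to
    Dm-proportional.  ``dose_levels`` (totals for the mixture, per-drug doses
    for singles) default to a ``dilution_factor`` ladder centred on the
    relevant median dose.  Noise is additive on fa, truncated to [0, 1].
    """

    drugs: tuple[DrugTruth, ...]
    unit: str = "uM"
    weights: tuple[float, ...] | None = None
    true_ci: float | tuple[tuple[float, float], ...] = 1.0
    dose_levels: tuple[float, ...] | None = None
    n_levels: int = 8
    dilution_factor: float = 1.5
    sigma: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.drugs:
            raise InvalidArgumentError("config needs at least one drug")
        if self.sigma < 0:
            raise InvalidArgumentError("sigma must be >= 0")
        if self.replicates < 1:
            raise InvalidArgumentError("replicates must be >= 1")
        if self.weights is not None:
            if len(self.weights) != len(self.drugs):
                raise InvalidArgumentError("one weight per drug required")
            if any(w <= 0 for w in self.weights):
                raise InvalidArgumentError("weights must be positive")
        kappa = self.kappa_fn()
        if kappa(0.5) <= 0:
            raise InvalidArgumentError("true_ci must be positive")

    def resolved_weights(self) -> tuple[float, ...]:
        if self.weights is not None:
            total = sum(self.weights)
            return tuple(w / total for w in self.weights)
        dm_sum = sum(d.dm for d in self.drugs)
        return tuple(d.dm / dm_sum for d in self.drugs)

    def kappa_fn(self) -> Callable[[float], float]:
        if isinstance(self.true_ci, (int, float)):
            k = float(self.true_ci)
            return lambda fa: k
        table = sorted((float(fa), float(k)) for fa, k in self.true_ci)
        xs = np.array([t[0] for t in table])
        ys = np.array([t[1] for t in table])
        return lambda fa: float(np.interp(fa, xs, ys))

    def single_params(self) -> list[MedianEffectParams]:
        return [d.params(self.unit) for d in self.drugs]


def _ladder(center: float, factor: float, n_levels: int) -> list[float]:
    # geometric ladder with `center` at (or next to) the middle rung, descending
    mid = (n_levels - 1) // 2
    top = center * factor**mid
    return [top / factor**k for k in range(n_levels)]


def _noisy_fa(fa_true: float, rng: np.random.Generator, sigma: float) -> float:
    if sigma == 0.0:
        return fa_true
    return float(np.clip(fa_true + rng.normal(0.0, sigma), 0.0, 1.0))


def simulate_single_drug(
    config: SimulationConfig, drug: str | int = 0
) -> list[DoseResponsePoint]:
    """Simulate one drug's dose-response points.

    Noiseless mode lies exactly on the forward median-effect curve; noisy
    mode adds truncated Gaussian noise to fa independently per replicate.
    Identical seeds produce identical output.
    """
    if isinstance(drug, int):
        truth = config.drugs[drug]
    else:
        matches = [d for d in config.drugs if d.name == drug]
        if not matches:
            raise InvalidArgumentError(f"no drug named {drug!r} in config")
        truth = matches[0]
    params = truth.params(config.unit)
    doses = config.dose_levels or _ladder(truth.dm, config.dilution_factor, config.n_levels)
    rng = np.random.default_rng(config.seed)
    points = []
    for dose in doses:
        fa_true = fa_from_dose(params, dose)
        for _ in range(config.replicates):
            points.append(
                DoseResponsePoint(
                    dose=float(dose), fa=_noisy_fa(fa_true, rng, config.sigma), unit=config.unit
                )
            )
    return points


def loewe_additive_dose(
    single_params: Sequence[MedianEffectParams], weights: Sequence[float], fa: float
) -> float:
    """Total mixture dose that Loewe additivity predicts for fraction affected fa."""
    return 1.0 / sum(w / dose_for_fa(p, fa) for p, w in zip(single_params, weights))


def simulate_combination(config: SimulationConfig) -> list[CombinationObservation]:
    """Simulate fixed-ratio mixture observations with true CI profile ``kappa``.

    For each total dose D on the ladder, solves
    ``kappa(fa) * D_add(fa) = D`` for fa by bisection on
    [1e-6, 1 - 1e-6] (monotone, derivative-free), then applies the
    configured fa-noise per replicate.
    """
    params = config.single_params()
    weights = config.resolved_weights()
    kappa = config.kappa_fn()

    def mixture_dose(fa: float) -> float:
        return kappa(fa) * loewe_additive_dose(params, weights, fa)

    totals = config.dose_levels or _ladder(
        mixture_dose(0.5), config.dilution_factor, config.n_levels
    )
    rng = np.random.default_rng(config.seed)
    observations = []
    lo, hi = _FA_BRACKET
    for total in totals:
        g = lambda fa: mixture_dose(fa) - total  # noqa: E731 — local objective
        if g(lo) > 0 or g(hi) < 0:
            raise NumericalError(
                f"total dose {total!r} outside the attainable range "
                f"[{mixture_dose(lo):.4g}, {mixture_dose(hi):.4g}]"
            )
        try:
            fa_true = float(bisect(g, lo, hi, xtol=1e-10))
        except RuntimeError as exc:  # pragma: no cover - bisection on a bracket converges
            raise NumericalError(f"root finding failed at total dose {total!r}: {exc}") from exc
        doses = tuple(w * total for w in weights)
        for _ in range(config.replicates):
            observations.append(
                CombinationObservation(
                    component_doses=doses, fa=_noisy_fa(fa_true, rng, config.sigma)
                )
            )
    return observations


def points_to_plate_rows(
    points: Sequence[DoseResponsePoint],
    drug: str,
    control_od: float = 2.0,
    blank_od: float = 0.2,
    n_controls: int = 3,
) -> list[PlateMeasurement]:
    """Render fa points as raw OD490 plate rows (for viability-module tests).

    OD = blank + (control - blank) * (1 - fa); control/blank rows are
    appended as constants.
    """
    if control_od <= blank_od:
        raise InvalidArgumentError("control_od must exceed blank_od")
    rows = []
    rep_counter: dict[float, int] = {}
    for p in points:
        rep = rep_counter.get(p.dose, 0) + 1
        rep_counter[p.dose] = rep
        od = blank_od + (control_od - blank_od) * (1.0 - p.fa)
        rows.append(
            PlateMeasurement(
                drug=drug, dose=p.dose, unit=p.unit, replicate=rep, role="sample", od490=od
            )
        )
    for rep in range(1, n_controls + 1):
        rows.append(
            PlateMeasurement(
                drug=drug, dose=0.0, unit=points[0].unit if points else "uM",
                replicate=rep, role="control", od490=control_od,
            )
        )
        rows.append(
            PlateMeasurement(
                drug=drug, dose=0.0, unit=points[0].unit if points else "uM",
                replicate=rep, role="blank", od490=blank_od,
            )
        )
    return rows


@dataclass(frozen=True)
class ProteinTableTruth:
    """Simulated protein fold-change table plus the planted ground truth."""

    proteins: tuple[ProteinQuant, ...]
    up_ids: frozenset[str]
    down_ids: frozenset[str]


def simulate_protein_table(
    n: int,
    frac_up: float,
    frac_down: float,
    effect_size: float = 1.0,
    seed: int = 0,
) -> ProteinTableTruth:
    """Plant differential proteins among nulls.

    Planted up-regulated proteins get fold change strictly above 1.5 and
    planted down-regulated strictly below 0.67 (margins scale with
    ``effect_size``, a log2 spread).  Null fold changes are lognormal
    centred at 1 and clipped into [0.67, 1.5] so the strict thresholds
    recover exactly the planted sets.
    """
    if frac_up < 0 or frac_down < 0 or frac_up + frac_down > 1:
        raise InvalidArgumentError("need frac_up, frac_down >= 0 and frac_up + frac_down <= 1")
    if effect_size <= 0:
        raise InvalidArgumentError("effect_size must be positive")
    n_up = round(n * frac_up)
    n_down = round(n * frac_down)
    n_null = n - n_up - n_down
    rng = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(1, n + 1)]
    order = rng.permutation(n)
    up_ids = frozenset(ids[i] for i in order[:n_up])
    down_ids = frozenset(ids[i] for i in order[n_up : n_up + n_down])

    fc = np.empty(n)
    fc[order[:n_up]] = 1.5 * 2.0 ** rng.uniform(0.1, 0.1 + effect_size, n_up)
    fc[order[n_up : n_up + n_down]] = 0.67 / 2.0 ** rng.uniform(0.1, 0.1 + effect_size, n_down)
    nulls = 2.0 ** rng.normal(0.0, 0.15, n_null)
    fc[order[n_up + n_down :]] = np.clip(nulls, 0.67, 1.5)

    proteins = tuple(ProteinQuant(id=i, fold_change=float(f)) for i, f in zip(ids, fc))
    return ProteinTableTruth(proteins=proteins, up_ids=up_ids, down_ids=down_ids)
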