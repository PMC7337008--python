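"""End-to-end synergy pipeline: fit singles, fit mixture, CI table, Fa-CI curve.

All outputs are UTF-8 CSV with dot decimals.  The display CI table rounds
doses and CI to 2 decimals; a lossless full-precision companion file
(``*_full.csv``) is always written alongside.  A machine-readable run
manifest records inputs, configuration, package versions, and seed so that
re-running the same manifest reproduces byte-identical full-precision
outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__ as _pkg_version
from .combination import (
    CIRecord,
    classify_ci,
    ci_records_from_observations,
    default_fa_grid,
    design_fixed_ratio,
    fa_ci_curve,
    fit_combination_as_single,
    read_combination_csv,
)
from .errors import DrugComboError, InvalidArgumentError, PipelineError, SchemaError
from .median_effect import MedianEffectParams, fit_median_effect, read_points_csv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_synergy_pipeline", "write_ci_table"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run."""

    single_csv: Path
    combo_csv: Path
    outdir: Path
    dilution_factor: float = 1.5
    n_levels: int = 8
    fa_grid: tuple[float, ...] = field(default_factory=lambda: tuple(default_fa_grid()))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1.0:
            raise InvalidArgumentError("dilution_factor must be > 1")
        if self.n_levels < 2:
            raise InvalidArgumentError("n_levels must be >= 2")
        if any(not 0.0 < fa < 1.0 for fa in self.fa_grid):
            raise InvalidArgumentError("fa_grid values must lie strictly in (0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {
            "single_csv": Path(raw["single_csv"]),
            "combo_csv": Path(raw["combo_csv"]),
            "outdir": Path(raw["outdir"]),
        }
        for key in ("dilution_factor", "n_levels", "seed"):
            if key in raw:
                known[key] = raw[key]
        if "fa_grid" in raw:
            known["fa_grid"] = tuple(float(x) for x in raw["fa_grid"])
        return cls(**known)

    def to_dict(self) -> dict:
        return {
            "single_csv": str(self.single_csv),
            "combo_csv": str(self.combo_csv),
            "outdir": str(self.outdir),
            "dilution_factor": self.dilution_factor,
            "n_levels": self.n_levels,
            "fa_grid": list(self.fa_grid),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class PipelineResult:
    single_fits: dict[str, MedianEffectParams]
    combo_fit: MedianEffectParams
    ci_records: list[CIRecord]
    curve: list[tuple[float, float]]
    components: list[str]
    outputs: dict[str, Path]


@contextmanager
def _stage(name: str):
    start = time.perf_counter()
    try:
        yield
    except DrugComboError as exc:
        raise PipelineError(f"[{name}] {exc}") from exc
    logger.info("stage %s finished in %.3f s", name, time.perf_counter() - start)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_ci_table(
    records: Sequence[CIRecord], path: str | Path, components: Sequence[str] | None = None
) -> Path:
    """Write the CI table: component doses, fa, CI, verdict.

    Doses and CI are formatted to 2 decimals in the display file; the
    ``*_full.csv`` companion keeps full precision and round-trips exactly.
    """
    path = Path(path)
    if components is None:
        n = len(records[0].component_doses) if records else 0
        components = [f"drug{i + 1}" for i in range(n)]
    header = [*components, "fa", "ci", "verdict"]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            writer.writerow(
                [
                    *(f"{d:.2f}" for d in rec.component_doses),
                    f"{rec.fa_observed:.4f}",
                    f"{rec.ci:.2f}",
                    rec.verdict.label,
                ]
            )
    full = path.with_name(path.stem + "_full.csv")
    with full.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            writer.writerow(
                [
                    *(repr(d) for d in rec.component_doses),
                    repr(rec.fa_observed),
                    repr(rec.ci),
                    rec.verdict.label,
                ]
            )
    return full


def read_ci_table_full(path: str | Path) -> list[CIRecord]:
    """Round-trip reader for the full-precision CI table."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        try:
            fa_idx = header.index("fa")
        except ValueError as exc:
            raise SchemaError(f"{path}: missing column(s) ['fa']") from exc
        records = []
        for row in reader:
            doses = tuple(float(v) for v in row[:fa_idx])
            fa = float(row[fa_idx])
            ci = float(row[fa_idx + 1])
            records.append(
                CIRecord(component_doses=doses, fa_observed=fa, ci=ci, verdict=classify_ci(ci))
            )
    return records


def run_synergy_pipeline(config: RunConfig) -> PipelineResult:
    """Run fit -> design -> CI -> curve and write the report bundle.

    Outputs (all CSV unless noted): ``single_fits.csv``, ``combo_fit.csv``,
    ``ci_table.csv`` + ``ci_table_full.csv``, ``fa_ci_curve.csv``, and
    ``manifest.json``.  Any stage error aborts with a stage-tagged message
    and no partial outputs are left in ``outdir``.
    """
    with _stage("read-singles"):
        groups = read_points_csv(config.single_csv)
        if not groups:
            raise SchemaError(f"{config.single_csv}: no data rows")

    with _stage("fit-singles"):
        single_fits = {drug: fit_median_effect(pts) for drug, pts in sorted(groups.items())}

    with _stage("read-combination"):
        components, observations = read_combination_csv(config.combo_csv)
        unknown = [c for c in components if c not in single_fits]
        if unknown:
            raise SchemaError(
                f"{config.combo_csv}: component column(s) {unknown} have no single-drug curve"
            )
        single_params = [single_fits[c] for c in components]

    with _stage("fit-combination"):
        unit = single_params[0].unit
        combo_fit = fit_combination_as_single(observations, unit=unit)

    with _stage("design"):
        design = design_fixed_ratio(
            single_params,
            dilution_factor=config.dilution_factor,
            n_levels=config.n_levels,
            components=components,
        )

    with _stage("ci-table"):
        ci_records = ci_records_from_observations(single_params, observations)

    with _stage("fa-ci-curve"):
        curve = fa_ci_curve(single_params, combo_fit, design, config.fa_grid)

    with _stage("write-report"):
        outputs = _write_bundle(
            config, components, single_fits, combo_fit, design, ci_records, curve
        )

    return PipelineResult(
        single_fits=single_fits,
        combo_fit=combo_fit,
        ci_records=ci_records,
        curve=curve,
        components=components,
        outputs=outputs,
    )


def _write_bundle(config, components, single_fits, combo_fit, design, ci_records, curve):
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        fits_path = outdir / "single_fits.csv"
        with fits_path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["drug", "dm", "m", "r", "unit", "n_used", "n_excluded"])
            for drug, p in single_fits.items():
                writer.writerow([drug, repr(p.dm), repr(p.m), repr(p.r), p.unit, p.n_used, p.n_excluded])
        written["single_fits"] = fits_path

        combo_path = outdir / "combo_fit.csv"
        with combo_path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["dm", "m", "r", "unit", "n_used", "n_excluded", "weights"])
            writer.writerow(
                [
                    repr(combo_fit.dm), repr(combo_fit.m), repr(combo_fit.r), combo_fit.unit,
                    combo_fit.n_used, combo_fit.n_excluded,
                    ";".join(repr(w) for w in design.weights),
                ]
            )
        written["combo_fit"] = combo_path

        ci_path = outdir / "ci_table.csv"
        full = write_ci_table(ci_records, ci_path, components)
        written["ci_table"] = ci_path
        written["ci_table_full"] = full

        curve_path = outdir / "fa_ci_curve.csv"
        with curve_path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fa", "ci", "verdict"])
            for fa, ci in curve:
                writer.writerow([repr(fa), repr(ci), classify_ci(ci).label])
        written["fa_ci_curve"] = curve_path

        manifest = {
            "tool": "drugcombo",
            "version": _pkg_version,
            "config": config.to_dict(),
            "inputs": {
                "single_csv": _sha256(Path(config.single_csv)),
                "combo_csv": _sha256(Path(config.combo_csv)),
            },
            "components": list(components),
            "seed": config.seed,
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = manifest_path
    except Exception:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise
    return written
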