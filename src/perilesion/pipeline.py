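"""Reproducible simulate -> annotate -> curves -> fit pipeline.

Configuration lives in one YAML/JSON-able mapping; a single seed drives
all randomness; every run writes a manifest (config echo, seed, package
version, row counts at each filter stage) from which the outputs are fully
regenerable.  Partial outputs are removed if a stage fails.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .grid import build_t_grid, write_grid
from .lesions import annotate_dataset, read_mask, write_mask
from .loess import curves_by_stratum, curves_to_frame
from .model import FitOptions, fit
from .simulate import LesionFieldConfig, SimulationConfig, simulate_cohort
from .model import SegmentedModelParams

__all__ = ["PipelineConfig", "RecordValidationError", "validate_records", "run_pipeline"]

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["participant_id", "visit_month", "locus_id", "sensitivity_db", "scotoma"]


class RecordValidationError(ValueError):
    """Schema violations in an input records table, with row numbers."""

    def __init__(self, problems: list[str]) -> None:
        self.problems = problems
        super().__init__("invalid records:\n" + "\n".join(problems))


def validate_records(records: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Type- and range-check a sensitivity records table.

    Row numbers in error messages refer to CSV data lines (header = line 1).
    Checks: required columns present; months >= 0; sensitivity in [0, 20];
    scotoma implies 0 dB; no duplicate (participant, visit, locus) keys.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.read_csv(records)
    problems: list[str] = []
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise RecordValidationError([f"missing columns: {missing}"])

    df = records.copy()
    line = df.index + 2  # header occupies line 1

    months = pd.to_numeric(df["visit_month"], errors="coerce")
    for i in df.index[months.isna() | (months < 0)]:
        problems.append(f"line {line[i]}: visit_month must be a number >= 0")
    sens = pd.to_numeric(df["sensitivity_db"], errors="coerce")
    for i in df.index[sens.isna() | (sens < 0) | (sens > 20)]:
        problems.append(f"line {line[i]}: sensitivity_db must be in [0, 20]")
    scot = df["scotoma"].astype(bool)
    for i in df.index[scot & (sens != 0)]:
        problems.append(f"line {line[i]}: scotoma records must have sensitivity_db = 0")
    dup = df.duplicated(subset=["participant_id", "visit_month", "locus_id"], keep=False)
    for i in df.index[dup & ~df.duplicated(subset=["participant_id", "visit_month", "locus_id"])]:
        problems.append(
            f"line {line[i]}: duplicate (participant_id, visit_month, locus_id) key"
        )
    if problems:
        raise RecordValidationError(problems)

    df["visit_month"] = months
    df["sensitivity_db"] = sens
    df["scotoma"] = scot
    df["locus_id"] = df["locus_id"].astype(int)
    df["participant_id"] = df["participant_id"].astype(str)
    return df


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Either ``simulate`` is set (synthetic inputs) or ``records_csv`` and
    ``masks_dir`` point at existing data.  CLI flags override config keys.
    """

    out_dir: str | Path = "pipeline_out"
    records_csv: str | Path | None = None
    masks_dir: str | Path | None = None
    simulate: SimulationConfig | None = None
    grid_args: dict[str, float] = field(default_factory=dict)
    exclude_intralesional: bool = True
    loess_span: float = 0.5
    loess_degree: int = 1
    stratify: tuple[str, ...] = ("none", "axis", "visit")
    fit_options: FitOptions = field(default_factory=FitOptions)
    write_masks: bool = False
    make_plots: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if isinstance(sim, dict):
            sim = dict(sim)
            lesions = sim.pop("lesions", None)
            params = sim.pop("true_params", None)
            if isinstance(lesions, dict):
                lesions = LesionFieldConfig(**lesions)
                sim["lesions"] = lesions
            if isinstance(params, dict):
                sim["true_params"] = SegmentedModelParams(**params)
            if "visit_months" in sim:
                sim["visit_months"] = tuple(sim["visit_months"])
            sim = SimulationConfig(**sim)
        fo = raw.pop("fit_options", None)
        if isinstance(fo, dict):
            fo = FitOptions(**fo)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = sim
        if fo is not None:
            cfg.fit_options = fo
        if "stratify" in raw:
            cfg.stratify = tuple(raw["stratify"])
        return cfg

    def to_dict(self) -> dict[str, Any]:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis and write an artifact bundle under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``).  Outputs are
    deterministic given the config, so re-running with an identical config
    yields byte-identical CSVs.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    if config.records_csv is not None and Path(config.records_csv).resolve() == out.resolve():
        raise ValueError("output directory must differ from inputs")
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict[str, int] = {}
    try:
        grid = build_t_grid(**config.grid_args)
        write_grid(grid, out / "grid.csv")
        written.append(out / "grid.csv")

        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, rng_seed=config.seed)
            cohort = simulate_cohort(sim_cfg)
            records, masks = cohort.records, cohort.masks
            counts["simulated"] = len(records)
            _write_csv(records, out / "records.csv")
            written.append(out / "records.csv")
            _write_csv(cohort.truth, out / "truth.csv")
            written.append(out / "truth.csv")
            if config.write_masks:
                mask_dir = out / "masks"
                mask_dir.mkdir(exist_ok=True)
                for (pid, month), mask in masks.items():
                    write_mask(mask, mask_dir / f"{pid}_m{month:g}.png")
        else:
            if config.records_csv is None or config.masks_dir is None:
                raise ValueError("need records_csv and masks_dir when not simulating")
            records = validate_records(config.records_csv)
            counts["validated"] = len(records)
            masks = {}
            for png in sorted(Path(config.masks_dir).glob("*.png")):
                m = read_mask(png)
                masks[(m.participant_id, m.visit_month)] = m
        log.info("records: %d", len(records))

        annotated = annotate_dataset(records, masks, grid)
        counts["annotated"] = len(annotated)
        extralesional = annotated[~annotated["inside_ga"]]
        counts["extralesional"] = len(extralesional)
        _write_csv(annotated, out / "annotated.csv")
        written.append(out / "annotated.csv")

        all_curves = []
        for strat in config.stratify:
            all_curves.extend(
                curves_by_stratum(
                    annotated, strat, span=config.loess_span, degree=config.loess_degree
                )
            )
        curve_frame = curves_to_frame(all_curves)
        _write_csv(curve_frame, out / "curves.csv")
        written.append(out / "curves.csv")
        if config.make_plots:
            _plot_curves(all_curves, out / "curves.png")

        model_input = extralesional if config.exclude_intralesional else annotated
        counts["modeled"] = len(model_input)
        result = fit(annotated, config.fit_options)
        report = result.to_frame()
        _write_csv(report, out / "fit_report.csv")
        written.append(out / "fit_report.csv")
        (out / "fit_report.json").write_text(
            json.dumps(
                {
                    "estimates": {r.parameter: r.estimate for r in report.itertuples()},
                    "ci95": {r.parameter: [r.ci95_low, r.ci95_high] for r in report.itertuples()},
                    "loglik": result.loglik,
                    "n_obs": result.n_obs,
                    "n_clusters": result.n_clusters,
                    "converged": result.converged,
                },
                indent=1,
            )
        )
        written.append(out / "fit_report.json")

        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "version": __version__,
            "counts": counts,
            "outputs": [p.name for p in written],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _plot_curves(curves, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for c in curves:
        ax.plot(c.grid_x, c.fitted_y, label=c.stratum)
    ax.set_xlabel("distance from GA border (deg)")
    ax.set_ylabel("sensitivity (dB)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
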