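"""End-to-end analysis pipeline: measurements -> D_P -> species fit ->
censored report -> scenario maps.

Deterministic given inputs and seed: results go to files, logging to
standard error, and rows are written in sorted order with fixed float
formatting so repeated runs are byte-identical.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import scenarios as sc
from .batch import BatchCondition, aggregate_dp, dp_from_measurement
from .errors import InvalidInputError, PipelineError, PhsorbError
from .fitting import censor_fit, fit_species_k
from .io import format_sci, read_compound_table, read_measurements
from .synthetic import MP_KG, VW_L

log = logging.getLogger("phsorb")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    ``compound_table`` of None selects the bundled property table.
    ``vw``/``mp`` give the batch geometry used for the mass balance
    (defaults: 100 mL over 100 mg, LSR 1e3 L/kg).
    """

    measurements: Path
    outdir: Path
    compound_table: Path | None = None
    vw: float = VW_L
    mp: float = MP_KG
    epsilon: float = 0.05
    error_bound: float = 1.0
    censor_threshold: float = 50.0
    cv_flag_threshold: float = 100.0
    fit_mode: str = "pooled"
    seed: int = 0
    log_level: str = "INFO"
    scenario_overlays: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.measurements = Path(self.measurements)
        self.outdir = Path(self.outdir)
        if self.compound_table is not None:
            self.compound_table = Path(self.compound_table)
        for name in ("censor_threshold", "cv_flag_threshold", "error_bound", "epsilon"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON config file."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise InvalidInputError(f"{path}: config must be a mapping")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write its reports.

    Outputs under ``config.outdir``:

    * ``dp_table.csv`` — per compound x polymer x pH: mean D_P, CV%, n.
    * ``fit_report.json`` — per compound x polymer: coefficients, tokens,
      flags, per-pH CV, rss.
    * ``fits_censored.csv`` — flat result-table-style mirror.
    * ``scenario_I_map.csv`` / ``scenario_II_map.csv`` — dissolved-fraction
      grids for the laboratory and environmental plastic loadings.
    * ``scenario_overlays.csv`` — only when overlays are configured.

    Returns a mapping of output names to paths.
    """
    logging.basicConfig(level=config.log_level)
    compounds = {c.name: c for c in read_compound_table(config.compound_table)}
    log.info("loaded %d compound records", len(compounds))
    df = read_measurements(config.measurements)
    log.info("loaded %d measurement rows", len(df))

    missing = sorted(set(df["compound"]) - set(compounds))
    if missing:
        raise PipelineError(
            f"stage dp: measurement compounds missing from the compound "
            f"table: {', '.join(missing)}"
        )

    config.outdir.mkdir(parents=True, exist_ok=True)

    # Stage 1: per-measurement D_P, aggregated per compound x polymer x pH.
    post = df[df["time_days"] > 0]
    dp_rows = []
    dp_values: dict[tuple[str, str], list[tuple[float, float]]] = {}
    estimates: dict[tuple[str, str], list] = {}
    for (compound, polymer, ph), grp in post.groupby(
        ["compound", "polymer", "ph"], sort=True
    ):
        try:
            values = [
                dp_from_measurement(
                    BatchCondition(
                        vw=config.vw, mp=config.mp, c0=row.c0_ug_per_L, ph=ph
                    ),
                    row.cw_ug_per_L,
                )
                for row in grp.itertuples(index=False)
            ]
        except PhsorbError as exc:
            raise PipelineError(f"stage dp: {compound}/{polymer}: {exc}") from exc
        est = aggregate_dp(values, ph)
        estimates.setdefault((compound, polymer), []).append(est)
        dp_values.setdefault((compound, polymer), []).extend(
            (ph, v) for v in values
        )
        dp_rows.append(
            {
                "compound": compound,
                "polymer": polymer,
                "ph": ph,
                "dp_mean_L_per_kg": est.dp_mean,
                "cv_percent": est.cv_percent,
                "n_obs": est.n_obs,
            }
        )
    log.info("computed D_P for %d compound/polymer/pH groups", len(dp_rows))

    dp_path = config.outdir / "dp_table.csv"
    with open(dp_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["compound", "polymer", "ph", "dp_mean_L_per_kg", "cv_percent", "n_obs"]
        )
        for r in dp_rows:
            writer.writerow(
                [
                    r["compound"],
                    r["polymer"],
                    format_sci(r["ph"], 6),
                    format_sci(r["dp_mean_L_per_kg"]),
                    "" if r["cv_percent"] is None else format_sci(r["cv_percent"]),
                    r["n_obs"],
                ]
            )

    # Stage 2: species fits and censored report.
    report: dict[str, dict[str, Any]] = {}
    n_flagged = 0
    for (compound, polymer), obs in sorted(dp_values.items()):
        comp = compounds[compound]
        try:
            fit = fit_species_k(
                obs,
                comp.pka,
                comp.ion_class,
                censor_threshold=config.censor_threshold,
                mode=config.fit_mode,
            )
        except PhsorbError as exc:
            raise PipelineError(f"stage fit: {compound}/{polymer}: {exc}") from exc
        row = censor_fit(
            fit,
            estimates[(compound, polymer)],
            censor_threshold=config.censor_threshold,
            cv_flag_threshold=config.cv_flag_threshold,
        )
        n_flagged += sum(row["cv_flags"].values())
        report.setdefault(compound, {})[polymer] = row
    log.info(
        "fitted %d compound/polymer pairs; %d pH groups carry CV flags",
        sum(len(v) for v in report.values()),
        n_flagged,
    )

    fit_json = config.outdir / "fit_report.json"
    with open(fit_json, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    censored_csv = config.outdir / "fits_censored.csv"
    phs = sorted({r["ph"] for r in dp_rows})
    with open(censored_csv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        cv_cols = [f"cv_ph{g:g}" for g in phs]
        flag_cols = [f"cv_flag_ph{g:g}" for g in phs]
        writer.writerow(
            ["compound", "polymer", "kp_n_report", "kp_i_report"]
            + cv_cols
            + flag_cols
            + ["kp_n_value", "kp_i_value", "n_points", "rss"]
        )
        for compound in sorted(report):
            for polymer in sorted(report[compound]):
                row = report[compound][polymer]
                cvs = [
                    ""
                    if row["cv_percent"].get(g) is None
                    else format_sci(row["cv_percent"][g], 6)
                    for g in phs
                ]
                flags = [str(bool(row["cv_flags"].get(g, False))) for g in phs]
                writer.writerow(
                    [compound, polymer, row["kp_n"], row["kp_i"]]
                    + cvs
                    + flags
                    + [
                        format_sci(row["kp_n_value"]),
                        format_sci(row["kp_i_value"]),
                        row["n_points"],
                        format_sci(row["rss"]),
                    ]
                )

    # Stage 3: scenario maps (and optional overlays).
    outputs = {
        "dp_table": dp_path,
        "fit_report": fit_json,
        "fits_censored": censored_csv,
    }
    for label, spec in (("I", sc.SCENARIO_I), ("II", sc.SCENARIO_II)):
        grid = sc.scenario_map(spec)
        path = config.outdir / f"scenario_{label}_map.csv"
        _write_grid(grid, path)
        outputs[f"scenario_{label}_map"] = path
    if config.scenario_overlays:
        rows = [
            (o["name"], float(o["koc"]), float(o["kp"]), float(o.get("ph", 7.0)))
            for o in config.scenario_overlays
        ]
        frames = []
        for label, spec in (("I", sc.SCENARIO_I), ("II", sc.SCENARIO_II)):
            ov = sc.overlay_points(spec, rows)
            ov.insert(0, "scenario", label)
            frames.append(ov)
        path = config.outdir / "scenario_overlays.csv"
        _write_overlays(frames, path)
        outputs["scenario_overlays"] = path
    log.info("wrote %d outputs to %s", len(outputs), config.outdir)
    return outputs


def _write_grid(grid, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["koc", "kp", "f_diss", "cw_eq"])
        for row in grid.itertuples(index=False):
            writer.writerow(
                [
                    format_sci(row.koc),
                    format_sci(row.kp),
                    format_sci(row.f_diss),
                    format_sci(row.cw_eq),
                ]
            )


def _write_overlays(frames, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scenario", "name", "ph", "koc", "kp", "f_diss", "cw_eq"])
        for frame in frames:
            for row in frame.itertuples(index=False):
                writer.writerow(
                    [
                        row.scenario,
                        row.name,
                        format_sci(row.ph, 6),
                        format_sci(row.koc),
                        format_sci(row.kp),
                        format_sci(row.f_diss),
                        format_sci(row.cw_eq),
                    ]
                )
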