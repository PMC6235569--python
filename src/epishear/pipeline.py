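"""End-to-end orchestration: generate -> kymograph -> fits -> model -> compare.

One `run_pipeline(config)` call executes, per condition and replicate,
the synthetic generation (or loading of external PIV tables), kymograph
folding and integration, oscillation and force-relaxation fits, the
mechanical-model simulation, and — when several conditions run — the
rank-based condition comparison.  Outputs are CSV stage files plus a JSON
`RunReport`; a run is byte-reproducible from its config and master seed.

Replicate seeds derive from the master seed as
``seed + 1000 * condition_index + replicate`` so any single replicate can be
regenerated in isolation.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .grid import GridSpec, VelocityField
from .presets import make_condition_preset
from .synth import (GroundTruth, generate_sensing_trace, generate_velocity_series,
                    write_velocity_csv, VELOCITY_COLUMNS, DEFAULT_SPRING_CONSTANT)
from .kymo import (bin_kymograph, build_plank_kymographs, fold_kymograph,
                   integrate_displacement, mean_velocity_series,
                   estimate_propagation_speed, DEFAULT_POSITIONS)
from .relaxation import displacement_to_force, extract_fmax, fit_exponential_decay
from .oscillation import compare_conditions, find_reversals, fit_damped_sinusoid
from .mech import ShearCircuit


class StageToggles(BaseModel):
    generate: bool = True
    kymo: bool = True
    force: bool = True
    fit: bool = True
    simulate: bool = True
    compare: bool = True


class RunConfig(BaseModel):
    """Fully serializable pipeline configuration."""

    conditions: list[str] = Field(default_factory=lambda: ["+Shear"])
    seed: int = 0
    replicates: int = 3
    out_dir: str = "epishear_run"
    grid: dict = Field(default_factory=dict)          # GridSpec overrides
    presets: dict = Field(default_factory=dict)       # per-condition overrides
    stages: StageToggles = Field(default_factory=StageToggles)
    bin_frames: int = 3
    positions: list[float] = Field(default_factory=lambda: list(DEFAULT_POSITIONS))
    threshold_frac: float = 0.25
    fit_t_min: float = 10.0   # h; fit the oscillation after the inward transient
    min_front_r2: float = 0.5  # reject noise-driven front fits below this
    k_s: float = DEFAULT_SPRING_CONSTANT
    f_max: float = 1.0
    model_k: float = 1.0
    sim_t_end: float = 20.0
    alpha: float = 0.05

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class RunReport(BaseModel):
    """Machine-readable record of one pipeline run."""

    version: str
    config_hash: str
    config: RunConfig
    conditions: dict[str, dict] = Field(default_factory=dict)
    comparisons: list[dict] = Field(default_factory=list)
    files: dict[str, list[str]] = Field(default_factory=dict)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage and condition for diagnosis."""


def _derived_seed(master: int, condition_index: int, replicate: int) -> int:
    return int(master) + 1000 * condition_index + replicate


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = GridSpec(**config.grid)
    report = RunReport(version=__version__, config_hash=config.config_hash(),
                       config=config)

    fitted_params: dict[str, dict[str, list[float]]] = {
        "A": {}, "P": {}, "D": {}}
    for ci, cond in enumerate(config.conditions):
        cond_report: dict = {"replicates": []}
        cond_dir = out / _slug(cond)
        cond_dir.mkdir(exist_ok=True)
        preset = make_condition_preset(cond, **config.presets.get(cond, {}))
        osc_fits = []
        for rep in range(config.replicates):
            seed = _derived_seed(config.seed, ci, rep)
            rep_report = _run_replicate(config, grid, preset, cond, rep, seed,
                                        cond_dir, report)
            cond_report["replicates"].append(rep_report)
            if rep_report.get("oscillation") is not None:
                o = rep_report["oscillation"]
                osc_fits.append(o)
                fitted_params["A"].setdefault(cond, []).append(o["amplitude_um_per_h"])
                fitted_params["P"].setdefault(cond, []).append(o["period_h"])
                d = o["damping_time_h"]
                fitted_params["D"].setdefault(cond, []).append(
                    math.inf if d is None else d)
        if config.stages.simulate and osc_fits:
            cond_report["model"] = _simulate_condition(
                config, preset, osc_fits, cond_report, cond_dir, report, cond)
        report.conditions[cond] = cond_report

    if config.stages.compare and len(config.conditions) >= 2:
        rows = []
        for param, groups in fitted_params.items():
            groups = {k: v for k, v in groups.items() if len(v)}
            if len(groups) < 2:
                continue
            cmp = compare_conditions(groups, alpha=config.alpha, parameter=param)
            rows.extend(cmp.to_rows())
        report.comparisons = rows
        if rows:
            path = out / "comparisons.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            report.files.setdefault("comparisons", []).append(str(path))

    report_path = out / "report.json"
    report_path.write_text(report.model_dump_json(indent=2))
    return report


def _slug(name: str) -> str:
    return name.replace("+", "plus_").replace("-", "minus_")


def _run_replicate(config, grid, preset, cond, rep, seed, cond_dir, report) -> dict:
    rep_report: dict = {"replicate": rep, "seed": seed}
    stage = "generate"
    try:
        fields, truth = generate_velocity_series(preset, grid=grid, seed=seed)
        if config.stages.generate:
            vpath = cond_dir / f"velocity_rep{rep}.csv"
            write_velocity_csv(fields, vpath)
            truth.to_json(cond_dir / f"velocity_rep{rep}_truth.json")
            report.files.setdefault("velocity", []).append(str(vpath))
            rep_report["velocity_csv"] = str(vpath)

        if config.stages.kymo:
            stage = "kymo"
            folded = {}
            for comp in ("y", "x"):
                per_plank = build_plank_kymographs(fields, comp)
                folded[comp] = fold_kymograph(per_plank["top"], per_plank["bottom"])
                binned = bin_kymograph(folded[comp], config.bin_frames)
                kpath = cond_dir / f"kymo_{comp}_rep{rep}.csv"
                binned.to_csv(kpath)
                report.files.setdefault("kymographs", []).append(str(kpath))
                traces = integrate_displacement(binned, config.positions)
                dpath = cond_dir / f"displacement_{comp}_rep{rep}.csv"
                traces.to_csv(dpath)
                report.files.setdefault("displacement", []).append(str(dpath))
            series = mean_velocity_series(folded["y"])
            try:
                prop = estimate_propagation_speed(folded["y"], config.threshold_frac)
                credible = (math.isinf(prop.speed)
                            or (prop.speed > 0
                                and prop.r_squared >= config.min_front_r2))
                speed = prop.speed if credible else 0.0
                rep_report["propagation_um_per_h"] = (
                    None if math.isinf(speed) else speed)
                rep_report["propagation_r2"] = prop.r_squared
            except ValueError:
                rep_report["propagation_um_per_h"] = 0.0

            if config.stages.fit:
                stage = "fit"
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    res = fit_damped_sinusoid(series, t_min=config.fit_t_min)
                rep_report["oscillation"] = res.to_dict()
                rev = find_reversals(series)
                rep_report["reversals_h"] = [round(x, 4) for x in rev.times.tolist()]

        if config.stages.force and preset.tau_force is not None:
            stage = "force"
            trace, _ = generate_sensing_trace(preset, f_max=config.f_max,
                                              seed=seed, k_s=config.k_s)
            spath = cond_dir / f"sensing_rep{rep}.csv"
            trace.to_csv(spath)
            report.files.setdefault("sensing", []).append(str(spath))
            force = displacement_to_force(trace, k_s=config.k_s)
            fmax = extract_fmax(force)
            fit = fit_exponential_decay(force)
            rep_report["force"] = dict(fit.to_dict(),
                                       f_max_observed_uN=fmax.value,
                                       tau_crossing_min=fit.crossing_tau())
    except Exception as err:  # noqa: BLE001 - reraise with stage context
        raise PipelineError(
            f"stage {stage!r} failed for condition {cond!r} replicate {rep} "
            f"(outputs so far kept in {cond_dir}): {err}") from err
    return rep_report


def _simulate_condition(config, preset, osc_fits, cond_report, cond_dir,
                        report, cond) -> dict:
    """Build the circuit from the median replicate fit and simulate the step."""

    class _Fit:
        period = float(np.median([o["period_h"] for o in osc_fits]))
        ds = [o["damping_time_h"] for o in osc_fits]
        damping_time = (math.inf if any(d is None for d in ds)
                        else float(np.median(ds)))
        degenerate = all(o.get("degenerate") for o in osc_fits)

    speeds = []
    for r in cond_report["replicates"]:
        s = r.get("propagation_um_per_h", 0.0)
        speeds.append(math.inf if s is None else s)  # None encodes inf
    propagation = float(np.median(speeds)) if speeds else 0.0
    circuit = ShearCircuit.from_measurements(
        config.model_k, _Fit, propagation,
        sheared=preset.f_ext_to_f_int > 0,
        f_ratio=preset.f_ext_to_f_int or 1.0)
    resp = circuit.simulate_step_response(t_end=config.sim_t_end)
    path = cond_dir / "simulation.csv"
    detr = resp.detrended()
    df = resp.to_frame()
    df["velocity_detrended"] = detr.velocity
    df.to_csv(path, index=False)
    report.files.setdefault("simulation", []).append(str(path))
    reversals = detr.reversal_times()
    return {
        "k": circuit.k, "c": circuit.c, "b": circuit.b,
        "zeta": None if math.isinf(circuit.zeta) else circuit.zeta,
        "natural_period_h": (None if math.isinf(circuit.natural_period())
                             else circuit.natural_period()),
        "propagation_um_per_h": propagation,
        "simulated_reversals_h": [round(float(x), 4) for x in reversals[:6]],
        "simulation_csv": str(path),
    }


# ---------------------------------------------------------------------------
# external data loading


def load_external_fields(path) -> list[VelocityField]:
    """Read a long-format velocity CSV back into validated VelocityFields.

    The file must carry the columns written by the generator
    (time_h, plank, row, col, y_um, u_um_per_h, v_um_per_h) with a complete,
    uniform grid at every (time, plank) and strictly increasing times.
    """
    df = pd.read_csv(path)
    missing = [c for c in VELOCITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"velocity CSV is missing column(s): {missing}")
    dup = df.duplicated(subset=["time_h", "plank", "row", "col"])
    if dup.any():
        i = int(np.nonzero(dup.to_numpy())[0][0])
        r = df.iloc[i]
        raise ValueError(
            f"duplicate (time, plank, row, col) entry at data row {i} "
            f"(time_h={r.time_h}, plank={r.plank}, row={int(r.row)}, "
            f"col={int(r.col)})")
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    per_frame = n_rows * n_cols

    # infer spatial calibration from the row centers
    y_by_row = df.drop_duplicates("row").sort_values("row")["y_um"].to_numpy()
    if len(y_by_row) > 1:
        heights = np.diff(y_by_row)
        if not np.allclose(heights, heights[0], rtol=1e-6):
            raise ValueError("non-uniform grid: row spacing is not constant")
        row_height = float(heights[0])
    else:
        row_height = float(2 * y_by_row[0])
    times = np.sort(df["time_h"].unique())
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    frame_interval = float(np.median(np.diff(times)) * 60) if len(times) > 1 else 5.0
    grid = GridSpec(n_cols=n_cols, n_rows=n_rows,
                    field_width=300.0, plank_height=row_height * n_rows,
                    frame_interval=frame_interval,
                    t_start=float(times[0]), t_end=float(times[-1]))

    fields: list[VelocityField] = []
    for (t, plank), g in df.groupby(["time_h", "plank"], sort=True):
        if len(g) != per_frame:
            raise ValueError(
                f"non-uniform grid: frame (time_h={t}, plank={plank}) has "
                f"{len(g)} cells, expected {per_frame}")
        g = g.sort_values(["row", "col"])
        u = g["u_um_per_h"].to_numpy().reshape(n_rows, n_cols)
        v = g["v_um_per_h"].to_numpy().reshape(n_rows, n_cols)
        fields.append(VelocityField(time=float(t), plank=str(plank),
                                    u=u, v=v, grid=grid))
    fields.sort(key=lambda f: (f.time, f.plank != "top"))
    return fields
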