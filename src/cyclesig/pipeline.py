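"""File schemas, configuration, and end-to-end workflows.

All tabular data are plain CSV (UTF-8, "." decimal): a trace table with one
row per (cell, frame) and a companion event table with one row per
annotated cycle event.  Images travel as TIFF stacks, reports as JSON.
Every workflow stamps its outputs with a short hash of the configuration
so reruns are identifiable and idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cyclealign, gptools, imgquant, riborate, synthdata
from .cyclealign import CellTrace

__all__ = [
    "TraceTable",
    "RunConfig",
    "read_traces",
    "write_traces",
    "run_workflow",
]

log = logging.getLogger("cyclesig")

TRACE_COLUMNS = ["cell_id", "time_min", "value"]
EVENT_COLUMNS = ["cell_id", "event_type", "time_min"]


@dataclass
class TraceTable:
    """Long-format trace table plus its companion event table."""

    frames: pd.DataFrame
    events: pd.DataFrame

    def to_cell_traces(self) -> list[CellTrace]:
        traces = []
        for cell_id, grp in self.frames.groupby("cell_id", sort=True):
            grp = grp.sort_values("time_min")
            ev = self.events[self.events.cell_id == cell_id]
            events = list(zip(ev.event_type, ev.time_min.astype(float)))
            volumes = None
            if "volume_fl" in grp and grp.volume_fl.notna().all():
                volumes = grp.volume_fl.to_numpy(float)
            traces.append(
                CellTrace(
                    cell_id=str(cell_id),
                    times=grp.time_min.to_numpy(float),
                    values=grp.value.to_numpy(float),
                    volumes=volumes,
                    events=events,
                )
            )
        return traces

    @classmethod
    def from_cell_traces(cls, traces) -> "TraceTable":
        frame_rows, event_rows = [], []
        for tr in traces:
            for i, t in enumerate(tr.times):
                row = {"cell_id": tr.cell_id, "time_min": t, "value": tr.values[i]}
                if tr.volumes is not None:
                    row["volume_fl"] = tr.volumes[i]
                frame_rows.append(row)
            for etype, t in tr.events:
                event_rows.append(
                    {"cell_id": tr.cell_id, "event_type": etype, "time_min": t}
                )
        return cls(
            frames=pd.DataFrame(frame_rows),
            events=pd.DataFrame(event_rows, columns=EVENT_COLUMNS),
        )


def read_traces(trace_path, event_path=None) -> TraceTable:
    """Read and validate the CSV trace schema.

    Rejects duplicate (cell_id, time) pairs and events outside a cell's
    observation span; unsorted times are sorted with a warning.
    """
    frames = pd.read_csv(trace_path)
    missing = [c for c in TRACE_COLUMNS if c not in frames.columns]
    if missing:
        raise ValueError(f"{trace_path}: missing required columns {missing}")
    dup = frames.duplicated(subset=["cell_id", "time_min"])
    if dup.any():
        rows = (frames.index[dup] + 2).tolist()[:5]
        raise ValueError(f"{trace_path}: duplicate (cell_id, time_min) at rows {rows}")
    unsorted = (
        frames.groupby("cell_id")["time_min"].apply(lambda s: (s.diff() < 0).any()).any()
    )
    if unsorted:
        log.warning("%s: times were not sorted; sorting", trace_path)
        frames = frames.sort_values(["cell_id", "time_min"]).reset_index(drop=True)
    if event_path is not None:
        events = pd.read_csv(event_path)
        missing = [c for c in EVENT_COLUMNS if c not in events.columns]
        if missing:
            raise ValueError(f"{event_path}: missing required columns {missing}")
        span = frames.groupby("cell_id")["time_min"].agg(["min", "max"])
        for _, row in events.iterrows():
            if row.cell_id not in span.index:
                raise ValueError(f"event for unknown cell_id {row.cell_id!r}")
            lo, hi = span.loc[row.cell_id]
            if not (lo <= row.time_min <= hi):
                raise ValueError(
                    f"cell {row.cell_id!r}: event at t={row.time_min} outside the "
                    f"observed span [{lo}, {hi}]"
                )
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return TraceTable(frames=frames, events=events)


def write_traces(table: TraceTable, trace_path, event_path=None):
    table.frames.to_csv(trace_path, index=False)
    if event_path is not None:
        table.events.to_csv(event_path, index=False)


@dataclass
class RunConfig:
    """All tunable pipeline constants, defaulting to the study's values."""

    pixel_size_um: float = imgquant.DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = 3.0
    r_small_um: float = imgquant.SMALL_RADIUS_UM
    r_large_um: float = imgquant.LARGE_RADIUS_UM
    ball_radius_px: int = 25
    n_points: int = 80  # N/C-ratio cycle alignment
    n_points_rate: int = 60  # synthesis-rate cycle alignment
    normalization: str = "none"
    t_half_min: float = riborate.DEFAULT_HALFTIME_MIN
    n_extra_frames: int = 3
    J: int = 10
    L: int = 5
    n_restarts: int = 5
    eig_tol: float | None = None
    seed: int = 0
    # simulate-subcommand knobs
    sim_n_cells: int = 20
    sim_n_cycles: int = 3
    sim_mean_g1: float = 40.0
    sim_mean_sg2m: float = 60.0
    sim_phase_cv: float = 0.15
    sim_noise_sd: float = 0.02

    def __post_init__(self):
        for name in (
            "pixel_size_um", "frame_interval_min", "r_small_um", "r_large_um",
            "t_half_min", "sim_mean_g1", "sim_mean_sg2m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def km(self) -> float:
        return riborate.km_from_halftime(self.t_half_min)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


@dataclass
class WorkflowResult:
    outputs: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)


def _out(out_dir: Path, stem: str, ext: str, cfg_hash: str) -> Path:
    return out_dir / f"{stem}_{cfg_hash}.{ext}"


def _setup_run(config: RunConfig, out_dir) -> tuple[Path, str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    handler = logging.FileHandler(out_dir / f"run_{cfg_hash}.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("config hash %s seed %d: %s", cfg_hash, config.seed, asdict(config))
    return out_dir, cfg_hash


def _write_aligned(cycles, path: Path, sidecar: Path):
    mat = np.stack([c.values for c in cycles])
    cols = [f"p{j:03d}" for j in range(mat.shape[1])]
    df = pd.DataFrame(mat, columns=cols)
    df.insert(0, "cell_id", [c.cell_id for c in cycles])
    df.to_csv(path, index=False)
    meta = {
        "n_total": int(len(cycles[0].values)),
        "boundary_index": int(cycles[0].boundary_index),
        "g1_durations": [float(c.g1_duration) for c in cycles],
        "sg2m_durations": [float(c.sg2m_duration) for c in cycles],
    }
    sidecar.write_text(json.dumps(meta, indent=1))


def run_workflow(command: str, config: RunConfig, out_dir, **inputs) -> WorkflowResult:
    """Run one pipeline stage and write its artifacts under `out_dir`.

    Commands: simulate, quantify, align, rate, compare (see the CLI for the
    expected inputs of each).  Output filenames carry the config hash.
    """
    out_dir, cfg_hash = _setup_run(config, out_dir)
    res = WorkflowResult()
    try:
        if command == "simulate":
            _wf_simulate(config, out_dir, cfg_hash, res)
        elif command == "quantify":
            _wf_quantify(config, out_dir, cfg_hash, res, **inputs)
        elif command == "align":
            _wf_align(config, out_dir, cfg_hash, res, **inputs)
        elif command == "rate":
            _wf_rate(config, out_dir, cfg_hash, res, **inputs)
        elif command == "compare":
            _wf_compare(config, out_dir, cfg_hash, res, **inputs)
        else:
            raise ValueError(f"unknown workflow command {command!r}")
    finally:
        for h in list(log.handlers):
            log.removeHandler(h)
            h.close()
    return res


def _wf_simulate(config, out_dir, cfg_hash, res):
    import tifffile

    scene = synthdata.make_nc_scene(
        synthdata.SceneSpec(pixel_size=config.pixel_size_um, noise_sd=5.0),
        seed=config.seed,
    )
    tif = _out(out_dir, "scene", "tif", cfg_hash)
    tifffile.imwrite(
        tif, np.stack([scene.gfp_image, scene.rfp_image]).astype(np.float32)
    )
    mask_tif = _out(out_dir, "scene_mask", "tif", cfg_hash)
    tifffile.imwrite(mask_tif, scene.cell_mask.astype(np.uint8))
    truth = _out(out_dir, "scene_truth", "json", cfg_hash)
    truth.write_text(json.dumps(scene.truth, indent=1))

    spec = synthdata.CycleSimSpec(
        n_cells=config.sim_n_cells,
        n_cycles=config.sim_n_cycles,
        frame_interval=config.frame_interval_min,
        mean_g1=config.sim_mean_g1,
        mean_sg2m=config.sim_mean_sg2m,
        phase_cv=config.sim_phase_cv,
        noise_sd=config.sim_noise_sd,
        seed=config.seed,
    )
    table = TraceTable.from_cell_traces(synthdata.simulate_cycles(spec))
    tr_csv = _out(out_dir, "traces", "csv", cfg_hash)
    ev_csv = _out(out_dir, "events", "csv", cfg_hash)
    write_traces(table, tr_csv, ev_csv)
    res.outputs = {
        "scene": tif, "scene_mask": mask_tif, "scene_truth": truth,
        "traces": tr_csv, "events": ev_csv,
    }
    log.info("simulate: wrote %d traces", config.sim_n_cells)


def _wf_quantify(config, out_dir, cfg_hash, res, scene=None, mask=None,
                 background_correct=False):
    import tifffile

    stack = tifffile.imread(scene)
    cell_mask = tifffile.imread(mask).astype(bool)
    if stack.ndim == 3 and stack.shape[0] == 2:  # one frame, 2 channels
        stack = stack[None, ...]
    rows = []
    for f in range(stack.shape[0]):
        gfp, rfp = stack[f, 0].astype(float), stack[f, 1].astype(float)
        if background_correct:
            gfp = imgquant.background_subtract(gfp, config.ball_radius_px)
        ratio, masks = imgquant.quantify_frame(
            gfp, rfp, cell_mask, config.pixel_size_um,
            config.r_small_um, config.r_large_um,
        )
        rows.append(
            {
                "cell_id": "cell0000",
                "time_min": f * config.frame_interval_min,
                "value": ratio,
                "flag_boundary": masks.nucleus_touches_boundary,
            }
        )
    tr_csv = _out(out_dir, "nc_traces", "csv", cfg_hash)
    pd.DataFrame(rows).to_csv(tr_csv, index=False)
    res.outputs = {"traces": tr_csv}
    res.values = {"nc_ratio_first_frame": rows[0]["value"]}
    log.info("quantify: %d frame(s)", len(rows))


def _wf_align(config, out_dir, cfg_hash, res, traces=None, events=None):
    table = read_traces(traces, events)
    cycles = cyclealign.align_traces(table.to_cell_traces(), config.n_points)
    if config.normalization != "none":
        cycles = [cyclealign.normalize_cycle(c, config.normalization) for c in cycles]
    aligned_csv = _out(out_dir, "aligned", "csv", cfg_hash)
    sidecar = _out(out_dir, "aligned_meta", "json", cfg_hash)
    _write_aligned(cycles, aligned_csv, sidecar)
    avg = cyclealign.average_cycles(cycles, "none")
    avg_csv = _out(out_dir, "average", "csv", cfg_hash)
    pd.DataFrame(
        {
            "rel_time": avg.rel_time,
            "mean": avg.mean,
            "ci_half_width": avg.ci_half_width,
        }
    ).to_csv(avg_csv, index=False)
    fig_png = _out(out_dir, "heatmap", "png", cfg_hash)
    _plot_heatmap(cycles, avg, fig_png)
    res.outputs = {"aligned": aligned_csv, "meta": sidecar, "average": avg_csv,
                   "heatmap": fig_png}
    res.values = {"n_cycles": avg.n_cycles}
    log.info("align: %d cycles on %d points", avg.n_cycles, config.n_points)


def _plot_heatmap(cycles, avg, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    norm = []
    for c in cycles:
        try:
            norm.append(cyclealign.normalize_cycle(c, "minmax01").values)
        except cyclealign.DegenerateCycleError:
            continue
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(6, 6), sharex=True, height_ratios=[2, 1]
    )
    ax0.imshow(
        np.stack(norm), aspect="auto", extent=(0, 1, len(norm), 0), cmap="viridis"
    )
    ax0.axvline(cycles[0].boundary_index / (len(cycles[0].values) - 1), color="w",
                ls="--", lw=0.8)
    ax0.set_ylabel("cell cycle")
    ax1.plot(avg.rel_time, avg.mean, color="k")
    ax1.fill_between(
        avg.rel_time, avg.mean - avg.ci_half_width, avg.mean + avg.ci_half_width,
        alpha=0.3,
    )
    ax1.set_xlabel("relative cell cycle position")
    ax1.set_ylabel("mean readout")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _wf_rate(config, out_dir, cfg_hash, res, traces=None, events=None):
    table = read_traces(traces, events)
    km = config.km
    rate_traces = []
    rows = []
    for tr in table.to_cell_traces():
        if tr.volumes is None:
            raise ValueError(f"cell {tr.cell_id}: rate estimation needs volumes")
        abundance = riborate.total_abundance(tr.values, tr.volumes)
        for k, seg in enumerate(cyclealign.split_cycles(tr)):
            ext = riborate.extend_trace(
                tr.times, seg.t_start, seg.t_end, config.n_extra_frames
            )
            fit = riborate.estimate_kp(
                tr.times[ext.window],
                abundance[ext.window],
                km,
                volumes=tr.volumes[ext.window],
                core=ext.core,
            )
            cyc_id = f"{tr.cell_id}_c{k}"
            rows.extend(
                {
                    "cell_id": cyc_id,
                    "time_min": t,
                    "kp": kp,
                    "kp_per_volume": kpv,
                }
                for t, kp, kpv in zip(fit.times, fit.kp, fit.kp_per_volume)
            )
            rate_traces.append(
                CellTrace(
                    cell_id=cyc_id,
                    times=fit.times,
                    values=fit.kp_per_volume,
                    events=[
                        (cyclealign.KARYOKINESIS, seg.t_start),
                        (cyclealign.BUDDING, seg.t_bud),
                        (cyclealign.KARYOKINESIS, seg.t_end),
                    ],
                )
            )
    kp_csv = _out(out_dir, "kp", "csv", cfg_hash)
    pd.DataFrame(rows).to_csv(kp_csv, index=False)
    cycles = cyclealign.align_traces(rate_traces, config.n_points_rate)
    aligned_csv = _out(out_dir, "kp_aligned", "csv", cfg_hash)
    sidecar = _out(out_dir, "kp_aligned_meta", "json", cfg_hash)
    _write_aligned(cycles, aligned_csv, sidecar)
    res.outputs = {"kp": kp_csv, "aligned": aligned_csv, "meta": sidecar}
    res.values = {"n_cycles": len(cycles)}
    log.info("rate: %d cycles, km=%.4f", len(cycles), km)


def _read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("p")]
    mat = df[cols].to_numpy(float)
    return mat, np.arange(mat.shape[1], dtype=float)


def _wf_compare(config, out_dir, cfg_hash, res, group_x=None, group_y=None):
    mat_x, times = _read_matrix(group_x)
    mat_y, times_y = _read_matrix(group_y)
    if mat_x.shape[1] != mat_y.shape[1]:
        raise ValueError("groups are not on a shared grid")
    result, post_x, post_y = gptools.compare_trace_groups(
        mat_x, mat_y, times,
        J=config.J, L=config.L, seed=config.seed,
        n_restarts=config.n_restarts, eig_tol=config.eig_tol,
    )
    report = _out(out_dir, "comparison", "json", cfg_hash)
    report.write_text(
        json.dumps(
            {"T": result.T, "nu": result.nu, "epsilon": result.epsilon}, indent=1
        )
    )
    effect_csv = _out(out_dir, "effect", "csv", cfg_hash)
    pd.DataFrame({"component": np.arange(result.nu), "E": result.effect}).to_csv(
        effect_csv, index=False
    )
    for name, post in (("x", post_x), ("y", post_y)):
        band = 1.96 * np.sqrt(np.clip(np.diag(post.cov), 0, None))
        pd.DataFrame(
            {"grid": post.grid, "mean": post.mu, "ci_half_width": band}
        ).to_csv(_out(out_dir, f"posterior_mean_{name}", "csv", cfg_hash), index=False)
    res.outputs = {"report": report, "effect": effect_csv}
    res.values = {"T": result.T, "nu": result.nu, "epsilon": result.epsilon}
    log.info("compare: T=%.3f nu=%d epsilon=%.3g", result.T, result.nu, result.epsilon)
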