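"""Trajectory/map/delay file I/O and the end-to-end experiment runner.

All files are tab-separated UTF-8 text with '.' decimal separator and the
token ``NA`` for missing values.  A run manifest (JSON) records every
parameter and per-flight seed, so a run can be reproduced bit-identically
from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinematics import kinematic_series
from .leadership import DEFAULT_MAX_LAG, directional_correlation_delay
from .response_maps import (
    DEFAULT_MIN_COUNT,
    NeighbourPairMap,
    PolarResponseMap,
    ThetaPhiMap,
    accumulate_polar_map,
    acceleration_sign_profile,
    front_back_profile,
    multi_neighbour_observed,
    pair_observations,
    theta_phi_turning_map,
)
from .simulate import (
    FRONT_BACK,
    SIDE_BY_SIDE,
    SimulationConfig,
    TrackSet,
    flight_seeds,
    simulate_flock,
)

__all__ = [
    "ExperimentSpec",
    "TrackParseError",
    "write_tracks",
    "read_tracks",
    "run_experiment",
    "analyse_tracks",
]

log = logging.getLogger("flocknoise")

NA = "NA"
_SEP = "\t"
_CONDITIONS = {"front_back": FRONT_BACK, "side_by_side": SIDE_BY_SIDE}
_REQUIRED_COLUMNS = ["trajectory_id", "t", "individual_id", "x_recorded", "y_recorded"]
_IDEAL_COLUMNS = ["x_ideal", "y_ideal"]


class TrackParseError(ValueError):
    """A trajectory table could not be parsed."""


# ---------------------------------------------------------------------------
# trajectory tables


def write_tracks(tracksets: list[TrackSet], path) -> None:
    """Write flights as a delimited table, one row per (flight, step,
    individual): trajectory_id, t, individual_id, recorded and ideal
    coordinates (a.u.), and the individual's segment offset."""
    frames = []
    for traj_id, ts in enumerate(tracksets):
        n = ts.n_steps
        for k in range(ts.n_individuals):
            frames.append(
                pd.DataFrame(
                    {
                        "trajectory_id": traj_id,
                        "t": np.arange(n),
                        "individual_id": k,
                        "x_recorded": ts.recorded[k, :, 0],
                        "y_recorded": ts.recorded[k, :, 1],
                        "x_ideal": ts.ideal[k, :, 0],
                        "y_ideal": ts.ideal[k, :, 1],
                        "offset": ts.offsets[k],
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, sep=_SEP, index=False, na_rep=NA)


def read_tracks(path, dt: float = 0.2) -> list[TrackSet]:
    """Read a trajectory table back into per-flight :class:`TrackSet`s.

    Requires columns trajectory_id, t, individual_id, x_recorded,
    y_recorded; ideal coordinates and offsets are optional (external
    tables may carry recorded positions only, in which case analyses that
    need ideal positions are disabled and a notice is logged).  Unknown
    columns are preserved on the returned frames' metadata but ignored.
    Malformed numeric fields raise :class:`TrackParseError` with the
    offending line number (1-based, counting the header).
    """
    try:
        raw = pd.read_csv(
            path, sep=_SEP, na_values=[NA], keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise TrackParseError(f"{path}: {exc}") from exc
    for col in _REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise TrackParseError(f"{path}: missing required column {col!r}")
    numeric_cols = [c for c in _REQUIRED_COLUMNS + _IDEAL_COLUMNS + ["offset"] if c in raw.columns]
    for col in numeric_cols:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise TrackParseError(
                f"{path}: malformed value {raw[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        raw[col] = converted

    has_ideal = all(c in raw.columns for c in _IDEAL_COLUMNS) and (
        raw[_IDEAL_COLUMNS].notna().all().all()
    )
    if not has_ideal:
        log.info("trajectory table %s has no ideal positions; ideal-dependent outputs disabled", path)
    has_offset = "offset" in raw.columns and raw["offset"].notna().all()

    tracksets = []
    for _, flight in raw.groupby("trajectory_id", sort=True):
        inds = np.sort(flight["individual_id"].unique())
        n = flight["t"].nunique()
        rec = np.full((inds.size, n, 2), np.nan)
        ideal = np.full((inds.size, n, 2), np.nan)
        offsets = np.full(inds.size, np.nan)
        for k, ind in enumerate(inds):
            sub = flight[flight["individual_id"] == ind].sort_values("t")
            rec[k, :, 0] = sub["x_recorded"].to_numpy()
            rec[k, :, 1] = sub["y_recorded"].to_numpy()
            if has_ideal:
                ideal[k, :, 0] = sub["x_ideal"].to_numpy()
                ideal[k, :, 1] = sub["y_ideal"].to_numpy()
            if has_offset:
                offsets[k] = sub["offset"].iloc[0]
        tracksets.append(
            TrackSet(
                ideal=ideal,
                recorded=rec,
                displacements=rec - ideal,
                offsets=offsets,
                config=None,
            )
        )
    return tracksets


# ---------------------------------------------------------------------------
# map tables


def polar_map_frame(m: PolarResponseMap) -> pd.DataFrame:
    """One row per polar cell: bin edges, count, mean turning, mean acceleration."""
    rows = []
    for i in range(m.radial_edges.size - 1):
        for j in range(m.angular_edges.size - 1):
            rows.append(
                {
                    "r_lo": m.radial_edges[i],
                    "r_hi": m.radial_edges[i + 1],
                    "theta_lo": m.angular_edges[j],
                    "theta_hi": m.angular_edges[j + 1],
                    "count": m.counts[i, j],
                    "mean_turning": m.mean_turning[i, j],
                    "mean_acceleration": m.mean_acceleration[i, j],
                }
            )
    return pd.DataFrame(rows)


def theta_phi_frame(m: ThetaPhiMap) -> pd.DataFrame:
    rows = []
    for i in range(m.theta_edges.size - 1):
        for j in range(m.phi_edges.size - 1):
            rows.append(
                {
                    "theta_lo": m.theta_edges[i],
                    "theta_hi": m.theta_edges[i + 1],
                    "phi_lo": m.phi_edges[j],
                    "phi_hi": m.phi_edges[j + 1],
                    "count": m.counts[i, j],
                    "mean_turning": m.mean_turning[i, j],
                }
            )
    return pd.DataFrame(rows)


def neighbour_pair_frame(m: NeighbourPairMap) -> pd.DataFrame:
    rows = []
    for i in range(m.fb1_edges.size - 1):
        for j in range(m.fb2_edges.size - 1):
            rows.append(
                {
                    "fb1_lo": m.fb1_edges[i],
                    "fb1_hi": m.fb1_edges[i + 1],
                    "fb2_lo": m.fb2_edges[j],
                    "fb2_hi": m.fb2_edges[j + 1],
                    "count": m.counts[i, j],
                    "mean_response": m.mean_response[i, j],
                }
            )
    return pd.DataFrame(rows)


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep=_SEP, index=False, na_rep=NA)


# ---------------------------------------------------------------------------
# experiment spec and runner


@dataclass
class ExperimentSpec:
    """A complete, reproducible experiment description.

    Unspecified simulation fields fall back to the reference defaults of
    :class:`SimulationConfig` (4096 steps, S0=5, s=0.2, a=0.02, C_T=300,
    C_D=20, r=5, displacement std r/2, dt=0.2 s, 100 flights).
    """

    condition: str = "front_back"
    n_individuals: int = 2
    n_trajectories: int = 100
    master_seed: int = 0
    out_dir: str = "."
    config_overrides: dict = field(default_factory=dict)
    polar_maps: bool = True
    theta_phi_maps: bool = True
    delays: bool = True
    multi_neighbour: bool = False
    max_lag: int = DEFAULT_MAX_LAG
    min_count: int = DEFAULT_MIN_COUNT

    def validate(self) -> None:
        problems = []
        if self.condition not in _CONDITIONS:
            problems.append(
                f"condition must be one of {sorted(_CONDITIONS)} (got {self.condition!r})"
            )
        if self.n_trajectories < 1:
            problems.append(f"n_trajectories must be >= 1 (got {self.n_trajectories})")
        allowed = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(self.config_overrides) - allowed
        if unknown:
            problems.append(f"unknown config_overrides fields: {sorted(unknown)}")
        if self.multi_neighbour and self.n_individuals != 3:
            problems.append("multi_neighbour analysis requires n_individuals = 3")
        if problems:
            raise ValueError("invalid ExperimentSpec: " + "; ".join(problems))

    def build_config(self) -> SimulationConfig:
        self.validate()
        kwargs = dict(
            configuration_angle=_CONDITIONS[self.condition],
            n_individuals=self.n_individuals,
            n_trajectories=self.n_trajectories,
        )
        kwargs.update(self.config_overrides)
        return SimulationConfig(**kwargs)


def analyse_tracks(
    tracksets: list[TrackSet],
    spec: ExperimentSpec,
    out_dir: Path,
    dt: float = 0.2,
) -> dict:
    """Run the enabled analyses on a collection of flights and write the
    map/delay tables.  Returns a summary dict for the manifest."""
    summary: dict = {}
    if spec.polar_maps or spec.theta_phi_maps:
        frames = []
        for i, ts in enumerate(tracksets):
            obs = pair_observations(ts)
            obs.insert(0, "trajectory_id", i)
            frames.append(obs)
        pooled = pd.concat(frames, ignore_index=True)
        if spec.polar_maps:
            pmap = accumulate_polar_map(pooled, min_count=spec.min_count)
            _write(polar_map_frame(pmap), out_dir / "polar_map.tsv")
            profile = front_back_profile(pooled, "accel", min_count=spec.min_count)
            table, crossing = acceleration_sign_profile(profile)
            _write(table, out_dir / "accel_profile_ahead.tsv")
            summary["accel_sign_crossing_au"] = crossing
        if spec.theta_phi_maps:
            tmap = theta_phi_turning_map(pooled, min_count=spec.min_count)
            _write(theta_phi_frame(tmap), out_dir / "theta_phi_map.tsv")
    if spec.delays and tracksets and tracksets[0].n_individuals == 2:
        rows = []
        angle = _CONDITIONS[spec.condition]
        for i, ts in enumerate(tracksets):
            kin = [kinematic_series(ts.recorded[k], dt) for k in range(2)]
            for focal in (0, 1):
                tau, c = directional_correlation_delay(
                    kin[focal].heading, kin[1 - focal].heading, spec.max_lag
                )
                off = ts.offsets[focal]
                if np.isnan(off):
                    role = "unknown"
                elif np.isclose(angle % (2 * np.pi), SIDE_BY_SIDE):
                    role = "left" if off > 0 else "right"
                else:
                    role = "front" if off > 0 else "back"
                rows.append(
                    {
                        "trajectory_id": i,
                        "focal_role": role,
                        "tau_star": tau,
                        "max_correlation": c,
                    }
                )
        _write(pd.DataFrame(rows), out_dir / "delays.tsv")
    if spec.multi_neighbour and tracksets and tracksets[0].n_individuals == 3:
        for kind in ("turn", "accel"):
            m = multi_neighbour_observed(tracksets, kind, min_count=spec.min_count)
            _write(neighbour_pair_frame(m), out_dir / f"multi_neighbour_{kind}.tsv")
    return summary


def run_experiment(spec: ExperimentSpec) -> Path:
    """Simulate all flights of an experiment, run the enabled analyses and
    write every output plus a manifest to ``spec.out_dir``.

    Re-running with the same spec reproduces all outputs bit-identically.
    Returns the output directory path.
    """
    config = spec.build_config()
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = flight_seeds(spec.master_seed, spec.n_trajectories)
    tracksets = [simulate_flock(config.with_seed(s)) for s in seeds]
    write_tracks(tracksets, out_dir / "tracks.tsv")
    summary = analyse_tracks(tracksets, spec, out_dir, dt=config.dt)
    manifest = {
        "flocknoise_version": __version__,
        "spec": dataclasses.asdict(spec),
        "config": dataclasses.asdict(config),
        "flight_seeds": [int(s) for s in seeds],
        "summary": summary,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir
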