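"""Binned "apparent interaction rule" maps.

Given recorded tracks of individuals that by construction do not interact,
these routines build the maps an experimenter would build to infer
interaction rules: mean turning and acceleration responses of a focal
individual binned by where its neighbour is (polar maps), by the
neighbour's direction and relative bearing (theta-phi maps), and by the
signed front-back distances to two neighbours (multi-neighbour maps), plus
the pairwise-average prediction for the latter.

Turning responses are reported right-positive (positive = turning towards
the focal's right), consistent with the right-positive angle convention of
the geometry layer, so "turning towards the neighbour" reads as
``sign(mean turning) == sign(theta)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import kinematic_series, pair_geometry
from .simulate import SimulationConfig, TrackSet, flight_seeds, simulate_flock

__all__ = [
    "PolarResponseMap",
    "ThetaPhiMap",
    "NeighbourPairMap",
    "FrontBackProfile",
    "pair_observations",
    "pooled_pair_observations",
    "accumulate_polar_map",
    "front_back_profile",
    "acceleration_sign_profile",
    "theta_phi_turning_map",
    "modulation_along_theta",
    "alignment_modulation",
    "modulation_along_phi",
    "multi_neighbour_observed",
    "predict_from_pairwise",
    "modulation_range",
    "DEFAULT_MIN_COUNT",
]

#: Minimum per-cell count below which a cell mean is flagged unreliable.
DEFAULT_MIN_COUNT = 100

#: Default polar grid: 8 radial bins out to 20 a.u., 12 angular bins.
DEFAULT_RADIAL_EDGES = np.linspace(0.0, 20.0, 9)
DEFAULT_ANGULAR_EDGES = np.linspace(-np.pi, np.pi, 13)
#: Default front-back profile grid: 1 a.u. bins over [-15, 15].
DEFAULT_FB_EDGES = np.linspace(-15.0, 15.0, 31)


def _bin_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Index of the half-open bin (edge[i], edge[i+1]] containing x; -1 outside."""
    idx = np.digitize(x, edges, right=True) - 1
    idx[(x <= edges[0]) | (x > edges[-1])] = -1
    return idx


def _cell_means(
    ix: np.ndarray, iy: np.ndarray, nx: int, ny: int, *responses: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray], int]:
    """Counts and per-cell means on a (nx, ny) grid; observations with a
    negative index are dropped and counted."""
    inside = (ix >= 0) & (iy >= 0)
    flat = ix[inside] * ny + iy[inside]
    counts = np.bincount(flat, minlength=nx * ny).reshape(nx, ny)
    means = []
    with np.errstate(invalid="ignore"):
        for r in responses:
            total = np.bincount(flat, weights=r[inside], minlength=nx * ny).reshape(nx, ny)
            means.append(np.where(counts > 0, total / np.maximum(counts, 1), np.nan))
    return counts, means, int((~inside).sum())


# ---------------------------------------------------------------------------
# observation tables


def pair_observations(trackset: TrackSet, focal: int = 0) -> pd.DataFrame:
    """Long-form table of (time step, neighbour) observations for one flight.

    One row per valid time step and neighbour of the focal individual, with
    the neighbour's relative geometry at t and the focal's responses over
    the step t -> t+1.  Columns: ``t``, ``neighbour``, ``d``, ``theta``,
    ``phi``, ``d_fb``, ``d_lat``, ``turn`` (rad/s, right-positive),
    ``accel`` (a.u./s^2), ``focal_offset``, ``neighbour_offset``.
    """
    dt = trackset.config.dt if trackset.config is not None else 0.2
    kin = [kinematic_series(trackset.recorded[k], dt) for k in range(trackset.n_individuals)]
    fk = kin[focal]
    frames = []
    for nb in range(trackset.n_individuals):
        if nb == focal:
            continue
        geom = pair_geometry(
            trackset.recorded[focal], fk.heading, trackset.recorded[nb], kin[nb].heading
        )
        ok = geom.valid & np.isfinite(fk.turn_rate) & np.isfinite(fk.accel)
        t = np.nonzero(ok)[0]
        frames.append(
            pd.DataFrame(
                {
                    "t": t,
                    "neighbour": nb,
                    "d": geom.distance[t],
                    "theta": geom.theta[t],
                    "phi": geom.phi[t],
                    "d_fb": geom.d_fb[t],
                    "d_lat": geom.d_lat[t],
                    # right-positive turning response
                    "turn": -fk.turn_rate[t],
                    "accel": fk.accel[t],
                    "focal_offset": trackset.offsets[focal],
                    "neighbour_offset": trackset.offsets[nb],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def pooled_pair_observations(
    config: SimulationConfig, n_flights: int, master_seed: int
) -> pd.DataFrame:
    """Simulate ``n_flights`` independent flights and pool their observation
    tables (individual 0 as focal; its place in the formation is randomized
    per flight by construction).  Adds a ``trajectory_id`` column."""
    frames = []
    for i, s in enumerate(flight_seeds(master_seed, n_flights)):
        obs = pair_observations(simulate_flock(config.with_seed(s)))
        obs.insert(0, "trajectory_id", i)
        frames.append(obs)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# polar maps


@dataclass(frozen=True)
class PolarResponseMap:
    """Mean responses binned by the neighbour's polar position.

    ``counts``, ``mean_turning`` and ``mean_acceleration`` have shape
    (n_radial, n_angular); cell means are NaN where the count is zero.
    ``dropped`` counts observations beyond the outermost radial edge.
    """

    radial_edges: np.ndarray
    angular_edges: np.ndarray
    counts: np.ndarray
    mean_turning: np.ndarray
    mean_acceleration: np.ndarray
    dropped: int = 0
    min_count: int = DEFAULT_MIN_COUNT

    @property
    def reliable(self) -> np.ndarray:
        """Boolean mask of cells with at least ``min_count`` observations."""
        return self.counts >= self.min_count

    @property
    def radial_centres(self) -> np.ndarray:
        return 0.5 * (self.radial_edges[:-1] + self.radial_edges[1:])

    @property
    def angular_centres(self) -> np.ndarray:
        return 0.5 * (self.angular_edges[:-1] + self.angular_edges[1:])


def accumulate_polar_map(
    observations: pd.DataFrame,
    radial_edges: np.ndarray = DEFAULT_RADIAL_EDGES,
    angular_edges: np.ndarray = DEFAULT_ANGULAR_EDGES,
    min_count: int = DEFAULT_MIN_COUNT,
) -> PolarResponseMap:
    """Bin observations by neighbour distance and direction.

    Observations beyond the outermost radial edge are dropped and counted in
    ``dropped`` so that counts are conserved.
    """
    radial_edges = np.asarray(radial_edges, dtype=float)
    angular_edges = np.asarray(angular_edges, dtype=float)
    if np.any(np.diff(radial_edges) <= 0) or np.any(np.diff(angular_edges) <= 0):
        raise ValueError("grid edges must be strictly increasing")
    d = observations["d"].to_numpy()
    theta = observations["theta"].to_numpy()
    ir = np.digitize(d, radial_edges, right=False) - 1  # [lo, hi) radially, d >= 0
    ir[(d < radial_edges[0]) | (d >= radial_edges[-1])] = -1
    ia = _bin_index(theta, angular_edges)
    counts, (mt, ma), dropped = _cell_means(
        ir,
        ia,
        radial_edges.size - 1,
        angular_edges.size - 1,
        observations["turn"].to_numpy(),
        observations["accel"].to_numpy(),
    )
    return PolarResponseMap(
        radial_edges=radial_edges,
        angular_edges=angular_edges,
        counts=counts,
        mean_turning=mt,
        mean_acceleration=ma,
        dropped=dropped,
        min_count=min_count,
    )


# ---------------------------------------------------------------------------
# front-back profiles and the acceleration sign change


@dataclass(frozen=True)
class FrontBackProfile:
    """Mean response binned by the neighbour's signed front-back distance."""

    edges: np.ndarray
    counts: np.ndarray
    mean_response: np.ndarray
    dropped: int = 0
    min_count: int = DEFAULT_MIN_COUNT

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def reliable(self) -> np.ndarray:
        return self.counts >= self.min_count


def front_back_profile(
    observations: pd.DataFrame,
    response: str = "accel",
    edges: np.ndarray = DEFAULT_FB_EDGES,
    min_count: int = DEFAULT_MIN_COUNT,
) -> FrontBackProfile:
    """Bin a response column by signed front-back distance ``d_fb``."""
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    idx = _bin_index(observations["d_fb"].to_numpy(), edges)
    counts, (mean,), dropped = _cell_means(
        idx, np.zeros_like(idx), edges.size - 1, 1, observations[response].to_numpy()
    )
    return FrontBackProfile(
        edges=edges,
        counts=counts[:, 0],
        mean_response=mean[:, 0],
        dropped=dropped,
        min_count=min_count,
    )


def acceleration_sign_profile(profile: FrontBackProfile) -> tuple[pd.DataFrame, float | None]:
    """Signed acceleration profile on the neighbour-ahead branch and the
    location of its sign change.

    Scans reliable bins with positive front-back distance outward from the
    focal individual for the repulsion-to-attraction boundary: the first
    pair of adjacent bins where the mean acceleration passes from negative
    (braking away from a too-close neighbour) to positive (accelerating
    towards a too-far one).  The boundary is located by linear
    interpolation between the bin centres.  Returns the ahead-branch
    profile and the crossing position, or ``None`` when no such sign
    change occurs in range.
    """
    ahead = profile.centres > 0
    use = ahead & profile.reliable & np.isfinite(profile.mean_response)
    centres = profile.centres[use]
    means = profile.mean_response[use]
    table = pd.DataFrame(
        {"d_fb": centres, "mean_accel": means, "count": profile.counts[use]}
    )
    crossing = None
    for i in range(len(means) - 1):
        a, b = means[i], means[i + 1]
        if a == 0 and b > 0:
            crossing = float(centres[i])
            break
        if a < 0 < b:
            crossing = float(centres[i] + (centres[i + 1] - centres[i]) * (-a) / (b - a))
            break
    return table, crossing


# ---------------------------------------------------------------------------
# theta-phi (attraction vs alignment) maps


@dataclass(frozen=True)
class ThetaPhiMap:
    """Mean turning binned by neighbour direction and relative bearing,
    restricted to the attraction zone (distance above ``r_min``)."""

    theta_edges: np.ndarray
    phi_edges: np.ndarray
    counts: np.ndarray
    mean_turning: np.ndarray
    r_min: float
    excluded: int = 0
    min_count: int = DEFAULT_MIN_COUNT


def theta_phi_turning_map(
    observations: pd.DataFrame,
    r_min: float = 5.0,
    theta_edges: np.ndarray = DEFAULT_ANGULAR_EDGES,
    phi_edges: np.ndarray = DEFAULT_ANGULAR_EDGES,
    min_count: int = DEFAULT_MIN_COUNT,
) -> ThetaPhiMap:
    """Mean turning response per (theta, phi) cell, attraction zone only."""
    if r_min < 0:
        raise ValueError(f"r_min must be >= 0, got {r_min!r}")
    theta_edges = np.asarray(theta_edges, dtype=float)
    phi_edges = np.asarray(phi_edges, dtype=float)
    inside = observations["d"].to_numpy() > r_min
    obs = observations.loc[inside]
    it = _bin_index(obs["theta"].to_numpy(), theta_edges)
    ip = _bin_index(obs["phi"].to_numpy(), phi_edges)
    counts, (mt,), dropped = _cell_means(
        it, ip, theta_edges.size - 1, phi_edges.size - 1, obs["turn"].to_numpy()
    )
    return ThetaPhiMap(
        theta_edges=theta_edges,
        phi_edges=phi_edges,
        counts=counts,
        mean_turning=mt,
        r_min=float(r_min),
        excluded=int((~inside).sum()) + dropped,
        min_count=min_count,
    )


def _marginal_range(counts: np.ndarray, means: np.ndarray, axis: int, min_count: int) -> float:
    """Range (max - min) of count-weighted marginal mean turning along an axis."""
    with np.errstate(invalid="ignore"):
        weighted = np.nansum(np.where(counts > 0, means * counts, 0.0), axis=axis)
    n = counts.sum(axis=axis)
    marg = np.where(n >= min_count, weighted / np.maximum(n, 1), np.nan)
    if np.all(np.isnan(marg)):
        raise ValueError("no marginal bin reaches the minimum count")
    return float(np.nanmax(marg) - np.nanmin(marg))


def modulation_along_theta(m: ThetaPhiMap) -> float:
    """Range of the marginal mean turning across theta bins (attraction axis)."""
    return _marginal_range(m.counts, m.mean_turning, axis=1, min_count=m.min_count)


def modulation_along_phi(m: ThetaPhiMap) -> float:
    """Range of the marginal mean turning across phi bins (alignment axis)."""
    return _marginal_range(m.counts, m.mean_turning, axis=0, min_count=m.min_count)


def alignment_modulation(
    observations: pd.DataFrame,
    r_min: float = 5.0,
    n_theta: int = 12,
    min_row_fraction: float = 0.005,
) -> float:
    """Strength of the turning response's dependence on relative bearing.

    Count-weighted mean, over bins of neighbour direction theta, of the
    magnitude of the linear slope of the turning response on the relative
    bearing phi (units: (rad/s) per rad), restricted to the attraction zone
    (distance above ``r_min``).

    Two features of these trajectories make this the right measure of
    "modulation along the alignment axis" where a phi-marginal range is
    not.  First, the apparent alignment response reverses sign between the
    neighbour-ahead and neighbour-behind halves of the map — a follower
    appears to copy its leader's heading, a leader to anti-copy — so
    averaging over theta cancels it.  Second, smoother positional noise
    shrinks the spread of phi itself; a range over the observed phi support
    would conflate that shrinking support with the strength of the
    phi-dependence, which is what actually grows.  Rows holding less than
    ``min_row_fraction`` of the attraction-zone observations are skipped
    (their slopes are sampling noise).
    """
    az = observations[observations["d"] > r_min]
    edges = np.linspace(-np.pi, np.pi, n_theta + 1)
    idx = _bin_index(az["theta"].to_numpy(), edges)
    total = len(az)
    slopes, weights = [], []
    for i in range(n_theta):
        sub = az[idx == i]
        if len(sub) < max(2, min_row_fraction * total) or sub["phi"].std() == 0:
            continue
        slopes.append(abs(np.polyfit(sub["phi"], sub["turn"], 1)[0]))
        weights.append(len(sub))
    if not slopes:
        raise ValueError("no theta row holds enough observations for a phi slope")
    return float(np.average(slopes, weights=weights))


# ---------------------------------------------------------------------------
# responses to two neighbours


@dataclass(frozen=True)
class NeighbourPairMap:
    """Mean response binned by signed front-back distance to two neighbours.

    ``mean_response`` is NaN in cells with no observations ("missing").
    For predicted maps (``observed=False``) the counts are zero and the
    surface comes from averaging a pairwise profile.
    """

    fb1_edges: np.ndarray
    fb2_edges: np.ndarray
    counts: np.ndarray
    mean_response: np.ndarray
    response_kind: str
    observed: bool = True
    dropped: int = 0
    min_count: int = DEFAULT_MIN_COUNT
    ordering: str = "nearest"

    @property
    def reliable(self) -> np.ndarray:
        return self.counts >= self.min_count


def multi_neighbour_observed(
    tracksets: list[TrackSet],
    response_kind: str = "turn",
    edges: np.ndarray = DEFAULT_FB_EDGES,
    ordering: str = "nearest",
    min_count: int = DEFAULT_MIN_COUNT,
    rng: np.random.Generator | None = None,
) -> NeighbourPairMap:
    """Observed mean response of a focal individual to two neighbours.

    Works on three-individual flights; the focal is individual 0, whose
    position in the formation (front, centre, back) is randomized per
    flight by the simulator.  Each observation is binned by the signed
    front-back distances to the two neighbours.  ``ordering`` assigns
    neighbours to axes: ``"nearest"`` puts the neighbour with the smaller
    |front-back distance| on axis 1 at each observation; ``"random"``
    assigns the axes uniformly at random per observation (requires ``rng``).
    """
    if response_kind not in ("turn", "accel"):
        raise ValueError(f"response_kind must be 'turn' or 'accel', got {response_kind!r}")
    if ordering not in ("nearest", "random"):
        raise ValueError(f"ordering must be 'nearest' or 'random', got {ordering!r}")
    if ordering == "random" and rng is None:
        rng = np.random.default_rng()
    edges = np.asarray(edges, dtype=float)
    nb = edges.size - 1
    d1_all, d2_all, resp_all = [], [], []
    for ts in tracksets:
        if ts.n_individuals != 3:
            raise ValueError("multi-neighbour maps require three-individual flights")
        obs = pair_observations(ts)
        wide = obs.pivot(index="t", columns="neighbour", values="d_fb").dropna()
        resp = (
            obs.drop_duplicates("t").set_index("t")[response_kind].reindex(wide.index).to_numpy()
        )
        a = wide.iloc[:, 0].to_numpy()
        b = wide.iloc[:, 1].to_numpy()
        if ordering == "nearest":
            swap = np.abs(b) < np.abs(a)
        else:
            swap = rng.random(a.size) < 0.5
        d1 = np.where(swap, b, a)
        d2 = np.where(swap, a, b)
        d1_all.append(d1)
        d2_all.append(d2)
        resp_all.append(resp)
    d1 = np.concatenate(d1_all)
    d2 = np.concatenate(d2_all)
    resp = np.concatenate(resp_all)
    i1 = _bin_index(d1, edges)
    i2 = _bin_index(d2, edges)
    counts, (mean,), dropped = _cell_means(i1, i2, nb, nb, resp)
    return NeighbourPairMap(
        fb1_edges=edges,
        fb2_edges=edges,
        counts=counts,
        mean_response=mean,
        response_kind=response_kind,
        observed=True,
        dropped=dropped,
        min_count=min_count,
        ordering=ordering,
    )


def predict_from_pairwise(
    profile: FrontBackProfile, template: NeighbourPairMap
) -> NeighbourPairMap:
    """Predicted two-neighbour response assuming independent pairwise
    responses: ``predicted(d1, d2) = (profile(d1) + profile(d2)) / 2``.

    The pairwise profile must be estimated on exactly the bins of the
    template map (typically from two-individual flights at the same
    parameters)."""
    if not (
        np.array_equal(profile.edges, template.fb1_edges)
        and np.array_equal(profile.edges, template.fb2_edges)
    ):
        raise ValueError("profile bins and target grid edges must match exactly")
    p = profile.mean_response
    surface = 0.5 * (p[:, None] + p[None, :])
    return NeighbourPairMap(
        fb1_edges=template.fb1_edges,
        fb2_edges=template.fb2_edges,
        counts=np.zeros_like(template.counts),
        mean_response=surface,
        response_kind=template.response_kind,
        observed=False,
        dropped=0,
        min_count=template.min_count,
        ordering=template.ordering,
    )


def modulation_range(m: NeighbourPairMap, reliable_mask: np.ndarray | None = None) -> float:
    """Max minus min of the mean response over the given cells (defaults to
    the map's own reliable cells for observed maps, all finite cells for
    predicted ones)."""
    if reliable_mask is None:
        reliable_mask = m.reliable if m.observed else np.isfinite(m.mean_response)
    vals = m.mean_response[reliable_mask & np.isfinite(m.mean_response)]
    if vals.size == 0:
        raise ValueError("no reliable cells to measure a modulation range on")
    return float(vals.max() - vals.min())
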