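"""Generate co-moving tracks: a common correlated-random path, individuals
placed on it at fixed mutual target positions, and autocorrelated
positional noise added on top.

The individuals never interact.  Each one occupies a fixed offset on a
placement segment that rides along the common path, so with zero recording
noise the group is perfectly rigid.  Recording noise displaces each
individual independently around its target position; every "apparent"
interaction the analysis layer later reports is a by-product of this
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .noise import correlated_sequence, normalize_by_max_abs, rescale_to_std

__all__ = [
    "SimulationConfig",
    "PathState",
    "TrackSet",
    "generate_common_path",
    "place_individuals",
    "add_recording_noise",
    "simulate_flock",
    "FRONT_BACK",
    "SIDE_BY_SIDE",
]

#: Placement-segment angle for a front-back configuration (segment parallel
#: to the direction of motion).
FRONT_BACK = 0.0
#: Placement-segment angle for a side-by-side configuration (segment
#: perpendicular to the direction of motion; positive offsets lie to the
#: left in the mathematical convention used internally).
SIDE_BY_SIDE = np.pi / 2


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters for one simulated flight.

    Defaults are the reference conditions used throughout: 4096-step flights
    at base speed 5 a.u./step with speed fluctuations of amplitude 0.2 and
    turning fluctuations of amplitude 0.02 rad/step, both correlated over
    C_T = 300 steps; two individuals spaced r = 5 a.u. apart in a front-back
    configuration; per-component displacement noise of standard deviation
    r/2 = 2.5 a.u. correlated over C_D = 20 steps; 5 steps per second
    (dt = 0.2 s).
    """

    n_steps: int = 4096
    base_speed: float = 5.0
    speed_amplitude: float = 0.2
    turn_amplitude: float = 0.02
    path_cutoff: float = 300.0
    displacement_cutoff: float = 20.0
    spacing: float = 5.0
    configuration_angle: float = FRONT_BACK
    n_individuals: int = 2
    displacement_std: float = 2.5
    dt: float = 0.2
    seed: int = 0
    n_trajectories: int = 100

    def __post_init__(self) -> None:
        problems = []
        if self.n_steps < 2:
            problems.append(f"n_steps must be >= 2 (got {self.n_steps})")
        if not (self.base_speed > self.speed_amplitude >= 0):
            problems.append(
                "need base_speed > speed_amplitude >= 0 so speed stays positive "
                f"(got {self.base_speed}, {self.speed_amplitude})"
            )
        if self.turn_amplitude < 0:
            problems.append(f"turn_amplitude must be >= 0 (got {self.turn_amplitude})")
        if not self.spacing > 0:
            problems.append(f"spacing must be positive (got {self.spacing})")
        if self.displacement_std < 0:
            problems.append(f"displacement_std must be >= 0 (got {self.displacement_std})")
        if self.n_individuals not in (2, 3):
            problems.append(f"n_individuals must be 2 or 3 (got {self.n_individuals})")
        if not self.dt > 0:
            problems.append(f"dt must be positive (got {self.dt})")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class PathState:
    """The common trajectory all individuals ride on.

    ``positions[t + 1] - positions[t]`` has length ``speeds[t]`` and
    direction ``headings[t]``; headings accumulate the turning angles.
    """

    speeds: np.ndarray  # a.u./step, length N
    turns: np.ndarray  # rad/step, length N
    headings: np.ndarray  # rad, length N
    positions: np.ndarray  # (N, 2), a.u.


@dataclass(frozen=True)
class TrackSet:
    """Ideal and recorded tracks for the individuals of one flight.

    ``recorded[k] = ideal[k] + displacements[k]`` element-wise.  ``offsets``
    holds each individual's signed position along the placement segment,
    constant for the whole flight.
    """

    ideal: np.ndarray  # (n_individuals, N, 2)
    recorded: np.ndarray  # (n_individuals, N, 2)
    displacements: np.ndarray  # (n_individuals, N, 2)
    offsets: np.ndarray  # (n_individuals,), a.u.
    config: SimulationConfig | None = field(default=None, compare=False)

    @property
    def n_individuals(self) -> int:
        return self.ideal.shape[0]

    @property
    def n_steps(self) -> int:
        return self.ideal.shape[1]


def generate_common_path(config: SimulationConfig, rng: np.random.Generator) -> PathState:
    """Integrate the common correlated-random trajectory.

    Speeds are ``S0 + s * eps1 / max|eps1|`` and per-step turning angles
    ``a * eps2 / max|eps2|``, where ``eps1`` and ``eps2`` are independent
    uniform-based correlated sequences with cut-off ``path_cutoff``.  The
    path starts at the origin heading along +x; heading at step t is the
    cumulative sum of the turning angles before t.
    """
    n = config.n_steps
    if config.speed_amplitude > 0 or config.turn_amplitude > 0:
        eps1 = correlated_sequence(n, config.path_cutoff, "uniform_half", rng=rng).values
        eps2 = correlated_sequence(n, config.path_cutoff, "uniform_half", rng=rng).values
        speeds = config.base_speed + config.speed_amplitude * normalize_by_max_abs(eps1)
        turns = config.turn_amplitude * normalize_by_max_abs(eps2)
        if config.speed_amplitude == 0:
            speeds = np.full(n, config.base_speed)
        if config.turn_amplitude == 0:
            turns = np.zeros(n)
    else:
        speeds = np.full(n, config.base_speed)
        turns = np.zeros(n)

    headings = np.empty(n)
    headings[0] = 0.0
    headings[1:] = np.cumsum(turns[:-1])
    steps = speeds[:, None] * np.column_stack([np.cos(headings), np.sin(headings)])
    positions = np.empty((n, 2))
    positions[0] = 0.0
    positions[1:] = np.cumsum(steps[:-1], axis=0)
    return PathState(speeds=speeds, turns=turns, headings=headings, positions=positions)


def _segment_offsets(n_individuals: int, spacing: float) -> np.ndarray:
    """Equally spaced offsets, symmetric about the path point."""
    if n_individuals == 2:
        return np.array([-spacing / 2, spacing / 2])
    if n_individuals == 3:
        return np.array([-spacing, 0.0, spacing])
    raise ValueError(f"n_individuals must be 2 or 3 (got {n_individuals})")


def place_individuals(
    path: PathState, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pin individuals to fixed offsets on the moving placement segment.

    At each step t the segment passes through the path point at angle
    ``configuration_angle`` relative to the direction of the step t -> t+1
    (the final step reuses the preceding direction).  Offsets are symmetric
    about zero with spacing r, and which individual gets which offset is
    drawn uniformly at random once per flight.

    Returns
    -------
    ideal : numpy.ndarray, shape (n_individuals, N, 2)
    offsets : numpy.ndarray, shape (n_individuals,)
        Signed position of each individual along the segment.
    """
    n = path.positions.shape[0]
    if n < 2:
        raise ValueError("path must have at least 2 steps")
    step_dir = np.empty(n)
    step_dir[:-1] = path.headings[:-1]
    step_dir[-1] = path.headings[-2]
    seg_angle = step_dir + config.configuration_angle
    u = np.column_stack([np.cos(seg_angle), np.sin(seg_angle)])

    base = _segment_offsets(config.n_individuals, config.spacing)
    offsets = base[rng.permutation(config.n_individuals)]
    ideal = path.positions[None, :, :] + offsets[:, None, None] * u[None, :, :]
    return ideal, offsets


def add_recording_noise(
    ideal: np.ndarray,
    offsets: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TrackSet:
    """Displace each individual independently around its target position.

    For each individual, the x and y components of the displacement are
    independent standard-normal-based correlated sequences with cut-off
    ``displacement_cutoff``, rescaled after filtering to sample standard
    deviation ``displacement_std`` (per flight, per component).  There is no
    cross-correlation between individuals.
    """
    n_ind, n, _ = ideal.shape
    eta = np.zeros_like(ideal)
    if config.displacement_std > 0:
        for k in range(n_ind):
            for c in range(2):
                seq = correlated_sequence(
                    n, config.displacement_cutoff, "standard_normal", rng=rng
                ).values
                eta[k, :, c] = rescale_to_std(seq, config.displacement_std)
    return TrackSet(
        ideal=ideal,
        recorded=ideal + eta,
        displacements=eta,
        offsets=offsets,
        config=config,
    )


def simulate_flock(config: SimulationConfig) -> TrackSet:
    """Run one complete flight, deterministically from ``config.seed``.

    Substreams of the seed are consumed in a fixed order: common path
    (eps1 then eps2), offset assignment, then per-individual x and y
    displacement series in individual order.
    """
    ss = np.random.SeedSequence(config.seed)
    path_ss, place_ss, noise_ss = ss.spawn(3)
    path = generate_common_path(config, np.random.default_rng(path_ss))
    ideal, offsets = place_individuals(path, config, np.random.default_rng(place_ss))
    return add_recording_noise(ideal, offsets, config, np.random.default_rng(noise_ss))


def flight_seeds(master_seed: int, n_flights: int) -> np.ndarray:
    """Derive ``n_flights`` independent per-flight seeds from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_flights, dtype=np.uint32)
    return (state & 0x7FFFFFFF).astype(np.int64)
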