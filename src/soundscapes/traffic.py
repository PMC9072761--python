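"""Vehicle microsimulation on the acoustically infinite loop road.

The road is a closed loop built by stacking the landscape's columns: a
400 x 301-cell landscape yields 1 m road patches down each of 400 columns
plus the half-row offsets, a 120,700 m loop whose unwrapped coordinate runs
y in [-60,350, +60,350] m.  Only the central segment (|y| <= 1,505 m for
the default world) runs alongside the ecological landscape; the rest is the
approach and departure.  Vehicles wrap modulo the loop length, so a finite
vehicle population produces an indefinite stream of pass-bys.

Car following is deliberately minimal: constant acceleration up to a
per-vehicle maximum speed (speed limit plus a centred Gamma deviate), and a
stochastic overtaking rule — a vehicle catching its leader either passes
unaffected (probability ``vpass_probability``) or falls in behind at the
leader's speed minus ``excess_brake``.  Braking below the leader's speed is
what lets platoons condense: congestion is emergent, not prescribed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoadLoop",
    "TrafficParams",
    "TrafficState",
    "kph_to_mps",
    "mps_to_kph",
    "vehicle_count_for_vph",
    "init_vehicles",
    "step_traffic",
    "realized_vph",
    "congestion_metrics",
]


def kph_to_mps(v):
    return np.asarray(v, dtype=float) / 3.6 if np.ndim(v) else float(v) / 3.6


def mps_to_kph(v):
    return np.asarray(v, dtype=float) * 3.6 if np.ndim(v) else float(v) * 3.6


@dataclass
class RoadLoop:
    """Closed loop road; positions in metres in [0, length)."""

    length: float
    landscape_half_extent: float  # |unwrapped y| below this runs along the landscape

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("loop length must be positive")
        if not 0 < self.landscape_half_extent <= self.length / 2:
            raise ValueError("landscape segment must fit inside the loop")

    @classmethod
    def from_landscape(cls, nx: int, ny: int, cell_size: float = 10.0) -> "RoadLoop":
        """Stacked-column construction: nx columns of ny 1 m patches plus the
        (ny-1) m of half-row offsets; half-extent (nx/2)*ny + (ny-1)/2 m."""
        length = float(nx * ny + ny - 1)
        return cls(length=length, landscape_half_extent=ny * cell_size / 2.0)

    @property
    def half_extent(self) -> float:
        return self.length / 2.0

    def unwrapped_y(self, position):
        """Map loop position(s) to the signed road coordinate in [-L/2, L/2)."""
        return np.asarray(position, dtype=float) - self.half_extent


@dataclass
class TrafficParams:
    num_vehicles: float = 50.0  # target vehicles/hour (or direct count, see mode)
    speed_limit: float = 60.0  # kph
    speed_limit_sd: float = 10.0  # kph
    acceleration: float = 2.0  # m/s^2
    vpass_probability: float = 0.5
    excess_brake: float = 5.0  # kph
    gamma_shape: float = 2.0  # shape of the max-speed deviate distribution

    def __post_init__(self) -> None:
        if min(self.num_vehicles, self.speed_limit, self.speed_limit_sd,
               self.acceleration, self.excess_brake) < 0:
            raise ValueError("traffic parameters must be non-negative")
        if not 0.0 <= self.vpass_probability <= 1.0:
            raise ValueError("vpass_probability must be in [0, 1]")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    @property
    def speed_limit_mps(self) -> float:
        return kph_to_mps(self.speed_limit)


@dataclass
class TrafficState:
    """Positions (m, loop coordinate), speeds and per-vehicle max speeds (m/s)."""

    positions: np.ndarray
    speeds: np.ndarray
    max_speeds: np.ndarray
    vehicle_type: str = "sedan"
    crossing_times: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.max_speeds = np.asarray(self.max_speeds, dtype=float)

    @property
    def n(self) -> int:
        return len(self.positions)


def vehicle_count_for_vph(vph: float, loop: RoadLoop, speed_limit_mps: float) -> int:
    """Vehicle count whose steady flux at the speed limit equals ``vph``/hour.

    count = round(VPH * L / (v * 3600)): ``count`` vehicles circulating at
    the limit pass any fixed point VPH times per hour.
    """
    if speed_limit_mps <= 0:
        raise ValueError("speed limit must be positive")
    return int(round(vph * loop.length / (speed_limit_mps * 3600.0)))


def init_vehicles(
    n: int, loop: RoadLoop, params: TrafficParams, rng: np.random.Generator,
    vehicle_type: str = "sedan",
) -> TrafficState:
    """Place ``n`` vehicles at distinct integer-metre patches, at max speed.

    Each max speed is the limit plus a centred Gamma deviate: with
    X ~ Gamma(k, theta), theta = SD/sqrt(k), the deviate X - k*theta has
    mean 0 and standard deviation ``speed_limit_sd`` while allowing both
    slower and faster vehicles.  Speeds are floored at 1 m/s so every
    vehicle eventually clears the landscape segment.
    """
    n_patches = int(loop.length)
    if n < 0 or n > n_patches:
        raise ValueError(f"need 0 <= n <= {n_patches} (available road patches)")
    positions = rng.choice(n_patches, size=n, replace=False).astype(float)
    positions.sort()

    sd = kph_to_mps(params.speed_limit_sd)
    limit = params.speed_limit_mps
    if sd == 0:
        max_speeds = np.full(n, limit)
    else:
        k = params.gamma_shape
        theta = sd / np.sqrt(k)
        x = rng.gamma(shape=k, scale=theta, size=n)
        max_speeds = limit + (x - k * theta)
    max_speeds = np.maximum(max_speeds, 1.0)
    return TrafficState(positions, max_speeds.copy(), max_speeds, vehicle_type)


def _crossed(old: np.ndarray, new_disp: np.ndarray, point: float, length: float) -> np.ndarray:
    """True where a vehicle's displacement carried it past ``point`` on the loop."""
    gap = np.mod(point - old, length)
    return (new_disp >= gap) & (new_disp > 0)


def step_traffic(
    state: TrafficState,
    loop: RoadLoop,
    params: TrafficParams,
    dt: float,
    rng: np.random.Generator,
    time_s: float | None = None,
) -> TrafficState:
    """Advance one tick, in place.

    Each vehicle accelerates toward its max speed, then resolves overtaking
    against its leader in ascending-position order: catching the leader this
    tick, it passes unchanged with probability ``vpass_probability`` and
    otherwise brakes to (leader speed - excess_brake) and holds 1 m behind
    the leader's new position.  When ``time_s`` is given, crossings of the
    landscape-segment entry point are appended to ``state.crossing_times``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = state.n
    if n == 0:
        return state

    speeds = np.minimum(state.max_speeds, state.speeds + params.acceleration * dt)
    old_pos = state.positions.copy()
    brake = kph_to_mps(params.excess_brake)
    L = loop.length

    order = np.argsort(old_pos, kind="stable")  # ties broken by vehicle id
    new_pos = np.empty(n)
    new_speed = speeds.copy()
    if n == 1:
        new_pos[0] = (old_pos[0] + speeds[0] * dt) % L
    else:
        # leader of order[i] is order[i+1] (wrapping); passing is resolved
        # against the leader's pre-move position and post-acceleration speed
        for idx in range(n):
            i = order[idx]
            lead = order[(idx + 1) % n]
            gap = (old_pos[lead] - old_pos[i]) % L
            rel = (speeds[i] - speeds[lead]) * dt
            if rel >= gap and gap > 0:
                if rng.random() < params.vpass_probability:
                    new_pos[i] = (old_pos[i] + speeds[i] * dt) % L
                else:
                    new_speed[i] = max(0.0, speeds[lead] - brake)
                    new_pos[i] = (old_pos[lead] + speeds[lead] * dt - 1.0) % L
            else:
                new_pos[i] = (old_pos[i] + speeds[i] * dt) % L

    if time_s is not None:
        entry_point = (loop.half_extent - loop.landscape_half_extent) % L
        disp = np.mod(new_pos - old_pos, L)
        # braked vehicles may be repositioned slightly backwards; count only
        # genuine forward passage (displacement bounded by one tick's travel)
        disp = np.where(disp <= speeds * dt + 1.0, disp, 0.0)
        for _ in range(int(np.count_nonzero(_crossed(old_pos, disp, entry_point, L)))):
            state.crossing_times.append(float(time_s))

    state.positions = new_pos
    state.speeds = new_speed
    return state


def realized_vph(crossing_times, duration: float | None = None, window: float = 3600.0):
    """Median hourly passage rate from a log of boundary-crossing times.

    The log is split into non-overlapping windows of ``window`` seconds
    (default one hour); the median of the per-window rates is returned.  A
    trailing partial window is dropped; runs shorter than one window use a
    single whole-run estimate.  An empty log gives 0.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    times = np.sort(np.asarray(list(crossing_times), dtype=float))
    if times.size == 0:
        return 0.0
    if duration is None:
        duration = float(times[-1])
    if duration <= 0:
        return 0.0
    n_windows = int(duration // window)
    if n_windows == 0:
        return float(times.size * 3600.0 / duration)
    counts = np.histogram(times, bins=n_windows, range=(0.0, n_windows * window))[0]
    return float(np.median(counts) * 3600.0 / window)


def congestion_metrics(state: TrafficState) -> dict:
    """Mean speed and the number of vehicles held below their max speed."""
    if state.n == 0:
        return {"mean_speed_mps": float("nan"), "n_blocked": 0}
    return {
        "mean_speed_mps": float(np.mean(state.speeds)),
        "n_blocked": int(np.count_nonzero(state.speeds < state.max_speeds - 1e-9)),
    }
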