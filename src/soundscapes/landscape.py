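"""The ecological landscape: resources, acoustic searchers, trail and stations.

The landscape is a grid of 10 m cells (400 x 301 by default, i.e. 4 km x
3.01 km) with the road running up its left edge (x = 0) and a trail along
the central row (y = 0).  Searchers are correlated-random-walk foragers:
each tick the heading deviates from the previous one by a Gaussian turn,
until an unvisited resource falls within the current (noise-degraded)
detection radius, at which point the searcher homes in on it.  Resources
are stationary, continuously calling, and never revisited by the same
searcher.  Humans on the trail and fixed monitoring stations listen for
searchers with their own (noise-degraded) radii.

Alongside every noise-limited detection the model books the detection that
would have happened at the full noiseless radius — the counterfactual that
turns a run into an estimate of how much traffic noise masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustics import PropagationTable
from .traffic import RoadLoop

__all__ = [
    "Landscape",
    "Resources",
    "Searchers",
    "Station",
    "n_resources_for_spacing",
    "place_resources",
    "column_exposure_levels",
    "noise_constrained_weights",
    "reflect_at_boundary",
    "step_searchers",
    "searcher_noise_exposure",
    "trail_audibility",
    "noiseless_birdable_probability",
    "actual_birdable_probability",
    "station_update",
]


@dataclass
class Landscape:
    """Grid of square cells with the road at x=0 and the trail at y=0."""

    nx: int = 400
    ny: int = 301
    cell_size: float = 10.0
    ambient_level: float = 25.0  # dBA

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.cell_size <= 0:
            raise ValueError("invalid landscape dimensions")
        if self.ny % 2 == 0:
            raise ValueError("ny must be odd so a central trail row exists")

    @property
    def width(self) -> float:
        """Extent along x (away from the road), m."""
        return self.nx * self.cell_size

    @property
    def half_height(self) -> float:
        """Half-extent along y (parallel to the road), m."""
        return self.ny * self.cell_size / 2.0

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def area(self) -> float:
        return self.n_cells * self.cell_size**2

    @property
    def trail_row(self) -> int:
        return (self.ny - 1) // 2

    def cell_center(self, i, j):
        """Centre of cell (i, j); cell (0, trail_row) is the road-trail junction."""
        x = (np.asarray(i) + 0.5) * self.cell_size
        y = (np.asarray(j) - self.trail_row) * self.cell_size
        return x, y

    def cell_of(self, x, y):
        i = np.clip(np.floor(np.asarray(x) / self.cell_size).astype(int), 0, self.nx - 1)
        j = np.clip(
            np.floor((np.asarray(y) + self.half_height) / self.cell_size).astype(int),
            0,
            self.ny - 1,
        )
        return i, j

    def trail_x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.cell_size

    def road_loop(self) -> RoadLoop:
        return RoadLoop.from_landscape(self.nx, self.ny, self.cell_size)

    @property
    def bounds(self):
        """(xmin, xmax, ymin, ymax) of the searchable area."""
        return 0.0, self.width, -self.half_height, self.half_height


# --------------------------------------------------------------------------
# Resources
# --------------------------------------------------------------------------


def n_resources_for_spacing(meters_per_resource: float, base_radius: float, area: float) -> int:
    """Resource count giving the requested mean travel distance per detection.

    A searcher moving on a straight transect with detection half-width r
    through density rho encounters resources every 1/(2*r*rho) metres, so
    N = area / (2 * base_radius * meters_per_resource).
    """
    if min(meters_per_resource, base_radius, area) <= 0:
        raise ValueError("all inputs must be positive")
    n = int(round(area / (2.0 * base_radius * meters_per_resource)))
    if n < 1:
        raise ValueError("resource spacing implies fewer than one resource")
    return n


@dataclass
class Resources:
    """Stationary calling resources at cell centres."""

    cells: np.ndarray  # (n, 2) int cell indices
    positions: np.ndarray  # (n, 2) float centres, m
    visit_counts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.visit_counts is None:
            self.visit_counts = np.zeros(len(self.cells), dtype=int)

    @property
    def n(self) -> int:
        return len(self.cells)


def column_exposure_levels(
    landscape: Landscape,
    table: PropagationTable,
    speed_mps: float,
    vehicle_spacing_m: float,
    cutoff_m: float | None = None,
) -> np.ndarray:
    """Expected traffic-only A-level (dBA) at the trail row of each column.

    Emulates steady traffic: virtual vehicles every ``vehicle_spacing_m``
    along the (effectively infinite) road at ``speed_mps``, energy-summed at
    each column's distance from the road.  Used for noise-constrained
    resource placement, where only relative levels across columns matter.
    """
    if cutoff_m is None:
        cutoff_m = 20.0 * landscape.width
    ys = np.arange(-cutoff_m, cutoff_m + vehicle_spacing_m, vehicle_spacing_m)
    x = landscape.trail_x_centers()
    dist = np.hypot(x[:, None], ys[None, :])
    levels = table.lookup(dist, speed_mps)
    return 10.0 * np.log10(np.sum(10.0 ** (levels / 10.0), axis=1))


def noise_constrained_weights(
    landscape: Landscape, column_levels_db: np.ndarray, floor_db: float = 0.1
) -> np.ndarray:
    """Per-cell sampling weights inversely proportional to expected noise excess.

    The excess is the time-averaged total level above ambient at the cell's
    column, floored at ``floor_db`` so quiet cells get a large, finite
    weight; a spatially uniform field reduces to uniform sampling.
    """
    ambient = landscape.ambient_level
    total = 10.0 * np.log10(10.0 ** (column_levels_db / 10.0) + 10.0 ** (ambient / 10.0))
    excess = np.maximum(total - ambient, floor_db)
    col_w = 1.0 / excess
    return np.repeat(col_w, landscape.ny)


def place_resources(
    landscape: Landscape,
    n: int,
    rng: np.random.Generator,
    mode: str = "random",
    weights: np.ndarray | None = None,
) -> Resources:
    """Sample ``n`` distinct cells, uniformly or biased toward quiet cells.

    ``mode="noise-constrained"`` requires per-cell ``weights`` (from
    ``noise_constrained_weights``); sampling is without replacement with
    probability proportional to weight.
    """
    if n > landscape.n_cells:
        raise ValueError("more resources than landscape cells")
    if mode == "random":
        flat = rng.choice(landscape.n_cells, size=n, replace=False)
    elif mode == "noise-constrained":
        if weights is None:
            raise ValueError("noise-constrained placement needs per-cell weights")
        p = np.asarray(weights, dtype=float)
        if len(p) != landscape.n_cells or np.any(p < 0):
            raise ValueError("weights must be non-negative, one per cell")
        flat = rng.choice(landscape.n_cells, size=n, replace=False, p=p / p.sum())
    else:
        raise ValueError(f"unknown placement mode: {mode!r}")
    i, j = flat // landscape.ny, flat % landscape.ny
    x, y = landscape.cell_center(i, j)
    return Resources(np.column_stack([i, j]), np.column_stack([x, y]))


# --------------------------------------------------------------------------
# Searchers
# --------------------------------------------------------------------------


@dataclass
class Searchers:
    """Vectorised state of all searchers.

    ``visited`` is the append-only per-searcher memory; ``counterfactual``
    and ``detected`` book, per (searcher, resource) pair, whether the pair
    ever came within the noiseless / the noise-degraded radius while the
    resource was not yet in that searcher's memory.
    """

    positions: np.ndarray  # (n, 2), m
    headings: np.ndarray  # (n,), degrees, 0 = +x, CCW
    speed: float  # m/s
    turn_sd: float  # degrees
    base_radius: float  # m, noiseless detection radius
    n_resources: int
    targets: np.ndarray = field(default=None)  # resource index or -1
    current_radius: np.ndarray = field(default=None)
    visited: np.ndarray = field(default=None)  # (n, n_resources) bool
    counterfactual: np.ndarray = field(default=None)
    detected: np.ndarray = field(default=None)
    exposure_sum: np.ndarray = field(default=None)  # accumulated dBA-ticks
    distance_traveled: np.ndarray = field(default=None)
    audible_ticks: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.positions)
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        if self.targets is None:
            self.targets = np.full(n, -1, dtype=int)
        if self.current_radius is None:
            self.current_radius = np.full(n, self.base_radius)
        shape = (n, self.n_resources)
        for name in ("visited", "counterfactual", "detected"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape, dtype=bool))
        for name in ("exposure_sum", "distance_traveled", "audible_ticks"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n))

    @property
    def n(self) -> int:
        return len(self.positions)

    @classmethod
    def init_random(
        cls,
        landscape: Landscape,
        n: int,
        speed: float,
        turn_sd: float,
        base_radius: float,
        n_resources: int,
        rng: np.random.Generator,
    ) -> "Searchers":
        xmin, xmax, ymin, ymax = landscape.bounds
        pos = np.column_stack(
            [rng.uniform(xmin, xmax, size=n), rng.uniform(ymin, ymax, size=n)]
        )
        headings = rng.uniform(0.0, 360.0, size=n)
        return cls(pos, headings, speed, turn_sd, base_radius, n_resources)


def _unit(heading_deg):
    h = np.deg2rad(heading_deg)
    return np.cos(h), np.sin(h)


def reflect_at_boundary(
    position: np.ndarray,
    heading_deg: float,
    step: float,
    bounds,
    turn_sd: float,
    rng: np.random.Generator,
    max_tries: int = 20,
) -> float:
    """Forward reflection off an impassable edge.

    The specular reflection of the heading about the violated edge, plus a
    Gaussian jitter of SD ``turn_sd`` degrees, redrawn until the proposed
    step stays inside; falls back to pure specular reflection (clamped
    inward) if the jitter keeps failing.  The landscape does not wrap —
    noise is asymmetric across it, so wrapping would teleport searchers
    between different noise regimes.
    """
    xmin, xmax, ymin, ymax = bounds
    x, y = position
    dx, dy = _unit(heading_deg)
    px, py = x + dx * step, y + dy * step
    flip_x = px < xmin or px > xmax
    flip_y = py < ymin or py > ymax
    if not flip_x and not flip_y:
        return heading_deg

    if flip_x and flip_y:
        spec = heading_deg + 180.0
    elif flip_x:
        spec = 180.0 - heading_deg
    else:
        spec = -heading_deg
    spec %= 360.0

    for attempt in range(max_tries):
        cand = spec + (rng.normal(0.0, turn_sd) if turn_sd > 0 else 0.0)
        cx, cy = _unit(cand)
        qx, qy = x + cx * step, y + cy * step
        if xmin <= qx <= xmax and ymin <= qy <= ymax:
            return cand % 360.0
        if attempt == max_tries - 1:
            return spec
    return spec


def step_searchers(
    s: Searchers,
    resources: Resources,
    landscape: Landscape,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """One movement-and-scan tick for every searcher, in place.

    Order per searcher: move (pursuit if targeting, otherwise correlated
    random walk with boundary reflection); on arrival commit the resource to
    memory; then scan — book counterfactual (noiseless-radius) and actual
    (current-radius) first contacts with unvisited resources, and if idle
    lock onto the nearest resource within the current radius.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    step = s.speed * dt
    bounds = landscape.bounds
    rpos = resources.positions

    for i in range(s.n):
        t = s.targets[i]
        if t >= 0:
            vec = rpos[t] - s.positions[i]
            dist = float(np.hypot(*vec))
            s.headings[i] = np.degrees(np.arctan2(vec[1], vec[0])) % 360.0
            if dist <= step:
                s.positions[i] = rpos[t]
                s.visited[i, t] = True
                resources.visit_counts[t] += 1
                s.targets[i] = -1
                s.distance_traveled[i] += dist
            else:
                s.positions[i] += vec / dist * step
                s.distance_traveled[i] += step
        else:
            if s.turn_sd > 0:
                s.headings[i] = (s.headings[i] + rng.normal(0.0, s.turn_sd)) % 360.0
            for _ in range(10):
                dx, dy = _unit(s.headings[i])
                px, py = s.positions[i, 0] + dx * step, s.positions[i, 1] + dy * step
                if bounds[0] <= px <= bounds[1] and bounds[2] <= py <= bounds[3]:
                    break
                s.headings[i] = reflect_at_boundary(
                    s.positions[i], s.headings[i], step, bounds, s.turn_sd, rng
                )
            dx, dy = _unit(s.headings[i])
            s.positions[i, 0] = np.clip(s.positions[i, 0] + dx * step, bounds[0], bounds[1])
            s.positions[i, 1] = np.clip(s.positions[i, 1] + dy * step, bounds[2], bounds[3])
            s.distance_traveled[i] += step

        # scan from the new position
        if resources.n:
            d = np.hypot(
                rpos[:, 0] - s.positions[i, 0], rpos[:, 1] - s.positions[i, 1]
            )
            unvisited = ~s.visited[i]
            s.counterfactual[i] |= unvisited & (d <= s.base_radius)
            in_range = unvisited & (d <= s.current_radius[i])
            s.detected[i] |= in_range
            if s.targets[i] < 0 and np.any(in_range):
                idx = np.nonzero(in_range)[0]
                s.targets[i] = int(idx[np.argmin(d[idx])])


# --------------------------------------------------------------------------
# Noise exposure of receivers
# --------------------------------------------------------------------------


def searcher_noise_exposure(
    positions: np.ndarray,
    vehicle_y: np.ndarray,
    vehicle_speeds: np.ndarray,
    table: PropagationTable,
    ambient: float,
    cutoff_m: float | None = None,
) -> np.ndarray:
    """Total A-level (dBA) at each receiver: ambient (+) all vehicle pass-bys.

    ``positions`` are ecological (x = distance from road, y) in metres;
    ``vehicle_y`` are unwrapped road coordinates.  Vehicles beyond
    ``cutoff_m`` (where their table level is negligible against ambient)
    are skipped.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    power = np.full(len(pos), 10.0 ** (ambient / 10.0))
    if len(vehicle_y):
        vy = np.asarray(vehicle_y, dtype=float)
        dy = vy[None, :] - pos[:, 1:2]
        if cutoff_m is not None:
            mask = np.abs(dy) <= cutoff_m
        else:
            mask = np.ones_like(dy, dtype=bool)
        if np.any(mask):
            dist = np.hypot(pos[:, 0:1], dy)
            levels = np.where(
                mask, table.lookup(dist, np.asarray(vehicle_speeds)[None, :]), -np.inf
            )
            power += np.sum(10.0 ** (levels / 10.0), axis=1, where=mask, initial=0.0)
    return 10.0 * np.log10(power)


# --------------------------------------------------------------------------
# Trail and stations
# --------------------------------------------------------------------------


def trail_audibility(
    positions: np.ndarray, trail_x: np.ndarray, trail_radii: np.ndarray
) -> np.ndarray:
    """True per searcher if any trail cell can hear it.

    A searcher is audible from trail cell t when its distance to the cell
    centre is at most that cell's current (noise-degraded) human radius.
    """
    pos = np.atleast_2d(positions)
    dx = pos[:, 0:1] - np.asarray(trail_x)[None, :]
    d2 = dx * dx + pos[:, 1:2] ** 2
    return np.any(d2 <= np.asarray(trail_radii)[None, :] ** 2, axis=1)


def noiseless_birdable_probability(landscape: Landscape, human_radius: float) -> float:
    """Fraction of the landscape within ``human_radius`` of the trail.

    The trail spans every column, so a cell's distance to the nearest trail
    cell centre is just its |y|; the fraction is the share of rows with
    |y| <= radius.
    """
    if human_radius < 0:
        raise ValueError("radius must be >= 0")
    j = np.arange(landscape.ny)
    y = (j - landscape.trail_row) * landscape.cell_size
    return float(np.count_nonzero(np.abs(y) <= human_radius)) / landscape.ny


def actual_birdable_probability(landscape: Landscape, trail_radii: np.ndarray) -> float:
    """Birdable fraction under per-trail-cell noise-degraded radii."""
    trail_x = landscape.trail_x_centers()
    r2 = np.asarray(trail_radii, dtype=float) ** 2
    xc = trail_x  # cell x-centres coincide with trail x-centres
    # per column: the largest reach^2 minus along-trail offset^2 any trail cell provides
    m = np.max(r2[None, :] - (xc[:, None] - trail_x[None, :]) ** 2, axis=1)
    y = (np.arange(landscape.ny) - landscape.trail_row) * landscape.cell_size
    counts = np.count_nonzero(y[None, :] ** 2 <= m[:, None], axis=1)
    return float(np.sum(counts)) / landscape.n_cells


@dataclass
class Station:
    """Fixed listening station on the trail with episode-based tallies.

    A counterfactual episode opens when a searcher enters the noiseless
    radius and closes when it leaves; each episode adds one counterfactual
    detection, and at most one actual detection (the first tick the searcher
    is also inside the noise-degraded radius).  Tallying at most one actual
    per episode keeps the noiseless count an upper bound even when the
    degraded radius fluctuates tick to tick.
    """

    x_m: float
    y_m: float = 0.0
    actual: int = 0
    counterfactual: int = 0
    _inside: np.ndarray = None
    _tallied: np.ndarray = None

    def _ensure(self, n: int) -> None:
        if self._inside is None or len(self._inside) != n:
            self._inside = np.zeros(n, dtype=bool)
            self._tallied = np.zeros(n, dtype=bool)


def station_update(
    stations: list,
    positions: np.ndarray,
    actual_radii: np.ndarray,
    noiseless_radius: float,
) -> None:
    """Advance all stations' episode bookkeeping one tick, in place."""
    pos = np.atleast_2d(positions)
    n = len(pos)
    for k, st in enumerate(stations):
        st._ensure(n)
        d = np.hypot(pos[:, 0] - st.x_m, pos[:, 1] - st.y_m)
        in_cf = d <= noiseless_radius
        entering = in_cf & ~st._inside
        st.counterfactual += int(np.count_nonzero(entering))
        st._tallied[entering] = False
        st._inside = in_cf
        hit = in_cf & ~st._tallied & (d <= actual_radii[k])
        st.actual += int(np.count_nonzero(hit))
        st._tallied[hit] = True
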