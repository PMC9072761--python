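"""Simulation engine: configuration, per-tick scheduling and run metrics.

A run couples three layers on a shared 1 s clock: the vehicle
microsimulation on the loop road, the acoustic field (per-receiver ISO 9613
propagation through a precomputed table), and the searcher/trail/station
agents whose detection radii shrink with the total sound level.  A run
lasts as long as a vehicle at the speed limit would need to traverse the
loop five times, so every simulated landscape sees the same number of
nominal pass-bys regardless of speed.

Reproducibility: the run seed spawns independent substreams for traffic,
searcher movement and resource placement, so turning noise bookkeeping off
(or removing all vehicles) leaves agent trajectories bit-identical.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import acoustics as ac
from . import fixtures, landscape as ls, traffic as tr

__all__ = ["SimulationConfig", "RunMetrics", "run", "default_station_positions"]

#: semigeometric trail offsets of the five monitoring stations, as a fraction
#: of the 4 km reference landscape width (125, 250, 500, 1000, 2000 m there)
_STATION_FRACTIONS = (0.03125, 0.0625, 0.125, 0.25, 0.5)


def default_station_positions(width_m: float) -> tuple:
    return tuple(f * width_m for f in _STATION_FRACTIONS)


@dataclass
class SimulationConfig:
    """Every model input, named after the model's parameter vocabulary.

    Config files may use the dashed spellings (``ambient-level``,
    ``speed-limit-SD``, ``noise-affects-resources?``, ``basePercept``);
    unknown keys are rejected.
    """

    # --- environment
    ambient_level: float = 25.0  # dBA background
    temp_celsius: float = 20.0
    relative_humidity: float = 60.0  # %
    atm_pressure_bar: float = 1.01325
    ground_hardness: float = 0.5  # 0 porous .. 1 hard
    height_noiz: float = 0.5  # vehicle source height, m
    height_rcvr: float = 1.5  # ear height of searchers/humans/stations, m
    # --- traffic
    num_vehicles: float = 50.0  # target vehicles/hour (or count, see mode)
    speed_limit: float = 60.0  # kph
    speed_limit_sd: float = 10.0  # kph
    acceleration: float = 2.0  # m/s^2
    vpass_probability: float = 0.5
    excess_brake: float = 5.0  # kph
    veh_name: str = "sedan"
    # --- agents
    num_searchers: int = 10
    searcher_speed: float = 0.5  # m/s
    search_turn_sd: float = 30.0  # degrees
    base_percept: float = 50.0  # noiseless searcher detection radius, m
    human_mult: float = 2.0  # human/station radius multiplier
    meters_moved_per_resource: float = 50.0
    noise_affects_resources: bool = False
    calc_noise: bool = True
    # --- world/run structure
    nx: int = 400
    ny: int = 301
    cell_size: float = 10.0
    seed: int = 0
    dt: float = 1.0  # s
    station_positions: tuple | None = None
    band_fmin: float = 50.0
    band_fmax: float = 10000.0
    divergence: str = "source-ref"
    vehicle_count_mode: str = "per-hour"  # or "count"
    gamma_shape: float = 2.0
    num_resources: int | None = None  # overrides the spacing-derived count
    ticks: int | None = None  # overrides the five-traversal rule
    ticks_factor: float = 1.0  # scales the default run length
    n_distance_bins: int = 10

    _ALIASES = {
        "basePercept": "base_percept",
        "noise-affects-resources?": "noise_affects_resources",
        "speed-limit-SD": "speed_limit_sd",
    }

    def __post_init__(self) -> None:
        bad = []
        if not 0 <= self.relative_humidity <= 100:
            bad.append("relative_humidity")
        if self.atm_pressure_bar <= 0:
            bad.append("atm_pressure_bar")
        if not 0 <= self.ground_hardness <= 1:
            bad.append("ground_hardness")
        if self.height_noiz < 0 or self.height_rcvr < 0:
            bad.append("height_noiz/height_rcvr")
        if self.num_vehicles < 0:
            bad.append("num_vehicles")
        if self.speed_limit <= 0 or self.speed_limit_sd < 0:
            bad.append("speed_limit")
        if not 0 <= self.vpass_probability <= 1:
            bad.append("vpass_probability")
        if self.excess_brake < 0 or self.acceleration < 0:
            bad.append("excess_brake/acceleration")
        if self.veh_name not in fixtures.VEHICLE_TYPES:
            bad.append("veh_name")
        if self.num_searchers < 0 or self.searcher_speed <= 0:
            bad.append("num_searchers/searcher_speed")
        if self.search_turn_sd < 0 or self.base_percept <= 0 or self.human_mult <= 0:
            bad.append("search_turn_sd/base_percept/human_mult")
        if self.meters_moved_per_resource <= 0:
            bad.append("meters_moved_per_resource")
        if self.nx < 1 or self.ny < 1 or self.ny % 2 == 0 or self.cell_size <= 0:
            bad.append("nx/ny/cell_size")
        if self.dt <= 0 or self.ticks_factor <= 0:
            bad.append("dt/ticks_factor")
        if self.divergence not in ("source-ref", "iso"):
            bad.append("divergence")
        if self.vehicle_count_mode not in ("per-hour", "count"):
            bad.append("vehicle_count_mode")
        if bad:
            raise ValueError(f"invalid configuration values for: {', '.join(bad)}")

    # ---- construction from mappings / files -----------------------------

    @classmethod
    def _canonical_key(cls, key: str) -> str | None:
        if key in cls._ALIASES:
            return cls._ALIASES[key]
        k = key.rstrip("?").replace("-", "_")
        names = {f.name for f in dataclasses.fields(cls) if f.init}
        return k if k in names else None

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimulationConfig":
        out, unknown = {}, []
        for key, val in mapping.items():
            canon = cls._canonical_key(str(key))
            if canon is None:
                unknown.append(str(key))
            else:
                out[canon] = val
        if unknown:
            raise ValueError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
        if isinstance(out.get("station_positions"), list):
            out["station_positions"] = tuple(out["station_positions"])
        return cls(**out)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a flat key-value mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    # ---- derived quantities ---------------------------------------------

    def landscape(self) -> ls.Landscape:
        return ls.Landscape(self.nx, self.ny, self.cell_size, self.ambient_level)

    def n_ticks(self) -> int:
        """Run length: five loop traversals at the speed limit (scaled)."""
        if self.ticks is not None:
            return int(self.ticks)
        loop = self.landscape().road_loop()
        base = math.ceil(5.0 * loop.length / (tr.kph_to_mps(self.speed_limit) * self.dt))
        return max(1, math.ceil(base * self.ticks_factor))

    def vehicle_count(self) -> int:
        if self.vehicle_count_mode == "count":
            return int(round(self.num_vehicles))
        loop = self.landscape().road_loop()
        return tr.vehicle_count_for_vph(
            self.num_vehicles, loop, tr.kph_to_mps(self.speed_limit)
        )


@dataclass
class RunMetrics:
    """Everything a single run measures."""

    config: SimulationConfig
    n_ticks: int
    n_resources: int
    n_vehicles: int
    proportion_missed: float
    mean_exposure_dba: np.ndarray  # per searcher
    birdable_duration: np.ndarray  # per searcher, ticks audible from trail
    station_x: np.ndarray
    station_actual: np.ndarray
    station_counterfactual: np.ndarray
    realized_vph: float
    mean_vehicle_speed: float  # m/s
    noiseless_birdable_probability: float
    actual_birdable_probability: float
    mean_distance_per_detection: float
    distance_bin_edges: np.ndarray  # m from road
    bin_actual: np.ndarray  # actual first-contacts per distance bin
    bin_counterfactual: np.ndarray
    resource_visit_counts: np.ndarray
    resource_counterfactual_counts: np.ndarray  # cf first-contacts per resource
    resource_detected_counts: np.ndarray  # in-radius first-contacts per resource
    resource_cells: np.ndarray

    @property
    def detection_fraction_by_distance(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.bin_counterfactual > 0,
                self.bin_actual / np.maximum(self.bin_counterfactual, 1),
                np.nan,
            )

    def summary_row(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": [self.config.seed],
                "ambient_level": [self.config.ambient_level],
                "speed_limit": [self.config.speed_limit],
                "vpass_probability": [self.config.vpass_probability],
                "num_vehicles": [self.config.num_vehicles],
                "n_ticks": [self.n_ticks],
                "realized_vph": [self.realized_vph],
                "mean_vehicle_speed_mps": [self.mean_vehicle_speed],
                "proportion_missed": [self.proportion_missed],
                "mean_exposure_dba": [float(np.mean(self.mean_exposure_dba))
                                      if len(self.mean_exposure_dba) else np.nan],
                "mean_birdable_ticks": [float(np.mean(self.birdable_duration))
                                        if len(self.birdable_duration) else np.nan],
                "station_actual": [int(np.sum(self.station_actual))],
                "station_counterfactual": [int(np.sum(self.station_counterfactual))],
                "noiseless_birdable_probability": [self.noiseless_birdable_probability],
                "actual_birdable_probability": [self.actual_birdable_probability],
                "mean_distance_per_detection": [self.mean_distance_per_detection],
            }
        )

    def distance_table(self) -> pd.DataFrame:
        lo, hi = self.distance_bin_edges[:-1], self.distance_bin_edges[1:]
        return pd.DataFrame(
            {
                "distance_lo_m": lo,
                "distance_hi_m": hi,
                "actual": self.bin_actual,
                "counterfactual": self.bin_counterfactual,
                "fraction": self.detection_fraction_by_distance,
            }
        )


# --------------------------------------------------------------------------
# Propagation-table cache (rebuilding it per run would dominate runtime)
# --------------------------------------------------------------------------

_TABLE_CACHE: dict = {}


def propagation_table_for(config: SimulationConfig) -> ac.PropagationTable:
    key = (
        config.veh_name, config.band_fmin, config.band_fmax,
        config.temp_celsius, config.relative_humidity, config.atm_pressure_bar,
        config.ground_hardness, config.height_noiz, config.height_rcvr,
        config.divergence,
    )
    if key not in _TABLE_CACHE:
        laws = fixtures.vehicle_power_laws(config.veh_name, config.band_fmin, config.band_fmax)
        table = ac.build_propagation_table(
            laws,
            ac.AtmosphericConditions(
                config.temp_celsius, config.relative_humidity, config.atm_pressure_bar
            ),
            ac.GroundProfile(config.ground_hardness),
            ac.PropagationGeometry(config.height_noiz, config.height_rcvr, 1.0),
            divergence=config.divergence,
        )
        _TABLE_CACHE[key] = table
    return _TABLE_CACHE[key]


# --------------------------------------------------------------------------
# The run loop
# --------------------------------------------------------------------------


def run(config: SimulationConfig) -> RunMetrics:
    """Execute one simulation and return its metrics.

    Per tick: advance traffic; refresh receiver noise exposures and
    detection radii (when ``calc_noise``); step searchers (move, visit,
    scan); book trail audibility and station detections.  Same seed and
    config give bit-identical metrics.
    """
    world = config.landscape()
    loop = world.road_loop()
    ss = np.random.SeedSequence(config.seed)
    rng_traffic, rng_search, rng_place = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    params = tr.TrafficParams(
        num_vehicles=config.num_vehicles,
        speed_limit=config.speed_limit,
        speed_limit_sd=config.speed_limit_sd,
        acceleration=config.acceleration,
        vpass_probability=config.vpass_probability,
        excess_brake=config.excess_brake,
        gamma_shape=config.gamma_shape,
    )
    n_veh = config.vehicle_count()
    vehicles = tr.init_vehicles(n_veh, loop, params, rng_traffic, config.veh_name)

    use_noise = config.calc_noise and n_veh > 0
    table = propagation_table_for(config) if use_noise or config.noise_affects_resources else None
    ambient = config.ambient_level
    cutoff = table.max_distance_for_level(ambient - 16.0) if table is not None else None

    # resources
    if config.num_resources is not None:
        n_res = int(config.num_resources)
    else:
        n_res = ls.n_resources_for_spacing(
            config.meters_moved_per_resource, config.base_percept, world.area
        )
    if config.noise_affects_resources and n_veh > 0:
        spacing = loop.length / n_veh
        col = ls.column_exposure_levels(world, table, tr.kph_to_mps(config.speed_limit), spacing)
        weights = ls.noise_constrained_weights(world, col)
        resources = ls.place_resources(world, n_res, rng_place, "noise-constrained", weights)
    else:
        resources = ls.place_resources(world, n_res, rng_place, "random")

    searchers = ls.Searchers.init_random(
        world, config.num_searchers, config.searcher_speed, config.search_turn_sd,
        config.base_percept, n_res, rng_search,
    )

    human_radius = config.human_mult * config.base_percept
    station_x = np.asarray(
        config.station_positions
        if config.station_positions is not None
        else default_station_positions(world.width),
        dtype=float,
    )
    stations = [ls.Station(x) for x in station_x]
    station_pos = np.column_stack([station_x, np.zeros_like(station_x)])
    trail_x = world.trail_x_centers()

    n_ticks = config.n_ticks()
    dt = config.dt
    speed_sum = 0.0
    trail_radii_last = np.full(world.nx, human_radius)

    for t in range(n_ticks):
        tr.step_traffic(vehicles, loop, params, dt, rng_traffic, time_s=(t + 1) * dt)
        vy = loop.unwrapped_y(vehicles.positions)
        speed_sum += float(np.mean(vehicles.speeds)) if vehicles.n else 0.0

        if use_noise:
            levels = ls.searcher_noise_exposure(
                searchers.positions, vy, vehicles.speeds, table, ambient, cutoff
            )
            searchers.current_radius = ac.detection_radius(levels, config.base_percept, ambient)
        else:
            levels = np.full(searchers.n, ambient)
            searchers.current_radius = np.full(searchers.n, config.base_percept)
        searchers.exposure_sum += levels

        ls.step_searchers(searchers, resources, world, dt, rng_search)

        # trail audibility: only cells within reach of some searcher matter
        if searchers.n:
            if use_noise:
                near = np.abs(searchers.positions[:, 1]) <= human_radius
                cand = np.zeros(world.nx, dtype=bool)
                for x_s in searchers.positions[near, 0]:
                    lo, hi = world.cell_of(x_s - human_radius, 0)[0], world.cell_of(x_s + human_radius, 0)[0]
                    cand[lo : hi + 1] = True
                trail_radii = np.zeros(world.nx)
                if np.any(cand):
                    tpos = np.column_stack([trail_x[cand], np.zeros(int(cand.sum()))])
                    tlev = ls.searcher_noise_exposure(tpos, vy, vehicles.speeds, table, ambient, cutoff)
                    trail_radii[cand] = ac.detection_radius(tlev, human_radius, ambient)
            else:
                trail_radii = np.full(world.nx, human_radius)
            trail_radii_last = trail_radii
            audible = ls.trail_audibility(searchers.positions, trail_x, trail_radii)
            searchers.audible_ticks += audible

            if use_noise:
                slev = ls.searcher_noise_exposure(station_pos, vy, vehicles.speeds, table, ambient, cutoff)
                st_radii = ac.detection_radius(slev, human_radius, ambient)
            else:
                st_radii = np.full(len(stations), human_radius)
            ls.station_update(stations, searchers.positions, st_radii, human_radius)

    # --- final metrics ----------------------------------------------------
    duration = n_ticks * dt
    visited_any = searchers.visited.any(axis=0) if searchers.n else np.zeros(n_res, dtype=bool)
    prop_missed = 1.0 - float(np.count_nonzero(visited_any)) / n_res if n_res else float("nan")

    total_visits = int(searchers.visited.sum()) if searchers.n else 0
    total_dist = float(searchers.distance_traveled.sum()) if searchers.n else 0.0
    mean_dist_per_det = total_dist / total_visits if total_visits else float("nan")

    edges = np.linspace(0.0, world.width, config.n_distance_bins + 1)
    res_bin = np.clip(
        np.digitize(resources.positions[:, 0], edges) - 1, 0, config.n_distance_bins - 1
    )
    if searchers.n:
        act_per_res = searchers.detected.sum(axis=0)
        cf_per_res = searchers.counterfactual.sum(axis=0)
    else:
        act_per_res = cf_per_res = np.zeros(n_res)
    bin_actual = np.bincount(res_bin, weights=act_per_res, minlength=config.n_distance_bins)
    bin_cf = np.bincount(res_bin, weights=cf_per_res, minlength=config.n_distance_bins)

    # full-trail radii at the final tick for the actual birdable probability
    if use_noise:
        tpos = np.column_stack([trail_x, np.zeros(world.nx)])
        tlev = ls.searcher_noise_exposure(
            tpos, loop.unwrapped_y(vehicles.positions), vehicles.speeds, table, ambient, cutoff
        )
        full_trail_radii = ac.detection_radius(tlev, human_radius, ambient)
    else:
        full_trail_radii = np.full(world.nx, human_radius)

    return RunMetrics(
        config=config,
        n_ticks=n_ticks,
        n_resources=n_res,
        n_vehicles=n_veh,
        proportion_missed=prop_missed,
        mean_exposure_dba=searchers.exposure_sum / n_ticks if searchers.n else np.array([]),
        birdable_duration=searchers.audible_ticks.copy() if searchers.n else np.array([]),
        station_x=station_x,
        station_actual=np.array([s.actual for s in stations]),
        station_counterfactual=np.array([s.counterfactual for s in stations]),
        realized_vph=tr.realized_vph(vehicles.crossing_times, duration),
        mean_vehicle_speed=speed_sum / n_ticks if vehicles.n else float("nan"),
        noiseless_birdable_probability=ls.noiseless_birdable_probability(world, human_radius),
        actual_birdable_probability=ls.actual_birdable_probability(world, full_trail_radii),
        mean_distance_per_detection=mean_dist_per_det,
        distance_bin_edges=edges,
        bin_actual=bin_actual,
        bin_counterfactual=bin_cf,
        resource_visit_counts=resources.visit_counts.copy(),
        resource_counterfactual_counts=np.asarray(cf_per_res),
        resource_detected_counts=np.asarray(act_per_res),
        resource_cells=resources.cells.copy(),
    )
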