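"""Raster–network geosimulation of an individual patient's journey.

A patient agent placed on the accumulated travel-time surface "flows"
downhill: at every cycle it takes the downhill 16-neighbour move that
minimises remaining travel time plus the move's own traversal seconds (the
streamline of the surface, so a walking-only journey replays the surface
value at its start cell; pure smallest-neighbour-value descent is available
as an option), until it reaches a destination (a zero cell). With cars enabled,
car agents appear on the road network by a seeded Poisson process and drive
toward the destination along a road-constrained travel-time field; when the
patient — who keeps walking along the road rather than standing still — is
co-located with a car, it rides at road speed for the rest of the journey.
The run reports distance travelled, elapsed time and average speed, allowing
the purely raster travel-time estimate to be compared with travel under a
variable, random traffic flow.

Time is event-driven: each move costs its exact cell-pair seconds, so the
elapsed-time accounting does not depend on a tick length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid, check_coregistered
from .schema import IMPASSABLE_SECONDS, ROAD_CLASSES
from .travelcost import MOVES, DestinationSet, dijkstra_travel_time

__all__ = ["SimulationState", "SimulationResult", "init_simulation", "step", "run_simulation"]


@dataclass
class CarAgent:
    cell: tuple[int, int]
    progress_s: float = 0.0  # seconds already spent on the current move


@dataclass
class SimulationResult:
    arrived: bool
    elapsed_minutes: float
    distance_km: float
    average_speed_kmh: float
    pickup_occurred: bool
    pickup_cell: tuple[int, int] | None
    pickup_minutes: float | None
    trajectory: list[tuple[int, int]]


@dataclass
class SimulationState:
    tt: RasterGrid
    cost: RasterGrid
    walk_cost: np.ndarray  # patient's per-cell seconds while on foot
    road_tt: np.ndarray  # road-constrained travel time, inf off-road
    on_road: np.ndarray
    patient_cell: tuple[int, int]
    mode: str  # walking | riding | arrived
    elapsed_s: float = 0.0
    distance_m: float = 0.0
    path: list[tuple[int, int]] = field(default_factory=list)
    cars: list[CarAgent] = field(default_factory=list)
    traffic_intensity: float = 0.0  # expected car arrivals per minute
    use_cars: bool = False
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    descent: str = "least_cost"  # or "value": pure smallest-neighbour descent
    pickup_cell: tuple[int, int] | None = None
    pickup_s: float | None = None
    steps: int = 0

    @property
    def arrived(self) -> bool:
        return self.mode == "arrived"


def _neighbors(cell, shape):
    r, c = cell
    for dr, dc, d in MOVES:
        nr, nc = r + dr, c + dc
        if 0 <= nr < shape[0] and 0 <= nc < shape[1]:
            yield (nr, nc), d


def _descend_step(surface: np.ndarray, cost: np.ndarray, cell, cell_size, policy="least_cost"):
    """One downhill move on *surface* among the 16 neighbours.

    policy "least_cost" (default) picks the neighbour minimising
    ``surface[nb] + move_cost`` — the streamline of the accumulated-cost
    surface, so a walk from any cell replays its surface value exactly;
    policy "value" is pure smallest-neighbour-value descent. Either way the
    chosen neighbour's value must be strictly below the current one, or the
    surface violates the descent invariant. Returns (next_cell, seconds,
    metres).
    """
    cur = surface[cell]
    best = None
    best_key = np.inf
    for (nr, nc), d in _neighbors(cell, surface.shape):
        v = surface[nr, nc]
        if not (np.isfinite(v) and v < cur):
            continue
        seconds = d * 0.5 * (cost[cell] + cost[nr, nc])
        key = v if policy == "value" else v + seconds
        if key < best_key:
            best_key = key
            best = ((nr, nc), seconds, d * cell_size)
    if best is None:
        raise RuntimeError(
            f"no smaller neighbour at {cell}: travel-time surface violates "
            "the strict-descent invariant"
        )
    return best


def init_simulation(
    tt: RasterGrid,
    lc: RasterGrid,
    cost: RasterGrid,
    patient_cell: tuple[int, int],
    traffic_intensity: float = 0.0,
    use_cars: bool = False,
    seed: int = 0,
    descent: str = "least_cost",
    walk_on_road_kmh: float = 5.0,
) -> SimulationState:
    """Place the patient and prepare the car process (deterministic per seed).

    With cars disabled the journey replays the multi-modal cost surface
    (vehicle travel assumed available the moment a road is reached). With
    cars enabled that assumption is dropped: on road cells the patient moves
    on foot at *walk_on_road_kmh* until a car arrives. The road-constrained
    travel-time field that steers cars is computed here by the exact engine
    over road cells (destination cells included so routes terminate)."""
    check_coregistered(tt, lc, cost)
    if traffic_intensity < 0:
        raise ValueError("traffic_intensity must be >= 0")
    r, c = patient_cell
    v = tt.values[r, c]
    if not (0 <= v < IMPASSABLE_SECONDS):
        raise ValueError(
            f"patient cell {patient_cell} is unreachable on the travel-time surface"
        )
    on_road = np.isin(lc.values, list(ROAD_CLASSES))
    dest_cells = [tuple(int(i) for i in rc) for rc in zip(*np.nonzero(tt.values == 0))]
    road_tt = np.full(tt.shape, np.inf)
    if use_cars and on_road.any():
        road_cost_vals = np.where(on_road, cost.values, IMPASSABLE_SECONDS)
        for rc in dest_cells:
            road_cost_vals[rc] = min(cost.values[rc], 1.0)
        reachable_dests = [
            rc for rc in dest_cells if road_cost_vals[rc] < IMPASSABLE_SECONDS
        ]
        if reachable_dests:
            road_cost = cost.copy_with(road_cost_vals)
            dset = DestinationSet(points=[(0.0, 0.0)] * len(reachable_dests), cells=reachable_dests)
            road_tt = dijkstra_travel_time(road_cost, dset).values.astype(float)
            road_tt[road_tt >= IMPASSABLE_SECONDS] = np.inf
    walk_cost = cost.values.astype(float).copy()
    if use_cars:
        if walk_on_road_kmh <= 0:
            raise ValueError("walk_on_road_kmh must be > 0")
        foot_s = cost.cell_size / (walk_on_road_kmh * 1000.0 / 3600.0)
        walk_cost[on_road] = np.maximum(walk_cost[on_road], foot_s)
    state = SimulationState(
        tt=tt,
        cost=cost,
        walk_cost=walk_cost,
        road_tt=road_tt,
        on_road=on_road,
        patient_cell=(r, c),
        mode="arrived" if v == 0 else "walking",
        traffic_intensity=float(traffic_intensity),
        use_cars=bool(use_cars),
        rng=np.random.default_rng(seed),
        descent=descent,
    )
    state.path.append((r, c))
    return state


def _spawn_cells(state: SimulationState) -> list[tuple[int, int]]:
    """Road cells where new cars can appear: the reachable road network."""
    rows, cols = np.nonzero(np.isfinite(state.road_tt) & state.on_road)
    return list(zip(rows.tolist(), cols.tolist()))


def _advance_car(state: SimulationState, car: CarAgent, dt: float) -> list[tuple[int, int]]:
    """Drive a car downhill on the road travel-time field for dt seconds;
    returns every cell the car occupied during the interval."""
    visited = [car.cell]
    cost = state.cost.values
    while dt > 0:
        if state.road_tt[car.cell] == 0:  # at destination: parks
            break
        try:
            nxt, seconds, _ = _descend_step(
                state.road_tt, cost, car.cell, state.cost.cell_size
            )
        except RuntimeError:
            break
        remaining = seconds - car.progress_s
        if dt >= remaining:
            dt -= remaining
            car.cell = nxt
            car.progress_s = 0.0
            visited.append(nxt)
        else:
            car.progress_s += dt
            dt = 0.0
    return visited


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one patient move (mutates and returns state)."""
    if state.arrived:
        raise RuntimeError("simulation already arrived")
    riding = state.mode == "riding"
    surface = state.road_tt if riding else state.tt.values
    surface = np.where(np.isfinite(surface) & (surface < IMPASSABLE_SECONDS), surface, np.inf)
    move_cost = state.cost.values if riding else state.walk_cost
    nxt, seconds, metres = _descend_step(
        surface, move_cost, state.patient_cell, state.cost.cell_size,
        policy=state.descent,
    )
    state.patient_cell = nxt
    state.elapsed_s += seconds
    state.distance_m += metres
    state.path.append(nxt)
    state.steps += 1

    if state.use_cars and state.mode == "walking":
        _update_cars(state, seconds)

    if state.tt.values[state.patient_cell] == 0:
        state.mode = "arrived"
    return state


def _update_cars(state: SimulationState, dt: float) -> None:
    # advance existing cars; collect the cells each swept through
    pickup = None
    for car in state.cars:
        swept = _advance_car(state, car, dt)
        if state.on_road[state.patient_cell] and state.patient_cell in swept:
            pickup = car
            break
    # new cars: seeded Poisson arrivals at rate traffic_intensity per minute
    if pickup is None and state.traffic_intensity > 0:
        spawn = _spawn_cells(state)
        if spawn:
            n_new = state.rng.poisson(state.traffic_intensity * dt / 60.0)
            for _ in range(int(n_new)):
                idx = int(state.rng.integers(len(spawn)))
                car = CarAgent(cell=spawn[idx])
                state.cars.append(car)
                if state.on_road[state.patient_cell] and car.cell == state.patient_cell:
                    pickup = car
                    break
    if pickup is not None and np.isfinite(state.road_tt[state.patient_cell]):
        state.mode = "riding"
        state.pickup_cell = state.patient_cell
        state.pickup_s = state.elapsed_s


def run_simulation(state: SimulationState, max_minutes: float) -> SimulationResult:
    """Step until arrival or time-out; a time-out is a result, not an error."""
    if max_minutes <= 0:
        raise ValueError("max_minutes must be > 0")
    max_steps = int(np.isfinite(state.tt.values).sum()) + state.tt.values.size
    while not state.arrived and state.elapsed_s < max_minutes * 60.0:
        if state.steps >= max_steps:
            break
        step(state)
    elapsed_min = state.elapsed_s / 60.0
    dist_km = state.distance_m / 1000.0
    speed = dist_km / (elapsed_min / 60.0) if elapsed_min > 0 else 0.0
    return SimulationResult(
        arrived=state.arrived,
        elapsed_minutes=elapsed_min,
        distance_km=dist_km,
        average_speed_kmh=speed,
        pickup_occurred=state.pickup_cell is not None,
        pickup_cell=state.pickup_cell,
        pickup_minutes=None if state.pickup_s is None else state.pickup_s / 60.0,
        trajectory=list(state.path),
    )
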