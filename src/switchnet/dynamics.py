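"""Deterministic and stochastic simulation, and trajectory-level analyses.

Deterministic time courses come from stiff-capable adaptive integration of
the mass-action vector field; stochastic runs use the exact Gillespie direct
method with the distinct-pair propensity convention.  On top of these sit
the analyses used throughout the package: consensus statistics of
population-protocol runs, sustained-oscillation detection, counting of
degenerate (overlapping) trajectory classes, and quasi-static input sweeps
for hysteresis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .crn import ReactionNetwork
from .influence import InfluenceNetwork, expand, initial_state

__all__ = [
    "Trajectory",
    "SSATrace",
    "ConsensusSummary",
    "OscillationVerdict",
    "ScanPoint",
    "simulate_ode",
    "simulate_ssa",
    "consensus_stats",
    "detect_oscillation",
    "count_distinct_traces",
    "scan_input",
    "relax_to_steady_state",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails to produce a solution."""


@dataclass
class Trajectory:
    """Deterministic time course on a uniform grid (time × species)."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_species)
    species: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, len(self.species)):
            raise ValueError("values shape inconsistent with times/species")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < -1e-9):
            raise ValueError("negative concentrations beyond tolerance")
        self.values = np.clip(self.values, 0.0, None)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.values[-1].copy()


@dataclass
class SSATrace:
    """Exact stochastic event trace: jump times, reaction indices, states."""

    times: np.ndarray  # event times, t[0] == 0
    reaction_indices: np.ndarray  # length len(times) - 1
    states: np.ndarray  # integer states, shape (len(times), n_species)
    species: list[str]
    seed: int
    absorbed: bool  # True iff no reaction is enabled in the final state

    @property
    def n_events(self) -> int:
        return int(self.reaction_indices.size)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-constant state sampled at query times."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.times) - 1)]


@dataclass
class ConsensusSummary:
    """Replicate statistics of stochastic protocol runs."""

    replicates: int
    frac_x_wins: float
    frac_y_wins: float
    n_unabsorbed: int
    mean_events: float
    median_events: float
    parallel_time: float  # mean events / population size


@dataclass
class OscillationVerdict:
    sustained: bool
    period: float | None
    amplitude: float | None
    n_peaks_analyzed: int


@dataclass
class ScanPoint:
    input_value: float
    state: dict[str, float]
    converged: bool
    residual: float


# ---------------------------------------------------------------------------
# Deterministic integration
# ---------------------------------------------------------------------------


def simulate_ode(
    net: ReactionNetwork,
    init,
    t_end: float,
    rel_tol: float = 1e-9,
    n_out: int = 500,
    t_start: float = 0.0,
) -> Trajectory:
    """Integrate the mass-action ODEs on a uniform output grid.

    Uses LSODA (switches to BDF on stiffness) with ``rtol=rel_tol`` and a
    tight absolute tolerance so that the conserved per-node totals hold to
    better than 1e-6 relative along the trajectory.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    x0 = net.state_vector(init)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    t_eval = np.linspace(t_start, t_end, n_out)

    def rhs(_t, x):
        return net.vector_field(np.clip(x, 0.0, None))

    sol = solve_ivp(
        rhs,
        (t_start, t_end),
        x0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rel_tol,
        atol=rel_tol * 1e-3,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return Trajectory(times=sol.t, values=sol.y.T, species=net.species_names)


def relax_to_steady_state(
    net: ReactionNetwork,
    init,
    f_tol: float = 1e-9,
    t_max: float = 1e4,
    chunk: float = 50.0,
    rel_tol: float = 1e-9,
) -> tuple[np.ndarray, bool, float]:
    """Integrate until ‖vector_field‖∞ < f_tol or t_max is reached.

    Returns (state, converged flag, final residual).
    """
    x = net.state_vector(init)
    t = 0.0
    resid = float(np.max(np.abs(net.vector_field(x))))
    while resid >= f_tol and t < t_max:
        traj = simulate_ode(net, x, t_end=chunk, rel_tol=rel_tol, n_out=2)
        x = traj.final_state
        t += chunk
        resid = float(np.max(np.abs(net.vector_field(x))))
    return x, resid < f_tol, resid


# ---------------------------------------------------------------------------
# Stochastic simulation (Gillespie direct method)
# ---------------------------------------------------------------------------


def _ssa_propensities(net: ReactionNetwork, counts: np.ndarray) -> np.ndarray:
    """Distinct-pair combinatorics: n·(n−1) for two identical reactants."""
    props = np.empty(len(net.reactions))
    for j, r in enumerate(net.reactions):
        a = r.rate
        if len(r.reactants) == 1:
            a *= counts[net.index[r.reactants[0]]]
        elif len(r.reactants) == 2:
            i1, i2 = (net.index[q] for q in r.reactants)
            if i1 == i2:
                a *= counts[i1] * (counts[i1] - 1)
            else:
                a *= counts[i1] * counts[i2]
        props[j] = a
    return props


def simulate_ssa(
    net: ReactionNetwork,
    counts,
    seed: int,
    max_events: int = 1_000_000,
) -> SSATrace:
    """Exact stochastic simulation (Gillespie direct method).

    Runs until an absorbing state (all propensities zero) or *max_events*;
    an unabsorbed partial trace is returned with ``absorbed=False``.
    Clamped species counts never change.  Fully reproducible given *seed*.
    """
    x = np.asarray(net.state_vector(counts), dtype=np.int64)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative integers")
    rng = np.random.default_rng(seed)

    n_s = len(net.species)
    clamped = np.array([s.clamped for s in net.species], dtype=bool)
    deltas = np.zeros((len(net.reactions), n_s), dtype=np.int64)
    for j, r in enumerate(net.reactions):
        for q in r.species:
            deltas[j, net.index[q]] = r.net_stoichiometry(q)
    deltas[:, clamped] = 0

    times = [0.0]
    events: list[int] = []
    states = [x.copy()]
    t = 0.0
    for _ in range(max_events):
        props = _ssa_propensities(net, x)
        total = props.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        j = int(rng.choice(len(props), p=props / total))
        x = x + deltas[j]
        times.append(t)
        events.append(j)
        states.append(x.copy())
    absorbed = _ssa_propensities(net, x).sum() <= 0
    return SSATrace(
        times=np.array(times),
        reaction_indices=np.array(events, dtype=int),
        states=np.array(states),
        species=net.species_names,
        seed=seed,
        absorbed=absorbed,
    )


def consensus_stats(
    net: ReactionNetwork,
    counts,
    replicates: int,
    seed: int,
    x_species: str = "X",
    y_species: str = "Y",
    max_events: int = 1_000_000,
) -> ConsensusSummary:
    """Replicate SSA runs of a two-decision protocol, aggregated.

    A run is an X (resp. Y) win when it absorbs with the opposing decided
    species extinct.  Replicate seeds are spawned deterministically from
    *seed* so individual runs are independently reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    x_wins = y_wins = unabsorbed = 0
    events = []
    population = int(np.sum(net.state_vector(counts)))
    for i in range(replicates):
        trace = simulate_ssa(net, counts, seed=int(child_seeds[i]), max_events=max_events)
        if not trace.absorbed:
            unabsorbed += 1
            continue
        final = trace.final_state
        events.append(trace.n_events)
        if final[net.index[y_species]] == 0 and final[net.index[x_species]] > 0:
            x_wins += 1
        elif final[net.index[x_species]] == 0 and final[net.index[y_species]] > 0:
            y_wins += 1
    done = x_wins + y_wins
    return ConsensusSummary(
        replicates=replicates,
        frac_x_wins=x_wins / done if done else 0.0,
        frac_y_wins=y_wins / done if done else 0.0,
        n_unabsorbed=unabsorbed,
        mean_events=float(np.mean(events)) if events else 0.0,
        median_events=float(np.median(events)) if events else 0.0,
        parallel_time=(float(np.mean(events)) / population) if events and population else 0.0,
    )


# ---------------------------------------------------------------------------
# Trajectory analyses
# ---------------------------------------------------------------------------


def detect_oscillation(
    traj: Trajectory,
    species: str,
    settle_frac: float = 0.5,
    peak_tol: float = 0.10,
    min_peaks: int = 4,
) -> OscillationVerdict:
    """Classify a trace as sustained oscillation or not.

    The first *settle_frac* of the trace is discarded as transient.  The
    remainder must contain at least *min_peaks* maxima whose amplitudes and
    inter-peak intervals each vary by less than *peak_tol* (relative spread)
    to count as a sustained (limit-cycle-like) oscillation.  Period is the
    mean inter-peak interval; amplitude the mean peak-to-trough difference.
    """
    if traj.times.size < 10:
        raise ValueError("trajectory too short for oscillation analysis")
    if not 0 <= settle_frac < 1:
        raise ValueError("settle_frac must be in [0, 1)")
    y_full = traj[species]
    start = int(settle_frac * traj.times.size)
    t, y = traj.times[start:], y_full[start:]

    span = float(np.max(y) - np.min(y))
    if span <= 1e-9:
        return OscillationVerdict(False, None, None, 0)
    prominence = 0.05 * span
    peaks, _ = find_peaks(y, prominence=prominence)
    troughs, _ = find_peaks(-y, prominence=prominence)
    if peaks.size < min_peaks or troughs.size < 1:
        return OscillationVerdict(False, None, None, int(peaks.size))

    heights = y[peaks]
    intervals = np.diff(t[peaks])
    amp = float(np.mean(heights) - np.mean(y[troughs]))

    def spread(v: np.ndarray, scale: float) -> float:
        return float(np.max(v) - np.min(v)) / scale if scale > 0 else np.inf

    # height spread is judged against the amplitude, not the mean level:
    # a decaying ripple on a large offset must not count as sustained
    sustained = (
        amp > 1e-6
        and spread(heights, amp) < peak_tol
        and spread(intervals, float(np.mean(intervals))) < peak_tol
    )
    return OscillationVerdict(
        sustained=sustained,
        period=float(np.mean(intervals)) if sustained else None,
        amplitude=amp if sustained else None,
        n_peaks_analyzed=int(peaks.size),
    )


def count_distinct_traces(
    traj: Trajectory, tol: float = 1e-6
) -> tuple[int, list[list[str]]]:
    """Partition species whose traces overlap (sup-norm < tol).

    Closeness is closed transitively, so the classes are the connected
    components of the "overlaps" relation.  Returns (count, classes) with
    classes sorted by first species name.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    names = traj.species
    n = len(names)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.max(np.abs(traj.values[:, i] - traj.values[:, j])) < tol:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        groups.setdefault(find(i), []).append(name)
    classes = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
    return len(classes), classes


def scan_input(
    inet: InfluenceNetwork,
    clamped_name: str,
    values,
    direction: str = "up",
    f_tol: float = 1e-9,
    t_max: float = 2000.0,
    init_overrides: dict | None = None,
) -> list[ScanPoint]:
    """Quasi-static sweep of a clamped input, tracking one steady branch.

    The first point relaxes from the network's default initial state; each
    later point starts from the previous steady state, so up- and down-sweeps
    follow their own branch and may disagree over a bistable window
    (hysteresis).  ``direction`` only orients the sweep: values are sorted
    ascending for "up" and descending for "down".
    """
    if clamped_name not in inet.clamped_names:
        raise ValueError(f"{clamped_name!r} is not a clamped species of the network")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    values = sorted(values, reverse=(direction == "down"))
    points: list[ScanPoint] = []
    net = expand(inet)
    state = net.state_vector(initial_state(inet, overrides=init_overrides))
    clamp_idx = net.index[clamped_name]
    for v in values:
        state = state.copy()
        state[clamp_idx] = float(v)
        state, ok, resid = relax_to_steady_state(net, state, f_tol=f_tol, t_max=t_max)
        points.append(
            ScanPoint(
                input_value=float(v),
                state=dict(zip(net.species_names, map(float, state))),
                converged=ok,
                residual=resid,
            )
        )
    return points
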