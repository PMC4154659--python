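"""Exact SSA and the synchronised (vectorised) tau-leap engine.

A metapopulation of omega niche lineages is held as a single integer
state matrix (species x lineages) and advanced synchronously: at each
step the propensities of every lineage are computed, the lineage with
the largest total propensity — the one with the most frequent
transitions, hence the bottleneck — donates its propensity vector to
the adaptive step-size rule, and every lineage is then advanced over
the same step by Poisson transition counts.  Sharing one step keeps
all lineages at the same simulation time, which is what makes coupled
feedback fields well defined; an exact SSA, whose lineages each jump
at their own random times, is offered for uncoupled runs only.

The step-size rule bounds the expected change and the standard
deviation of the change of each species over one step by
``max(epsilon * x_i, 1)``; every transition here is first order in its
reactant, so the highest-order factor g_i is 1 for all species.  If a
Poisson draw would make any count negative (or push a stem-cell count
above the niche capacity, which the logistic propensity alone cannot
prevent across a finite leap), the whole step is redone with tau/2 and
fresh draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coupling import NicheGrouping, broadcast_feedbacks
from .model import (
    SPECIES,
    HSCParameters,
    FeedbackSignals,
    build_transition_table,
    eval_propensities,
)
from .perturbation import PerturbationSpec, RemovalReport, apply_perturbation

__all__ = [
    "LeapControl",
    "HSCSystem",
    "RunResult",
    "LeapFailure",
    "UnsupportedConfigurationError",
    "make_grid",
    "select_tau",
    "leap_step",
    "ssa_step",
    "simulate",
    "simulate_ssa",
]

_TIME_EPS = 1e-9


class UnsupportedConfigurationError(ValueError):
    """Raised for configurations the requested engine cannot honour."""


class LeapFailure(RuntimeError):
    """A leap step could not be accepted within the halving budget."""

    def __init__(self, message, t, tau, counts):
        super().__init__(message)
        self.t = t
        self.tau = tau
        self.counts = counts


@dataclass(frozen=True)
class LeapControl:
    """Error control of the tau-leap.

    epsilon bounds the relative change of each population per step
    (common values are of order 0.01; smaller is more accurate),
    tau_min is a floor preventing pathological stalls, max_halvings
    caps the negativity redos of a single step.
    """

    epsilon: float = 0.03
    tau_min: float = 1e-6
    max_halvings: int = 30
    per_transition_max: bool = False  # tighter, off-by-default step bound

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.max_halvings < 1:
            raise ValueError("max_halvings must be >= 1")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be > 0")


class HSCSystem:
    """The niche-lineage transition system over a whole state matrix.

    Couples the model's propensities to the niche-group feedback
    broadcast; with a trivial grouping each lineage feeds back on
    itself.
    """

    def __init__(self, params: HSCParameters, grouping: NicheGrouping):
        self.params = params
        self.grouping = grouping
        self.table = build_transition_table(params)
        self.stoich = self.table.stoich
        self.species = SPECIES

    def signals(self, counts: np.ndarray) -> FeedbackSignals:
        return broadcast_feedbacks(counts, self.grouping, self.params)

    def propensities(self, counts: np.ndarray) -> np.ndarray:
        return eval_propensities(counts, self.signals(counts), self.table)

    def state_ok(self, counts: np.ndarray) -> bool:
        # a finite leap can overshoot the carrying capacity even though
        # the logistic propensity vanishes at S = K; treat it like a
        # negative count and redo the step
        return bool(counts[0].max(initial=0) <= self.params.K)

    def founding_state(self, n_lineages: int | None = None) -> np.ndarray:
        """One stem cell and no other cells, per lineage."""
        omega = self.grouping.n_lineages if n_lineages is None else n_lineages
        counts = np.zeros((len(SPECIES), omega), dtype=np.int64)
        counts[0] = 1
        return counts


@dataclass
class RunResult:
    """Recorded trajectories plus provenance of one simulation run."""

    times: np.ndarray                     # (T,)
    counts: np.ndarray                    # (T, n_species, omega) int64
    species: tuple[str, ...]
    seed: int
    engine: str
    grouping: NicheGrouping | None = None
    signals: np.ndarray | None = None     # (T, 4, omega): h1, h2, h3, p
    removals: list[RemovalReport] = field(default_factory=list)
    n_steps: int = 0
    n_halvings: int = 0
    tau_summary: dict = field(default_factory=dict)
    limiting_counts: np.ndarray | None = None  # how often each lineage set tau

    @property
    def n_lineages(self) -> int:
        return self.counts.shape[2]

    def at(self, t: float) -> np.ndarray:
        """State matrix recorded at time t (exact match required)."""
        idx = np.nonzero(np.isclose(self.times, t, rtol=0.0, atol=1e-9))[0]
        if idx.size == 0:
            near = self.times[np.argsort(np.abs(self.times - t))[:2]]
            raise KeyError(f"time {t} not recorded; nearest recorded times: {sorted(near)}")
        return self.counts[idx[0]]

    def ensemble_mean(self, species: str) -> np.ndarray:
        """Mean count of one species over lineages, per recorded time."""
        return self.counts[:, self.species.index(species), :].mean(axis=1)

    def to_dataframe(self):
        """Tidy records: one row per (time, lineage)."""
        import pandas as pd

        T, S, omega = self.counts.shape
        group = (
            self.grouping.group_of
            if self.grouping is not None
            else np.arange(omega)
        )
        data = {
            "time": np.repeat(self.times, omega),
            "lineage": np.tile(np.arange(omega), T),
            "group": np.tile(group, T),
        }
        for i, name in enumerate(self.species):
            data[name] = self.counts[:, i, :].ravel()
        if self.signals is not None:
            for i, name in enumerate(("h1", "h2", "h3", "p")):
                data[name] = self.signals[:, i, :].ravel()
        return pd.DataFrame(data)


def make_grid(
    t_end: float,
    dt: float,
    dense_window: tuple[float, float] | None = None,
    dense_dt: float | None = None,
) -> np.ndarray:
    """Strictly increasing record times on [0, t_end].

    A base spacing of ``dt``, optionally refined to ``dense_dt`` inside
    ``dense_window`` (used to sample the period around a perturbation
    more often).
    """
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")
    times = np.arange(0.0, t_end + dt / 2, dt)
    if dense_window is not None:
        if dense_dt is None or dense_dt <= 0:
            raise ValueError("dense_window requires a positive dense_dt")
        lo, hi = dense_window
        if not (0 <= lo < hi <= t_end):
            raise ValueError("dense_window must lie inside [0, t_end]")
        dense = np.arange(lo, hi + dense_dt / 2, dense_dt)
        times = np.unique(np.concatenate([times, dense, [t_end]]))
    else:
        times = np.unique(np.concatenate([times, [t_end]]))
    return times


def select_tau(
    propensities: np.ndarray,
    counts: np.ndarray,
    stoich: np.ndarray,
    epsilon: float,
) -> float:
    """Adaptive step from one lineage's propensity vector.

    tau = min over species i of
          min( max(eps*x_i, 1)/|mu_i| , max(eps*x_i, 1)^2/sigma2_i )
    with mu_i = sum_j nu_ij a_j and sigma2_i = sum_j nu_ij^2 a_j,
    skipping species with mu_i = sigma2_i = 0.  Returns +inf when all
    propensities vanish (the caller jumps to the next scheduled time).
    All transitions are first order in their reactant, so the
    highest-order scaling factor is 1 for every species.
    """
    a = np.asarray(propensities, dtype=float)
    if a.sum() <= 0.0:
        return np.inf
    nu = stoich
    mu = nu @ a
    sig2 = (nu * nu) @ a
    bound = np.maximum(epsilon * np.asarray(counts, dtype=float), 1.0)
    with np.errstate(divide="ignore"):
        t_mu = np.where(mu != 0.0, bound / np.abs(mu), np.inf)
        t_sig = np.where(sig2 > 0.0, bound * bound / sig2, np.inf)
    return float(np.minimum(t_mu, t_sig).min())


def _candidate_tau(system, props, counts, control: LeapControl) -> tuple[float, int]:
    """Common step from the bottleneck lineage (or tighter variant)."""
    a0 = props.sum(axis=0)
    k = int(np.argmax(a0))
    if control.per_transition_max:
        # per-transition maxima across lineages with the most
        # conservative per-species bound; tighter than the single
        # bottleneck lineage
        synth = props.max(axis=1)
        x = counts.min(axis=1)
        return select_tau(synth, x, system.stoich, control.epsilon), k
    return select_tau(props[:, k], counts[:, k], system.stoich, control.epsilon), k


def leap_step(
    system,
    counts: np.ndarray,
    control: LeapControl,
    rng: np.random.Generator,
    tau_cap: float = np.inf,
    t: float = 0.0,
):
    """One synchronised tau-leap over the whole state matrix.

    Selects the common step from the lineage with the highest total
    propensity (capped at ``tau_cap``, the distance to the next
    scheduled event), draws independent Poisson transition counts for
    every lineage, and redoes the whole step with tau/2 and fresh draws
    if any count would go negative or violate a state invariant.

    Returns ``(new_counts, tau_used, n_halvings)``; ``tau_used`` is
    +inf when all propensities vanish (absorbing metapopulation, counts
    returned unchanged).
    """
    props = system.propensities(counts)
    tau, _k = _candidate_tau(system, props, counts, control)
    if np.isinf(tau):
        return counts, np.inf, 0
    tau = min(tau, tau_cap)
    if tau < control.tau_min:
        warnings.warn("tau fell below tau_min; flooring", RuntimeWarning, stacklevel=2)
        tau = min(control.tau_min, tau_cap)
    halvings = 0
    while True:
        draws = rng.poisson(props * tau)
        new = counts + system.stoich @ draws
        if new.min() >= 0 and system.state_ok(new):
            return new, tau, halvings
        if halvings >= control.max_halvings:
            bad = int(np.nonzero(new.min(axis=0) < 0)[0][0]) if new.min() < 0 else -1
            raise LeapFailure(
                f"leap not accepted after {halvings} halvings "
                f"(t={t:.6g}, tau={tau:.3g}, lineage {bad})",
                t=t,
                tau=tau,
                counts=counts,
            )
        tau /= 2.0
        halvings += 1


def simulate(
    system,
    initial: np.ndarray,
    grid: np.ndarray,
    seed: int,
    control: LeapControl | None = None,
    perturbations: Sequence[PerturbationSpec] = (),
    record_signals: bool = True,
) -> RunResult:
    """Advance a metapopulation synchronously with the vectorised tau-leap.

    States are recorded at the grid times; scheduled perturbations are
    applied exactly at their times (the step is truncated so no leap
    straddles a record or perturbation time; a perturbation coinciding
    with a record time is applied first, so the recorded counts reflect
    the removal).
    """
    control = control or LeapControl()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a non-empty strictly increasing 1-d array")
    t_end = grid[-1]
    perts = sorted(perturbations, key=lambda s: s.time)
    for s in perts:
        if not 0.0 <= s.time <= t_end:
            raise ValueError(f"perturbation time {s.time} outside [0, {t_end}]")

    counts = np.array(initial, dtype=np.int64, copy=True)
    if counts.ndim != 2 or counts.shape[0] != system.stoich.shape[0]:
        raise ValueError("initial state must be a (n_species, omega) matrix")
    if counts.min() < 0:
        raise ValueError("initial counts must be non-negative")

    omega = counts.shape[1]
    n_rec = grid.size
    rec_counts = np.empty((n_rec, counts.shape[0], omega), dtype=np.int64)
    rec_signals = np.empty((n_rec, 4, omega)) if record_signals else None
    removals: list[RemovalReport] = []
    rng = np.random.Generator(np.random.PCG64(seed))
    pert_rngs = [
        np.random.Generator(
            np.random.PCG64(s.seed if s.seed is not None else (seed * 1000003 + 7 * i + 1) % (2**31 - 1))
        )
        for i, s in enumerate(perts)
    ]

    def _record(i: int) -> None:
        rec_counts[i] = counts
        if record_signals:
            sig = system.signals(counts)
            if sig is None:
                rec_signals[i] = 0.0
            else:
                rec_signals[i] = np.broadcast_to(
                    np.vstack([np.broadcast_to(np.asarray(v, float), (omega,)) for v in (sig.h1, sig.h2, sig.h3, sig.p)]),
                    (4, omega),
                )

    t = 0.0
    gi = 0
    pi = 0
    if grid[0] <= _TIME_EPS:
        _record(0)
        gi = 1
    n_steps = 0
    n_halvings = 0
    tau_sum, tau_min_seen, tau_max_seen, n_tau = 0.0, np.inf, 0.0, 0
    limiting = np.zeros(omega, dtype=np.int64)

    while True:
        next_rec = grid[gi] if gi < n_rec else np.inf
        next_pert = perts[pi].time if pi < len(perts) else np.inf
        next_event = min(next_rec, next_pert)
        if np.isinf(next_event):
            break

        gap = next_event - t
        props = system.propensities(counts)
        tau, k = _candidate_tau(system, props, counts, control)
        if np.isinf(tau):
            t = next_event  # absorbing metapopulation: jump to the event
        else:
            tau = min(tau, gap)
            if tau < control.tau_min:
                tau = min(control.tau_min, gap)
            hit = tau >= gap - _TIME_EPS
            halvings = 0
            while True:
                draws = rng.poisson(props * tau)
                new = counts + system.stoich @ draws
                if new.min() >= 0 and system.state_ok(new):
                    break
                if halvings >= control.max_halvings:
                    raise LeapFailure(
                        f"leap not accepted after {halvings} halvings at t={t:.6g}",
                        t=t,
                        tau=tau,
                        counts=counts,
                    )
                tau /= 2.0
                hit = False
                halvings += 1
            counts = new
            t = next_event if hit else t + tau
            n_steps += 1
            n_halvings += halvings
            limiting[k] += 1
            tau_sum += tau
            n_tau += 1
            tau_min_seen = min(tau_min_seen, tau)
            tau_max_seen = max(tau_max_seen, tau)

        # handle any events reached at this time
        while pi < len(perts) and perts[pi].time <= t + _TIME_EPS:
            counts, report = apply_perturbation(counts, perts[pi], pert_rngs[pi])
            removals.append(report)
            pi += 1
        while gi < n_rec and grid[gi] <= t + _TIME_EPS:
            _record(gi)
            gi += 1

    return RunResult(
        times=grid,
        counts=rec_counts,
        species=tuple(getattr(system, "species", tuple(f"x{i}" for i in range(counts.shape[0])))),
        seed=seed,
        engine="tau-leap",
        grouping=getattr(system, "grouping", None),
        signals=rec_signals,
        removals=removals,
        n_steps=n_steps,
        n_halvings=n_halvings,
        tau_summary={
            "mean": tau_sum / n_tau if n_tau else np.nan,
            "min": tau_min_seen if n_tau else np.nan,
            "max": tau_max_seen if n_tau else np.nan,
            "n": n_tau,
        },
        limiting_counts=limiting,
    )


def ssa_step(system, state: np.ndarray, rng: np.random.Generator):
    """One exact SSA event for a single lineage.

    Returns ``(waiting_time, transition_index, new_state)``; a state
    with zero total propensity is absorbing and is signalled by
    ``(inf, None, state)``.
    """
    a = system.propensities(state.reshape(-1, 1))[:, 0]
    a0 = a.sum()
    if a0 <= 0.0:
        return np.inf, None, state
    dt = rng.exponential(1.0 / a0)
    j = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
    return dt, j, state + system.stoich[:, j]


def simulate_ssa(
    system,
    initial: np.ndarray,
    grid: np.ndarray,
    seed: int,
    record_signals: bool = False,
) -> RunResult:
    """Exact, per-lineage SSA for uncoupled metapopulations.

    Each lineage is evolved independently and exactly; recorded states
    are the values immediately before each grid time.  Coupled niche
    groups are refused: SSA lineages advance at their own random
    times, so a shared feedback field would effectively average the
    interactions over time instead of evaluating them synchronously.
    """
    grouping = getattr(system, "grouping", None)
    if grouping is not None and not grouping.trivial:
        raise UnsupportedConfigurationError(
            "exact SSA supports uncoupled lineages only (group size 1): "
            "per-lineage waiting times are asynchronous, so pooled feedback "
            "signals would be evaluated at inconsistent times"
        )
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a non-empty strictly increasing 1-d array")

    counts = np.array(initial, dtype=np.int64, copy=True)
    if counts.min() < 0:
        raise ValueError("initial counts must be non-negative")
    n_species, omega = counts.shape
    rec = np.empty((grid.size, n_species, omega), dtype=np.int64)
    rng = np.random.Generator(np.random.PCG64(seed))
    t_end = grid[-1]
    stoich = system.stoich

    for lineage in range(omega):
        state = counts[:, lineage].copy()
        t = 0.0
        gi = 0
        while gi < grid.size:
            a = system.propensities(state.reshape(-1, 1))[:, 0]
            a0 = a.sum()
            if a0 <= 0.0:
                rec[gi:, :, lineage] = state[:, None].T  # absorbing
                break
            t_next = t + rng.exponential(1.0 / a0)
            while gi < grid.size and grid[gi] <= t_next:
                rec[gi, :, lineage] = state
                gi += 1
            if t_next > t_end:
                break
            j = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
            state += stoich[:, j]
            t = t_next

    result = RunResult(
        times=grid,
        counts=rec,
        species=tuple(getattr(system, "species", tuple(f"x{i}" for i in range(n_species)))),
        seed=seed,
        engine="ssa",
        grouping=grouping,
        signals=None,
    )
    return result
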