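"""Haematopoietic stem-cell niche-lineage model.

Six cell species per niche lineage — stem cells (S), multipotent
progenitors (MPP), common lymphoid/myeloid progenitors (CLP, CMP) and
fully differentiated lymphoid/myeloid blood cells (L, M) — connected by
fourteen stochastic transitions: S self-renewal (symmetric and
asymmetric), S symmetric differentiation, MPP renewal and commitment to
either progenitor route, progenitor maturation into blood cells, and
death of every species.

Blood cells regulate the primitive compartments through three
inhibitory feedbacks and one routing feedback:

* ``h1 = 1/(1 + b1L*L + b1M*M)`` inhibits all S activity,
* ``h2`` (same form) additionally inhibits S symmetric differentiation,
* ``h3`` inhibits all MPP activity,
* the multipotent progenitor commitment response (MPCR)
  ``p = gamma*(M/L)**theta / (1 + gamma*(M/L)**theta)`` is the
  probability that a committing MPP takes the lymphoid route; it
  steers production towards whichever blood-cell type is depleted.

The MPCR parameters are calibrated to a target homeostatic blood-cell
ratio ``rho = L*/M*`` via ``gamma = rho**(theta + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "N_TRANSITIONS",
    "HSCParameters",
    "FeedbackSignals",
    "Transition",
    "TransitionTable",
    "eval_feedback",
    "eval_mpcr",
    "calibrate_mpcr",
    "build_transition_table",
    "eval_propensities",
    "single_lineage_signals",
    "mean_field_rhs",
    "find_homeostasis",
    "calibrate_feedbacks",
]

SPECIES = ("S", "MPP", "CLP", "CMP", "L", "M")
N_SPECIES = 6
N_TRANSITIONS = 14

_S, _MPP, _CLP, _CMP, _L, _M = range(6)


@dataclass(frozen=True)
class HSCParameters:
    """All rate constants and feedback parameters of the niche model.

    Rates are per second, counts are cells.  The default feedback
    coefficients are calibrated (see :func:`calibrate_feedbacks`) so
    that a single uncoupled lineage reaches a homeostatic state of a
    few hundred myeloid cells with near-neutral stem-cell turnover;
    the homeostatic mean-field state under these defaults is roughly
    ``(S, MPP, CLP, CMP, L, M) = (4.8, 350, 21, 25, 75, 251)``.
    """

    K: float = 10.0            # niche carrying capacity of stem cells
    r_sym: float = 2.5         # S symmetric division (self-renewal)
    r_asym: float = 1.0        # S asymmetric division (self-renewal)
    r_sdiff: float = 0.001     # S symmetric differentiation
    r_mpp_ren: float = 0.25    # MPP multiplication
    r_mpp_diff: float = 0.1    # MPP differentiation (split by MPCR)
    r_clp_diff: float = 0.1    # CLP -> L maturation
    r_cmp_diff: float = 0.1    # CMP -> M maturation
    d_S: float = 0.004
    d_MPP: float = 0.02
    d_CLP: float = 0.001
    d_CMP: float = 0.001
    d_L: float = 0.028
    d_M: float = 0.01
    b1L: float = 1.0           # feedback coefficients (per cell)
    b1M: float = 1.0
    b2L: float = 1.0
    b2M: float = 1.0
    b3L: float = 0.02
    b3M: float = 0.02
    theta: float = 1.0         # MPCR exponent
    gamma: float = 0.25        # MPCR multiplier (= rho**(theta+1) at default)
    rho: float = 0.5           # target homeostatic ratio L*/M*
    # whether h1 multiplies transition 3 alongside h2 (flagged configurable)
    h1_on_sdiff: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.type in ("float", float):
                v = getattr(self, f.name)
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"parameter {f.name!r} must be finite and >= 0, got {v}")
        if self.K < 1:
            raise ValueError("carrying capacity K must be >= 1")
        if self.gamma <= 0:
            raise ValueError("MPCR multiplier gamma must be > 0")
        if self.rho <= 0:
            raise ValueError("target ratio rho must be > 0")

    @classmethod
    def with_mpcr(cls, theta: float, rho: float = 0.5, **kwargs) -> "HSCParameters":
        """Parameters with gamma recalibrated for the given MPCR exponent."""
        return cls(theta=theta, rho=rho, gamma=calibrate_mpcr(theta, rho), **kwargs)


@dataclass(frozen=True)
class FeedbackSignals:
    """Per-lineage feedback values; each field is a scalar or 1-d array.

    ``h1``, ``h2``, ``h3`` lie in (0, 1], ``p`` in (0, 1).
    """

    h1: np.ndarray
    h2: np.ndarray
    h3: np.ndarray
    p: np.ndarray


def eval_feedback(bL, bM, Lhat, Mhat):
    """Inhibitory feedback h = 1 / (1 + bL*Lhat + bM*Mhat).

    Additive in the two blood-cell counts, equal to 1 when both vanish,
    and strictly decreasing in either count when its coefficient is
    positive.  Accepts scalars or arrays.
    """
    bL, bM = np.asarray(bL, float), np.asarray(bM, float)
    Lhat, Mhat = np.asarray(Lhat, float), np.asarray(Mhat, float)
    if np.any(bL < 0) or np.any(bM < 0):
        raise ValueError("feedback coefficients must be non-negative")
    if np.any(Lhat < 0) or np.any(Mhat < 0):
        raise ValueError("cell counts must be non-negative")
    return 1.0 / (1.0 + bL * Lhat + bM * Mhat)


def eval_mpcr(theta, gamma, Lhat, Mhat):
    """MPCR commitment probability p = gamma*q / (1 + gamma*q), q = (M'/L')**theta.

    A zero count is replaced by 1 for the purpose of forming the ratio,
    which perturbs p only slightly while keeping the commitment pressure
    pointed at the depleted cell type.  theta = 0 gives a constant
    (non-responsive) MPCR.  Accepts scalars or arrays.
    """
    theta = float(theta)
    gamma = float(gamma)
    if theta < 0:
        raise ValueError("MPCR exponent theta must be >= 0")
    if gamma <= 0:
        raise ValueError("MPCR multiplier gamma must be > 0")
    Lhat, Mhat = np.asarray(Lhat, float), np.asarray(Mhat, float)
    if np.any(Lhat < 0) or np.any(Mhat < 0):
        raise ValueError("cell counts must be non-negative")
    Lp = np.where(Lhat > 0, Lhat, 1.0)
    Mp = np.where(Mhat > 0, Mhat, 1.0)
    # log-domain evaluation keeps extreme ratios finite:
    # p = expit(log gamma + theta * log(M'/L'))
    from scipy.special import expit

    p = expit(np.log(gamma) + theta * (np.log(Mp) - np.log(Lp)))
    # clamp float saturation back into the open interval
    return np.clip(p, np.finfo(float).tiny, np.nextafter(1.0, 0.0))


def calibrate_mpcr(theta: float, rho: float) -> float:
    """Gamma giving a homeostatic lymphoid:myeloid target ratio rho.

    At the target state L = rho*M the committed fraction must equal
    p* = rho/(1+rho); solving p(theta, gamma, rho*M, M) = p* gives
    gamma = rho**(theta+1), independent of M.  For rho < 1, gamma
    vanishes as theta grows, which bounds the usable exponent range.
    """
    if rho <= 0:
        raise ValueError("target ratio rho must be > 0")
    if theta < 0:
        raise ValueError("MPCR exponent theta must be >= 0")
    return float(rho ** (theta + 1))


@dataclass(frozen=True)
class Transition:
    name: str
    reactant: int                 # species index whose count the propensity is linear in
    rate: str                     # HSCParameters field name of the rate constant
    feedbacks: tuple[str, ...]    # subset of {"h1","h2","h3","p","1-p"}
    logistic: bool = False        # carries the (1 - S/K) capacity factor


@dataclass(frozen=True)
class TransitionTable:
    """Stoichiometry and propensity structure of the 14-transition system."""

    stoich: np.ndarray            # (6, 14) integer change vectors, one column per transition
    transitions: tuple[Transition, ...]
    params: HSCParameters

    def __post_init__(self) -> None:
        assert self.stoich.shape == (N_SPECIES, N_TRANSITIONS)

    def to_text(self) -> str:
        """Human-readable dump of the transition system."""
        lines = [f"{'#':>2}  {'process':<28} {'reactant':<8} {'rate':<12} feedbacks  stoich"]
        for j, tr in enumerate(self.transitions):
            nu = " ".join(
                f"{SPECIES[i]}{self.stoich[i, j]:+d}"
                for i in range(N_SPECIES)
                if self.stoich[i, j] != 0
            )
            fb = "*".join(tr.feedbacks) or "-"
            rate = f"{tr.rate}={getattr(self.params, tr.rate)}"
            cap = " (1-S/K)" if tr.logistic else ""
            lines.append(
                f"{j + 1:>2}  {tr.name:<28} {SPECIES[tr.reactant]:<8} {rate:<12} {fb:<9}{cap}  {nu}"
            )
        return "\n".join(lines)


def build_transition_table(params: HSCParameters) -> TransitionTable:
    """The fourteen transitions of the niche-lineage model.

    Feedback wiring: h1 multiplies all S activity (transitions 1-3), h2
    additionally multiplies symmetric differentiation only (3), h3
    multiplies all MPP activity (5-7); death transitions carry no
    feedback.  The carrying capacity enters only symmetric self-renewal
    as a logistic factor, so K bounds S without throttling output flux.
    Symmetric differentiation converts one S into two MPP; asymmetric
    division yields one MPP and retains the S.
    """
    h_sdiff = ("h1", "h2") if params.h1_on_sdiff else ("h2",)
    spec = [
        # (name, reactant, rate, feedbacks, logistic, {species: change})
        ("S symmetric self-renewal", _S, "r_sym", ("h1",), True, {_S: +1}),
        ("S asymmetric self-renewal", _S, "r_asym", ("h1",), False, {_MPP: +1}),
        ("S symmetric differentiation", _S, "r_sdiff", h_sdiff, False, {_S: -1, _MPP: +2}),
        ("S death", _S, "d_S", (), False, {_S: -1}),
        ("MPP renewal", _MPP, "r_mpp_ren", ("h3",), False, {_MPP: +1}),
        ("MPP -> CLP commitment", _MPP, "r_mpp_diff", ("p", "h3"), False, {_MPP: -1, _CLP: +1}),
        ("MPP -> CMP commitment", _MPP, "r_mpp_diff", ("1-p", "h3"), False, {_MPP: -1, _CMP: +1}),
        ("MPP death", _MPP, "d_MPP", (), False, {_MPP: -1}),
        ("CLP -> L maturation", _CLP, "r_clp_diff", (), False, {_CLP: -1, _L: +1}),
        ("CLP death", _CLP, "d_CLP", (), False, {_CLP: -1}),
        ("CMP -> M maturation", _CMP, "r_cmp_diff", (), False, {_CMP: -1, _M: +1}),
        ("CMP death", _CMP, "d_CMP", (), False, {_CMP: -1}),
        ("L death", _L, "d_L", (), False, {_L: -1}),
        ("M death", _M, "d_M", (), False, {_M: -1}),
    ]
    stoich = np.zeros((N_SPECIES, N_TRANSITIONS), dtype=np.int64)
    transitions = []
    for j, (name, reactant, rate, fb, logistic, changes) in enumerate(spec):
        for i, dv in changes.items():
            stoich[i, j] = dv
        transitions.append(Transition(name, reactant, rate, tuple(fb), logistic))
    return TransitionTable(stoich=stoich, transitions=tuple(transitions), params=params)


def eval_propensities(counts, signals: FeedbackSignals, table: TransitionTable):
    """Propensity matrix a_j for every lineage.

    ``counts`` is (6,) or (6, omega); returns (14,) or (14, omega).
    Each propensity is rate * reactant count * applicable feedback
    factors (* the logistic capacity factor for symmetric
    self-renewal).  Propensities are per unit time and may exceed 1.
    """
    counts = np.asarray(counts, dtype=float)
    squeeze = counts.ndim == 1
    if squeeze:
        counts = counts[:, None]
    if np.any(counts < 0):
        raise ValueError("cell counts must be non-negative")
    p = table.params
    factors = {
        "h1": np.asarray(signals.h1, float),
        "h2": np.asarray(signals.h2, float),
        "h3": np.asarray(signals.h3, float),
        "p": np.asarray(signals.p, float),
        "1-p": 1.0 - np.asarray(signals.p, float),
    }
    out = np.empty((N_TRANSITIONS, counts.shape[1]))
    for j, tr in enumerate(table.transitions):
        a = getattr(p, tr.rate) * counts[tr.reactant]
        for name in tr.feedbacks:
            a = a * factors[name]
        if tr.logistic:
            cap = 1.0 - counts[_S] / p.K
            if np.any(cap < 0):
                warnings.warn(
                    "stem-cell count above carrying capacity; clamping "
                    "symmetric self-renewal propensity to zero",
                    RuntimeWarning,
                    stacklevel=2,
                )
                cap = np.maximum(cap, 0.0)
            a = a * cap
        out[j] = a
    return out[:, 0] if squeeze else out


def single_lineage_signals(counts, params: HSCParameters) -> FeedbackSignals:
    """Feedbacks of an isolated lineage, driven by its own L and M."""
    counts = np.asarray(counts, dtype=float)
    L, M = counts[_L], counts[_M]
    return FeedbackSignals(
        h1=eval_feedback(params.b1L, params.b1M, L, M),
        h2=eval_feedback(params.b2L, params.b2M, L, M),
        h3=eval_feedback(params.b3L, params.b3M, L, M),
        p=eval_mpcr(params.theta, params.gamma, L, M),
    )


def mean_field_rhs(x, params: HSCParameters, table: TransitionTable | None = None):
    """Continuum-limit right-hand side dx/dt = sum_j nu_j a_j(x).

    Feedbacks are evaluated at x's own L and M (single-lineage mean
    field); this is the deterministic trajectory the stochastic
    ensemble mean is compared against, and the limit approached by
    large niche groups.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("mean-field state must be non-negative")
    if table is None:
        table = build_transition_table(params)
    a = eval_propensities(x, single_lineage_signals(x, params), table)
    return table.stoich @ a


def find_homeostasis(params: HSCParameters, x0=None, t_relax: float = 20000.0):
    """Numerically locate the interior homeostatic fixed point.

    Integrates the mean field from the founding state (or ``x0``) to
    damp transients, then polishes with a root finder.  Returns the
    6-vector x* with ``||mean_field_rhs(x*)|| < 1e-8``.
    """
    from scipy.integrate import solve_ivp
    from scipy.optimize import root

    table = build_transition_table(params)
    if x0 is None:
        x0 = np.array([1.0, 0, 0, 0, 0, 0])
    sol = solve_ivp(
        lambda t, x: mean_field_rhs(np.maximum(x, 0.0), params, table),
        (0.0, t_relax),
        np.asarray(x0, float),
        rtol=1e-8,
        atol=1e-10,
    )
    guess = np.maximum(sol.y[:, -1], 0.0)
    res = root(lambda x: mean_field_rhs(np.maximum(x, 0.0), params, table), guess, tol=1e-12)
    xstar = np.maximum(res.x, 0.0)
    if np.linalg.norm(mean_field_rhs(xstar, params, table)) > 1e-8:
        raise RuntimeError("failed to locate homeostatic fixed point")
    return xstar


def calibrate_feedbacks(
    target_M: float = 250.0,
    target_h1: float = 0.003,
    params: HSCParameters | None = None,
):
    """Solve for feedback coefficients hitting a requested homeostatic state.

    Finds ``b1 (= b1L = b1M = b2L = b2M)`` and ``b3 (= b3L = b3M)``
    such that the mean-field fixed point has myeloid level ``target_M``
    and stem-cell feedback ``h1(x*) = target_h1``.  The h1 target sets
    where the stem-cell compartment sits relative to neutral turnover
    (symmetric self-renewal at the quasi-steady S balances death when
    2.5*(1 - S/K)*h1 = d_S), which controls how often individual
    lineages lose their stem cells.

    Returns the calibrated :class:`HSCParameters`.
    """
    from scipy.optimize import root

    if params is None:
        params = HSCParameters()

    def residual(log_b):
        b1, b3 = np.exp(log_b)
        trial = replace(params, b1L=b1, b1M=b1, b2L=b1, b2M=b1, b3L=b3, b3M=b3)
        xs = find_homeostasis(trial)
        h1 = eval_feedback(b1, b1, xs[_L], xs[_M])
        return [xs[_M] / target_M - 1.0, h1 / target_h1 - 1.0]

    res = root(residual, np.log([1.0, 0.02]), method="hybr", tol=1e-10)
    if not res.success:
        raise RuntimeError(f"feedback calibration failed: {res.message}")
    b1, b3 = np.exp(res.x)
    return replace(params, b1L=b1, b1M=b1, b2L=b1, b2M=b1, b3L=b3, b3M=b3)
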