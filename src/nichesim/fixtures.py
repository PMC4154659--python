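"""Analytic fixture models for validating the simulation engine.

Each fixture is a one-species transition system with closed-form
moments, used as an independent oracle for the exact SSA and the
synchronised tau-leap:

* pure death (rate c):        E[X_t] = x0 * exp(-c t)
* immigration-death (kappa, c): stationary law Poisson(kappa / c),
  E[X_t] = kappa/c + (x0 - kappa/c) * exp(-c t)
* linear birth-death (b, d):  E[X_t] = x0 * exp((b - d) t);
  Var[X_t] = x0 * (b + d)/(b - d) * e^{(b-d)t} (e^{(b-d)t} - 1) for b != d

All three are instances of a single linear system with constant
immigration ``kappa``, per-capita birth ``b`` and per-capita death
``d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LinearBirthDeath", "pure_death", "immigration_death", "linear_birth_death"]


@dataclass(frozen=True)
class LinearBirthDeath:
    """One-species system: birth at kappa + b*x, death at d*x."""

    kappa: float = 0.0
    birth: float = 0.0
    death: float = 0.0
    name: str = "linear-birth-death"

    species = ("X",)
    # columns: birth event (+1), death event (-1)
    stoich = np.array([[1, -1]], dtype=np.int64)

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.birth < 0 or self.death < 0:
            raise ValueError("fixture rates must be non-negative")

    def propensities(self, counts: np.ndarray) -> np.ndarray:
        counts = np.atleast_2d(np.asarray(counts, dtype=float))
        x = counts[0]
        return np.vstack([self.kappa + self.birth * x, self.death * x])

    def signals(self, counts):  # no feedbacks in the fixtures
        return None

    def state_ok(self, counts) -> bool:
        return True

    # ---- closed forms --------------------------------------------------

    def mean(self, t, x0: float) -> float:
        """E[X_t] from X_0 = x0."""
        r = self.birth - self.death
        if abs(r) < 1e-300:
            return x0 + self.kappa * t
        return (x0 + self.kappa / r) * np.exp(r * t) - self.kappa / r

    def variance(self, t, x0: float) -> float:
        """Var[X_t] for the pure linear process (kappa = 0)."""
        if self.kappa != 0:
            raise NotImplementedError("variance closed form implemented for kappa = 0")
        b, d = self.birth, self.death
        r = b - d
        if abs(r) < 1e-12:
            return x0 * (b + d) * t
        e = np.exp(r * t)
        return x0 * (b + d) / r * e * (e - 1.0)

    @property
    def stationary_mean(self) -> float:
        """Mean of the stationary law (immigration-death only)."""
        if self.birth != 0 or self.death <= 0:
            raise ValueError("stationary law requires birth = 0 and death > 0")
        return self.kappa / self.death

    @property
    def stationary_variance(self) -> float:
        # stationary law is Poisson(kappa/death)
        return self.stationary_mean


def pure_death(c: float) -> LinearBirthDeath:
    return LinearBirthDeath(death=c, name="pure-death")


def immigration_death(kappa: float, c: float) -> LinearBirthDeath:
    return LinearBirthDeath(kappa=kappa, death=c, name="immigration-death")


def linear_birth_death(b: float, d: float) -> LinearBirthDeath:
    return LinearBirthDeath(birth=b, death=d, name="linear-birth-death")
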