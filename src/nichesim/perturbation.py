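"""Perturbation protocols: scheduled removal of differentiated blood cells.

Three protocols, designed to remove the same expected fraction of the
metapopulation's myeloid cells (37.5%):

* even    — every lineage loses 37.5% of its target cells;
* uneven  — every second lineage (the 2nd, 4th, ... in 1-based order)
            loses 75%, the rest are untouched;
* random  — each lineage independently has a 50% chance of losing 75%.

Removal counts are rounded half away from zero, so a 75% cut of 2
cells removes 2 and of 1 cell removes 1.  The random protocol draws
its hit pattern from its own seeded stream, separate from the dynamics
RNG, so the same pattern can be replayed across niche-group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SPECIES

__all__ = ["PerturbationSpec", "RemovalReport", "apply_perturbation"]

KINDS = ("even", "uneven", "random")


@dataclass(frozen=True)
class PerturbationSpec:
    """One scheduled removal of a fraction of a blood-cell species."""

    kind: str = "random"
    time: float = 1500.0
    even_fraction: float = 0.375
    strong_fraction: float = 0.75
    hit_probability: float = 0.5
    target_species: str = "M"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        for name in ("even_fraction", "strong_fraction", "hit_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.target_species not in SPECIES:
            raise ValueError(f"unknown target species {self.target_species!r}")
        if self.time < 0:
            raise ValueError("perturbation time must be >= 0")


@dataclass(frozen=True)
class RemovalReport:
    """Per-lineage removals of one applied perturbation."""

    kind: str
    time: float
    target_species: str
    removed: np.ndarray          # cells removed per lineage
    affected: np.ndarray         # boolean mask of perturbed lineages
    total_before: int
    total_removed: int

    @property
    def removed_fraction(self) -> float:
        """Metapopulation-wide fraction of the target species removed."""
        return self.total_removed / self.total_before if self.total_before else 0.0


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # round half away from zero; x is non-negative here
    return np.floor(x + 0.5).astype(np.int64)


def apply_perturbation(
    counts: np.ndarray,
    spec: PerturbationSpec,
    rng: np.random.Generator | None = None,
):
    """Apply one removal protocol to a state matrix.

    Returns ``(new_counts, report)``; the input matrix is not modified.
    Only the target species changes and no count goes negative.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be a (n_species, omega) state matrix")
    omega = counts.shape[1]
    target = SPECIES.index(spec.target_species)
    level = counts[target].astype(float)

    if spec.kind == "even":
        affected = np.ones(omega, dtype=bool)
        removed = _round_half_up(spec.even_fraction * level)
    elif spec.kind == "uneven":
        # every second lineage in 1-based order: the 2nd, 4th, ...
        affected = np.zeros(omega, dtype=bool)
        affected[1::2] = True
        removed = np.where(affected, _round_half_up(spec.strong_fraction * level), 0)
    else:  # random
        if rng is None:
            rng = np.random.Generator(np.random.PCG64(spec.seed))
        affected = rng.random(omega) < spec.hit_probability
        removed = np.where(affected, _round_half_up(spec.strong_fraction * level), 0)

    removed = np.minimum(removed, counts[target])  # never below zero
    new = counts.copy()
    new[target] = counts[target] - removed
    report = RemovalReport(
        kind=spec.kind,
        time=spec.time,
        target_species=spec.target_species,
        removed=removed,
        affected=affected,
        total_before=int(counts[target].sum()),
        total_removed=int(removed.sum()),
    )
    return new, report
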