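"""Niche-group coupling.

Lineages are partitioned into niche groups of size n.  Within a group
the feedback signals are driven not by each lineage's own blood cells
but by the group's pooled lymphoid and myeloid counts, normalised by
the group size.  The 1/n normalisation keeps the homeostatic state
independent of n (for the linear-in-counts feedbacks it is equivalent
to dividing the coefficients by n, and it cancels in the MPCR ratio),
so feedback coefficients need no per-n rescaling.  With n = 1 the
coupled computation reduces exactly to the uncoupled one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import HSCParameters, FeedbackSignals, eval_feedback, eval_mpcr

__all__ = ["NicheGrouping", "group_aggregate", "broadcast_feedbacks"]

_L, _M = 4, 5


@dataclass(frozen=True)
class NicheGrouping:
    """Partition of omega lineages into contiguous groups of size n."""

    n_lineages: int
    group_size: int = 1

    def __post_init__(self) -> None:
        if self.n_lineages < 1 or self.group_size < 1:
            raise ValueError("population and group sizes must be >= 1")
        if self.n_lineages % self.group_size:
            raise ValueError(
                f"population size {self.n_lineages} is not divisible by "
                f"group size {self.group_size}"
            )

    @property
    def n_groups(self) -> int:
        return self.n_lineages // self.group_size

    @property
    def group_of(self) -> np.ndarray:
        """Group index of each lineage (contiguous blocks)."""
        return np.repeat(np.arange(self.n_groups), self.group_size)

    @property
    def trivial(self) -> bool:
        return self.group_size == 1


def group_aggregate(counts: np.ndarray, grouping: NicheGrouping):
    """Pooled, normalised blood-cell counts, broadcast back to lineages.

    Returns ``(Lhat, Mhat)``, each of length omega: the sum of the
    species over each niche group divided by the group size, assigned
    to every member lineage.  With n = 1 this is the identity.
    """
    n = grouping.group_size
    if n == 1:
        # identity regardless of width, so single columns of a trivially
        # grouped metapopulation can be evaluated in isolation
        return counts[_L].astype(float), counts[_M].astype(float)
    if counts.shape[1] != grouping.n_lineages:
        raise ValueError("state matrix width does not match grouping")
    G = grouping.n_groups
    Lg = counts[_L].reshape(G, n).sum(axis=1) / n
    Mg = counts[_M].reshape(G, n).sum(axis=1) / n
    return np.repeat(Lg, n), np.repeat(Mg, n)


def broadcast_feedbacks(
    counts: np.ndarray, grouping: NicheGrouping, params: HSCParameters
) -> FeedbackSignals:
    """Feedback signals per lineage under niche-group coupling.

    h1, h2, h3 and the MPCR are computed once per group from the pooled
    normalised (Lhat, Mhat) and copied to each member lineage, so all
    four signals are identical within a group.
    """
    Lhat, Mhat = group_aggregate(counts, grouping)
    return FeedbackSignals(
        h1=eval_feedback(params.b1L, params.b1M, Lhat, Mhat),
        h2=eval_feedback(params.b2L, params.b2M, Lhat, Mhat),
        h3=eval_feedback(params.b3L, params.b3M, Lhat, Mhat),
        p=eval_mpcr(params.theta, params.gamma, Lhat, Mhat),
    )
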