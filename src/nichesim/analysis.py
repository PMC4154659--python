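"""Summary statistics: binned distributions, L1 bin-mass distance,
perturbation response (overshoot, band-and-dwell return time),
stem-cell extinction fraction, and per-lineage vs per-group
steady-state statistics.

Distribution comparisons use the L1 distance between bin *masses*
(density times bin width) on shared edges; the Monte-Carlo noise floor
of this distance is the "self-distance" between two independent exact
ensembles, against which approximate simulations are judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Histogram",
    "PerturbationResponse",
    "empirical_pdf",
    "l1_mass_distance",
    "shared_integer_edges",
    "perturbation_response",
    "extinction_fraction",
    "steady_state_stats",
]


@dataclass(frozen=True)
class Histogram:
    """Probability mass per bin on strictly increasing edges."""

    edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, float)
        masses = np.asarray(self.masses, float)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if masses.shape != (edges.size - 1,):
            raise ValueError("need one mass per bin")
        if np.any(masses < 0) or abs(masses.sum() - 1.0) > 1e-12:
            raise ValueError("masses must be non-negative and sum to 1")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "masses", masses)


def shared_integer_edges(*sample_sets, min_width: int = 1) -> np.ndarray:
    """Common integer-width bin edges covering all sample sets.

    Bin width is the Freedman-Diaconis width of the pooled samples,
    rounded to an integer >= ``min_width``, so that distances between
    histograms on these edges compare like with like.
    """
    pooled = np.concatenate([np.asarray(s, float).ravel() for s in sample_sets])
    if pooled.size == 0:
        raise ValueError("no samples")
    q75, q25 = np.percentile(pooled, [75, 25])
    width = 2.0 * (q75 - q25) / max(pooled.size, 1) ** (1 / 3)
    width = max(int(round(width)), min_width)
    lo = np.floor(pooled.min()) - 0.5
    hi = np.ceil(pooled.max()) + 0.5
    n_bins = int(np.ceil((hi - lo) / width))
    return lo + width * np.arange(n_bins + 1)


def empirical_pdf(samples, edges) -> Histogram:
    """Histogram of sample fractions per bin."""
    samples = np.asarray(samples, float).ravel()
    if samples.size == 0:
        raise ValueError("need at least one sample")
    edges = np.asarray(edges, float)
    if samples.min() < edges[0] or samples.max() > edges[-1]:
        raise ValueError("edges do not cover the sample range")
    hist, _ = np.histogram(samples, bins=edges)
    return Histogram(edges=edges, masses=hist / samples.size)


def l1_mass_distance(h1: Histogram, h2: Histogram) -> float:
    """Sum over bins of |mass1 - mass2|; in [0, 2], 0 iff identical."""
    if h1.edges.shape != h2.edges.shape or not np.allclose(h1.edges, h2.edges):
        raise ValueError("histograms must share identical bin edges")
    return float(np.abs(h1.masses - h2.masses).sum())


@dataclass(frozen=True)
class PerturbationResponse:
    """Overshoot and return-time indicators of one ensemble-mean trace."""

    steady_mean: float
    steady_sd: float
    peak: float
    overshoot: float
    return_time: float           # nan when the trace never re-enters the band
    band: float
    dwell: float

    @property
    def returned(self) -> bool:
        return np.isfinite(self.return_time)


def perturbation_response(
    times,
    mean_traj,
    t_p: float,
    steady_window: tuple[float, float] | None = None,
    band: float | None = None,
    dwell: float = 100.0,
) -> PerturbationResponse:
    """Overshoot and band-and-dwell return time of an ensemble mean.

    The steady level and its fluctuation scale are taken from a
    pre-perturbation window, by default the 1000 s preceding t_p: the
    ensemble mean fluctuates with an integrated autocorrelation time of
    order 100 s at homeostasis, so the window must span many
    autocorrelation times for the standard deviation estimate (and
    hence the band) to be reliable.  The
    overshoot is the post-perturbation maximum *after* the trace has
    first recovered past the steady mean (so the removal dip itself is
    not counted as the spike), minus the steady mean, floored at zero.
    The return time is the first time after t_p at which the trace
    enters ``steady_mean +/- band`` and stays inside for ``dwell``
    seconds; homeostatic turnover makes an instantaneous crossing an
    unreliable marker, hence the dwell requirement.  The band defaults
    to one pre-perturbation standard deviation of the trace.
    """
    times = np.asarray(times, float)
    traj = np.asarray(mean_traj, float)
    if times.shape != traj.shape or times.ndim != 1:
        raise ValueError("times and mean_traj must be matching 1-d arrays")
    if steady_window is None:
        steady_window = (t_p - 1000.0, t_p)
    lo, hi = steady_window
    pre = (times >= lo) & (times < hi)
    if pre.sum() < 10:
        raise ValueError("steady window must contain at least 10 samples before t_p")
    steady_mean = float(traj[pre].mean())
    steady_sd = float(traj[pre].std(ddof=0))
    if band is None:
        band = steady_sd

    post = times >= t_p
    t_post, x_post = times[post], traj[post]

    # overshoot: require recovery past the steady mean first
    above = np.nonzero(x_post >= steady_mean)[0]
    if above.size == 0:
        peak = steady_mean
    else:
        peak = float(x_post[above[0]:].max())
    overshoot = max(peak - steady_mean, 0.0)

    inside = np.abs(x_post - steady_mean) <= band
    return_time = np.nan
    i = 0
    while i < inside.size:
        if inside[i]:
            j = i
            while j < inside.size and inside[j]:
                j += 1
            # inside on [t_post[i], t_post[j-1]]; sustained if it covers
            # the dwell window or runs to the end of the record
            if t_post[j - 1] - t_post[i] >= dwell or j == inside.size:
                return_time = float(t_post[i] - t_p)
                break
            i = j
        else:
            i += 1

    return PerturbationResponse(
        steady_mean=steady_mean,
        steady_sd=steady_sd,
        peak=peak,
        overshoot=overshoot,
        return_time=return_time,
        band=float(band),
        dwell=float(dwell),
    )


def extinction_fraction(result, species: str, t: float) -> float:
    """Fraction of lineages whose count of ``species`` is zero at time t."""
    counts = result.at(t)
    i = result.species.index(species)
    return float((counts[i] == 0).mean())


def steady_state_stats(
    result,
    window: tuple[float, float],
    level: str = "per-lineage",
    species: tuple[str, ...] | None = None,
):
    """Means and variances over a steady-state window.

    ``level='per-lineage'`` pools lineage-time samples;
    ``level='per-group'`` first sums each species over niche groups and
    normalises by group size, then pools group-time samples.  Feedback
    signals, when recorded, are included (their per-group value is the
    group mean, which for coupled runs equals the common group signal).
    Variances are population variances (ddof=0).  Returns a tidy
    DataFrame with one row per quantity.
    """
    import pandas as pd

    if level not in ("per-lineage", "per-group"):
        raise ValueError("level must be 'per-lineage' or 'per-group'")
    lo, hi = window
    sel = (result.times >= lo) & (result.times <= hi)
    if not sel.any():
        raise ValueError(f"window {window} contains no recorded times")
    species = species or result.species
    grouping = result.grouping
    rows = []

    def _samples(values: np.ndarray) -> np.ndarray:
        # values: (T_sel, omega)
        if level == "per-lineage" or grouping is None or grouping.trivial:
            return values.ravel()
        G, n = grouping.n_groups, grouping.group_size
        return values.reshape(values.shape[0], G, n).mean(axis=2).ravel()

    for name in species:
        vals = result.counts[sel, result.species.index(name), :].astype(float)
        s = _samples(vals)
        rows.append({"quantity": name, "level": level, "mean": s.mean(), "variance": s.var(ddof=0)})
    if result.signals is not None:
        for i, name in enumerate(("h1", "h2", "h3", "p")):
            s = _samples(result.signals[sel, i, :])
            rows.append({"quantity": name, "level": level, "mean": s.mean(), "variance": s.var(ddof=0)})
    return pd.DataFrame(rows)
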