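"""Time-rescaling goodness-of-fit for fitted conditional-intensity models.

If a point process has conditional intensity λ(t|H), the rescaled
inter-spike quantities τ_j = Λ(t_j) − Λ(t_{j−1}), with Λ the cumulative
intensity, are unit-mean exponential when the model is correct, so
z_j = 1 − exp(−τ_j) are Uniform(0,1).  Comparing the ordered z against
uniform quantiles with a Kolmogorov–Smirnov band (half-width 1.36/√n at
95%) gives an absolute goodness-of-fit check per unit and model.

The intensity is piecewise constant within observation bins (no sub-bin
interpolation of covariates), so Λ is piecewise linear.  Spike times keep
their fine simulation/recording resolution for Λ evaluation; exact ties
within a bin (which would yield τ = 0) are broken by respacing that bin's
spikes evenly across the bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ciglm import CountSeries, FitResult, _design_one

__all__ = [
    "RescaledSample",
    "KsSummary",
    "predicted_rate",
    "cumulative_intensity",
    "rescale",
    "ks_summary",
    "ks_for_fit",
]

KS_BAND_CONST = {0.95: 1.36, 0.99: 1.63}


@dataclass
class RescaledSample:
    """Uniform-under-the-model z values, one per rescaled inter-spike gap."""

    z: np.ndarray

    @property
    def n(self) -> int:
        return int(self.z.size)


@dataclass
class KsSummary:
    """K-S comparison of rescaled spikes against Uniform(0,1)."""

    statistic: float
    band: float
    n: int
    level: float
    empirical: np.ndarray  # ordered z
    quantiles: np.ndarray  # uniform plotting positions (j − 0.5)/n

    @property
    def passed(self) -> bool:
        return self.statistic <= self.band


def predicted_rate(fr: FitResult, cs: CountSeries) -> tuple[np.ndarray, np.ndarray]:
    """Fitted expected count per bin over a whole session.

    Returns (expected counts, validity mask); bins whose history window
    precedes the session start are invalid.  Columns dropped from the fit
    as structural zeros contribute nothing.
    """
    X, names, valid = _design_one(cs, fr.spec)
    beta = np.array([fr.coef_or_zero(n) for n in names])
    return np.exp(X @ beta), valid


def cumulative_intensity(
    fr: FitResult, cs: CountSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Λ evaluated at bin edges over the history-valid part of the session.

    Returns (edge times, Λ values); Λ is nondecreasing and piecewise linear
    with slope exp(x·coef)/bin_width within each bin.
    """
    mu, valid = predicted_rate(fr, cs)
    first = int(np.argmax(valid)) if valid.any() else len(valid)
    mu = mu[first:]
    edges = np.concatenate([
        cs.starts[first:], [cs.starts[-1] + cs.bin_width]
    ])
    Lam = np.concatenate([[0.0], np.cumsum(mu)])
    return edges, Lam


def _break_ties(times: np.ndarray, cs: CountSeries) -> np.ndarray:
    """Respace spikes of any bin containing duplicate times evenly."""
    if times.size < 2 or not np.any(np.diff(times) <= 0):
        return times
    out = times.astype(float).copy()
    bw = cs.bin_width
    t0 = cs.starts[0]
    bins = np.floor((out - t0) / bw).astype(np.intp)
    for b in np.unique(bins):
        sel = bins == b
        grp = out[sel]
        if np.unique(grp).size < grp.size:
            k = grp.size
            out[sel] = t0 + b * bw + (np.arange(k) + 0.5) * bw / k
    return np.sort(out)


def rescale(spike_times: np.ndarray, edges: np.ndarray, Lam: np.ndarray,
            cs: CountSeries | None = None) -> RescaledSample:
    """Transform spike times through Λ; z_j = 1 − exp(−ΔΛ between spikes)."""
    t = np.asarray(spike_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be ascending")
    t = t[(t >= edges[0]) & (t < edges[-1])]
    if cs is not None:
        t = _break_ties(t, cs)
    if t.size < 2:
        return RescaledSample(z=np.zeros(0))
    L = np.interp(t, edges, Lam)
    tau = np.diff(L)
    return RescaledSample(z=1.0 - np.exp(-tau))


def ks_summary(sample: RescaledSample, level: float = 0.95) -> KsSummary:
    """K-S statistic of z against uniform quantiles b_j = (j − 0.5)/n."""
    n = sample.n
    if n < 2:
        raise ValueError("need at least 2 rescaled spikes for a K-S summary")
    if level not in KS_BAND_CONST:
        raise ValueError(f"level must be one of {sorted(KS_BAND_CONST)}")
    z = np.sort(sample.z)
    b = (np.arange(1, n + 1) - 0.5) / n
    D = float(np.max(np.abs(z - b)))
    band = KS_BAND_CONST[level] / np.sqrt(n)
    return KsSummary(statistic=D, band=band, n=n, level=level,
                     empirical=z, quantiles=b)


def ks_for_fit(
    fr: FitResult, series: list[CountSeries], spike_times: list[np.ndarray],
    level: float = 0.95,
) -> KsSummary:
    """Pooled K-S summary of one fit across one or more sessions."""
    zs = []
    for cs, times in zip(series, spike_times):
        edges, Lam = cumulative_intensity(fr, cs)
        zs.append(rescale(np.asarray(times), edges, Lam, cs=cs).z)
    return ks_summary(RescaledSample(z=np.concatenate(zs)), level=level)
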