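"""Peri-event time histograms and interval firing-rate statistics.

Rates are summarized per behavioral interval (Delay, Run, Branch, Choice,
Reward, Pickup) on correct analyzed trials.  Because interval durations
vary across trials, interval profiles are temporally normalized: each
occurrence is resampled onto a fixed number of equal sub-bins before
averaging.  Stress effects are expressed as percent of the baseline
session's rate (stress/baseline × 100), matched on T-maze arm choice, and
tested with a one-way ANOVA across intervals plus FDR-corrected one-sample
t-tests against 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ciglm import bh_fdr
from .session import (
    BASELINE,
    INTERVAL_LABELS,
    STRESS,
    LabeledInterval,
    Session,
    SpikeTrain,
    correct_trials,
    session_intervals,
)

__all__ = [
    "Peth",
    "NormalizedProfile",
    "compute_peth",
    "normalized_peth",
    "interval_rates",
    "percent_of_baseline",
    "percent_of_baseline_table",
    "rate_stats",
]


@dataclass
class Peth:
    """Spike probability per bin, aligned to an interval onset across trials."""

    align_label: str
    bin_edges: np.ndarray   # seconds relative to the alignment event
    probability: np.ndarray  # spike count per bin / n_trials
    n_trials: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class NormalizedProfile:
    """Mean firing rate (Hz) over n equal sub-bins of a variable-duration interval."""

    label: str
    rate_hz: np.ndarray
    n_intervals: int


def _label_intervals(session: Session, label: str) -> list[LabeledInterval]:
    analyzed = {tr.trial_index for tr in correct_trials(session).trials}
    return [
        iv for iv in session_intervals(session)
        if iv.label == label and iv.trial_index in analyzed
    ]


def compute_peth(
    spikes: SpikeTrain,
    session: Session,
    label: str,
    window: tuple[float, float] = (0.0, 5.0),
    bin_width: float = 0.005,
) -> Peth:
    """Histogram of spikes aligned to each onset of one interval label.

    Time 0 is the interval onset; probability per bin is the aligned spike
    count divided by the number of analyzed trials, so sessions with
    different trial counts are comparable.
    """
    onsets = [iv.start for iv in _label_intervals(session, label)]
    if not onsets:
        raise ValueError(f"no analyzed {label!r} intervals in session")
    lo, hi = window
    edges = lo + bin_width * np.arange(int(round((hi - lo) / bin_width)) + 1)
    counts = np.zeros(len(edges) - 1)
    for t0 in onsets:
        # round away float jitter so boundary spikes land deterministically
        rel = np.round(spikes.times - t0, 9)
        rel = rel[(rel >= lo) & (rel < edges[-1])]
        counts += np.histogram(rel, bins=edges)[0]
    return Peth(
        align_label=label,
        bin_edges=edges,
        probability=counts / len(onsets),
        n_trials=len(onsets),
    )


def normalized_peth(
    spikes: SpikeTrain,
    intervals: list[LabeledInterval],
    n_norm_bins: int = 20,
) -> NormalizedProfile:
    """Temporally normalized rate profile over same-label intervals.

    Each interval is divided into ``n_norm_bins`` equal sub-bins; the rate
    in each sub-bin (count / sub-bin duration) is averaged over intervals,
    so the profile of a stationary train is flat regardless of how
    interval durations vary across trials.
    """
    if not intervals:
        raise ValueError("no intervals given")
    labels = {iv.label for iv in intervals}
    if len(labels) > 1:
        raise ValueError(f"intervals mix labels {sorted(labels)}")
    rates = np.zeros((len(intervals), n_norm_bins))
    for i, iv in enumerate(intervals):
        if iv.duration <= 0:
            raise ValueError(f"zero-duration interval in trial {iv.trial_index}")
        sub = iv.start + (iv.duration / n_norm_bins) * np.arange(n_norm_bins + 1)
        counts = np.histogram(spikes.times, bins=sub)[0]
        rates[i] = counts / (iv.duration / n_norm_bins)
    return NormalizedProfile(
        label=intervals[0].label,
        rate_hz=rates.mean(axis=0),
        n_intervals=len(intervals),
    )


def interval_rates(session: Session, unit_id: str | None = None) -> pd.DataFrame:
    """Mean rate (Hz) per interval × arm on analyzed trials of one session.

    Rates pool spike counts and durations over the trials of each arm.
    """
    sts = session.spikes if unit_id is None else [session.spike_train(unit_id)]
    analyzed = correct_trials(session).trials
    arm_of = {tr.trial_index: tr.arm for tr in analyzed}
    ivs = [iv for iv in session_intervals(session) if iv.trial_index in arm_of]
    rows = []
    for st in sts:
        for label in INTERVAL_LABELS:
            for arm in ("left", "right"):
                sel = [iv for iv in ivs if iv.label == label and arm_of[iv.trial_index] == arm]
                if not sel:
                    continue
                dur = sum(iv.duration for iv in sel)
                n = sum(
                    int(np.count_nonzero((st.times >= iv.start) & (st.times < iv.end)))
                    for iv in sel
                )
                rows.append({
                    "unit_id": st.unit_id,
                    "condition": session.condition,
                    "interval": label,
                    "arm": arm,
                    "rate_hz": n / dur,
                    "total_s": dur,
                    "n_spikes": n,
                })
    return pd.DataFrame(rows)


def percent_of_baseline(stress_rate: float, baseline_rate: float) -> float:
    """Stress rate as percent of the baseline rate (100 × stress/baseline)."""
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be positive; undefined otherwise")
    return 100.0 * stress_rate / baseline_rate


def percent_of_baseline_table(
    baseline: Session, stress: Session, unit_id: str | None = None
) -> pd.DataFrame:
    """Per unit × interval percent-of-baseline, matched on arm choice.

    Percent values are computed within each arm and averaged over the arms
    represented in both sessions; intervals whose baseline rate is zero are
    flagged undefined and excluded from downstream statistics.
    """
    rb = interval_rates(baseline, unit_id)
    rs = interval_rates(stress, unit_id)
    rows = []
    for (uid, label), grp_b in rb.groupby(["unit_id", "interval"]):
        grp_s = rs[(rs.unit_id == uid) & (rs.interval == label)]
        pcts, undef = [], False
        rate_b = rate_s = np.nan
        for arm in ("left", "right"):
            b = grp_b[grp_b.arm == arm]
            s = grp_s[grp_s.arm == arm]
            if b.empty or s.empty:
                continue
            if b.rate_hz.iloc[0] <= 0:
                undef = True
                continue
            pcts.append(percent_of_baseline(s.rate_hz.iloc[0], b.rate_hz.iloc[0]))
        # pooled rates for reporting
        rate_b = grp_b.n_spikes.sum() / grp_b.total_s.sum()
        if not grp_s.empty:
            rate_s = grp_s.n_spikes.sum() / grp_s.total_s.sum()
        rows.append({
            "unit_id": uid,
            "interval": label,
            "baseline_rate_hz": rate_b,
            "stress_rate_hz": rate_s,
            "percent_of_baseline": float(np.mean(pcts)) if pcts else np.nan,
            "undefined": undef and not pcts,
        })
    return pd.DataFrame(rows)


def rate_stats(table: pd.DataFrame, q: float = 0.05) -> dict:
    """Interval-rate statistics across units.

    One-way ANOVA of percent-of-baseline across intervals, plus
    two-sided one-sample t-tests of each interval's percents against 100,
    Benjamini–Hochberg corrected at level ``q``.  Requires ≥2 units.
    """
    tab = table[~table["percent_of_baseline"].isna()]
    if tab["unit_id"].nunique() < 2:
        raise ValueError("need at least 2 units for interval-rate statistics")
    groups = {
        label: grp["percent_of_baseline"].to_numpy()
        for label, grp in tab.groupby("interval")
    }
    allv = np.concatenate(list(groups.values()))
    if np.ptp(allv) == 0:
        F, p = 0.0, 1.0  # no variability anywhere
    else:
        F, p = stats.f_oneway(*groups.values())
    per_interval = []
    pvals = []
    for label in INTERVAL_LABELS:
        if label not in groups or len(groups[label]) < 2:
            continue
        g = groups[label]
        if g.std(ddof=1) == 0:
            t, pv = (0.0, 1.0) if np.allclose(g, 100.0) else (np.inf, 0.0)
        else:
            t, pv = stats.ttest_1samp(g, 100.0)
        per_interval.append({
            "interval": label,
            "mean_percent": float(np.mean(groups[label])),
            "t": float(t),
            "p": float(pv),
            "n": int(len(groups[label])),
        })
        pvals.append(float(pv))
    rej, p_adj = bh_fdr(pvals, q=q)
    for row, r, pa in zip(per_interval, rej, p_adj):
        row["p_fdr"] = float(pa)
        row["significant"] = bool(r)
    return {
        "anova": {"F": float(F), "p": float(p), "k": len(groups)},
        "per_interval": per_interval,
        "q": q,
    }
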