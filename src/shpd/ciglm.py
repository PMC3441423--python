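"""Conditional-intensity GLMs for task spike trains.

The spike train of one unit is discretized to 250 ms counts and modeled
with a Poisson GLM (log link) whose linear predictor is the log
conditional intensity per bin.  Six model families are supported:

``h0``
    homogeneous Poisson: intercept only.
``inhom``
    inhomogeneous Poisson: intercept + task-interval dummies.
``1b``
    intercept + stress indicator + condition-split spike history
    (alpha_k on baseline bins, eta_k on stress bins, k = 1..K lags of
    250 ms).
``1a``
    Model 1b plus the task-interval dummies (the full additive model).
``2`` / ``3``
    intercept + global history gamma_k + stress + a composite-interval
    dummy (ExtendedDelay for 2, Response = Run∪Branch∪Choice for 3) +
    condition-split history × composite interactions alpha_k / eta_k —
    interval-specific history gain over and above the main effects.

Interval dummies are reference-coded against Delay (the intervals tile
each trial, so a full dummy set would be collinear with the intercept).
History lags are computed over continuous session time, crossing trial
and interval boundaries; the first K bins of a session, whose history
window precedes the recording, are excluded from the likelihood, as are
bins outside analyzed (correct, non-first) trials.  Exponentiated history
coefficients are the "spiking gains" (rate ratios) that quantify
spike-history-predicted discharge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .session import (
    COMPOSITE_MEMBERS,
    INTERVAL_LABELS,
    STRESS,
    Session,
    correct_trials,
    session_intervals,
)

__all__ = [
    "CountSeries",
    "ModelSpec",
    "DesignMatrix",
    "FitResult",
    "GainProfile",
    "bin_session",
    "history_matrix",
    "build_design",
    "fit",
    "gain_profile",
    "deviance_test",
    "bh_fdr",
]

_Z95 = float(stats.norm.ppf(0.975))

#: |coefficient| beyond which a fit is flagged as separated/degenerate
SEPARATION_BOUND = 15.0


@dataclass
class CountSeries:
    """Binned spike counts of one session with per-bin covariate labels."""

    bin_width: float
    starts: np.ndarray          # bin start times (session clock), contiguous
    counts: np.ndarray          # nonnegative integer count per bin
    stress: np.ndarray          # 0/1 per bin
    labels: np.ndarray          # elementary interval label per bin
    in_scope: np.ndarray        # bin lies inside an analyzed correct trial
    session_id: str = ""

    def __post_init__(self):
        n = len(self.counts)
        for name in ("starts", "stress", "labels", "in_scope"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch with counts")


@dataclass(frozen=True)
class ModelSpec:
    """Which CI-GLM to build and its history geometry."""

    model_id: str = "1a"
    history_order: int = 10
    history_bin: float = 0.25
    reference_interval: str = "Delay"

    _COMPOSITES = {"2": "ExtendedDelay", "3": "Response"}

    def __post_init__(self):
        if self.model_id not in ("h0", "inhom", "1a", "1b", "2", "3"):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.reference_interval not in INTERVAL_LABELS:
            raise ValueError(f"unknown reference interval {self.reference_interval!r}")

    @property
    def target_composite(self) -> Optional[str]:
        return self._COMPOSITES.get(self.model_id)

    @property
    def lags_s(self) -> np.ndarray:
        return self.history_bin * np.arange(1, self.history_order + 1)


@dataclass
class DesignMatrix:
    """Stacked design rows (likelihood scope only) plus the response."""

    X: np.ndarray
    y: np.ndarray
    colnames: list[str]
    spec: ModelSpec
    dropped: list[str] = field(default_factory=list)  # structurally-zero columns
    n_total_bins: int = 0

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class FitResult:
    """Maximum-likelihood fit of one CI-GLM."""

    coef: dict[str, float]
    se: dict[str, float]
    cov: np.ndarray
    loglik: float
    deviance: float
    converged: bool
    degenerate: bool
    n_iter: int
    n_bins: int
    spec: ModelSpec
    dropped: list[str] = field(default_factory=list)

    @property
    def colnames(self) -> list[str]:
        return list(self.coef)

    def coef_or_zero(self, name: str) -> float:
        """Coefficient by name; structurally-dropped columns count as zero."""
        if name in self.coef:
            return self.coef[name]
        if name in self.dropped:
            return 0.0
        raise KeyError(name)


@dataclass
class GainProfile:
    """Spiking gains exp(coef) per history lag for one condition."""

    unit_id: str
    condition: str
    model_id: str
    lags_s: np.ndarray
    gain: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    se_log: np.ndarray


def bin_session(session: Session, bin_width: float = 0.25) -> CountSeries:
    """Discretize one session to contiguous half-open count bins.

    Interval label and stress indicator are assigned by bin start time;
    ``in_scope`` marks bins inside analyzed (correct, non-first) trials.
    """
    session.validate()
    start, end = session.span
    n_bins = int(np.ceil((end - start) / bin_width - 1e-9))
    starts = start + bin_width * np.arange(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for st in session.spikes:
        if st.n_spikes == 0:
            continue
        if st.times[0] < start or st.times[-1] >= end + 1e-9:
            raise ValueError(
                f"unit {st.unit_id}: spikes outside session span [{start}, {end})"
            )
        idx = np.minimum(
            ((st.times - start) / bin_width).astype(np.intp), n_bins - 1
        )
        np.add.at(counts, idx, 1)

    labels = np.empty(n_bins, dtype=object)
    labels[:] = "Delay"  # fully overwritten below; intervals tile the span
    for iv in session_intervals(session):
        lo = int(np.ceil((iv.start - start) / bin_width - 1e-9))
        hi = int(np.ceil((iv.end - start) / bin_width - 1e-9))
        labels[lo:hi] = iv.label

    in_scope = np.zeros(n_bins, dtype=bool)
    analyzed = correct_trials(session).trials
    trials = session.trials
    for tr in analyzed:
        j = next(i for i, t in enumerate(trials) if t.trial_index == tr.trial_index)
        if j + 1 < len(trials):
            t_end = trials[j + 1].t_startbox
        else:
            t_end = tr.t_pickup + session.pickup_tail_s
        lo = int(np.ceil((tr.t_startbox - start) / bin_width - 1e-9))
        hi = int(np.ceil((t_end - start) / bin_width - 1e-9))
        in_scope[lo:hi] = True

    s = 1.0 if session.condition == STRESS else 0.0
    return CountSeries(
        bin_width=bin_width,
        starts=starts,
        counts=counts,
        stress=np.full(n_bins, s),
        labels=labels,
        in_scope=in_scope,
        session_id=session.session_id,
    )


def history_matrix(cs: CountSeries, order: int = 10, history_bin: float = 0.25
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Lagged-count columns H[m, k−1] = count of bin m−k, and a validity mask.

    The history bin must be an integer multiple of the observation bin
    (with the default geometry they coincide); lags run over continuous
    session time.  Bins whose full K-lag window precedes the session start
    are marked invalid and are excluded from any likelihood.
    """
    step = history_bin / cs.bin_width
    if abs(step - round(step)) > 1e-9:
        raise ValueError(
            f"history_bin {history_bin} is not an integer multiple of the "
            f"observation bin {cs.bin_width}"
        )
    step = int(round(step))
    n = len(cs.counts)
    H = np.zeros((n, order))
    if step == 1:
        for k in range(1, order + 1):
            H[k:, k - 1] = cs.counts[:-k]
    else:
        # sum the `step` observation bins composing each coarser history bin
        csum = np.concatenate([[0], np.cumsum(cs.counts)])
        for k in range(1, order + 1):
            hi = np.arange(n) - (k - 1) * step
            lo = hi - step
            valid = lo >= 0
            H[valid, k - 1] = csum[hi[valid]] - csum[lo[valid]]
    valid_mask = np.arange(n) >= order * step
    return H, valid_mask


def _interval_dummies(cs: CountSeries, reference: str) -> tuple[np.ndarray, list[str]]:
    labels = [l for l in INTERVAL_LABELS if l != reference]
    cols = np.column_stack([(cs.labels == l).astype(float) for l in labels])
    return cols, [f"B[{l}]" for l in labels]


def _composite_indicator(cs: CountSeries, composite: str) -> np.ndarray:
    members = COMPOSITE_MEMBERS[composite]
    return np.isin(cs.labels, members).astype(float)


def _design_one(cs: CountSeries, spec: ModelSpec) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Full design rows for every bin of one series (no scope masking)."""
    n = len(cs.counts)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["mu"]
    mid = spec.model_id

    if mid in ("1a", "1b", "2", "3"):
        cols.append(cs.stress.astype(float))
        names.append("stress")

    if mid in ("inhom", "1a"):
        d, dn = _interval_dummies(cs, spec.reference_interval)
        cols.append(d)
        names.extend(dn)

    valid = np.ones(n, dtype=bool)
    if mid in ("1a", "1b", "2", "3"):
        H, valid = history_matrix(cs, spec.history_order, spec.history_bin)
        if mid in ("1a", "1b"):
            base = (1.0 - cs.stress)[:, None]
            strs = cs.stress[:, None]
            cols.append(H * base)
            names.extend(f"alpha_{k}" for k in range(1, spec.history_order + 1))
            cols.append(H * strs)
            names.extend(f"eta_{k}" for k in range(1, spec.history_order + 1))
        else:
            comp = spec.target_composite
            E = _composite_indicator(cs, comp)
            cols.insert(1, H)  # gamma right after mu
            names[1:1] = [f"gamma_{k}" for k in range(1, spec.history_order + 1)]
            cols.append(E[:, None])
            names.append(f"I[{comp}]")
            base = ((1.0 - cs.stress) * E)[:, None]
            strs = (cs.stress * E)[:, None]
            cols.append(H * base)
            names.extend(f"alpha_{k}" for k in range(1, spec.history_order + 1))
            cols.append(H * strs)
            names.extend(f"eta_{k}" for k in range(1, spec.history_order + 1))

    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    assert X.shape[1] == len(names)
    return X, names, valid


def build_design(
    series: CountSeries | Sequence[CountSeries], spec: ModelSpec
) -> DesignMatrix:
    """Assemble the likelihood design for one or several sessions.

    Sessions are stacked row-wise (the default joint baseline+stress fit of
    the additive and interaction models).  Columns that are identically
    zero on the retained rows — e.g. the stress-split history columns of a
    single-condition fit — are dropped and recorded; a remaining rank
    deficiency raises, naming the offending columns.
    """
    if isinstance(series, CountSeries):
        series = [series]
    blocks, ys, names = [], [], None
    n_total = 0
    for cs in series:
        X, nm, valid = _design_one(cs, spec)
        if names is None:
            names = nm
        elif nm != names:
            raise ValueError("sessions produced differing design columns")
        rows = cs.in_scope & valid
        blocks.append(X[rows])
        ys.append(np.asarray(cs.counts)[rows])
        n_total += len(cs.counts)
    X = np.vstack(blocks)
    y = np.concatenate(ys)
    if y.size == 0:
        raise ValueError("no in-scope bins: nothing to fit")

    # single-condition fits: a constant stress column duplicates the intercept
    keep = np.ones(X.shape[1], dtype=bool)
    dropped: list[str] = []
    if "stress" in names:
        j = names.index("stress")
        if np.all(X[:, j] == X[0, j]):
            keep[j] = False
    zero = ~np.any(X != 0, axis=0)
    keep &= ~zero
    if not np.all(keep):
        dropped = [n for n, k in zip(names, keep) if not k]
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design is rank-deficient; dependent columns: {bad}")
    return DesignMatrix(
        X=X, y=y, colnames=list(names), spec=spec, dropped=dropped,
        n_total_bins=n_total,
    )


def fit(dm: DesignMatrix, maxiter: int = 100, tol: float = 1e-8) -> FitResult:
    """Poisson maximum likelihood (log link) via IRLS.

    Convergence follows the standard iteratively-reweighted-least-squares
    criterion; the coefficient covariance is the inverse observed (= Fisher,
    for the canonical link) information at the optimum.  Fits with any
    |coefficient| > 15 are flagged degenerate (complete-separation analog)
    and are excluded from population aggregation by the callers.
    """
    y = np.asarray(dm.y, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    model = sm.GLM(y, dm.X, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=tol)
    params = np.asarray(res.params, dtype=float)
    coef = dict(zip(dm.colnames, params))
    se = dict(zip(dm.colnames, np.asarray(res.bse, dtype=float)))
    degenerate = bool(np.any(np.abs(params) > SEPARATION_BOUND))
    return FitResult(
        coef=coef,
        se=se,
        cov=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        deviance=float(res.deviance),
        converged=bool(getattr(res, "converged", True)),
        degenerate=degenerate,
        n_iter=len(getattr(res, "fit_history", {}).get("deviance", [])),
        n_bins=int(y.size),
        spec=dm.spec,
        dropped=list(dm.dropped),
    )


def gain_profile(fr: FitResult, which: str, unit_id: str = "") -> GainProfile:
    """Per-lag spiking gains exp(coef) with 95% Wald CIs.

    ``which`` selects the baseline ("alpha") or stress ("eta") history
    split of models 1a/1b, or the interaction split of models 2/3.
    """
    if which not in ("alpha", "eta"):
        raise ValueError("which must be 'alpha' or 'eta'")
    spec = fr.spec
    names = [f"{which}_{k}" for k in range(1, spec.history_order + 1)]
    missing = [n for n in names if n not in fr.coef and n not in fr.dropped]
    if missing:
        raise ValueError(
            f"model {spec.model_id!r} fit has no columns {missing}; "
            "was it built with history terms?"
        )
    if any(n in fr.dropped for n in names):
        raise ValueError(
            f"the {which} history columns were structurally zero in this fit "
            "(single-condition session); request the other split"
        )
    coef = np.array([fr.coef[n] for n in names])
    se = np.array([fr.se[n] for n in names])
    old = np.seterr(over="ignore")  # degenerate fits can overflow the upper CI
    try:
        ci_lo = np.exp(coef - _Z95 * se)
        ci_hi = np.exp(coef + _Z95 * se)
    finally:
        np.seterr(**old)
    return GainProfile(
        unit_id=unit_id,
        condition="baseline" if which == "alpha" else "stress",
        model_id=spec.model_id,
        lags_s=spec.lags_s,
        gain=np.exp(coef),
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        se_log=se,
    )


def deviance_test(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio (deviance) test of nested CI-GLMs.

    Returns (chi2, df, p).  The reduced model's columns must be a subset of
    the full model's and both must be fit to the same observations; the
    interaction models (2, 3) are not nested in each other and are rejected.
    """
    full_cols = set(full.colnames) | set(full.dropped)
    red_cols = set(reduced.colnames) | set(reduced.dropped)
    if not red_cols <= full_cols:
        raise ValueError(
            "models are not nested (reduced has columns "
            f"{sorted(red_cols - full_cols)} absent from the full model) "
            "and cannot be compared by the deviance test"
        )
    if full.n_bins != reduced.n_bins:
        raise ValueError("models were fit to different numbers of bins")
    chi2 = reduced.deviance - full.deviance
    df = len(full.colnames) - len(reduced.colnames)
    if df <= 0:
        return (max(chi2, 0.0), 0, 1.0)
    p = float(stats.chi2.sf(max(chi2, 0.0), df))
    return (float(max(chi2, 0.0)), df, p)


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (rejected flags, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    from statsmodels.stats.multitest import multipletests

    rej, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rej, p_adj
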