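"""Synthetic T-maze sessions from a known conditional-intensity model.

The generator is the test bed for the whole pipeline: every downstream
stage (binning, design construction, fitting, goodness-of-fit, population
statistics) is validated by recovering the parameters written here.

A unit's spiking follows a log-linear conditional intensity on the 250 ms
observation grid,

    log E[count in bin m] = mu + beta*S + B[interval(m)]
                            + sum_k (gamma_k + scope(m)*(alpha_k or eta_k)) * N_k(m)

where S is the stress indicator of the session, N_k(m) is the spike count
of bin m−k (k = 1..K history lags of width 0.25 s, computed over
continuous session time so lags cross trial and interval boundaries), and
``scope`` is 1 everywhere when ``history_scope`` is None (the additive
models) or the indicator of a composite interval (the interaction models).
Within a bin the intensity is constant and spikes are drawn by Bernoulli
thinning on a 5 ms grid, so a bin's own spikes first enter the history of
the following bin.

Defaults emulate the study conditions: 41 trials per session (the first
always rewarded), delay length 10 s (task range 10–40 s), ~30 s trials,
background rate ≈0.5 Hz, error rates 7% (baseline) vs 35% (stress),
history gains decaying 1.5 → 1.05 over 2.5 s with stress suppressing them
to 0.9×.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .session import (
    BASELINE,
    STRESS,
    COMPOSITE_MEMBERS,
    INTERVAL_LABELS,
    Session,
    SpikeTrain,
    TrialEvents,
    UnitWaveform,
    session_intervals,
)

__all__ = [
    "TruthParams",
    "GeneratorConfig",
    "CohortUnit",
    "decaying_gains",
    "make_trial_plan",
    "simulate_spike_train",
    "simulate_session",
    "simulate_cohort",
]


def decaying_gains(
    g0: float = 1.5, g_inf: float = 1.05, tau_s: float = 0.35,
    order: int = 10, history_bin: float = 0.25,
) -> np.ndarray:
    """Exponentially decaying history gains g_k = g_inf + (g0-g_inf)·e^(−(k−1)Δ/τ)."""
    lags = np.arange(order) * history_bin
    return g_inf + (g0 - g_inf) * np.exp(-lags / tau_s)


@dataclass
class TruthParams:
    """Generating coefficients of one unit (all on the log scale).

    ``mu`` is the log expected count per 250 ms bin in the reference
    interval (Delay) at baseline with empty history.  ``B`` maps interval
    labels to log rate-ratios relative to Delay.  ``alpha``/``eta`` are the
    baseline/stress history log-gains; ``gamma`` is a global history term
    used with ``history_scope`` to emulate the interaction models (when
    ``history_scope`` is None, alpha/eta apply everywhere and gamma is
    typically zero).
    """

    mu: float = float(np.log(0.06))
    beta: float = 0.0
    B: dict[str, float] = field(default_factory=dict)
    alpha: np.ndarray = field(default_factory=lambda: np.log(decaying_gains()))
    eta: np.ndarray = field(default_factory=lambda: np.log(0.9 * decaying_gains()))
    gamma: Optional[np.ndarray] = None
    history_bin: float = 0.25
    order: int = 10
    history_scope: Optional[str] = None  # None, "ExtendedDelay" or "Response"

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.gamma is None:
            self.gamma = np.zeros(self.order)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not (len(self.alpha) == len(self.eta) == len(self.gamma) == self.order):
            raise ValueError(
                f"alpha/eta/gamma must each have length order={self.order}"
            )
        if self.history_bin <= 0:
            raise ValueError("history_bin must be positive")
        if self.history_scope is not None and self.history_scope not in COMPOSITE_MEMBERS:
            raise ValueError(f"history_scope must be a composite label or None")

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "beta": self.beta,
            "B": dict(self.B),
            "alpha": self.alpha.tolist(),
            "eta": self.eta.tolist(),
            "gamma": self.gamma.tolist(),
            "history_bin": self.history_bin,
            "order": self.order,
            "history_scope": self.history_scope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthParams":
        return cls(
            mu=d["mu"], beta=d["beta"], B=dict(d["B"]),
            alpha=np.asarray(d["alpha"]), eta=np.asarray(d["eta"]),
            gamma=np.asarray(d["gamma"]), history_bin=d["history_bin"],
            order=d["order"], history_scope=d["history_scope"],
        )


@dataclass
class GeneratorConfig:
    """Trial structure, noise levels and cohort layout of a simulated study."""

    n_trials: int = 41
    delay_length_s: float = 10.0
    #: (mean, half-width) of uniform duration jitter per interval, seconds
    durations: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Run": (3.0, 1.0),
            "Branch": (2.0, 0.5),
            "Choice": (3.0, 1.0),
            "Reward": (5.0, 1.0),
            "Pickup": (5.0, 1.0),
        }
    )
    error_rate: dict[str, float] = field(
        default_factory=lambda: {BASELINE: 0.07, STRESS: 0.35}
    )
    noise_db: dict[str, float] = field(
        default_factory=lambda: {BASELINE: 60.0, STRESS: 93.0}
    )
    sim_resolution: float = 0.005
    pickup_tail_s: float = 5.0
    seed: int = 0
    n_units: int = 1
    truth: Optional[TruthParams] = None  # shared truth; per-unit override in simulate_cohort

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.delay_length_s <= 0:
            raise ValueError("delay_length_s must be positive")
        for lbl, (m, j) in self.durations.items():
            if m - j <= 0:
                raise ValueError(f"{lbl} duration can reach {m - j} <= 0")
        truth = self.truth or TruthParams()
        if self.sim_resolution > truth.history_bin:
            raise ValueError("sim_resolution must not exceed the history bin")


def make_trial_plan(
    cfg: GeneratorConfig, rng: np.random.Generator, condition: str = BASELINE
) -> list[TrialEvents]:
    """Draw one session's behavioral timeline.

    Arms alternate on correct trials (delayed non-match to position); an
    error repeats the previously visited arm.  Trial 1 is always correct.
    The delay is exactly ``delay_length_s``; the other interval durations
    are uniform around their configured means.
    """
    cfg.validate()
    err = cfg.error_rate.get(condition, 0.0)

    def dur(lbl: str) -> float:
        m, j = cfg.durations[lbl]
        return float(rng.uniform(m - j, m + j))

    trials: list[TrialEvents] = []
    t = 0.0
    visited = rng.choice(["left", "right"])  # arm occupied before trial 1
    for i in range(1, cfg.n_trials + 1):
        correct = True if i == 1 else bool(rng.random() >= err)
        arm = ("left" if visited == "right" else "right") if correct else visited
        t_startbox = t
        t_gate = t_startbox + cfg.delay_length_s
        t_branch = t_gate + dur("Run")
        t_choice = t_branch + dur("Branch")
        if correct:
            t_reward = t_choice + dur("Choice")
            t_pickup = t_reward + dur("Reward")
        else:
            t_reward = None
            t_pickup = t_choice + dur("Choice")
        trials.append(
            TrialEvents(
                trial_index=i, condition=condition, arm=arm, correct=correct,
                t_startbox=t_startbox, t_gate=t_gate, t_branch=t_branch,
                t_choice=t_choice, t_pickup=t_pickup, t_reward=t_reward,
            )
        )
        visited = arm
        t = t_pickup + dur("Pickup")
    return trials


def _bin_labels_and_scope(
    trials: list[TrialEvents], truth: TruthParams, pickup_tail_s: float,
    bin_width: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-observation-bin interval label index, scope flag, and bin starts."""
    sess = Session(
        session_id="_plan", condition=trials[0].condition, noise_db=0.0,
        delay_length_s=0.0, trials=trials, pickup_tail_s=pickup_tail_s,
    )
    intervals = session_intervals(sess)
    start, end = sess.span
    n_bins = int(np.ceil((end - start) / bin_width - 1e-9))
    starts = start + bin_width * np.arange(n_bins)
    label_idx = np.zeros(n_bins, dtype=np.intp)
    for iv in intervals:
        lo = int(np.ceil((iv.start - start) / bin_width - 1e-9))
        hi = int(np.ceil((iv.end - start) / bin_width - 1e-9))
        label_idx[lo:hi] = INTERVAL_LABELS.index(iv.label)
    if truth.history_scope is None:
        scope = np.ones(n_bins)
    else:
        members = [INTERVAL_LABELS.index(l) for l in COMPOSITE_MEMBERS[truth.history_scope]]
        scope = np.isin(label_idx, members).astype(float)
    return label_idx, scope, starts


def simulate_spike_train(
    plan: list[TrialEvents],
    truth: TruthParams,
    condition: str,
    rng: np.random.Generator,
    sim_resolution: float = 0.005,
    pickup_tail_s: float = 5.0,
    unit_id: str = "u0",
) -> SpikeTrain:
    """Simulate one unit's spikes over a planned session.

    The intensity is evaluated once per 250 ms observation bin from the
    counts of the previous K bins, then thinned on the fine grid.  Raises
    if the per-step spike probability reaches 1 (intensity too high for
    ``sim_resolution``, or the self-exciting regime has gone unstable).
    """
    if sim_resolution > truth.history_bin:
        raise ValueError("sim_resolution must not exceed the history bin")
    K = truth.order
    bw = truth.history_bin
    n_fine = int(round(bw / sim_resolution))
    S = 1.0 if condition == STRESS else 0.0
    hist_coef = (truth.eta if S else truth.alpha)

    label_idx, scope, starts = _bin_labels_and_scope(
        plan, truth, pickup_tail_s, bw
    )
    B_by_idx = np.array(
        [truth.B.get(lbl, 0.0) for lbl in INTERVAL_LABELS], dtype=float
    )
    base = truth.mu + truth.beta * S + B_by_idx[label_idx]

    n_bins = starts.size
    recent = np.zeros(K)  # recent[k-1] = count of bin m-k
    times: list[float] = []
    for m in range(n_bins):
        log_lam = base[m] + truth.gamma @ recent + scope[m] * (hist_coef @ recent)
        lam_bin = np.exp(log_lam)  # expected count in this bin
        p = lam_bin / n_fine
        if p >= 1.0:
            raise ValueError(
                f"spike probability per step reached {p:.3f} at bin {m}; "
                "reduce sim_resolution or the intensity parameters"
            )
        c = int(rng.binomial(n_fine, p))
        if c:
            steps = rng.choice(n_fine, size=c, replace=False)
            steps.sort()
            t0 = starts[m]
            times.extend(t0 + (steps + 0.5) * sim_resolution)
        recent[1:] = recent[:-1]
        recent[0] = c
    t = np.asarray(times)
    span_end = plan[-1].t_pickup + pickup_tail_s
    return SpikeTrain(unit_id=unit_id, times=t[t < span_end], session_id="")


def simulate_session(
    cfg: GeneratorConfig,
    truth: TruthParams,
    condition: str,
    rng: np.random.Generator,
    session_id: str,
    unit_id: str = "u0",
    plan: Optional[list[TrialEvents]] = None,
) -> Session:
    """One session (plan + one unit's spikes) under ``condition``."""
    if plan is None:
        plan = make_trial_plan(cfg, rng, condition)
    st = simulate_spike_train(
        plan, truth, condition, rng,
        sim_resolution=cfg.sim_resolution,
        pickup_tail_s=cfg.pickup_tail_s,
        unit_id=unit_id,
    )
    sess = Session(
        session_id=session_id,
        condition=condition,
        noise_db=cfg.noise_db.get(condition, 0.0),
        delay_length_s=cfg.delay_length_s,
        trials=plan,
        spikes=[SpikeTrain(unit_id=unit_id, times=st.times, session_id=session_id)],
        waveforms={
            unit_id: UnitWaveform(unit_id=unit_id, pp_duration_us=float(rng.uniform(220, 450)))
        },
        pickup_tail_s=cfg.pickup_tail_s,
    )
    sess.validate()
    return sess


@dataclass
class CohortUnit:
    """One simulated unit: its generating truth and its two sessions."""

    unit_id: str
    truth: TruthParams
    baseline: Session
    stress: Session


def simulate_cohort(
    cfg: GeneratorConfig,
    truths: Optional[list[TruthParams]] = None,
    max_resim: int = 10,
) -> list[CohortUnit]:
    """Simulate ``cfg.n_units`` units, one baseline + one stress session each.

    Per-unit substreams are spawned deterministically from ``cfg.seed`` so a
    cohort is reproducible and units are independent.

    The log-linear self-exciting intensity has a small probability of a
    runaway cascade on any finite session; such realizations are rejected
    and the unit is redrawn from a deterministically spawned fresh
    substream (at most ``max_resim`` times, so cohorts condition on
    non-explosive realizations; set ``max_resim=0`` to propagate the
    instability error instead).
    """
    if truths is None:
        truths = [cfg.truth or TruthParams() for _ in range(cfg.n_units)]
    if len(truths) != cfg.n_units:
        raise ValueError("need one TruthParams per unit")
    units: list[CohortUnit] = []
    root = np.random.SeedSequence(cfg.seed)
    for j, (truth, child) in enumerate(zip(truths, root.spawn(cfg.n_units))):
        uid = f"u{j:03d}"
        for attempt in range(max_resim + 1):
            rng = np.random.Generator(np.random.PCG64(child))
            try:
                base = simulate_session(cfg, truth, BASELINE, rng,
                                        f"{uid}-base", unit_id=uid)
                strs = simulate_session(cfg, truth, STRESS, rng,
                                        f"{uid}-stress", unit_id=uid)
                break
            except ValueError:
                if attempt == max_resim:
                    raise
                child = child.spawn(1)[0]
        units.append(CohortUnit(unit_id=uid, truth=truth, baseline=base, stress=strs))
    return units
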