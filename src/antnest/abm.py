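"""Finite-population stochastic twin of the mean-field model.

Every term of the mean-field equations becomes one of fifteen Poisson event
channels; each event moves exactly one ant between compartments.  The
reference engine is exact event-driven simulation (exponential waiting times
from the total rate, channel chosen proportionally to its rate).  A
fixed-step engine - per-ant Bernoulli transitions with probability
``rate * dt`` per step - is provided to cross-validate it.

A run terminates when either site's vote count reaches the quorum threshold
(recording which site), when every ant is back in the home nest (the
absorbing "unsuccessful emigration" state, reachable only through leakage),
or at ``t_max`` (censored; reported separately and expected to be rare).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import _kernels as K
from ._kernels import CHANNEL_DST, CHANNEL_NAMES, CHANNEL_SRC
from .params import ModelParams, ParameterError

__all__ = [
    "AbmCounts",
    "EventChannel",
    "RunOutcome",
    "COUNT_FIELDS",
    "make_initial_counts",
    "event_rates",
    "gillespie_run",
    "gillespie_run_logged",
    "discrete_time_run",
    "integer_votes",
]

COUNT_FIELDS = (
    "n_lc", "n_hc", "n_lpcom", "n_hpvis", "n_lgcom",
    "n_hgcom", "n_lprec", "n_lgrec", "n_hgrec",
)

Result = Literal["good_quorum", "poor_quorum", "unsuccessful", "censored"]
_CODE_TO_RESULT: dict[int, Result] = {
    K.GOOD_QUORUM: "good_quorum",
    K.POOR_QUORUM: "poor_quorum",
    K.UNSUCCESSFUL: "unsuccessful",
    K.CENSORED: "censored",
}


@dataclass(frozen=True)
class AbmCounts:
    """Integer occupancies of the nine compartments (sum to N)."""

    n_lc: int
    n_hc: int
    n_lpcom: int
    n_hpvis: int
    n_lgcom: int
    n_hgcom: int
    n_lprec: int
    n_lgrec: int
    n_hgrec: int

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in COUNT_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray) -> "AbmCounts":
        a = np.asarray(a)
        if a.shape != (9,):
            raise ValueError(f"count array must have shape (9,), got {a.shape}")
        return cls(*(int(round(v)) for v in a))

    @property
    def total(self) -> int:
        return sum(getattr(self, f) for f in COUNT_FIELDS)


@dataclass(frozen=True)
class EventChannel:
    """One of the fifteen Poisson transition channels."""

    name: str
    rate: float
    source: str  # count field losing one ant
    dest: str    # count field gaining one ant


@dataclass(frozen=True)
class RunOutcome:
    """Result of a single stochastic run."""

    result: Result
    t_event: float
    n_events: int
    seed: int


def integer_votes(counts: AbmCounts | np.ndarray) -> tuple[int, int]:
    """Integer vote counts ``(v_good, v_poor)`` for a count state."""
    c = counts.to_array() if isinstance(counts, AbmCounts) else np.asarray(counts)
    v_good = c[K.LGCOM] + c[K.HGCOM] + c[K.LGREC] + c[K.HGREC]
    v_poor = c[K.LPCOM] + c[K.LPREC] + c[K.HPVIS]
    return int(round(float(v_good))), int(round(float(v_poor)))


def make_initial_counts(
    params: ModelParams,
    rounding: Literal["exact", "largest_remainder"] = "exact",
) -> AbmCounts:
    """Integer initial occupancies matching the mean-field initial condition.

    The exact mode requires every compartment target ``N*L*(1-z)``,
    ``N*L*z/2``, ``N*H*(1-z)``, ``N*H*z/2`` to be an integer and raises
    otherwise - parameter values are expected to be chosen so the split is
    exact.  ``rounding="largest_remainder"`` opts into apportioning the
    residual ants to the largest fractional parts instead.
    """
    N, H, L, z = params.N, params.H, params.L, params.z
    targets = np.array([
        N * L * (1 - z),      # n_lc
        N * H * (1 - z),      # n_hc
        N * L * z / 2,        # n_lpcom
        N * H * z / 2,        # n_hpvis
        N * L * z / 2,        # n_lgcom
        N * H * z / 2,        # n_hgcom
        0.0, 0.0, 0.0,        # recruiters
    ])
    if rounding == "exact":
        frac = np.abs(targets - np.round(targets))
        if np.any(frac > 1e-9):
            bad = {COUNT_FIELDS[i]: targets[i] for i in np.flatnonzero(frac > 1e-9)}
            raise ParameterError(
                f"initial compartments are not integers for N={N}, H={H}, "
                f"z={z}: {bad}; choose parameters with an exact split or use "
                "rounding='largest_remainder'"
            )
        counts = np.round(targets).astype(int)
    elif rounding == "largest_remainder":
        floors = np.floor(targets).astype(int)
        short = int(round(targets.sum())) - floors.sum()
        order = np.argsort(-(targets - floors))
        counts = floors.copy()
        counts[order[:short]] += 1
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    if counts.sum() != N:
        raise ParameterError(
            f"initial counts sum to {counts.sum()} != N={N} (H={H}, z={z})"
        )
    return AbmCounts(*(int(v) for v in counts))


def event_rates(counts: AbmCounts, params: ModelParams) -> list[EventChannel]:
    """The fifteen event channels with their current rates.

    Recruitment channels are mass-action normalized by the total colony
    size N; in the large-N limit the per-capita rates reproduce the
    mean-field equations.
    """
    c = counts.to_array()
    r = np.empty(K.N_CHANNELS)
    K.channel_rates(c, params.alpha_p, params.alpha_g, params.alpha_s,
                    params.alpha_leak, float(params.N), r)
    return [
        EventChannel(
            name=CHANNEL_NAMES[k],
            rate=float(r[k]),
            source=COUNT_FIELDS[CHANNEL_SRC[k]],
            dest=COUNT_FIELDS[CHANNEL_DST[k]],
        )
        for k in range(K.N_CHANNELS)
    ]


def _validate_run_setup(params: ModelParams, counts: AbmCounts) -> float:
    quorum = params.quorum_fraction * params.N
    v_good, v_poor = integer_votes(counts)
    if max(v_good, v_poor) >= quorum:
        raise ParameterError(
            f"quorum threshold {quorum} is already met at t=0 "
            f"(initial votes good={v_good}, poor={v_poor})"
        )
    return quorum


def gillespie_run(
    params: ModelParams,
    seed: int,
    t_max: float = 1e5,
    counts0: AbmCounts | None = None,
) -> RunOutcome:
    """One exact event-driven run (the reference stochastic engine)."""
    counts0 = make_initial_counts(params) if counts0 is None else counts0
    quorum = _validate_run_setup(params, counts0)
    seeds = np.array([seed], dtype=np.int64)
    codes, times, n_events = K.ssa_batch(
        counts0.to_array(), params.alpha_p, params.alpha_g, params.alpha_s,
        params.alpha_leak, float(params.N), quorum, t_max, seeds,
    )
    return RunOutcome(
        result=_CODE_TO_RESULT[int(codes[0])],
        t_event=float(times[0]),
        n_events=int(n_events[0]),
        seed=int(seed),
    )


def gillespie_run_logged(
    params: ModelParams,
    seed: int,
    t_max: float = 1e5,
    counts0: AbmCounts | None = None,
) -> tuple[RunOutcome, pd.DataFrame]:
    """Event-driven run in pure Python with a full event log.

    Draws the identical random stream as :func:`gillespie_run` (verified
    bit-for-bit in the test suite), so a compiled run can be replayed with
    its per-event history.  The log has one row per event: time, channel
    name, and the nine counts after the event.
    """
    counts0 = make_initial_counts(params) if counts0 is None else counts0
    quorum = _validate_run_setup(params, counts0)
    rng = np.random.RandomState(seed)
    c = counts0.to_array()
    n = float(params.N)
    t = 0.0
    rows: list[tuple] = []
    r = np.empty(K.N_CHANNELS)
    result: Result
    while True:
        K.channel_rates(c, params.alpha_p, params.alpha_g, params.alpha_s,
                        params.alpha_leak, n, r)
        # sequential accumulation, bit-identical to the compiled engine
        total = 0.0
        for v in r:
            total += float(v)
        if total <= 0.0:
            result = "unsuccessful" if c[K.LC] + c[K.HC] >= n else "censored"
            break
        u1 = 1.0 - rng.random_sample()
        t_next = t - np.log(u1) / total
        if t_next > t_max:
            result, t = "censored", t_max
            break
        t = t_next
        u2 = rng.random_sample() * total
        k = int(np.searchsorted(np.cumsum(r), u2, side="right"))
        k = min(k, K.N_CHANNELS - 1)
        c[CHANNEL_SRC[k]] -= 1.0
        c[CHANNEL_DST[k]] += 1.0
        rows.append((t, CHANNEL_NAMES[k], *(int(v) for v in c)))
        v_good, v_poor = integer_votes(c)
        if v_good >= quorum:
            result = "good_quorum"
            break
        if v_poor >= quorum:
            result = "poor_quorum"
            break
    log = pd.DataFrame(rows, columns=["time", "channel", *COUNT_FIELDS])
    outcome = RunOutcome(result=result, t_event=float(t),
                         n_events=len(rows), seed=int(seed))
    return outcome, log


def discrete_time_run(
    params: ModelParams,
    dt: float,
    seed: int,
    t_max: float = 1e5,
    counts0: AbmCounts | None = None,
) -> RunOutcome:
    """Fixed-step cross-validation engine (per-ant Bernoulli updates).

    Requires every per-ant per-step transition probability to stay below
    0.1 so that the Bernoulli approximation of the Poisson channels is
    accurate; raises naming the offending channel otherwise.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    counts0 = make_initial_counts(params) if counts0 is None else counts0
    quorum = _validate_run_setup(params, counts0)
    # Worst-case per-ant rates per channel family; recruitment is bounded by
    # (N-1)/N < 1 recruiter-fraction.
    bounds = {
        "recruitment (recruiter fraction <= 1)": 1.0,
        "convert poor (alpha_p + alpha_leak)": params.alpha_p + params.alpha_leak,
        "convert good (alpha_g + alpha_leak)": params.alpha_g + params.alpha_leak,
        "switch (alpha_s + alpha_leak)": params.alpha_s + params.alpha_leak,
    }
    for name, rate in bounds.items():
        if rate * dt >= 0.1:
            raise ValueError(
                f"dt={dt} too large: per-ant step probability {rate * dt:.3f} "
                f">= 0.1 for channel {name}"
            )
    seeds = np.array([seed], dtype=np.int64)
    codes, times, n_steps = K.discrete_batch(
        counts0.to_array(), params.alpha_p, params.alpha_g, params.alpha_s,
        params.alpha_leak, float(params.N), quorum, dt, t_max, seeds,
    )
    return RunOutcome(
        result=_CODE_TO_RESULT[int(codes[0])],
        t_event=float(times[0]),
        n_events=int(n_steps[0]),
        seed=int(seed),
    )
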