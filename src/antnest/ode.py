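"""Mean-field (infinite-population) model of two-site nest choice.

Nine compartments track the fractions of the colony by acceptance threshold
(low ants accept both sites, high ants only the good one), location (home
nest, poor site, good site) and activity (committed, visiting, recruiting).
Recruitment is mass-action: ants at home are drawn to a site at a rate equal
to the fraction of the colony recruiting for it.  Committed ants convert to
recruiters at ``alpha_p`` / ``alpha_g``, high-threshold visitors at the poor
site defect to the good one at ``alpha_s``, and any ant away from home
abandons its site at ``alpha_leak``.

Two exact conservation laws hold: the low-threshold compartments always sum
to ``L`` and the high-threshold ones to ``H``, so the system is effectively
seven-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _kernels as K
from .params import ModelParams, ParameterError

__all__ = [
    "OdeState",
    "Trajectory",
    "VotePair",
    "IntegrationError",
    "STATE_FIELDS",
    "make_initial_state",
    "ode_rhs",
    "integrate_euler",
    "votes",
    "ode_quorum_time",
]

STATE_FIELDS = (
    "x_lc", "x_hc", "x_lpcom", "x_hpvis", "x_lgcom",
    "x_hgcom", "x_lprec", "x_lgrec", "x_hgrec",
)


class IntegrationError(RuntimeError):
    """The integrator left the physical region (step size too large)."""


class VotePair(NamedTuple):
    """Vote fractions for the two candidate sites.

    A site's vote counts every ant present there: committed ants and
    recruiters, and - for the poor site - uncommitted high-threshold
    visitors.
    """

    v_good: float
    v_poor: float


@dataclass(frozen=True)
class OdeState:
    """The nine compartment fractions of the mean-field model."""

    x_lc: float
    x_hc: float
    x_lpcom: float
    x_hpvis: float
    x_lgcom: float
    x_hgcom: float
    x_lprec: float
    x_lgrec: float
    x_hgrec: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray) -> "OdeState":
        a = np.asarray(a, dtype=float)
        if a.shape != (9,):
            raise ValueError(f"state array must have shape (9,), got {a.shape}")
        return cls(*a)

    @property
    def low_sum(self) -> float:
        """Total low-threshold fraction (conserved, equals L)."""
        return self.x_lc + self.x_lpcom + self.x_lprec + self.x_lgcom + self.x_lgrec

    @property
    def high_sum(self) -> float:
        """Total high-threshold fraction (conserved, equals H)."""
        return self.x_hc + self.x_hpvis + self.x_hgcom + self.x_hgrec


@dataclass(frozen=True)
class Trajectory:
    """A decimated Euler trajectory plus full-resolution quorum info."""

    times: np.ndarray          # (n,) strictly increasing, starts at 0
    states: np.ndarray         # (n, 9)
    quorum_fraction: float | None = None
    quorum_time: float | None = None    # earliest full-resolution crossing
    quorum_site: str | None = None      # "good" | "poor" | None

    @property
    def v_good(self) -> np.ndarray:
        s = self.states
        return s[:, K.LGCOM] + s[:, K.HGCOM] + s[:, K.LGREC] + s[:, K.HGREC]

    @property
    def v_poor(self) -> np.ndarray:
        s = self.states
        return s[:, K.LPCOM] + s[:, K.LPREC] + s[:, K.HPVIS]

    def state_at(self, i: int) -> OdeState:
        return OdeState.from_array(self.states[i])


def make_initial_state(params: ModelParams) -> OdeState:
    """Initial condition: scouts split equally between the two new sites.

    A fraction ``z`` of each threshold class is out scouting at t = 0, half
    at each site; low-threshold scouts are committed, high-threshold scouts
    at the poor site are uncommitted visitors.  No one is recruiting yet.
    """
    H, L, z = params.H, params.L, params.z
    return OdeState(
        x_lc=L * (1.0 - z),
        x_hc=H * (1.0 - z),
        x_lpcom=L * z / 2.0,
        x_hpvis=H * z / 2.0,
        x_lgcom=L * z / 2.0,
        x_hgcom=H * z / 2.0,
        x_lprec=0.0,
        x_lgrec=0.0,
        x_hgrec=0.0,
    )


def ode_rhs(state: OdeState | np.ndarray, params: ModelParams) -> np.ndarray:
    """Time derivative of the nine compartment fractions."""
    c = state.to_array() if isinstance(state, OdeState) else np.asarray(state, float)
    out = np.empty(9)
    K.rhs(c, params.alpha_p, params.alpha_g, params.alpha_s, params.alpha_leak, out)
    return out


def votes(state: OdeState | np.ndarray) -> VotePair:
    """Vote fractions (good, poor) for a state."""
    c = state.to_array() if isinstance(state, OdeState) else np.asarray(state, float)
    v_good = c[K.LGCOM] + c[K.HGCOM] + c[K.LGREC] + c[K.HGREC]
    v_poor = c[K.LPCOM] + c[K.LPREC] + c[K.HPVIS]
    return VotePair(float(v_good), float(v_poor))


def integrate_euler(
    params: ModelParams,
    dt: float = 0.001,
    t_max: float = 100.0,
    stride: int = 100,
    quorum_fraction: float | None = None,
    negativity_tol: float = 1e-9,
) -> Trajectory:
    """Forward-Euler integration from the model initial condition.

    Parameters
    ----------
    dt, t_max : float
        Step size and horizon; the reference resolution is ``dt = 0.001``.
    stride : int
        Keep every ``stride``-th step in the returned trajectory (the final
        state is always kept).  Quorum detection runs at full resolution.
    quorum_fraction : float, optional
        Vote fraction at which a site becomes quorate; defaults to
        ``params.quorum_fraction``.
    negativity_tol : float
        Largest negative excursion tolerated before the run is rejected as a
        step-size failure.  The exact dynamics preserve positivity, so any
        sizeable undershoot means ``dt`` is too large.  Surviving round-off
        excursions are clipped to zero in the stored states.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if t_max < dt:
        raise ValueError(f"t_max must be >= dt, got {t_max}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    qf = params.quorum_fraction if quorum_fraction is None else quorum_fraction
    c0 = make_initial_state(params).to_array()
    _validate_quorum_at_start(votes(c0), qf)
    n_steps = int(round(t_max / dt))
    times, states, t_q, site, min_comp = K.euler_integrate(
        c0, params.alpha_p, params.alpha_g, params.alpha_s, params.alpha_leak,
        dt, n_steps, stride, qf,
    )
    if min_comp < -negativity_tol:
        raise IntegrationError(
            f"compartment reached {min_comp:.3e} (< -{negativity_tol:.1e}); "
            f"decrease dt={dt}"
        )
    states = np.clip(states, 0.0, None)
    return Trajectory(
        times=times,
        states=states,
        quorum_fraction=qf,
        quorum_time=None if t_q < 0 else float(t_q),
        quorum_site={1: "good", -1: "poor", 0: None}[site],
    )


def _validate_quorum_at_start(v0: VotePair, quorum_fraction: float,
                              allow_initial: bool = False) -> None:
    if max(v0.v_good, v0.v_poor) >= quorum_fraction and not allow_initial:
        raise ParameterError(
            f"quorum_fraction={quorum_fraction} is already met at t=0 "
            f"(initial votes {v0}); a sweep over such configurations is "
            "meaningless - raise the threshold or pass allow_initial=True"
        )


def ode_quorum_time(
    traj: Trajectory,
    quorum_fraction: float,
    allow_initial: bool = False,
) -> tuple[float, str] | None:
    """Earliest stored time at which either site's vote reaches the quorum.

    Returns ``(time, site)`` with site ``"good"`` or ``"poor"``, or ``None``
    if the quorum is never reached within the trajectory.  Resolution is the
    trajectory's stored grid; :func:`integrate_euler` performs the same
    detection at full step resolution and stores it on the trajectory.
    """
    vg, vp = traj.v_good, traj.v_poor
    _validate_quorum_at_start(VotePair(vg[0], vp[0]), quorum_fraction, allow_initial)
    hit = (vg >= quorum_fraction) | (vp >= quorum_fraction)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return None
    i = int(idx[0])
    site = "good" if vg[i] >= quorum_fraction else "poor"
    return float(traj.times[i]), site
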