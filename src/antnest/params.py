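"""Validated parameter records for the nest-choice models.

Two records cover the whole package: :class:`ModelParams` for the two-site
(good vs. poor) choice models, and :class:`CohesionParams` for the multi-site
equal-quality emigration model.  Time is measured in units of the recruiting
rate per recruiter-recruitee pair, which is fixed at 1; every rate constant is
expressed in that unit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import InitVar, dataclass
from typing import Any

__all__ = [
    "ParameterError",
    "ModelParams",
    "CohesionParams",
    "PRESETS",
    "get_preset",
]


class ParameterError(ValueError):
    """A parameter record violates a model constraint."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and population composition for the two-site model.

    Parameters
    ----------
    H : float
        Fraction of high-threshold ants (accept only the good site), in [0, 1].
        The low-threshold fraction is ``L = 1 - H``.
    z : float
        Initial scout fraction in [0, 1); scouts split equally between the
        two new sites at t = 0.
    alpha_p, alpha_g : float
        Rate at which an ant committed to the poor / good site converts into
        a recruiter.
    alpha_s : float
        Rate at which a high-threshold visitor at the poor site switches to
        the good site.
    alpha_leak : float
        Rate at which any ant away from the home nest abandons its site and
        returns home.
    N : int
        Colony size (finite-population model only; the ODE is density-based).
    quorum_fraction : float
        Quorum threshold as a fraction of ``N``, in (0, 1].
    alpha : float, optional
        Convenience init-only argument setting ``alpha_p = alpha_g = alpha``
        jointly (the symmetric-conversion case).
    """

    H: float = 0.2
    z: float = 0.3
    alpha_p: float = 0.1
    alpha_g: float = 0.1
    alpha_s: float = 0.1
    alpha_leak: float = 0.05
    N: int = 100
    quorum_fraction: float = 0.5
    alpha: InitVar[float | None] = None

    def __post_init__(self, alpha: float | None) -> None:
        if alpha is not None:
            _check(alpha >= 0.0, f"alpha must be >= 0, got {alpha}")
            object.__setattr__(self, "alpha_p", float(alpha))
            object.__setattr__(self, "alpha_g", float(alpha))
        _check(0.0 <= self.H <= 1.0, f"H must be in [0, 1], got {self.H}")
        _check(0.0 <= self.z < 1.0, f"z must be in [0, 1), got {self.z}")
        for name in ("alpha_p", "alpha_g", "alpha_s", "alpha_leak"):
            v = getattr(self, name)
            _check(v >= 0.0, f"{name} must be >= 0, got {v}")
        _check(
            isinstance(self.N, int) and not isinstance(self.N, bool) and self.N >= 1,
            f"N must be a positive integer, got {self.N!r}",
        )
        _check(
            0.0 < self.quorum_fraction <= 1.0,
            f"quorum_fraction must be in (0, 1], got {self.quorum_fraction}",
        )

    @property
    def L(self) -> float:
        """Fraction of low-threshold ants, ``1 - H``."""
        return 1.0 - self.H

    @property
    def quorum_count(self) -> float:
        """Quorum threshold in numbers of ants, ``quorum_fraction * N``."""
        return self.quorum_fraction * self.N

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced.

        Accepts the ``alpha`` shorthand to set both conversion rates.
        """
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def label(self) -> str:
        """Compact human-readable identifier used in output tables."""
        return (
            f"H={self.H:g},z={self.z:g},ap={self.alpha_p:g},ag={self.alpha_g:g},"
            f"as={self.alpha_s:g},al={self.alpha_leak:g},N={self.N},"
            f"q={self.quorum_fraction:g}"
        )


@dataclass(frozen=True)
class CohesionParams:
    """Parameters for the multi-site equal-quality emigration model.

    All sites are equally acceptable, so every ant behaves as low-threshold
    (H = 0) and site switching is off (alpha_s = 0).  The run finishes when
    ``finish_fraction * N`` ants are settled at new sites.
    """

    N: int = 100
    n_nest: int = 2
    z: float = 0.12
    alpha: float = 0.1
    alpha_leak: float = 0.05
    finish_fraction: float = 0.9

    def __post_init__(self) -> None:
        _check(
            isinstance(self.N, int) and not isinstance(self.N, bool) and self.N >= 1,
            f"N must be a positive integer, got {self.N!r}",
        )
        _check(
            isinstance(self.n_nest, int) and self.n_nest >= 2,
            f"n_nest must be an integer >= 2, got {self.n_nest!r}",
        )
        _check(0.0 <= self.z < 1.0, f"z must be in [0, 1), got {self.z}")
        _check(self.alpha >= 0.0, f"alpha must be >= 0, got {self.alpha}")
        _check(self.alpha_leak >= 0.0, f"alpha_leak must be >= 0, got {self.alpha_leak}")
        _check(
            0.0 < self.finish_fraction <= 1.0,
            f"finish_fraction must be in (0, 1], got {self.finish_fraction}",
        )

    @property
    def finish_count(self) -> float:
        """Emigrant count at which a run counts as finished."""
        return self.finish_fraction * self.N

    def replace(self, **changes: Any) -> "CohesionParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def label(self) -> str:
        return (
            f"N={self.N},nnest={self.n_nest},z={self.z:g},a={self.alpha:g},"
            f"al={self.alpha_leak:g},f={self.finish_fraction:g}"
        )


# Named presets.  "paper-default" is the baseline of the numerical
# experiments (N=100, quorum 0.5N, alpha=alpha_s=0.1, alpha_leak=0.05,
# H=0.2, z=0.3); "pratt-derived" rescales the tandem-running field estimates
# of Pratt and colleagues into the unit-recruiting-rate time unit
# (alpha ~ 0.5, alpha_s ~ 0.25).
PRESETS: dict[str, ModelParams] = {
    "paper-default": ModelParams(),
    "pratt-derived": ModelParams(alpha=0.5, alpha_s=0.25),
}


def get_preset(name: str) -> ModelParams:
    """Look up a named parameter preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
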