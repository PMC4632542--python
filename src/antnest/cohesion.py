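"""Speed-cohesion experiments: emigration to several equally good sites.

When all candidate sites are equal in quality every ant accepts the first
site it reaches, which is the H = 0, alpha_s = 0 special case of the main
model generalized to ``n_nest`` site compartment pairs (committed +
recruiting per site).  There is no quorum rule here: a run finishes when
``finish_fraction * N`` ants (0.9 N by default) are settled at new sites,
at time ``T_f``.  Cohesion is one minus the normalized Shannon entropy of
the final distribution of emigrants over sites::

    C = 1 - ( -sum_i p_i log p_i ) / log(n_nest)

so C = 0 when the colony splits evenly over all sites and C = 1 when it
ends up in a single site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from . import _kernels as K
from .experiments import ci_halfwidth, derive_seeds
from .params import CohesionParams, ParameterError

__all__ = [
    "CohesionCounts",
    "CohesionOutcome",
    "CohesionBatchSummary",
    "cohesion_index",
    "make_cohesion_initial",
    "cohesion_run",
    "cohesion_batch",
]

Result = Literal["finished", "unsuccessful", "censored"]
_CODE_TO_RESULT: dict[int, Result] = {
    K.FINISHED: "finished",
    K.UNSUCCESSFUL: "unsuccessful",
    K.CENSORED: "censored",
}


@dataclass(frozen=True)
class CohesionCounts:
    """Occupancies for the multi-site model."""

    n_home: int
    committed: tuple[int, ...]   # per site
    recruiting: tuple[int, ...]  # per site

    @property
    def total(self) -> int:
        return self.n_home + sum(self.committed) + sum(self.recruiting)


@dataclass(frozen=True)
class CohesionOutcome:
    """Result of one multi-site emigration run."""

    result: Result
    T_f: float                 # time the finish rule was met (or stop time)
    site_counts: np.ndarray    # committed + recruiting per site at T_f
    C: float                   # nan unless finished
    seed: int


@dataclass(frozen=True)
class CohesionBatchSummary:
    """Aggregates over finished runs (unsuccessful/censored excluded)."""

    params_id: str
    n_runs_requested: int
    n_finished: int
    n_unsuccessful: int
    n_censored: int
    Tf_mean: float
    Tf_ci_halfwidth: float
    C_mean: float
    C_ci_halfwidth: float

    def __post_init__(self) -> None:
        total = self.n_finished + self.n_unsuccessful + self.n_censored
        if total != self.n_runs_requested:
            raise ValueError(
                f"run accounting broken: {self.n_finished}+{self.n_unsuccessful}"
                f"+{self.n_censored} != {self.n_runs_requested}"
            )


def cohesion_index(p: Sequence[float]) -> float:
    """Cohesion of an occupancy distribution over sites.

    ``p`` must be a normalized probability vector of length >= 2; zero
    entries contribute nothing to the entropy.  Natural logarithms are used
    (the base cancels in the normalization).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError(f"p must be a vector of length >= 2, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("p must be non-negative")
    if not math.isclose(float(p.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"p must sum to 1, got {p.sum()}")
    pos = p[p > 0]
    entropy = float(-(pos * np.log(pos)).sum())
    return 1.0 - entropy / math.log(p.size)


def make_cohesion_initial(params: CohesionParams) -> CohesionCounts:
    """Scouts split equally over the sites; everyone else at home.

    ``N * z`` must divide evenly by ``n_nest`` (and be an integer); this is
    what ties usable ``z`` values to the site count.
    """
    N, z, k = params.N, params.z, params.n_nest
    scouts = N * z
    if abs(scouts - round(scouts)) > 1e-9:
        raise ParameterError(f"N*z = {scouts} is not an integer (N={N}, z={z})")
    scouts = int(round(scouts))
    if scouts % k != 0:
        raise ParameterError(
            f"N*z = {scouts} scouts cannot be split equally over {k} sites"
        )
    per_site = scouts // k
    return CohesionCounts(
        n_home=N - scouts,
        committed=(per_site,) * k,
        recruiting=(0,) * k,
    )


def cohesion_run(
    params: CohesionParams,
    seed: int,
    t_max: float = 1e5,
) -> CohesionOutcome:
    """One event-driven multi-site run.

    The cohesion index is computed from the site occupancies at ``T_f``
    normalized over the emigrants (ants at new sites), so that the
    distribution sums to one even though up to ``(1 - finish_fraction) N``
    ants may still be at home.
    """
    init = make_cohesion_initial(params)
    codes, times, occupancy = K.cohesion_batch(
        init.n_home,
        np.array(init.committed, dtype=np.float64),
        np.array(init.recruiting, dtype=np.float64),
        params.alpha, params.alpha_leak, float(params.N),
        params.finish_count, t_max,
        np.array([seed], dtype=np.int64),
    )
    result = _CODE_TO_RESULT[int(codes[0])]
    occ = occupancy[0]
    C = cohesion_index(occ / occ.sum()) if result == "finished" else float("nan")
    return CohesionOutcome(
        result=result,
        T_f=float(times[0]),
        site_counts=occ,
        C=C,
        seed=int(seed),
    )


def cohesion_batch(
    params: CohesionParams,
    n_runs: int,
    master_seed: int,
    t_max: float = 1e5,
) -> CohesionBatchSummary:
    """Mean finish time and cohesion over many independent runs."""
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    init = make_cohesion_initial(params)
    seeds = derive_seeds(master_seed, n_runs)
    codes, times, occupancy = K.cohesion_batch(
        init.n_home,
        np.array(init.committed, dtype=np.float64),
        np.array(init.recruiting, dtype=np.float64),
        params.alpha, params.alpha_leak, float(params.N),
        params.finish_count, t_max, seeds,
    )
    finished = codes == K.FINISHED
    n_fin = int(finished.sum())
    if n_fin:
        t_f = times[finished]
        occ = occupancy[finished]
        p = occ / occ.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        C = 1.0 + plogp.sum(axis=1) / math.log(params.n_nest)
        Tf_mean = float(t_f.mean())
        C_mean = float(C.mean())
        Tf_ci = ci_halfwidth(t_f) if n_fin >= 2 else float("nan")
        C_ci = ci_halfwidth(C) if n_fin >= 2 else float("nan")
    else:
        Tf_mean = C_mean = Tf_ci = C_ci = float("nan")
    return CohesionBatchSummary(
        params_id=params.label(),
        n_runs_requested=n_runs,
        n_finished=n_fin,
        n_unsuccessful=int((codes == K.UNSUCCESSFUL).sum()),
        n_censored=int((codes == K.CENSORED).sum()),
        Tf_mean=Tf_mean,
        Tf_ci_halfwidth=Tf_ci,
        C_mean=C_mean,
        C_ci_halfwidth=C_ci,
    )
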