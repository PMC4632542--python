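"""Monte-Carlo harness: speed (T) and accuracy (P) under parameter sweeps.

For each parameter set, many independent stochastic runs are launched; T is
the mean time until either site becomes quorate and P the fraction of
quorate runs in which the *good* site reached the quorum first.
Unsuccessful emigrations (all ants back home) and censored runs never enter
T or P, but their counts are first-class outputs.  The Pearson correlation
of the per-value (T, P) points diagnoses speed-accuracy trade-offs: r > 0
(slower goes with more accurate) is a trade-off, r < 0 means speed and
accuracy improve together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels as K
from .abm import make_initial_counts
from .params import ModelParams, ParameterError

__all__ = [
    "BatchSummary",
    "SweepResult",
    "SWEEPABLE",
    "derive_seeds",
    "run_batch",
    "ci_halfwidth",
    "pearson_r",
    "sweep",
    "correlation_grid",
]

SWEEPABLE = ("H", "z", "quorum_fraction", "alpha_s", "alpha", "alpha_p",
             "alpha_g", "alpha_leak")


def derive_seeds(master_seed: int, n: int, *, spawn_key: int = 0) -> np.ndarray:
    """Per-run seeds derived from a master seed (scheme ``seedseq-v1``).

    Uses :class:`numpy.random.SeedSequence` spawning so that distinct
    ``spawn_key`` values (e.g. per sweep point) give independent streams,
    masked to 31 bits for the compiled engines.
    """
    ss = np.random.SeedSequence(master_seed)
    if spawn_key:
        ss = ss.spawn(spawn_key + 1)[spawn_key]
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


@dataclass(frozen=True)
class BatchSummary:
    """Aggregate of one batch of stochastic runs at fixed parameters."""

    params_id: str
    n_runs_requested: int
    n_quorate: int
    n_unsuccessful: int
    n_censored: int
    T_mean: float            # nan if no quorate runs
    T_ci_halfwidth: float    # nan if < 2 quorate runs
    T_sd: float              # sample sd of T over quorate runs
    P: float                 # nan if no quorate runs

    def __post_init__(self) -> None:
        total = self.n_quorate + self.n_unsuccessful + self.n_censored
        if total != self.n_runs_requested:
            raise ValueError(
                f"run accounting broken: {self.n_quorate}+{self.n_unsuccessful}"
                f"+{self.n_censored} != {self.n_runs_requested}"
            )


def ci_halfwidth(
    samples: Sequence[float],
    mode: Literal["standard", "paper_literal"] = "standard",
) -> float:
    """Half-width of a 95% normal confidence interval for the mean.

    ``standard`` is ``1.96 * sd / sqrt(n)`` (sample sd, n-1 denominator).
    ``paper_literal`` is ``1.96 * sd / n``, reproducing a published figure
    caption verbatim; it is almost certainly a typo for the standard error
    and is kept only for like-for-like comparison.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 samples, got {x.size}")
    sd = float(np.std(x, ddof=1))
    if mode == "standard":
        return 1.96 * sd / math.sqrt(x.size)
    if mode == "paper_literal":
        return 1.96 * sd / x.size
    raise ValueError(f"unknown mode {mode!r}")


def pearson_r(points: Sequence[tuple[float, float]]) -> float:
    """Pearson product-moment correlation of (T, P) points.

    Requires at least 3 points with nonzero variance in both coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError(f"need >= 3 (x, y) points, got shape {pts.shape}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a coordinate is constant")
    return float(stats.pearsonr(x, y).statistic)


def run_batch(
    params: ModelParams,
    n_runs: int,
    master_seed: int,
    t_max: float = 1e5,
    ci_mode: Literal["standard", "paper_literal"] = "standard",
) -> BatchSummary:
    """Summarize ``n_runs`` independent event-driven runs.

    T statistics are computed over quorate runs only (either site); P is the
    fraction of quorate runs won by the good site.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    counts0 = make_initial_counts(params)
    quorum = params.quorum_fraction * params.N
    seeds = derive_seeds(master_seed, n_runs)
    codes, times, _ = K.ssa_batch(
        counts0.to_array(), params.alpha_p, params.alpha_g, params.alpha_s,
        params.alpha_leak, float(params.N), quorum, t_max, seeds,
    )
    quorate = (codes == K.GOOD_QUORUM) | (codes == K.POOR_QUORUM)
    n_quorate = int(quorate.sum())
    t_q = times[quorate]
    if n_quorate:
        T_mean = float(t_q.mean())
        T_sd = float(np.std(t_q, ddof=1)) if n_quorate >= 2 else float("nan")
        T_ci = ci_halfwidth(t_q, ci_mode) if n_quorate >= 2 else float("nan")
        P = float((codes[quorate] == K.GOOD_QUORUM).mean())
    else:
        T_mean = T_sd = T_ci = P = float("nan")
    return BatchSummary(
        params_id=params.label(),
        n_runs_requested=n_runs,
        n_quorate=n_quorate,
        n_unsuccessful=int((codes == K.UNSUCCESSFUL).sum()),
        n_censored=int((codes == K.CENSORED).sum()),
        T_mean=T_mean,
        T_ci_halfwidth=T_ci,
        T_sd=T_sd,
        P=P,
    )


@dataclass(frozen=True)
class SweepResult:
    """Batches along one varied parameter plus the (T, P) correlation."""

    vary: str
    values: tuple[float, ...]
    summaries: tuple[BatchSummary, ...]
    pearson_r: float                     # nan if undefined
    errors: tuple[tuple[float, str], ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per parameter value."""
        rows = []
        for v, s in zip(self.values, self.summaries):
            rows.append({
                self.vary: v,
                "n_quorate": s.n_quorate,
                "n_unsuccessful": s.n_unsuccessful,
                "n_censored": s.n_censored,
                "T_mean": s.T_mean,
                "T_ci": s.T_ci_halfwidth,
                "P": s.P,
            })
        return pd.DataFrame(rows)


def _set_param(base: ModelParams, name: str, value: float) -> ModelParams:
    if name not in SWEEPABLE:
        raise ValueError(f"cannot sweep {name!r}; choose one of {SWEEPABLE}")
    if name == "alpha":
        return base.replace(alpha=value)
    return base.replace(**{name: value})


def sweep(
    base_params: ModelParams,
    vary: str,
    values: Sequence[float],
    n_runs: int,
    master_seed: int,
    t_max: float = 1e5,
) -> SweepResult:
    """Run a batch per value of one parameter and correlate (T_mean, P).

    Values whose initial ant counts cannot be split exactly into integer
    compartments are reported in ``errors`` rather than silently skipped.
    """
    summaries: list[BatchSummary] = []
    kept_values: list[float] = []
    errors: list[tuple[float, str]] = []
    batch_seeds = derive_seeds(master_seed, len(values))
    for v, bseed in zip(values, batch_seeds):
        try:
            p = _set_param(base_params, vary, v)
            summaries.append(run_batch(p, n_runs, int(bseed), t_max))
            kept_values.append(float(v))
        except ParameterError as exc:
            errors.append((float(v), str(exc)))
    pts = [(s.T_mean, s.P) for s in summaries
           if math.isfinite(s.T_mean) and math.isfinite(s.P)]
    try:
        r = pearson_r(pts)
    except ValueError:
        r = float("nan")
    return SweepResult(
        vary=vary,
        values=tuple(kept_values),
        summaries=tuple(summaries),
        pearson_r=r,
        errors=tuple(errors),
    )


def correlation_grid(
    base_params: ModelParams,
    vary: str,
    values: Sequence[float],
    alphas: Sequence[float],
    quorum_fractions: Sequence[float],
    n_runs: int,
    master_seed: int,
    t_max: float = 1e5,
) -> pd.DataFrame:
    """Speed-accuracy correlation over an (alpha, quorum threshold) grid.

    For every grid cell, runs the ``vary`` sweep and records its Pearson r;
    this is the data behind the trade-off sign maps.  Returns a tidy frame
    with columns alpha, quorum_fraction, pearson_r, n_errors.
    """
    rows = []
    cell_seeds = derive_seeds(master_seed, len(alphas) * len(quorum_fractions))
    i = 0
    for a in alphas:
        for q in quorum_fractions:
            base = base_params.replace(alpha=a, quorum_fraction=q)
            res = sweep(base, vary, values, n_runs, int(cell_seeds[i]), t_max)
            rows.append({
                "alpha": a,
                "quorum_fraction": q,
                "pearson_r": res.pearson_r,
                "n_errors": len(res.errors),
            })
            i += 1
    return pd.DataFrame(rows)
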