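"""Configuration, provenance and serialization.

Config files are YAML with up to three sections (``model``, ``cohesion``,
``sweep``); a ``preset`` key inside ``model`` starts from a named parameter
preset, with any other keys overriding it.  Unknown keys are rejected.

Every batch result can be written together with a :class:`RunManifest` that
records the full parameter set, the master seed and the seed-derivation
scheme, which is sufficient to re-execute the batch bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .params import CohesionParams, ModelParams, ParameterError, get_preset

__all__ = [
    "SEED_SCHEME",
    "RunManifest",
    "load_config",
    "write_outputs",
]

SEED_SCHEME = "seedseq-v1"  # numpy SeedSequence(master).generate_state, 31-bit

_MODEL_KEYS = {"H", "z", "alpha", "alpha_p", "alpha_g", "alpha_s",
               "alpha_leak", "N", "quorum_fraction"}
_COHESION_KEYS = {"N", "n_nest", "z", "alpha", "alpha_leak", "finish_fraction"}
_SWEEP_KEYS = {"vary", "values", "n_runs", "t_max"}
_TOP_KEYS = {"model", "cohesion", "sweep"}


def _reject_unknown(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ParameterError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse and validate a YAML config file.

    Returns a dict with any of the keys ``model`` (:class:`ModelParams`),
    ``cohesion`` (:class:`CohesionParams`) and ``sweep`` (plain dict with
    keys vary/values/n_runs/t_max).  An empty file yields all defaults for
    the model section.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config root must be a mapping, got {type(raw)}")
    _reject_unknown("top level", raw, _TOP_KEYS)
    out: dict[str, Any] = {}

    model_raw = dict(raw.get("model", {}) or {})
    preset_name = model_raw.pop("preset", None)
    _reject_unknown("model", model_raw, _MODEL_KEYS)
    if preset_name is not None:
        base = get_preset(preset_name)
        if "alpha" in model_raw:
            alpha = model_raw.pop("alpha")
            base = base.replace(alpha=alpha)
        out["model"] = base.replace(**model_raw)
    else:
        out["model"] = ModelParams(**model_raw)

    if "cohesion" in raw:
        coh_raw = dict(raw["cohesion"] or {})
        _reject_unknown("cohesion", coh_raw, _COHESION_KEYS)
        out["cohesion"] = CohesionParams(**coh_raw)

    if "sweep" in raw:
        sweep_raw = dict(raw["sweep"] or {})
        _reject_unknown("sweep", sweep_raw, _SWEEP_KEYS)
        out["sweep"] = sweep_raw

    return out


@dataclass(frozen=True)
class RunManifest:
    """Provenance record sufficient to replay a batch bit-identically."""

    params: dict[str, Any]
    master_seed: int
    n_runs: int
    seed_scheme: str = SEED_SCHEME
    software: str = "antnest"
    version: str = "0.1.0"
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc)
        .isoformat(timespec="seconds")
    )
    counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def write_outputs(
    frame: pd.DataFrame,
    manifest: RunManifest,
    out_dir: str | Path,
    stem: str = "results",
    make_dirs: bool = True,
) -> dict[str, Path]:
    """Write a tidy CSV plus its JSON manifest.

    Numeric fields are written with ``repr`` round-trip precision so that a
    write-read cycle is lossless.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    if not out_dir.exists():
        if make_dirs:
            out_dir.mkdir(parents=True)
        else:
            raise FileNotFoundError(f"output directory does not exist: {out_dir}")
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.manifest.json"
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    json_path.write_text(manifest.to_json() + "\n")
    return {"csv": csv_path, "manifest": json_path}
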