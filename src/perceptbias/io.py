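"""Plain-text serialization: trials CSV, config YAML/JSON, run manifests.

Trials CSV dialect: comma-separated, UTF-8, "." decimal, ``NA`` for
missing values; angles in degrees throughout.  Columns:

    session_id, t, condition{L,N,R}, omega_deg, choice{left,right},
    reward{0,1,NA}, boundary_deg{float,NA}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .inference import PriorSpec, SamplerConfig
from .psychometric import ConditionLabel, TrialRecord, choice_to_pm1, choice_to_str

TRIALS_COLUMNS = (
    "session_id", "t", "condition", "omega_deg", "choice", "reward", "boundary_deg",
)


class TrialsSchemaError(ValueError):
    """Raised with an itemized report when a trials CSV violates the schema."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("trials CSV failed validation:\n" + "\n".join(self.problems))


def trials_to_frame(
    trials: Iterable[TrialRecord], session_id: str = "s1"
) -> pd.DataFrame:
    rows = [
        {
            "session_id": session_id,
            "t": tr.t,
            "condition": tr.condition.value,
            "omega_deg": tr.omega,
            "choice": choice_to_str(tr.choice),
            "reward": "NA" if tr.reward is None else int(tr.reward),
            "boundary_deg": "NA" if tr.boundary_used is None else tr.boundary_used,
        }
        for tr in trials
    ]
    return pd.DataFrame(rows, columns=list(TRIALS_COLUMNS))


def write_trials_csv(trials, path, session_id: str = "s1") -> None:
    trials_to_frame(trials, session_id).to_csv(path, index=False)


def read_trials_csv(path) -> dict[str, list[TrialRecord]]:
    """Parse and validate a trials CSV; returns trials grouped by session."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    problems = []
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise TrialsSchemaError([f"missing columns: {', '.join(missing)}"])

    sessions: dict[str, list[TrialRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            cond = ConditionLabel.from_str(row.condition)
            choice = choice_to_pm1(row.choice)
            reward = None if row.reward == "NA" else bool(int(row.reward))
            boundary = None if row.boundary_deg == "NA" else float(row.boundary_deg)
            tr = TrialRecord(
                t=int(row.t), condition=cond, omega=float(row.omega_deg),
                choice=choice, reward=reward, boundary_used=boundary,
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i} (session {row.session_id!r}): {exc}")
            continue
        sessions.setdefault(row.session_id, []).append(tr)

    for sid, trs in sessions.items():
        ts = [tr.t for tr in trs]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            problems.append(f"session {sid!r}: trial index t not strictly increasing")
    if problems:
        raise TrialsSchemaError(problems)
    return sessions


# ---------------------------------------------------------------------------
# config + manifest
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def priors_from_config(cfg: Mapping) -> PriorSpec:
    return PriorSpec.from_dict(dict(cfg))


def sampler_from_config(cfg: Mapping) -> SamplerConfig:
    allowed = {
        "n_draws", "burn_in", "seed", "n_chains", "refit_cadence",
        "warm_start", "compute_diagnostics", "rhat_threshold",
    }
    return SamplerConfig(**{k: v for k, v in dict(cfg).items() if k in allowed})


def write_manifest(path, config: Mapping, seed: int) -> None:
    """Sidecar JSON recording everything needed to reproduce an output file."""
    from . import __version__

    payload = {"package_version": __version__, "seed": seed, "config": dict(config)}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
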