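"""Reference parameter sets and structured-text (YAML/JSON) parameter files.

The shipped constructs are illustrative calibrations chosen to reproduce
the qualitative behaviour of the two formins studied most often in
single-filament processivity work: an mDia1-like construct (fast
elongation, moderate processivity, strong FH1/profilin protection) and an
mDia2-like construct (slower elongation, far more processive). Truncated
variants -- an FH1 with only two polyproline tracks and an FH2-DAD
construct without FH1 -- derive from the mDia1-like set.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .model import Conditions, ForminRateParams

__all__ = [
    "MDIA1", "MDIA2", "FH1_2PP", "FH2_ONLY", "DEFAULT_CONSTRUCTS",
    "params_to_dict", "params_from_dict",
    "conditions_to_dict", "conditions_from_dict",
    "save_parameter_file", "load_parameter_file",
]

# mDia1-like: transition route dominates at zero force (k_off rises with
# actin), FH1 ring protection strong enough that profilin lowers k_off
# while still speeding elongation.
MDIA1 = ForminRateParams(
    k_on=20.0,          # 1/µM/s from the open state
    K_co=1.0,           # open and closed equally likely at f=0
    k_offO0=2.0e-4,     # 1/s, open route
    k_offT0=0.3,        # 1/s, transition route
    k_decay=1000.0,     # 1/s, transition state is short-lived
    delta_O=2.7,        # nm (one subunit): open route force-sensitive
    delta_T=0.0,
    delta_step=2.7,
    K_PB=50.0,          # µM, weak solution binding to the barbed end
    K_ring=0.3,         # µM, ring complex forms at low profilin
    fh1_boost_max=5.0,
    K_boost=2.0,
    has_FH1=True,
)

# mDia2-like: slower elongation and much lower dissociation on both routes.
MDIA2 = MDIA1.with_(k_on=8.0, k_offO0=5.0e-5, k_offT0=0.06)

# Two polyproline tracks only: weaker delivery and weaker ring protection.
FH1_2PP = MDIA1.with_(fh1_boost_max=1.5, K_boost=2.0, K_ring=0.8)

# FH2-DAD: no FH1 at all; profilin acts only through the solution route.
FH2_ONLY = MDIA1.with_(has_FH1=False, fh1_boost_max=0.0)

DEFAULT_CONSTRUCTS: dict[str, ForminRateParams] = {
    "mDia1": MDIA1,
    "mDia2": MDIA2,
    "FH1_2PP": FH1_2PP,
    "FH2_only": FH2_ONLY,
}


def params_to_dict(params: ForminRateParams) -> dict:
    return dataclasses.asdict(params)


def params_from_dict(d: dict) -> ForminRateParams:
    return ForminRateParams(**d)


def conditions_to_dict(conditions: Conditions) -> dict:
    return dataclasses.asdict(conditions)


def conditions_from_dict(d: dict) -> Conditions:
    return Conditions(**d)


def save_parameter_file(path, constructs: dict[str, ForminRateParams],
                        conditions: dict[str, Conditions] | None = None) -> None:
    """Write constructs (and optionally condition sets) to a YAML/JSON file."""
    payload: dict = {"constructs": {n: params_to_dict(p) for n, p in constructs.items()}}
    if conditions:
        payload["conditions"] = {n: conditions_to_dict(c) for n, c in conditions.items()}
    path = Path(path)
    text = (json.dumps(payload, indent=2) if path.suffix == ".json"
            else yaml.safe_dump(payload, sort_keys=False))
    path.write_text(text)


def load_parameter_file(path) -> tuple[dict[str, ForminRateParams], dict[str, Conditions]]:
    """Read a parameter file written by :func:`save_parameter_file`.

    Returns ``(constructs, conditions)``; the conditions mapping may be empty.
    """
    path = Path(path)
    payload = (json.loads(path.read_text()) if path.suffix == ".json"
               else yaml.safe_load(path.read_text()))
    if not isinstance(payload, dict) or "constructs" not in payload:
        raise ValueError(f"{path} is not a parameter file (missing 'constructs')")
    constructs = {n: params_from_dict(d) for n, d in payload["constructs"].items()}
    conditions = {n: conditions_from_dict(d)
                  for n, d in payload.get("conditions", {}).items()}
    return constructs, conditions
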