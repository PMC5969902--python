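"""Synthetic single-filament experiments shaped like the microfluidics assays.

Three configurations are emulated:

* ``seed_anchored`` -- filaments grow from anchored seeds at negligible
  force and are observed at fixed frame intervals;
* ``striped`` -- the flowing solution alternates between two conditions
  on a fixed schedule, so the filament accumulates labeled/unlabeled
  stripes and the measured rates are duration-weighted composites;
* ``formin_anchored`` -- the formin is anchored to the surface and the
  viscous drag pulls on the filament with a force proportional to its
  length (the force-ramp assay). A fraction of the anchored formins is
  non-functional, producing spurious detachments unrelated to formin
  dissociation.

Observation effects applied on top of the exact simulation: dissociation
times are quantized up to the next acquisition frame, and filaments still
attached at the end of the movie are right-censored. Every generated
table carries hidden ground-truth columns, written to a separate sidecar
file so analysis code cannot consume them by accident.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Conditions, ForminRateParams, SUBUNIT_SIZE_UM, dissociation_rate
from .simulate import ForceProtocol, simulate_filament, simulate_population

__all__ = [
    "ExperimentDesign", "EventTable", "SchemaError",
    "generate_experiment", "write_event_table", "read_event_table",
    "OBSERVED_COLUMNS", "TRUTH_COLUMNS",
]

_CONFIGURATIONS = ("seed_anchored", "striped", "formin_anchored")

#: Acquisition cadences (s) typical of the three configurations.
DEFAULT_FRAME_INTERVALS = {"seed_anchored": 5.0, "striped": 120.0,
                           "formin_anchored": 10.0}

OBSERVED_COLUMNS = ["filament_id", "t_obs_s", "censored", "initial_length_um",
                    "condition", "kappa_pN_per_um", "frame_interval_s",
                    "movie_duration_s"]
TRUTH_COLUMNS = ["filament_id", "truth_time_s", "truth_route",
                 "truth_length_um"]


class SchemaError(ValueError):
    """An event-table file does not match the documented schema."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of one synthetic experiment.

    ``conditions_schedule`` is an ordered list of ``(Conditions, duration)``
    pairs; non-striped configurations use only the first entry's
    conditions. ``functional_fraction`` is the fraction of anchored
    formins confirmed functional in the post-experiment nucleation test
    (formin_anchored only).
    """

    configuration: str
    frame_interval: float
    movie_duration: float
    n_filaments: int
    conditions_schedule: tuple
    protocol: ForceProtocol = ForceProtocol(mode="zero")
    functional_fraction: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.configuration not in _CONFIGURATIONS:
            raise ValueError(f"configuration must be one of {_CONFIGURATIONS}")
        if not (self.frame_interval > 0 and self.movie_duration > 0):
            raise ValueError("frame_interval and movie_duration must be > 0")
        if self.n_filaments < 1:
            raise ValueError("n_filaments must be >= 1")
        if not (0.0 < self.functional_fraction <= 1.0):
            raise ValueError("functional_fraction must be in (0, 1]")
        if not self.conditions_schedule:
            raise ValueError("conditions_schedule must not be empty")
        if self.configuration == "striped":
            for _, dt in self.conditions_schedule:
                if dt < self.frame_interval:
                    raise ValueError(
                        "striped schedule durations must be >= frame_interval")


@dataclass
class EventTable:
    """Observed per-filament records plus segregated hidden truth."""

    observed: pd.DataFrame
    truth: pd.DataFrame

    def __eq__(self, other) -> bool:  # round-trip identity checks
        if not isinstance(other, EventTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.observed, other.observed)
            pd.testing.assert_frame_equal(self.truth, other.truth)
        except AssertionError:
            return False
        return True


def _quantize(t: float, frame: float, movie: float) -> float:
    return min(frame * math.ceil(t / frame), movie)


def _simulate_striped_filament(schedule, rates, rng, movie: float):
    """Piecewise-homogeneous exponential race across the alternating schedule.

    ``rates`` caches per-condition (k_total, k_open, v_subunits) at zero
    force. Returns (time, route, final_length_um).
    """
    t = 0.0
    length = 0.0
    while t < movie:
        for (cond, dt), (k_tot, k_open, v_sub) in zip(schedule, rates):
            seg = min(dt, movie - t)
            if seg <= 0:
                continue
            if k_tot > 0:
                w = rng.exponential(1.0 / k_tot)
                if w < seg:
                    length += v_sub * w * SUBUNIT_SIZE_UM
                    route = ("open" if rng.random() < k_open / k_tot
                             else "transition")
                    return t + w, route, length
            length += v_sub * seg * SUBUNIT_SIZE_UM
            t += seg
            if t >= movie:
                break
    return movie, "censored", length


def generate_experiment(design: ExperimentDesign, params: ForminRateParams,
                        seed) -> EventTable:
    """Generate one experiment-shaped dataset.

    Each filament is simulated exactly, then observed: dissociation times
    are rounded up to the next frame, and anything at or beyond the movie
    end is censored at the movie end. In ``formin_anchored`` mode a
    ``1 - functional_fraction`` share of the filaments detaches spuriously
    (non-formin events, uniform over the movie) and the truth table marks
    them as such.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pop, s_aux = ss.spawn(2)
    n = design.n_filaments
    frame, movie = design.frame_interval, design.movie_duration
    cfg = design.configuration

    true_t = np.empty(n)
    routes: list[str] = []
    init_len = np.zeros(n)
    final_len = np.zeros(n)

    if cfg == "striped":
        rates = []
        for cond, _ in design.conditions_schedule:
            pred = dissociation_rate(cond, 0.0, params)
            rates.append((pred.k_off, pred.k_off_open_route, pred.v_elong))
        children = s_pop.spawn(n)
        for i in range(n):
            rng = np.random.default_rng(children[i])
            t, route, L = _simulate_striped_filament(
                design.conditions_schedule, rates, rng, movie)
            true_t[i] = t
            routes.append(route)
            final_len[i] = L
    else:
        cond = design.conditions_schedule[0][0]
        traces = simulate_population(n, params, cond, design.protocol,
                                     horizon=movie, seed=s_pop)
        for i, tr in enumerate(traces):
            true_t[i] = tr.dissociation_time
            routes.append(tr.dissociation_route)
            init_len[i] = tr.initial_length
            final_len[i] = tr.final_length

    # Non-functional anchored formins: a (1 - functional_fraction) subset
    # carries an extra failure clock, uniform over the movie, competing
    # with the formin kinetics. Their detachments cannot be attributed to
    # formin dissociation, so the observed detachment rate overestimates
    # k_off by at most that share -- the basis of the 0.74 correction.
    spurious = np.zeros(n, dtype=bool)
    obs_t = true_t.copy()
    if cfg == "formin_anchored" and design.functional_fraction < 1.0:
        rng_sp = np.random.default_rng(s_aux)
        spurious = rng_sp.random(n) >= design.functional_fraction
        n_sp = int(spurious.sum())
        obs_t[spurious] = np.minimum(true_t[spurious],
                                     rng_sp.uniform(0.0, movie, size=n_sp))

    t_obs = np.empty(n)
    censored = np.zeros(n, dtype=bool)
    truth_route = list(routes)
    for i in range(n):
        if spurious[i]:
            truth_route[i] = "spurious"
            t_obs[i] = _quantize(obs_t[i], frame, movie)
        elif routes[i] == "censored" or obs_t[i] >= movie:
            censored[i] = True
            t_obs[i] = movie
            truth_route[i] = "censored"
        else:
            t_obs[i] = _quantize(obs_t[i], frame, movie)

    label = design.label or cfg
    observed = pd.DataFrame({
        "filament_id": np.arange(n),
        "t_obs_s": t_obs,
        "censored": censored,
        "initial_length_um": init_len,
        "condition": label,
        "kappa_pN_per_um": design.protocol.kappa,
        "frame_interval_s": frame,
        "movie_duration_s": float(movie),
    })
    truth = pd.DataFrame({
        "filament_id": np.arange(n),
        "truth_time_s": np.where(spurious, np.nan, true_t),
        "truth_route": truth_route,
        "truth_length_um": final_len,
    })
    return EventTable(observed=observed, truth=truth)


def _truth_path(path: Path) -> Path:
    return path.with_name(path.stem + ".truth.csv")


def write_event_table(table: EventTable, path) -> Path:
    """Write observables to ``path`` and hidden truth to a sidecar file.

    The sidecar is ``<stem>.truth.csv`` next to the main file, so routine
    analysis reading ``path`` never sees the ground truth.
    """
    path = Path(path)
    table.observed.to_csv(path, index=False)
    table.truth.to_csv(_truth_path(path), index=False)
    return path


def read_event_table(path, include_truth: bool = False) -> EventTable | pd.DataFrame:
    """Read an event table written by :func:`write_event_table`.

    Returns the observed DataFrame, or a full :class:`EventTable` when
    ``include_truth`` is set. Raises :class:`SchemaError` on a missing or
    malformed column set.
    """
    path = Path(path)
    observed = pd.read_csv(path)
    missing = [c for c in OBSERVED_COLUMNS if c not in observed.columns]
    if missing:
        raise SchemaError(f"{path} is missing required columns: {missing}")
    observed["censored"] = observed["censored"].astype(bool)
    if not include_truth:
        return observed
    tp = _truth_path(path)
    if not tp.exists():
        raise SchemaError(f"truth sidecar {tp} not found")
    truth = pd.read_csv(tp)
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise SchemaError(f"{tp} is missing required columns: {missing}")
    return EventTable(observed=observed, truth=truth)
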