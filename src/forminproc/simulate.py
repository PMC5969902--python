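"""Event-driven stochastic simulation of single formin-bound filaments.

Each filament is a continuous-time Markov realization of the closed-form
model in :mod:`forminproc.model`: subunit additions arrive at the
instantaneous elongation rate, every addition triggers a Bernoulli
transition-state dissociation trial, and an independent exponential clock
runs for the open-route dissociation. Under a length-proportional force
protocol the force is ``kappa * L`` and all rates are re-evaluated after
every event, making the realization statistically exact.

For constant-force protocols (including zero force and a ramp with
``kappa = 0``) the process is a homogeneous Poisson race, and the
simulator uses the equivalent direct construction: the dissociation time
is exponential with the total rate ``k_open + v * q``, the route is chosen
proportionally, and the non-lethal additions are a thinned Poisson count.
Traces produced by this fast path store only the start and end points of
the length trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model import (
    SUBUNIT_SIZE_UM,
    Conditions,
    ForminRateParams,
    UnphysicalParameterError,
    _boost,
    dissociation_rate,
    profilin_occupancy,
)

__all__ = [
    "ForceProtocol",
    "FilamentTrace",
    "simulate_filament",
    "simulate_population",
    "force_at",
    "events_frame",
    "population_frame",
]

_MODES = ("zero", "constant", "length_proportional")


@dataclass(frozen=True)
class ForceProtocol:
    """Force applied to the formin-filament bond.

    ``zero``: no force. ``constant``: ``f_const`` pN throughout.
    ``length_proportional``: viscous drag pulling at the anchoring point
    with force ``kappa * L`` (κ in pN/µm), the microfluidics ramp. In ramp
    mode populations draw per-filament initial lengths from a log-normal
    with mean ``L0`` (µm) and coefficient of variation ``L0_cv``.
    """

    mode: str = "zero"
    f_const: float = 0.0
    kappa: float = 0.0
    L0: float = 0.0
    L0_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.f_const < 0 or self.kappa < 0 or self.L0_cv < 0 or self.L0 < 0:
            raise ValueError("f_const, kappa, L0 and L0_cv must be >= 0")
        if self.mode == "length_proportional" and self.kappa > 0 and self.L0 <= 0:
            raise ValueError("ramp mode requires a positive initial length L0")

    def force(self, length_um: float) -> float:
        if self.mode == "constant":
            return self.f_const
        if self.mode == "length_proportional":
            return self.kappa * length_um
        return 0.0


@dataclass
class FilamentTrace:
    """One simulated filament.

    ``event_times``/``lengths`` sample the length trajectory (every
    addition in ramp mode; endpoints only on the constant-force fast
    path). ``dissociation_time`` equals the horizon for censored traces.
    """

    event_times: np.ndarray
    lengths: np.ndarray
    dissociation_time: float
    dissociation_route: str  # "open" | "transition" | "censored"
    seed: object = None

    @property
    def censored(self) -> bool:
        return self.dissociation_route == "censored"

    @property
    def final_length(self) -> float:
        return float(self.lengths[-1])

    @property
    def initial_length(self) -> float:
        return float(self.lengths[0])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_bell_domain(f_max: float, params: ForminRateParams, kBT: float) -> None:
    dmax = max(params.delta_O, params.delta_T, params.delta_step)
    if f_max * dmax / kBT > 700.0:
        raise UnphysicalParameterError(
            "f*delta/kBT exceeds 700: dissociation rates overflow"
        )


def _simulate_constant(params, conditions, protocol, horizon, rng, seed):
    """Exact direct sampling at constant force (thinned-Poisson race)."""
    f = protocol.force(protocol.L0)
    _check_bell_domain(f, params, conditions.kBT)
    pred = dissociation_rate(conditions, f, params)
    a = pred.v_elong                      # additions / s
    k_open = pred.k_off_open_route        # 1/s
    k_trans = pred.k_off_transition_route  # = a * q, 1/s
    q = k_trans / a if a > 0 else 0.0
    k_tot = k_open + k_trans
    L0 = protocol.L0

    if k_tot == 0.0:
        t_end, route = horizon, "censored"
        n_add = rng.poisson(a * horizon) if a > 0 else 0
    else:
        t = rng.exponential(1.0 / k_tot)
        if t >= horizon:
            t_end, route = horizon, "censored"
            n_add = rng.poisson(a * (1.0 - q) * horizon) if a > 0 else 0
        else:
            t_end = t
            route = "transition" if rng.random() < k_trans / k_tot else "open"
            n_add = rng.poisson(a * (1.0 - q) * t_end) if a > 0 else 0
            if route == "transition":
                n_add += 1  # the lethal addition itself
    L_end = L0 + n_add * SUBUNIT_SIZE_UM
    return FilamentTrace(
        event_times=np.array([0.0, t_end]),
        lengths=np.array([L0, L_end]),
        dissociation_time=t_end,
        dissociation_route=route,
        seed=seed,
    )


def _simulate_ramp(params, conditions, protocol, horizon, rng, seed,
                   explicit_transition):
    """Gillespie loop; force recomputed after every event."""
    kBT = conditions.kBT
    pi_sol, pi_fh1 = profilin_occupancy(conditions, params)
    mult = params.off_multiplier
    kO0 = params.k_offO0 * mult
    kT0 = params.k_offT0 * mult
    kon_eff = (params.k_on * conditions.actin
               * (1.0 + _boost(conditions.profilin, params))
               * (1.0 - pi_sol))
    K_co = params.K_co
    dO, dT, ds = params.delta_O, params.delta_T, params.delta_step
    kdec = params.k_decay
    gate_fh1 = 1.0 - pi_fh1

    exp_ = math.exp
    t = 0.0
    L = protocol.L0
    times = [0.0]
    lengths = [L]
    route = "censored"
    t_end = horizon
    while True:
        f = protocol.force(L)
        x = f / kBT
        if max(dO, dT, ds) * x > 700.0:
            raise UnphysicalParameterError(
                "f*delta/kBT exceeds 700: dissociation rates overflow")
        po = 1.0 / (1.0 + K_co * exp_(-ds * x))
        a = po * kon_eff
        r_open = po * (1.0 - pi_sol) * kO0 * exp_(dO * x)
        total = a + r_open
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= horizon:
            break
        if rng.random() < r_open / total:
            t_end, route = t, "open"
            break
        # subunit addition; transition trial at the post-addition force
        L += SUBUNIT_SIZE_UM
        times.append(t)
        lengths.append(L)
        f2 = protocol.force(L)
        kT = kT0 * exp_(dT * f2 / kBT)
        if explicit_transition:
            denom = kT + kdec
            if denom > 0.0:
                dwell = rng.exponential(1.0 / denom)
                lethal = rng.random() < (kT / denom) * gate_fh1
                t += dwell
                if t >= horizon:
                    break
                if lethal:
                    t_end, route = t, "transition"
                    break
        else:
            qf = (kT / (kT + kdec) if (kT + kdec) > 0 else 0.0) * gate_fh1
            if qf > 0.0 and rng.random() < qf:
                t_end, route = t, "transition"
                break
    return FilamentTrace(
        event_times=np.asarray(times),
        lengths=np.asarray(lengths),
        dissociation_time=t_end,
        dissociation_route=route,
        seed=seed,
    )


def simulate_filament(params: ForminRateParams, conditions: Conditions,
                      protocol: ForceProtocol, horizon: float, seed,
                      explicit_transition: bool = False) -> FilamentTrace:
    """Simulate one formin-bound filament until dissociation or ``horizon``.

    Parameters
    ----------
    explicit_transition : bool
        Resolve the transition state with finite dwell time (competing
        ``k_offT`` vs ``k_decay`` clocks) instead of the default
        instantaneous Bernoulli trial. Sensitivity-check mode only.
    seed : int, SeedSequence or Generator
        Source of randomness; identical seeds give identical traces.
    """
    if not (horizon > 0):
        raise ValueError(f"horizon must be > 0, got {horizon}")
    rng = _as_rng(seed)
    ramp = protocol.mode == "length_proportional" and protocol.kappa > 0
    if ramp or explicit_transition:
        return _simulate_ramp(params, conditions, protocol, horizon, rng, seed,
                              explicit_transition)
    return _simulate_constant(params, conditions, protocol, horizon, rng, seed)


def simulate_population(n: int, params: ForminRateParams,
                        conditions: Conditions, protocol: ForceProtocol,
                        horizon: float, seed,
                        explicit_transition: bool = False) -> list[FilamentTrace]:
    """Simulate ``n`` independent filaments.

    Per-filament RNG substreams are spawned deterministically from the
    population seed. In ramp mode with ``L0_cv > 0``, initial lengths are
    drawn per filament from a log-normal with mean ``L0`` and CV ``L0_cv``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    ramp = protocol.mode == "length_proportional"
    if ramp and protocol.L0_cv > 0:
        len_rng = np.random.default_rng(children[-1])
        sigma2 = math.log(1.0 + protocol.L0_cv ** 2)
        mu = math.log(protocol.L0) - sigma2 / 2.0
        L0s = len_rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    else:
        L0s = None
    traces = []
    for i in range(n):
        proto_i = protocol if L0s is None else replace(protocol, L0=float(L0s[i]))
        tr = simulate_filament(params, conditions, proto_i, horizon,
                               children[i], explicit_transition)
        tr.seed = (getattr(ss, "entropy", None), i)
        traces.append(tr)
    return traces


def force_at(trace: FilamentTrace, t: float, protocol: ForceProtocol) -> float:
    """Force on the bond at time ``t``, piecewise constant between events."""
    if t < 0 or t > trace.dissociation_time:
        raise ValueError(
            f"t={t} outside the trace domain [0, {trace.dissociation_time}]")
    if protocol.mode == "zero":
        return 0.0
    if protocol.mode == "constant":
        return protocol.f_const
    idx = int(np.searchsorted(trace.event_times, t, side="right")) - 1
    idx = max(idx, 0)
    return protocol.kappa * float(trace.lengths[idx])


def events_frame(traces: list[FilamentTrace], protocol: ForceProtocol):
    """Long-format event table (one row per event) for CSV export."""
    import pandas as pd

    rows = []
    for i, tr in enumerate(traces):
        for t, L in zip(tr.event_times, tr.lengths):
            rows.append({"filament_id": i, "t_event_s": float(t),
                         "length_um": float(L),
                         "force_pN": protocol.force(float(L)),
                         "event_type": "growth"})
        rows.append({"filament_id": i, "t_event_s": tr.dissociation_time,
                     "length_um": tr.final_length,
                     "force_pN": protocol.force(tr.final_length),
                     "event_type": tr.dissociation_route})
    return pd.DataFrame(rows)


def population_frame(traces: list[FilamentTrace]):
    """Per-filament summary (dissociation time, route, lengths)."""
    import pandas as pd

    return pd.DataFrame({
        "filament_id": np.arange(len(traces)),
        "dissociation_time_s": [tr.dissociation_time for tr in traces],
        "route": [tr.dissociation_route for tr in traces],
        "initial_length_um": [tr.initial_length for tr in traces],
        "final_length_um": [tr.final_length for tr in traces],
    })
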