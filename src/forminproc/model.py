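"""Closed-form kinetic model of formin processivity at the actin barbed end.

The FH2 dimer tracking a growing barbed end is modelled as a rapid
equilibrium between an elongation-competent *open* state and an
elongation-blocking *closed* state. Each subunit addition transiently puts
the dimer in a dissociation-prone *transition* state. The formin can
therefore leave the barbed end through two routes:

* the **open route** -- a first-order dissociation clock that runs while
  the dimer waits in the open state, with zero-force rate ``k_offO0`` and
  Bell working distance ``delta_O``;
* the **transition route** -- a per-addition dissociation trial entered
  every time a subunit adds, with zero-force rate ``k_offT0``, working
  distance ``delta_T``, and a fast decay ``k_decay`` back to the
  open/closed equilibrium.

Pulling force ``f`` (pN) tilts the open/closed equilibrium toward open
over one subunit size and accelerates both routes through Bell factors
``exp(f * delta / kBT)``. Profilin acts twice: occupancy of the barbed end
from solution (scale ``K_PB``) pauses elongation and gates the open route,
while FH1-mediated occupancy (the "ring complex", scale ``K_ring``)
protects against the transition route and exists only for constructs that
carry FH1 domains.

All forces are in pN, distances in nm, concentrations in µM, rates in
1/s, thermal energy in pN·nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SUBUNIT_SIZE_NM",
    "SUBUNIT_SIZE_UM",
    "SUBUNITS_PER_UM",
    "KBT_ROOM",
    "UnphysicalParameterError",
    "ForminRateParams",
    "Conditions",
    "ModelPrediction",
    "KoffForceFamily",
    "bell_rate",
    "p_open",
    "profilin_occupancy",
    "transition_probability",
    "elongation_rate",
    "dissociation_rate",
    "mean_filament_length",
    "koff_force_family",
    "predictions_table",
]

#: Length added to the filament per incorporated subunit (nm).
SUBUNIT_SIZE_NM = 2.7
SUBUNIT_SIZE_UM = SUBUNIT_SIZE_NM * 1e-3
#: Roughly 370 subunits per micrometre of filament.
SUBUNITS_PER_UM = 1.0 / SUBUNIT_SIZE_UM
#: Thermal energy at 25 C in pN nm.
KBT_ROOM = 4.11

# exp() overflows around 709; anything beyond this is outside the model's
# physical regime anyway.
_MAX_BELL_EXPONENT = 700.0


class UnphysicalParameterError(ValueError):
    """Raised when a force/working-distance combination overflows the Bell factor."""


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class ForminRateParams:
    """Kinetic constants and working distances of one formin construct.

    Parameters
    ----------
    k_on : float
        Subunit association rate from the open state (1/µM/s).
    K_co : float
        Closed:open equilibrium constant at zero force (dimensionless).
    k_offO0, k_offT0 : float
        Zero-force dissociation rates of the open-state and
        transition-state routes (1/s).
    k_decay : float
        Decay rate of the transition state back into the open/closed
        equilibrium (1/s).
    delta_O, delta_T : float
        Bell working distances of the two routes (nm).
    delta_step : float
        Working distance of the open/closed equilibrium; one subunit
        size for a stair-stepping geometry (nm).
    K_PB : float
        Effective profilin affinity for the barbed end from solution (µM).
    K_ring : float
        Profilin scale of FH1-mediated barbed-end occupancy (µM).
    fh1_boost_max : float
        Maximal FH1 delivery enhancement of elongation (dimensionless).
    K_boost : float
        Profilin scale of the delivery enhancement (µM).
    has_FH1 : bool
        False for FH2-DAD constructs; forces all FH1-mediated terms to zero.
    salt_multiplier, label_multiplier : float
        Phenomenological multipliers applied to both zero-force
        dissociation rates, calibrated per ionic strength and actin
        labeling fraction.
    """

    k_on: float
    K_co: float
    k_offO0: float
    k_offT0: float
    k_decay: float
    delta_O: float
    delta_T: float
    delta_step: float = SUBUNIT_SIZE_NM
    K_PB: float = 50.0
    K_ring: float = 0.3
    fh1_boost_max: float = 0.0
    K_boost: float = 2.0
    has_FH1: bool = True
    salt_multiplier: float = 1.0
    label_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_offO0", "k_offT0", "k_decay", "delta_O",
                     "delta_T", "delta_step", "fh1_boost_max",
                     "salt_multiplier", "label_multiplier"):
            v = getattr(self, name)
            _require_finite(**{name: v})
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("K_co", "K_PB", "K_ring", "K_boost"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not self.has_FH1 and self.fh1_boost_max != 0.0:
            # FH2-only constructs cannot deliver profilin-actin
            object.__setattr__(self, "fh1_boost_max", 0.0)

    @property
    def off_multiplier(self) -> float:
        """Combined salt and labeling multiplier on both dissociation routes."""
        return self.salt_multiplier * self.label_multiplier

    def with_(self, **kwargs) -> "ForminRateParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Conditions:
    """Solution composition and thermal energy of one experiment.

    ``actin`` and ``profilin`` in µM, ``kcl`` in mM, ``labeling_fraction``
    in [0, 1], ``kBT`` in pN·nm.
    """

    actin: float
    profilin: float = 0.0
    kcl: float = 100.0
    labeling_fraction: float = 0.0
    kBT: float = KBT_ROOM

    def __post_init__(self) -> None:
        for name in ("actin", "profilin", "kcl", "labeling_fraction"):
            v = getattr(self, name)
            _require_finite(**{name: v})
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.labeling_fraction > 1:
            raise ValueError("labeling_fraction must be <= 1")
        if not (self.kBT > 0) or not math.isfinite(self.kBT):
            raise ValueError("kBT must be finite and > 0")


@dataclass(frozen=True)
class ModelPrediction:
    """Model outputs at one (conditions, force) point.

    ``k_off`` is always the sum of the two route contributions;
    ``pi_profilin`` is the solution-route barbed-end profilin occupancy.
    """

    v_elong: float
    k_off: float
    k_off_open_route: float
    k_off_transition_route: float
    p_open: float
    pi_profilin: float


def bell_rate(k0: float, delta: float, f: float, kBT: float = KBT_ROOM) -> float:
    """Bell slip-bond rate ``k0 * exp(f * delta / kBT)``.

    Parameters are the zero-force rate ``k0`` (1/s), working distance
    ``delta`` (nm), force ``f`` (pN) and thermal energy ``kBT`` (pN·nm).
    Monotone non-decreasing in ``f`` for ``delta >= 0``.
    """
    _require_finite(k0=k0, delta=delta, f=f, kBT=kBT)
    if kBT <= 0:
        raise ValueError(f"kBT must be > 0, got {kBT}")
    if k0 < 0 or delta < 0 or f < 0:
        raise ValueError("k0, delta and f must all be >= 0")
    x = f * delta / kBT
    if x > _MAX_BELL_EXPONENT:
        raise UnphysicalParameterError(
            f"f*delta/kBT = {x:.3g} overflows the Bell factor; "
            "parameters are outside the physical regime"
        )
    return k0 * math.exp(x)


def p_open(f: float, params: ForminRateParams, kBT: float = KBT_ROOM) -> float:
    """Probability of the open state at force ``f``.

    Boltzmann occupancy ``1 / (1 + K_co * exp(-f * delta_step / kBT))``;
    tension over one subunit size favors the open state.
    """
    _require_finite(f=f)
    if f < 0:
        raise ValueError("f must be >= 0")
    if kBT <= 0:
        raise ValueError("kBT must be > 0")
    return 1.0 / (1.0 + params.K_co * math.exp(-f * params.delta_step / kBT))


def profilin_occupancy(conditions: Conditions,
                       params: ForminRateParams) -> tuple[float, float]:
    """Barbed-end profilin occupancies ``(pi_solution, pi_fh1)``.

    ``pi_solution`` is simple binding from solution, present for every
    construct. ``pi_fh1`` is the FH1-mediated ring-complex occupancy and is
    identically zero without FH1 domains.
    """
    p = conditions.profilin
    pi_solution = p / (p + params.K_PB)
    pi_fh1 = p / (p + params.K_ring) if params.has_FH1 else 0.0
    return pi_solution, pi_fh1


def _boost(profilin: float, params: ForminRateParams) -> float:
    if not params.has_FH1 or params.fh1_boost_max == 0.0:
        return 0.0
    return params.fh1_boost_max * profilin / (profilin + params.K_boost)


def transition_probability(f: float, params: ForminRateParams,
                           kBT: float = KBT_ROOM) -> float:
    """Per-addition probability of dissociating from the transition state.

    The transition state decays with rate ``k_decay`` and dissociates with
    the Bell-accelerated rate ``k_offT(f)``; the two compete, giving
    ``p_T = k_offT(f) / (k_offT(f) + k_decay)``.
    """
    kT = bell_rate(params.k_offT0 * params.off_multiplier, params.delta_T, f, kBT)
    denom = kT + params.k_decay
    if denom == 0.0:
        return 0.0
    return kT / denom


def elongation_rate(conditions: Conditions, f: float,
                    params: ForminRateParams) -> float:
    """Formin-mediated barbed-end elongation rate in subunits/s.

    ``v = p_open(f) * k_on * [actin] * (1 + boost(profilin)) * (1 - pi_solution)``.

    Linear in actin at fixed profilin. With FH1 present the profilin
    dependence is biphasic: delivery enhancement (``boost``) saturates
    while solution-route barbed-end occupancy keeps rising, so ``v``
    first increases then falls.
    """
    po = p_open(f, params, conditions.kBT)
    pi_solution, _ = profilin_occupancy(conditions, params)
    return (po * params.k_on * conditions.actin
            * (1.0 + _boost(conditions.profilin, params))
            * (1.0 - pi_solution))


def dissociation_rate(conditions: Conditions, f: float,
                      params: ForminRateParams) -> ModelPrediction:
    """Global dissociation rate and its two route contributions.

    The open route runs while the dimer waits in the open state and is
    gated by solution profilin occupancy::

        k_open = p_open(f) * (1 - pi_solution) * k_offO0 * mult * exp(f*delta_O/kBT)

    The transition route fires once per added subunit and is protected by
    the FH1-profilin ring complex::

        k_trans = v_elong * p_T(f) * (1 - pi_fh1)

    With ``pi_fh1 = 0`` the transition route depends on the conditions
    only through ``v_elong``, which is why FH2-only data collapse onto a
    single k_off(v) curve however a given elongation rate is reached.
    """
    kBT = conditions.kBT
    po = p_open(f, params, kBT)
    pi_solution, pi_fh1 = profilin_occupancy(conditions, params)
    v = elongation_rate(conditions, f, params)
    open_route = (po * (1.0 - pi_solution)
                  * bell_rate(params.k_offO0 * params.off_multiplier,
                              params.delta_O, f, kBT))
    trans_route = v * transition_probability(f, params, kBT) * (1.0 - pi_fh1)
    return ModelPrediction(
        v_elong=v,
        k_off=open_route + trans_route,
        k_off_open_route=open_route,
        k_off_transition_route=trans_route,
        p_open=po,
        pi_profilin=pi_solution,
    )


def mean_filament_length(conditions: Conditions, f: float,
                         params: ForminRateParams) -> float:
    """Mean filament length at steady state, in µm.

    Elongation rate divided by dissociation rate, converted at 2.7 nm per
    subunit. Returns ``math.inf`` when the dissociation rate vanishes
    (a formin that never leaves grows an unbounded filament).
    """
    pred = dissociation_rate(conditions, f, params)
    if pred.k_off == 0.0:
        return math.inf
    return pred.v_elong / pred.k_off * SUBUNIT_SIZE_UM


@dataclass(frozen=True)
class KoffForceFamily:
    """A family of k_off(f) curves across actin concentrations.

    ``ratio_low``/``ratio_high`` are the max/min spread of k_off across
    concentrations at the lowest and highest force of the grid.
    ``classification`` is ``"converging"`` when the family tightens with
    force (open route takes over, working distance larger on the open
    route) and ``"separated"`` otherwise; ties classify as separated.
    """

    curves: pd.DataFrame
    ratio_low: float
    ratio_high: float
    classification: str


def koff_force_family(actin_list, f_grid, conditions_base: Conditions,
                      params: ForminRateParams) -> KoffForceFamily:
    """Compute k_off(f) for several actin concentrations and classify the regime.

    Parameters
    ----------
    actin_list : sequence of float
        At least two actin concentrations (µM).
    f_grid : sequence of float
        Increasing force grid (pN).
    conditions_base : Conditions
        Template conditions; actin is replaced per curve.
    """
    actin_list = list(actin_list)
    f_grid = np.asarray(f_grid, dtype=float)
    if len(actin_list) < 2:
        raise ValueError("need at least two actin concentrations")
    if f_grid.ndim != 1 or f_grid.size < 1 or np.any(np.diff(f_grid) < 0):
        raise ValueError("f_grid must be a non-decreasing 1-D grid")

    rows = []
    for actin in actin_list:
        cond = replace(conditions_base, actin=actin)
        for f in f_grid:
            pred = dissociation_rate(cond, float(f), params)
            rows.append({"actin_uM": actin, "force_pN": float(f),
                         "koff_s": pred.k_off,
                         "route_open_s": pred.k_off_open_route,
                         "route_transition_s": pred.k_off_transition_route})
    curves = pd.DataFrame(rows)

    def _spread(f: float) -> float:
        ks = curves.loc[curves["force_pN"] == f, "koff_s"].to_numpy()
        kmin = ks.min()
        return math.inf if kmin == 0 else ks.max() / kmin

    ratio_low = _spread(float(f_grid[0]))
    ratio_high = _spread(float(f_grid[-1]))
    classification = "converging" if ratio_high < ratio_low else "separated"
    return KoffForceFamily(curves=curves, ratio_low=ratio_low,
                           ratio_high=ratio_high, classification=classification)


def predictions_table(constructs: dict[str, ForminRateParams],
                      conditions_list, forces) -> pd.DataFrame:
    """Tidy table of model predictions for export.

    One row per (construct, conditions, force) with the elongation rate,
    global dissociation rate and both route contributions.
    """
    rows = []
    for name, params in constructs.items():
        for cond in conditions_list:
            for f in forces:
                pred = dissociation_rate(cond, float(f), params)
                rows.append({
                    "construct": name,
                    "actin_uM": cond.actin,
                    "profilin_uM": cond.profilin,
                    "kcl_mM": cond.kcl,
                    "force_pN": float(f),
                    "v_elong_sub_s": pred.v_elong,
                    "koff_s": pred.k_off,
                    "route_open_s": pred.k_off_open_route,
                    "route_transition_s": pred.k_off_transition_route,
                })
    return pd.DataFrame(rows)
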