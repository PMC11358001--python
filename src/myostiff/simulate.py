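"""Synthetic stretch-hold force traces and component calibration.

The simulator produces the force a transducer would record while a cardiac
preparation is ramped to a target strain, held there (stress relaxation),
released and rested, for every step of a stretch protocol.  During a hold
the force of each intact component is

    F_i(t) = E_i(eps) + V_i(eps) * exp(-t / tau_i)

where ``E_i`` is the coupling-adjusted elastic force, ``V_i`` the
coupling-adjusted viscous amplitude and ``t`` time since the hold began.
The total force is the sum over intact components (parallel elements), so
noise-free traces superpose exactly.

``calibrate_components`` solves the inverse problem: given a total
force-strain polynomial and a schedule of per-component contribution shares
at anchor strains, it constructs component specs whose simulated
contributions reproduce the schedule exactly at the anchors.
"""

from __future__ import annotations

import numpy as np

from .components import (
    ComponentSpec,
    ConfigurationError,
    NoiseModel,
    PreparationState,
    StretchProtocol,
    effective_elastic,
    effective_viscous,
)
from .trace import ForceTrace

__all__ = ["simulate_trace", "simulate_replicates", "calibrate_components", "CalibrationError"]


class CalibrationError(ConfigurationError):
    """Raised when a contribution-share schedule cannot be realized."""


def _totals(state, strain, components, couplings, include=None):
    """Summed effective elastic force and viscous amplitude at ``strain``."""
    strain = np.asarray(strain, dtype=float)
    elastic = np.zeros_like(strain)
    viscous = np.zeros_like(strain)
    for name in state.present:
        if include is not None and name not in include:
            continue
        elastic += effective_elastic(state, name, strain, components, couplings)
        viscous += effective_viscous(state, name, strain, components, couplings)
    return elastic, viscous


def simulate_trace(
    state: PreparationState,
    protocol: StretchProtocol,
    components,
    couplings=(),
    noise: NoiseModel | None = None,
    replicate: int = 0,
    stream: int = 0,
    include=None,
) -> ForceTrace:
    """Simulate one stretch-hold recording for a preparation state.

    An empty present-set yields an all-zero (plus noise) trace.  Identical
    inputs and noise seed give identical output.  The multiplicative
    replicate scale depends only on ``replicate`` (the same physical sample
    keeps its scale across repeated recordings), while the additive noise
    additionally varies with ``stream`` (e.g. one stream per treatment
    stage).  ``include`` restricts which components' forces are summed while
    couplings and gates still see the full present-set, so single-component
    traces superpose exactly to the full trace.
    """
    state.check_components(components)
    noise = noise or NoiseModel()
    fs = protocol.fs
    strain_parts: list[np.ndarray] = []
    force_parts: list[np.ndarray] = []

    for target, hold_s in protocol.steps:
        n_up = max(1, round(target / protocol.ramp_rate * fs))
        n_hold = round(hold_s * fs)
        n_rest = round(protocol.rest_s * fs)

        # loading ramp: strain rises linearly; the viscous amplitude is
        # carried fully during loading so the hold onset is continuous
        ramp_strain = target * np.arange(n_up) / n_up
        e_up, v_up = _totals(state, ramp_strain, components, couplings, include)
        strain_parts.append(ramp_strain)
        force_parts.append(e_up + v_up)

        # hold: single-exponential stress relaxation per component
        t_hold = np.arange(n_hold) / fs
        hold_force = np.zeros(n_hold)
        for name in state.present:
            if include is not None and name not in include:
                continue
            e_i = effective_elastic(state, name, target, components, couplings)
            v_i = effective_viscous(state, name, target, components, couplings)
            tau = next(c.tau for c in components if c.name == name)
            hold_force += e_i + v_i * np.exp(-t_hold / tau)
        strain_parts.append(np.full(n_hold, target))
        force_parts.append(hold_force)

        # release ramp and rest at slack: relaxed (elastic-only) force
        down_strain = target * np.arange(n_up - 1, -1, -1) / n_up
        e_down, _ = _totals(state, down_strain, components, couplings, include)
        strain_parts.append(down_strain)
        force_parts.append(e_down)
        if n_rest:
            e_rest, _ = _totals(state, np.zeros(n_rest), components, couplings, include)
            strain_parts.append(np.zeros(n_rest))
            force_parts.append(e_rest)

    strain = np.concatenate(strain_parts)
    force = np.concatenate(force_parts)
    time_s = np.arange(strain.size) / fs

    if not noise.silent:
        scale_rng = np.random.default_rng([noise.seed, replicate])
        force = force * (1.0 + noise.replicate_cv * scale_rng.standard_normal())
        rng = np.random.default_rng([noise.seed, replicate, stream])
        fmax = np.max(np.abs(force))
        force = force + noise.sigma_rel * fmax * rng.standard_normal(force.size)

    meta = {
        "preparation": state.kind,
        "genotype": state.genotype,
        "history": ";".join(state.history) or "none",
        "replicate": replicate,
        "seed": noise.seed,
    }
    return ForceTrace(time_s, strain, force, meta=meta)


def simulate_replicates(state, protocol, components, couplings=(), noise=None):
    """Simulate ``protocol.replicates`` technical repeats (distinct noise)."""
    return [
        simulate_trace(state, protocol, components, couplings, noise, replicate=r)
        for r in range(protocol.replicates)
    ]


def _solve_elastic_poly(name, total_poly, anchors):
    """Quadratic through share anchors, constrained to zero slack force.

    With one anchor the share is held constant across strain; with two the
    two free coefficients (a1, a2) are pinned exactly; three anchors release
    the intercept.  More anchors fall back to least squares and must still
    reproduce every anchor share to 1e-6.
    """
    a0t, a1t, a2t = total_poly
    total = np.polynomial.polynomial.Polynomial([a0t, a1t, a2t])
    eps = np.array([e for e, _ in anchors])
    y = np.array([s * total(e) for e, s in anchors])

    if len(anchors) == 1:
        s = anchors[0][1]
        coef = (s * a0t, s * a1t, s * a2t)
    elif len(anchors) in (2, 3):
        if len(anchors) == 2:
            design = np.column_stack([eps, eps**2])
            sol = np.linalg.solve(design, y)
            coef = (0.0, sol[0], sol[1])
        else:
            design = np.column_stack([np.ones_like(eps), eps, eps**2])
            sol = np.linalg.solve(design, y)
            coef = tuple(sol)
    else:
        design = np.column_stack([np.ones_like(eps), eps, eps**2])
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        coef = tuple(sol)

    poly = np.polynomial.polynomial.Polynomial(coef)
    tot_at = total(eps)
    shares = np.divide(poly(eps), tot_at, out=np.zeros_like(tot_at), where=tot_at != 0)
    target_shares = np.array([s for _, s in anchors])
    if np.max(np.abs(shares - target_shares)) > 1e-6:
        raise CalibrationError(
            f"{name}: elastic share schedule not representable by a quadratic "
            f"(max anchor error {np.max(np.abs(shares - target_shares)):.2e})"
        )
    grid = np.linspace(0.0, 0.30, 121)
    if np.min(poly(grid)) < -1e-9:
        raise CalibrationError(f"{name}: calibrated elastic polynomial goes negative on [0, 0.30]")
    return tuple(float(c) for c in coef)


def calibrate_components(
    total_poly,
    share_schedule,
    fallback_tau: float = 1.0,
    viscous_ratio: float = 0.5,
    preparations=None,
    taus=None,
):
    """Construct component specs matching a contribution-share schedule.

    Parameters
    ----------
    total_poly
        Coefficients ``(a0, a1, a2)`` of the preparation's total elastic
        force vs strain.
    share_schedule
        Map ``component -> list of (strain, elastic_share, viscous_share)``.
        ``elastic_share`` entries of ``None`` are viscous-only anchors and
        vice versa.  Elastic shares are fractions of the total elastic force;
        viscous shares are fractions of the total viscous amplitude, taken
        as ``viscous_ratio`` times the total elastic force.
    fallback_tau
        Relaxation time constant (s) for components without an entry in
        ``taus``.
    viscous_ratio
        Total viscous amplitude / total elastic force (phenomenological).
    preparations, taus
        Optional per-component overrides.

    Returns
    -------
    list of ComponentSpec whose simulated contribution shares equal the
    schedule at every anchor strain (to 1e-6).
    """
    total = np.polynomial.polynomial.Polynomial(list(total_poly))
    preparations = preparations or {}
    taus = taus or {}

    # feasibility: shares at any shared anchor strain must not exceed 1
    for force_idx, label in ((1, "elastic"), (2, "viscous")):
        by_strain: dict[float, float] = {}
        for name, anchors in share_schedule.items():
            for entry in anchors:
                strain, share = entry[0], entry[force_idx]
                if share is not None:
                    by_strain[strain] = by_strain.get(strain, 0.0) + share
        for strain, tot_share in by_strain.items():
            if tot_share > 1.0 + 1e-9:
                raise CalibrationError(
                    f"{label} shares at strain {strain} sum to {tot_share:.6f} > 1"
                )

    specs = []
    for name, anchors in share_schedule.items():
        e_anchors = [(e, s) for e, s, _ in anchors if s is not None]
        v_anchors = [(e, s) for e, _, s in anchors if s is not None]
        if not e_anchors:
            raise CalibrationError(f"{name}: at least one elastic anchor required")
        coef = _solve_elastic_poly(name, tuple(total_poly), e_anchors)
        poly = np.polynomial.polynomial.Polynomial(coef)

        if v_anchors:
            vf_table = {}
            for strain, v_share in v_anchors:
                e_val = float(poly(strain))
                v_amp = v_share * viscous_ratio * float(total(strain))
                if v_amp > 0 and e_val <= 0:
                    raise CalibrationError(
                        f"{name}: viscous share {v_share} at strain {strain} needs a "
                        "positive elastic force to carry it"
                    )
                vf_table[strain] = v_amp / e_val if e_val > 0 else 0.0
            viscous_fraction: float | dict = (
                vf_table if len(vf_table) > 1 else next(iter(vf_table.values()))
            )
        else:
            viscous_fraction = 0.0

        specs.append(
            ComponentSpec(
                name=name,
                elastic_poly=coef,
                viscous_fraction=viscous_fraction,
                tau=taus.get(name, fallback_tau),
                preparations=frozenset(preparations.get(name, ("native_fiber", "permeabilized_fiber", "cardiomyocyte"))),
            )
        )
    return specs
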