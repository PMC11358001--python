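"""Mechanical components of the myocardium and their coupling rules.

The passive stiffness of cardiac tissue is carried by a small set of
structural elements -- titin, the microtubule (MT) network, actin, the
sarcolemma, the extracellular matrix (ECM) and the intermediate-filament
(desmin) network.  Each element is modeled as a parallel viscoelastic
element: a strain-dependent elastic force (second-order polynomial in
strain) in parallel with a single-exponential stress-relaxation term whose
amplitude is a configurable fraction of the elastic force.

Elements do not act in isolation.  Couplings express two observed
interactions:

* removing one filament system reduces the force borne by another
  (tensegrity; e.g. severing actin lowers titin-based force by a few
  percent), and
* one element can shield another so that the shielded element only bears
  load when the shield is gone (the MT network masks the sarcolemma's
  elastic contribution, while the sarcolemma's high-strain viscous term
  exists only while the MTs are intact).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ComponentSpec",
    "CouplingSpec",
    "PreparationState",
    "StretchProtocol",
    "NoiseModel",
    "ConfigurationError",
    "TREATMENT_EFFECTS",
    "effective_elastic",
    "effective_viscous",
    "apply_treatment",
]

PREPARATION_KINDS = ("native_fiber", "permeabilized_fiber", "cardiomyocyte")

#: treatment name -> component(s) it removes
TREATMENT_EFFECTS = {
    "colchicine": ("microtubules",),
    "triton": ("sarcolemma",),
    "gln40": ("actin",),
    "tevp": ("titin",),
}

#: components destroyed by the preparation itself (no drug needed)
_FORBIDDEN = {
    "native_fiber": frozenset(),
    "permeabilized_fiber": frozenset({"sarcolemma", "microtubules"}),
    "cardiomyocyte": frozenset({"sarcolemma", "microtubules", "ecm"}),
}


class ConfigurationError(ValueError):
    """Raised for inconsistent component/coupling/state configuration."""


@dataclass(frozen=True)
class ComponentSpec:
    """One structural element's mechanical parameters.

    Parameters
    ----------
    name
        Component identifier (``titin``, ``microtubules``, ``actin``,
        ``sarcolemma``, ``ecm``, ``desmin`` or user-defined).
    elastic_poly
        Coefficients ``(a0, a1, a2)`` of elastic force vs strain,
        force in relative units, strain a dimensionless fraction.
    viscous_fraction
        Ratio of the viscous (relaxing) amplitude to the elastic force.
        Either a scalar or a per-strain table ``{strain: fraction}``;
        tables are interpolated linearly and clamped at the ends.
    tau
        Stress-relaxation time constant in seconds.
    preparations
        Preparation kinds in which this component physically exists.
    """

    name: str
    elastic_poly: tuple[float, float, float]
    viscous_fraction: float | dict[float, float] = 0.0
    tau: float = 1.0
    preparations: frozenset[str] = frozenset(PREPARATION_KINDS)

    def __post_init__(self):
        if self.tau <= 0:
            raise ConfigurationError(f"{self.name}: tau must be > 0")
        if np.any(np.asarray(self._vf_values()) < 0):
            raise ConfigurationError(f"{self.name}: viscous_fraction must be >= 0")
        bad = set(self.preparations) - set(PREPARATION_KINDS)
        if bad:
            raise ConfigurationError(f"{self.name}: unknown preparations {sorted(bad)}")

    def _vf_values(self):
        if isinstance(self.viscous_fraction, dict):
            return list(self.viscous_fraction.values())
        return [self.viscous_fraction]

    def elastic(self, strain):
        """Raw (uncoupled) elastic force at ``strain``."""
        a0, a1, a2 = self.elastic_poly
        strain = np.asarray(strain, dtype=float)
        out = a0 + a1 * strain + a2 * strain**2
        return out if out.ndim else float(out)

    def vf(self, strain):
        """Viscous amplitude fraction at ``strain``."""
        if not isinstance(self.viscous_fraction, dict):
            return (
                np.full_like(np.asarray(strain, dtype=float), self.viscous_fraction)
                if np.ndim(strain)
                else float(self.viscous_fraction)
            )
        xs = np.array(sorted(self.viscous_fraction), dtype=float)
        ys = np.array([self.viscous_fraction[x] for x in sorted(self.viscous_fraction)])
        out = np.interp(np.asarray(strain, dtype=float), xs, ys)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class CouplingSpec:
    """Interaction between two components.

    ``loss_fraction`` models tensegrity: when ``source`` is absent, ``target``
    loses that fraction of its force.  ``gating`` models shielding: with
    ``gating="source_absent"`` the target term exists only once the source is
    gone; with ``gating="source_present"`` only while the source is intact.
    ``applies_to`` selects which force type the coupling acts on.
    """

    source: str
    target: str
    loss_fraction: float = 0.0
    gating: str = "none"  # none | source_absent | source_present
    applies_to: str = "both"  # elastic | viscous | both

    def __post_init__(self):
        if not 0.0 <= self.loss_fraction <= 1.0:
            raise ConfigurationError("loss_fraction must be in [0, 1]")
        if self.gating not in ("none", "source_absent", "source_present"):
            raise ConfigurationError(f"unknown gating mode {self.gating!r}")
        if self.gating != "none" and self.loss_fraction > 0:
            raise ConfigurationError(
                "gating and loss_fraction > 0 are mutually exclusive "
                f"for ({self.source} -> {self.target})"
            )
        if self.applies_to not in ("elastic", "viscous", "both"):
            raise ConfigurationError(f"unknown applies_to {self.applies_to!r}")

    def applies(self, force_type: str) -> bool:
        return self.applies_to in (force_type, "both")


@dataclass(frozen=True)
class PreparationState:
    """Which components are intact in a sample, plus its treatment history."""

    kind: str
    present: frozenset[str]
    history: tuple[str, ...] = ()
    genotype: str = "hom"  # hom carries the titin cleavage cassette; wt does not

    def __post_init__(self):
        if self.kind not in PREPARATION_KINDS:
            raise ConfigurationError(f"unknown preparation kind {self.kind!r}")
        clash = self.present & _FORBIDDEN[self.kind]
        if clash:
            raise ConfigurationError(
                f"{self.kind} cannot contain {sorted(clash)}; the preparation "
                "itself destroys these components"
            )
        if self.genotype not in ("hom", "het", "wt"):
            raise ConfigurationError(f"unknown genotype {self.genotype!r}")

    def check_components(self, components):
        by_name = {c.name: c for c in components}
        for name in self.present:
            if name not in by_name:
                raise ConfigurationError(f"unknown component {name!r} in state")
            if self.kind not in by_name[name].preparations:
                raise ConfigurationError(
                    f"component {name!r} does not exist in {self.kind} preparations"
                )


@dataclass(frozen=True)
class StretchProtocol:
    """A stepwise stretch-hold protocol.

    ``steps`` is an ordered list of ``(target_strain, hold_s)`` pairs; each
    step ramps from slack (0% strain) to the target at ``ramp_rate``, holds,
    releases back to slack and rests ``rest_s`` seconds before the next step.
    """

    steps: tuple[tuple[float, float], ...]
    ramp_rate: float = 1.0  # strain / s
    rest_s: float = 1.0
    fs: float = 1000.0  # Hz
    replicates: int = 1

    def __post_init__(self):
        strains = [s for s, _ in self.steps]
        if not strains:
            raise ConfigurationError("protocol needs at least one step")
        if any(not 0.0 < s <= 0.35 for s in strains):
            raise ConfigurationError("step strains must lie in (0, 0.35]")
        if any(b <= a for a, b in zip(strains, strains[1:])):
            raise ConfigurationError("step strains must be strictly increasing")
        if self.fs <= 0 or self.ramp_rate <= 0 or self.rest_s < 0:
            raise ConfigurationError("fs and ramp_rate must be > 0, rest_s >= 0")
        if any(h <= 0 for _, h in self.steps):
            raise ConfigurationError("hold durations must be > 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    @property
    def strains(self) -> tuple[float, ...]:
        return tuple(s for s, _ in self.steps)


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement noise and replicate-to-replicate variability.

    ``sigma_rel`` scales Gaussian force noise by the trace's maximum force;
    ``replicate_cv`` is the coefficient of variation of a multiplicative
    per-replicate scale factor (emulating sample-to-sample spread).
    """

    sigma_rel: float = 0.0
    replicate_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_rel < 0 or self.replicate_cv < 0:
            raise ConfigurationError("noise parameters must be >= 0")

    @property
    def silent(self) -> bool:
        return self.sigma_rel == 0.0 and self.replicate_cv == 0.0


def _component(components, name):
    for c in components:
        if c.name == name:
            return c
    raise ConfigurationError(f"unknown component name {name!r}")


def _coupling_factor(state, target, couplings, force_type):
    """Multiplicative factor from all couplings acting on ``target``."""
    factor = 1.0
    for cpl in couplings:
        if cpl.target != target or not cpl.applies(force_type):
            continue
        source_present = cpl.source in state.present
        if cpl.gating == "source_absent" and source_present:
            return 0.0
        if cpl.gating == "source_present" and not source_present:
            return 0.0
        if cpl.gating == "none" and not source_present:
            factor *= 1.0 - cpl.loss_fraction
    return factor


def effective_elastic(state, component, strain, components, couplings=()):
    """Elastic force of one component under the state's coupling context.

    The raw polynomial value is multiplied by ``(1 - loss_fraction)`` for
    every tensegrity coupling whose source is absent, and zeroed by any
    unsatisfied gate.  Depends only on the current present-set, never on the
    order of the treatment history.

    Parameters
    ----------
    state : PreparationState
    component : str
        Name of the component; must be present in the state.
    strain : float or array
    components : sequence of ComponentSpec
    couplings : sequence of CouplingSpec
    """
    if component not in state.present:
        raise ConfigurationError(f"component {component!r} not present in state")
    spec = _component(components, component)
    return spec.elastic(strain) * _coupling_factor(state, component, couplings, "elastic")


def effective_viscous(state, component, strain, components, couplings=()):
    """Viscous relaxation amplitude of one component (same coupling logic).

    The amplitude is the raw elastic force times the component's viscous
    fraction, then scaled/gated by viscous-applicable couplings.  Gating is
    evaluated separately from the elastic term so that, e.g., a component can
    carry viscous load while its elastic term is shielded.
    """
    if component not in state.present:
        raise ConfigurationError(f"component {component!r} not present in state")
    spec = _component(components, component)
    raw = spec.elastic(strain) * spec.vf(strain)
    return raw * _coupling_factor(state, component, couplings, "viscous")


def apply_treatment(state: PreparationState, treatment: str) -> PreparationState:
    """Return a new state with the treatment's target component(s) removed.

    colchicine depolymerizes microtubules, Triton X-100 permeabilizes the
    sarcolemma, GLN-40 severs actin and TEVp cleaves titin.  TEVp on a
    wild-type sample (no cleavage cassette) removes nothing.  Removing an
    already-absent component is a no-op apart from the history entry.
    """
    if treatment == "none":
        return replace(state, history=state.history + (treatment,))
    if treatment not in TREATMENT_EFFECTS:
        raise ConfigurationError(f"unknown treatment {treatment!r}")
    removed = set(TREATMENT_EFFECTS[treatment])
    if treatment == "tevp" and state.genotype == "wt":
        removed = set()
    return replace(
        state,
        present=frozenset(state.present - removed),
        history=state.history + (treatment,),
    )
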