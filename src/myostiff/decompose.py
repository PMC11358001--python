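"""Elastic/viscous decomposition of stretch-hold force traces.

Each hold segment of a stretch protocol shows stress relaxation: force
peaks at the end of the loading ramp and decays toward a steady state while
strain is constant.  The velocity-insensitive *elastic* force is the
asymptote of a one-phase exponential fit to the relaxation segment,

    F(t) = F_ss + A * exp(-(t - t_peak) / tau),

and the velocity-sensitive *viscous* force is the peak force minus that
asymptote, so ``F_elastic + F_viscous == F_peak`` holds exactly by
construction for every step.  The peak force is the fitted curve's value at
the peak time (``F_ss + A``): on noise-free stress-relaxation data this
equals the raw sample maximum, while under measurement noise the raw
maximum of many samples is biased upward by O(sigma * sqrt(log n)) --
enough to swamp the small viscous amplitudes at low strain -- whereas the
fitted value is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .trace import ForceTrace

__all__ = [
    "StepWindow",
    "StepDecomposition",
    "NormalizedSeries",
    "DecompositionError",
    "segment_steps",
    "fit_relaxation",
    "decompose_trace",
    "normalize",
    "fit_polynomial",
]

# plateau detection thresholds: a hold must sit at least 0.5 strain
# percentage points above slack, stay within 0.1 points of its level and
# last at least one second
MIN_PLATEAU_STRAIN = 0.005
PLATEAU_TOL = 0.001
MIN_PLATEAU_S = 1.0


class DecompositionError(ValueError):
    """Raised for windows or series the decomposition cannot process."""


@dataclass(frozen=True)
class StepWindow:
    """Half-open sample range [i_start, i_end) of one hold, 0-based."""

    target_strain: float
    i_start: int
    i_end: int
    i_peak: int

    def __post_init__(self):
        if not self.i_start <= self.i_peak < self.i_end:
            raise DecompositionError("require i_start <= i_peak < i_end")


@dataclass(frozen=True)
class StepDecomposition:
    """Per-step elastic/viscous split and relaxation-fit diagnostics."""

    target_strain: float
    F_peak: float
    F_elastic: float
    F_viscous: float
    tau_fit: float
    r2: float
    flags: tuple[str, ...] = ()


@dataclass
class NormalizedSeries:
    """Force-strain points expressed relative to a pre-treatment reference.

    ``points`` is a list of ``(strain, relative_force, replicate_id)``.
    """

    force_type: str  # elastic | viscous
    reference_rule: str  # max_at_20 | mean_at_25 | pre_value_cell
    reference_value: float
    points: list[tuple[float, float, object]] = field(default_factory=list)

    def at(self, strain, replicate=None, tol=1e-9):
        """Values at a strain (optionally one replicate's)."""
        return [
            v
            for s, v, r in self.points
            if abs(s - strain) <= tol and (replicate is None or r == replicate)
        ]


def segment_steps(trace: ForceTrace, protocol_hint=None) -> list[StepWindow]:
    """Detect hold windows as plateaus in the strain channel.

    Returns one window per constant-strain plateau above 0.5 percentage
    points lasting at least one second, ordered by time.  With a
    ``protocol_hint`` the detected windows are matched against the
    protocol's steps and a mismatch raises ``DecompositionError``.
    """
    strain = trace.strain
    n = strain.size
    dt = float(np.median(np.diff(trace.time_s)))
    min_len = max(2, int(round(MIN_PLATEAU_S / dt)))

    # contiguous runs where strain stays within tolerance of its local level
    windows: list[StepWindow] = []
    i = 0
    while i < n:
        if strain[i] <= MIN_PLATEAU_STRAIN:
            i += 1
            continue
        level = strain[i]
        j = i
        while j < n and abs(strain[j] - level) <= PLATEAU_TOL:
            j += 1
        if j - i >= min_len:
            force_win = trace.force[i:j]
            head = max(1, (j - i) // 10)  # peak expected in first 10% of hold
            # edge-normalized running mean before locating the peak, so noise
            # does not drag it late and edge padding does not push it inward
            k = min(51, head)
            kern = np.ones(k)
            smoothed = np.convolve(force_win[:head], kern, mode="same") / np.convolve(
                np.ones(head), kern, mode="same"
            )
            i_peak = i + int(np.argmax(smoothed))
            windows.append(
                StepWindow(
                    target_strain=float(np.median(strain[i:j])),
                    i_start=i,
                    i_end=j,
                    i_peak=i_peak,
                )
            )
        i = j

    if protocol_hint is not None:
        expected = list(protocol_hint.strains)
        got = [w.target_strain for w in windows]
        if len(got) != len(expected) or any(
            abs(a - b) > PLATEAU_TOL for a, b in zip(got, expected)
        ):
            raise DecompositionError(
                f"detected plateaus {got} do not match protocol steps {expected}"
            )
    return windows


def fit_relaxation(trace: ForceTrace, window: StepWindow) -> StepDecomposition:
    """One-phase exponential fit of the relaxation segment of one hold.

    The fit starts at the window's force maximum (excluding the ramp) and
    uses bounded least squares.  The reported peak is the fitted curve's
    value there, ``F_ss + A`` -- identical to the raw maximum on clean
    relaxation data and unbiased under noise (see module docstring) -- so
    ``F_viscous = A`` exactly.  Poor data is flagged, never raised:
    ``rising_force`` for a negative amplitude, ``negative_viscous`` when
    the fitted steady state exceeds the peak, ``nonconvergence`` when the
    optimizer fails (the steady state then falls back to the mean of the
    final 5% of the window, the peak to the raw maximum) and ``poor_fit``
    for r2 < 0.8.
    """
    force = trace.force[window.i_start : window.i_end]
    if not np.all(np.isfinite(force)):
        raise DecompositionError("non-finite force samples in window")
    i_peak_local = window.i_peak - window.i_start
    seg = trace.force[window.i_peak : window.i_end]
    if seg.size < 50:
        raise DecompositionError("need at least 50 samples after the peak")
    t = (trace.time_s[window.i_peak : window.i_end] - trace.time_s[window.i_peak])

    raw_peak = float(force[i_peak_local])
    hold_s = float(t[-1]) if t[-1] > 0 else 1.0
    tail = seg[max(1, int(0.95 * seg.size)) :]
    f_ss0 = float(np.mean(tail))
    a0 = raw_peak - f_ss0
    scale = max(abs(raw_peak), 1e-12)

    flags: list[str] = []

    def model(tt, f_ss, a, tau):
        return f_ss + a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model,
            t,
            seg,
            p0=[f_ss0, a0, 1.0],
            bounds=([-np.inf, -scale, 1e-3], [np.inf, 2 * scale, 10 * hold_s]),
            maxfev=10000,
        )
        f_ss, a, tau = (float(v) for v in popt)
    except RuntimeError:
        flags.append("nonconvergence")
        f_ss, a, tau = f_ss0, a0, float("nan")

    resid = seg - (f_ss if np.isnan(tau) else model(t, f_ss, a, tau))
    ss_tot = float(np.sum((seg - np.mean(seg)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    # fitted peak (F_ss + A) unless the fit failed, then the raw maximum
    f_peak = f_ss + a if not np.isnan(tau) else raw_peak
    if not np.isnan(tau) and a < 0:
        flags.append("rising_force")
    f_viscous = f_peak - f_ss
    if f_viscous < 0:
        flags.append("negative_viscous")
    if r2 < 0.8:
        flags.append("poor_fit")

    return StepDecomposition(
        target_strain=window.target_strain,
        F_peak=f_peak,
        F_elastic=f_ss,
        F_viscous=f_viscous,
        tau_fit=tau,
        r2=r2,
        flags=tuple(flags),
    )


def decompose_trace(trace: ForceTrace, protocol_hint=None) -> list[StepDecomposition]:
    """Segment a trace and fit every hold window."""
    return [fit_relaxation(trace, w) for w in segment_steps(trace, protocol_hint)]


def _reference(decomps_by_rep, rule, force_type):
    """Reference force from PRE-treatment decompositions only."""
    attr = "F_elastic" if force_type == "elastic" else "F_viscous"

    def values_at(strain):
        out = []
        for rep, decomps in decomps_by_rep.items():
            out.extend(
                getattr(d, attr) for d in decomps if abs(d.target_strain - strain) < 1e-9
            )
        return out

    if rule == "max_at_20":
        vals = values_at(0.20)
        if not vals:
            raise DecompositionError("no pre-treatment step at 20% strain for max_at_20")
        return max(vals)
    if rule == "mean_at_25":
        vals = values_at(0.25)
        if not vals:
            raise DecompositionError("no pre-treatment step at 25% strain for mean_at_25")
        return float(np.mean(vals))
    if rule == "pre_value_cell":
        vals = values_at(0.20)
        if not vals:
            raise DecompositionError("no pre-treatment step at 20% strain for pre_value_cell")
        return float(np.mean(vals))
    raise DecompositionError(f"unknown reference rule {rule!r}")


def normalize(pre, post, rule, force_type) -> tuple[NormalizedSeries, NormalizedSeries]:
    """Normalize paired pre/post decompositions by a pre-treatment reference.

    Parameters
    ----------
    pre, post
        Maps ``replicate id -> list of StepDecomposition`` (post may be an
        empty dict when only a pre-treatment series is needed).
    rule
        ``max_at_20`` (fibers: highest force at the 20% step before
        treatment), ``mean_at_25`` (titin-cleavage fibers: mean force at the
        25% step before treatment) or ``pre_value_cell`` (cardiomyocytes:
        each cell's own pre-treatment 20% value).
    force_type
        ``elastic`` or ``viscous``.

    Every value, pre and post, is divided by the same reference computed
    from pre-treatment data only.  A non-positive reference is an error.
    """
    ref = _reference(pre, rule, force_type)
    if not ref > 0:
        raise DecompositionError(
            f"non-positive {force_type} reference ({ref}) under rule {rule!r} "
            f"for replicates {sorted(pre)}"
        )
    attr = "F_elastic" if force_type == "elastic" else "F_viscous"

    def build(decomps_by_rep):
        series = NormalizedSeries(force_type=force_type, reference_rule=rule, reference_value=ref)
        for rep in sorted(decomps_by_rep):
            for d in decomps_by_rep[rep]:
                series.points.append((d.target_strain, getattr(d, attr) / ref, rep))
        return series

    return build(pre), build(post)


def fit_polynomial(series: NormalizedSeries):
    """Ordinary least-squares quadratic of relative force vs strain.

    Returns ``((a0, a1, a2), rss)``.  Requires at least three distinct
    strain values.
    """
    strains = np.array([s for s, _, _ in series.points])
    values = np.array([v for _, v, _ in series.points])
    if np.unique(np.round(strains, 12)).size < 3:
        raise DecompositionError("need >= 3 distinct strain values for a quadratic fit")
    design = np.column_stack([np.ones_like(strains), strains, strains**2])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    rss = float(np.sum((values - design @ coef) ** 2))
    return tuple(float(c) for c in coef), rss
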