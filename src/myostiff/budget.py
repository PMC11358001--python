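"""Contribution estimation and the native-scale stiffness budget.

The sequential-elimination ("musical chairs") design measures each
structural element's force contribution as the paired before/after drop
caused by its selective disruption.  Because later experiments run on
preparations that have already lost the sarcolemma and microtubules (and,
for single cells, the extracellular matrix), per-experiment shares are
expressed against different baselines.  ``compose_budget`` rescales them
onto the native-tissue scale:

1. the microtubule share is measured directly on native fibers;
2. the sarcolemma share (measured after microtubule disruption) is scaled
   by the remaining native fraction;
3. the rest of the native total is an intracellular + ECM pool;
4. the ECM fraction of that pool is inferred from how much smaller the
   titin share is in fiber bundles (ECM present) than in single cells
   (ECM absent);
5. titin and actin claim their cell-measured shares of the intracellular
   remainder; whatever is left is attributed to the residual component
   (desmin / intermediate filaments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .components import NoiseModel, apply_treatment
from .decompose import NormalizedSeries, decompose_trace, normalize
from .simulate import simulate_trace

__all__ = [
    "ContributionEstimate",
    "StiffnessBudget",
    "BudgetError",
    "contribution_from_pair",
    "compose_budget",
    "adjust_p_values",
    "run_experiment",
    "recover_budget",
]

REGIME_STRAIN = {"low": 0.10, "high": 0.20}


class BudgetError(ValueError):
    """Raised for infeasible contribution or budget inputs."""


@dataclass(frozen=True)
class ContributionEstimate:
    """One component's fractional force contribution at one strain."""

    component: str
    preparation: str
    baseline: str  # native_total | post_colchicine_total | permeabilized_total | cell_total
    force_type: str  # elastic | viscous
    strain: float
    share: float
    n: int
    sem: float
    p_value: float  # nan when undefined (n == 1)
    flags: tuple[str, ...] = ()


@dataclass
class StiffnessBudget:
    """Fractional contributions at one strain regime, summing to one."""

    regime: str  # low | high
    force_type: str
    shares: dict[str, float]
    residual_component: str = "desmin"
    log: list[str] = field(default_factory=list)


def _paired_p(pre, post):
    """Two-sided paired t-test p-value with degenerate-case conventions.

    Identically-zero differences give p = 1; non-zero differences with zero
    variance are infinitely significant (p = 0).
    """
    diffs = pre - post
    if np.allclose(diffs, 0.0):
        return 1.0
    if np.std(diffs, ddof=0) == 0.0:
        return 0.0
    return float(stats.ttest_rel(pre, post).pvalue)


def contribution_from_pair(
    pre: NormalizedSeries,
    post: NormalizedSeries,
    strain: float,
    component: str = "",
    preparation: str = "",
    baseline: str = "native_total",
) -> ContributionEstimate:
    """Paired pre/post contribution of the removed component at one strain.

    Per replicate, ``share_r = (pre_r - post_r) / pre_r`` where the
    reference is that replicate's own pre-treatment value at the strain.
    The p-value is a two-sided paired t-test on the pre/post values;
    identically-zero differences give p = 1 by convention, and a single
    pair returns the estimate with an undefined (NaN) p-value, flagged.
    """
    if pre.force_type != post.force_type or pre.reference_rule != post.reference_rule:
        raise BudgetError("pre and post series must share force type and normalization rule")
    reps_pre = {r for s, _, r in pre.points if abs(s - strain) < 1e-9}
    reps_post = {r for s, _, r in post.points if abs(s - strain) < 1e-9}
    if not reps_pre or reps_pre != reps_post:
        raise BudgetError(
            f"unpaired replicates at strain {strain}: pre {sorted(map(str, reps_pre))}, "
            f"post {sorted(map(str, reps_post))}"
        )
    pre_vals, post_vals, shares = [], [], []
    for rep in sorted(reps_pre, key=str):
        p_r = float(np.mean(pre.at(strain, rep)))
        q_r = float(np.mean(post.at(strain, rep)))
        if p_r == 0:
            raise BudgetError(f"replicate {rep!r} has zero pre-treatment force at {strain}")
        pre_vals.append(p_r)
        post_vals.append(q_r)
        shares.append((p_r - q_r) / p_r)
    shares = np.asarray(shares)
    n = shares.size
    flags: tuple[str, ...] = ()
    if n == 1:
        p_value = float("nan")
        flags = ("p_undefined",)
        sem = 0.0
    else:
        sem = float(np.std(shares, ddof=1) / np.sqrt(n))
        p_value = _paired_p(np.asarray(pre_vals), np.asarray(post_vals))
    return ContributionEstimate(
        component=component,
        preparation=preparation,
        baseline=baseline,
        force_type=pre.force_type,
        strain=strain,
        share=float(np.mean(shares)),
        n=int(n),
        sem=sem,
        p_value=p_value,
        flags=flags,
    )


def _share_at(estimates, component, baseline, strain):
    """Interpolate a component's share to ``strain``.

    Three or more distinct strains: quadratic least squares; two: linear;
    one: constant.  Returns None when no estimate matches.
    """
    pts = sorted(
        (e.strain, e.share)
        for e in estimates
        if e.component == component and e.baseline == baseline
    )
    if not pts:
        return None
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.unique(xs).size >= 3:
        design = np.column_stack([np.ones_like(xs), xs, xs**2])
        coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
        return float(coef[0] + coef[1] * strain + coef[2] * strain**2)
    if np.unique(xs).size == 2:
        return float(np.interp(strain, xs, ys))
    return float(ys[0])


def compose_budget(estimates, regime: str, force_type: str) -> StiffnessBudget:
    """Compose per-experiment contribution estimates into a native budget.

    See the module docstring for the rescaling chain.  Native-baseline
    estimates are used as-is; the sarcolemma estimate (post-colchicine
    baseline) is scaled by the remaining native fraction; titin and actin
    cell shares split the intracellular pool after the ECM fraction is
    inferred from the fiber-vs-cell titin difference.  Negative
    intermediates are clipped to zero (logged) and the result is
    renormalized to sum exactly to one.
    """
    estimates = [e for e in estimates if e.force_type == force_type]
    if not estimates:
        raise BudgetError("no contribution estimates supplied")
    if regime not in REGIME_STRAIN:
        raise BudgetError(f"unknown regime {regime!r}")
    strain = REGIME_STRAIN[regime]
    log: list[str] = [f"regime={regime} ({strain:.0%} strain), force_type={force_type}"]
    shares: dict[str, float] = {}

    # 1) direct native-baseline estimates (microtubules in the full ladder)
    native_components = {e.component for e in estimates if e.baseline == "native_total"}
    for comp in sorted(native_components):
        shares[comp] = _share_at(estimates, comp, "native_total", strain)
        log.append(f"{comp}: native baseline share {shares[comp]:.4f}")
    used = sum(shares.values())

    # 2) sarcolemma, measured against the post-colchicine total
    c_sarc_post = _share_at(estimates, "sarcolemma", "post_colchicine_total", strain)
    if c_sarc_post is not None:
        c_mt = shares.get("microtubules", 0.0)
        shares["sarcolemma"] = c_sarc_post * (1.0 - c_mt)
        used += shares["sarcolemma"]
        log.append(
            f"sarcolemma: {c_sarc_post:.4f} x (1 - {c_mt:.4f}) = {shares['sarcolemma']:.4f}"
        )

    # 3-5) intracellular + ECM pool
    titin_fiber = _share_at(estimates, "titin", "permeabilized_total", strain)
    titin_cell = _share_at(estimates, "titin", "cell_total", strain)
    actin_cell = _share_at(estimates, "actin", "cell_total", strain)
    if titin_cell is not None:
        if titin_cell == 0:
            raise BudgetError("titin cell share is zero; ECM inference impossible")
        pool = 1.0 - used
        log.append(f"intracellular+ECM pool P = 1 - {used:.4f} = {pool:.4f}")
        x = 0.0
        if titin_fiber is not None:
            x_raw = 1.0 - titin_fiber / titin_cell
            x = min(max(x_raw, 0.0), 1.0)
            if x != x_raw:
                log.append(f"WARNING: ECM fraction clipped from {x_raw:.4f} to {x:.4f}")
            log.append(f"ECM fraction x = 1 - {titin_fiber:.4f}/{titin_cell:.4f} = {x:.4f}")
        shares["ecm"] = pool * x
        shares["titin"] = pool * (1.0 - x) * titin_cell
        log.append(f"ecm = P*x = {shares['ecm']:.4f}; titin = P*(1-x)*{titin_cell:.4f} = {shares['titin']:.4f}")
        if actin_cell is not None:
            shares["actin"] = pool * (1.0 - x) * actin_cell
            log.append(f"actin = P*(1-x)*{actin_cell:.4f} = {shares['actin']:.4f}")

    # 6) residual component takes the remainder
    budget = StiffnessBudget(regime=regime, force_type=force_type, shares={}, log=log)
    residual = 1.0 - sum(shares.values())
    if residual < 0:
        log.append(f"WARNING: residual clipped from {residual:.4f} to 0")
        residual = 0.0
    shares[budget.residual_component] = shares.get(budget.residual_component, 0.0) + residual
    log.append(f"{budget.residual_component} (residual) = {residual:.4f}")

    # 7) clip negatives, renormalize to sum exactly 1
    for comp, val in shares.items():
        if val < 0:
            log.append(f"WARNING: {comp} share clipped from {val:.4f} to 0")
            shares[comp] = 0.0
    total = sum(shares.values())
    if total <= 0:
        raise BudgetError("all shares zero; cannot renormalize")
    budget.shares = {c: v / total for c, v in shares.items()}
    log.append(f"renormalized by {total:.6f}")
    return budget


def adjust_p_values(p, method: str = "holm_sidak"):
    """Step-down Holm-Sidak multiple-comparison adjustment.

    Adjusted values are monotone, order-preserving and never below the raw
    p-values.
    """
    if method != "holm_sidak":
        raise BudgetError(f"unknown adjustment method {method!r}")
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise BudgetError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return [float(v) for v in out]


# ---------------------------------------------------------------------------
# end-to-end recovery harness


def _decompose_state(exp, state, noise, replicate, stream):
    trace = simulate_trace(
        state, exp.protocol, exp.components, exp.couplings, noise, replicate, stream
    )
    return decompose_trace(trace, exp.protocol)


def run_experiment(exp, noise: NoiseModel | None = None):
    """Simulate and decompose every stage of one ladder experiment.

    Returns ``stages``: a list (baseline first) of maps
    ``replicate -> list of StepDecomposition``.
    """
    noise = noise or NoiseModel()
    reps = range(exp.protocol.replicates)
    states = [exp.baseline_state]
    for treatment in exp.treatments:
        states.append(apply_treatment(states[-1], treatment))
    stages = []
    for stage_idx, state in enumerate(states):
        # same replicate scale across stages (paired design), fresh additive
        # noise per stage
        stages.append(
            {
                r: _decompose_state(exp, state, noise, replicate=r, stream=stage_idx)
                for r in reps
            }
        )
    return stages


def _stage_values(stage, force_type, strain):
    """Per-replicate force of one type at one step strain (replicates averaged in)."""
    attr = "F_elastic" if force_type == "elastic" else "F_viscous"
    out = {}
    for rep, decomps in stage.items():
        vals = [getattr(d, attr) for d in decomps if abs(d.target_strain - strain) < 1e-6]
        if not vals:
            raise BudgetError(f"no step at strain {strain} in decomposition")
        out[rep] = float(np.mean(vals))
    return out


def measure_readout(stages, readout):
    """Evaluate one expected readout of an experiment, as a fraction.

    ``mode='drop'`` is the paired relative decrease caused by stage
    ``readout['stage']`` versus the comparison stage; ``mode='remaining'``
    is the force left relative to the comparison stage.  The comparison is
    the baseline by default, or the preceding stage with
    ``relative_to='previous'``.  Technical replicates are averaged per
    strain before the ratio is taken.
    """
    stage = readout["stage"]
    base_idx = stage - 1 if readout.get("relative_to") == "previous" else 0
    pre = _stage_values(stages[base_idx], readout["force_type"], readout["strain"])
    post = _stage_values(stages[stage], readout["force_type"], readout["strain"])
    remaining = float(np.mean(list(post.values())) / np.mean(list(pre.values())))
    return 1.0 - remaining if readout["mode"] == "drop" else remaining


def readout_estimate(stages, readout, preparation="") -> ContributionEstimate:
    """Turn one 'drop' readout into a paired ContributionEstimate."""
    stage = readout["stage"]
    base_idx = stage - 1 if readout.get("relative_to") == "previous" else 0
    pre = _stage_values(stages[base_idx], readout["force_type"], readout["strain"])
    post = _stage_values(stages[stage], readout["force_type"], readout["strain"])
    shares = np.array([(pre[r] - post[r]) / pre[r] for r in pre])
    n = shares.size
    if n > 1:
        p_value = _paired_p(
            np.array(list(pre.values())), np.array(list(post.values()))
        )
        sem = float(np.std(shares, ddof=1) / np.sqrt(n))
        flags: tuple[str, ...] = ()
    else:
        p_value, sem, flags = float("nan"), 0.0, ("p_undefined",)
    return ContributionEstimate(
        component=readout["component"],
        preparation=preparation,
        baseline=readout["baseline"],
        force_type=readout["force_type"],
        strain=readout["strain"],
        share=float(np.mean(shares)),
        n=int(n),
        sem=sem,
        p_value=p_value,
        flags=flags,
    )


def ladder_estimates(config, noise: NoiseModel | None = None):
    """Contribution estimates for every component-tagged readout in a ladder."""
    estimates = []
    for exp in config.experiments:
        tagged = [r for r in exp.readouts if r.get("component")]
        if not tagged:
            continue
        stages = run_experiment(exp, noise)
        for readout in tagged:
            estimates.append(readout_estimate(stages, readout, preparation=exp.baseline_state.kind))
    return estimates


def recover_budget(config, noise: NoiseModel | None = None):
    """Run the full simulate->segment->fit->contribute pipeline for a ladder.

    ``config`` is a ``PaperDefaults``-like object with an ``experiments``
    list; each experiment carries the configured (target) shares of its
    readouts.  Returns a report: list of dict rows with configured vs
    recovered shares and absolute errors (in percentage points).
    """
    report = []
    for exp in config.experiments:
        stages = run_experiment(exp, noise)
        for readout in exp.readouts:
            recovered = measure_readout(stages, readout)
            configured = readout["expected"]
            report.append(
                {
                    "experiment": exp.name,
                    "label": readout.get("label", ""),
                    "force_type": readout["force_type"],
                    "strain": readout["strain"],
                    "mode": readout["mode"],
                    "configured_pct": 100.0 * configured,
                    "recovered_pct": 100.0 * recovered,
                    "abs_error_pp": abs(100.0 * (recovered - configured)),
                }
            )
    return report
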