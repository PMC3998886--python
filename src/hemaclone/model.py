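r"""Model core: feedback signals, effective rates, ODE right-hand side, and
analytic steady-state / takeover results.

The model tracks cell counts :math:`c_i` through maturation compartments.
Each dividing compartment divides at rate :math:`p_i = p_{max,i}\,s_p` and a
dividing cell's daughters stay in the compartment with probability
:math:`a_i = a_{max,i}\,s_a` (self-renewal) or move to the next compartment
with probability :math:`1 - a_i` (differentiation), giving

.. math::

    dc_1/dt = (2 a_1 - 1) p_1 c_1,\qquad
    dc_i/dt = 2 (1 - a_{i-1}) p_{i-1} c_{i-1} + (2 a_i - 1) p_i c_i,

while a terminal pool receives the differentiation flux of its predecessor
and dies at rate :math:`d`.  The two signals are shared by all lineages:
:math:`s_p = 1/(1 + k_p M)` with :math:`M` the total mature peripheral-blood
count, and :math:`s_a = 1/(1 + k_a W)` with :math:`W` the total occupancy of
the bone-marrow niche (the ``niche_depth`` most primitive compartments of
every lineage).
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .params import (
    Layout,
    LayoutError,
    ModelParams,
    ParamError,
    Signals,
    SystemState,
)

__all__ = [
    "NoSteadyStateError",
    "compute_signals",
    "effective_rates",
    "rhs",
    "rhs_counts",
    "healthy_steady_state",
    "takeover_predicate",
]


class NoSteadyStateError(RuntimeError):
    """The requested positive equilibrium does not exist."""


def _check(state: SystemState, params: ModelParams) -> None:
    if state.counts.shape != (params.n_compartments,):
        raise LayoutError(
            f"state length {state.counts.shape} does not match params layout "
            f"({params.n_compartments} compartments)"
        )
    if np.any(state.counts < 0):
        raise ParamError("cell counts must be nonnegative")


def signals_from_counts(counts: np.ndarray, layout: Layout) -> Signals:
    m = float(counts[layout.in_pb].sum())
    w = float(counts[layout.in_niche].sum())
    return Signals(s_p=1.0 / (1.0 + layout.k_p * m), s_a=1.0 / (1.0 + layout.k_a * w))


def compute_signals(state: SystemState, params: ModelParams) -> Signals:
    """Evaluate (s_p, s_a) for a state.

    Both signals are reciprocal-saturation functions of their driving pools:
    they equal 1 exactly when the pool is empty and decrease monotonically
    as it fills.
    """
    _check(state, params)
    return signals_from_counts(state.counts, params.layout())


def effective_rates(
    state: SystemState, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-compartment effective self-renewal fractions and division rates.

    Returns ``(a, p)`` with ``a[i] = a_max[i] * s_a`` and
    ``p[i] = p_max[i] * s_p`` for dividing compartments and ``(0, 0)`` for
    terminal pools.
    """
    _check(state, params)
    layout = params.layout()
    sig = signals_from_counts(state.counts, layout)
    a = np.where(layout.divides, layout.a_max * sig.s_a, 0.0)
    p = np.where(layout.divides, layout.p_max * sig.s_p, 0.0)
    return a, p


def rhs_counts(counts: np.ndarray, layout: Layout) -> np.ndarray:
    """Time derivative of the raw count vector (cells/day).

    This is the hot path used by the integrators; ``rhs`` is the checked
    public wrapper.
    """
    sig = signals_from_counts(counts, layout)
    a = layout.a_max * sig.s_a
    p = layout.p_max * sig.s_p
    net = np.where(layout.divides, (2.0 * a - 1.0) * p * counts, 0.0)
    outflux = np.where(layout.divides, 2.0 * (1.0 - a) * p * counts, 0.0)
    has_src = layout.inflow_src >= 0
    inflow = np.zeros_like(counts)
    inflow[has_src] = outflux[layout.inflow_src[has_src]]
    return net + inflow - layout.d * counts


def rhs(state: SystemState, params: ModelParams) -> np.ndarray:
    """ODE right-hand side evaluated at a state (cells/day per compartment)."""
    _check(state, params)
    return rhs_counts(state.counts, params.layout())


def _equilibrium_chain(lineage, s_a: float) -> np.ndarray:
    """Relative flux-balance counts of the dividing compartments at signal s_a.

    The proliferation signal cancels between dividing compartments, so the
    ratios depend only on s_a.  Raises if a downstream compartment is not
    strictly subcritical (a_i * s_a < 1/2 for i >= 2).
    """
    div = [c for c in lineage.compartments if c.divides]
    rel = [1.0]
    for i in range(1, len(div)):
        if div[i - 1].p_max <= 0 or div[i].p_max <= 0:
            raise NoSteadyStateError(
                f"{lineage.label}: dividing compartments need p_max > 0"
            )
        num = 2.0 * (1.0 - div[i - 1].a_max * s_a) * div[i - 1].p_max
        den = (1.0 - 2.0 * div[i].a_max * s_a) * div[i].p_max
        if den <= 0:
            raise NoSteadyStateError(
                f"{lineage.label}: compartment {div[i].name!r} is not subcritical "
                f"at s_a = {s_a:.4f} (a_max = {div[i].a_max})"
            )
        rel.append(rel[-1] * num / den)
    return np.asarray(rel)


def healthy_steady_state(
    params: ModelParams, lineage_label: str = "normal"
) -> SystemState:
    """Positive equilibrium of a single lineage, all other lineages at zero.

    At the fixed point the stem compartment balances exactly:
    ``a_max,1 * s_a* = 1/2``, hence ``s_a* = 1/(2 a_max,1)`` and the niche
    occupancy ``W* = (2 a_max,1 - 1)/k_a``.  Downstream dividing
    compartments follow from flux balance (s_p cancels); a terminal pool
    solves the scalar balance ``d c (1 + k_p c) = influx`` by root finding
    when it feeds the proliferation signal.

    Raises :class:`NoSteadyStateError` when ``a_max,1 <= 0.5`` (no positive
    fixed point) or a downstream compartment is supercritical at s_a*.
    """
    if len(params.lineages) == 1:
        lineage = params.lineages[0]
    else:
        lineage = params.lineage(lineage_label)
    head = lineage.compartments[0]
    if not head.divides:
        raise NoSteadyStateError(f"{lineage.label}: first compartment must divide")
    a1 = head.a_max
    if a1 <= 0.5:
        raise NoSteadyStateError(
            f"no positive steady state: a_max of {head.name!r} is {a1} <= 0.5"
        )
    fb = params.feedback
    s_a = 1.0 / (2.0 * a1)
    rel = _equilibrium_chain(lineage, s_a)
    w_star = (2.0 * a1 - 1.0) / fb.k_a
    niche_rel = rel[: fb.niche_depth].sum()
    c1 = w_star / niche_rel
    div_counts = c1 * rel

    counts = np.zeros(params.n_compartments)
    off = 0
    for lin in params.lineages:
        if lin.label == lineage.label:
            counts[off : off + len(rel)] = div_counts
            term = lin.compartments[-1]
            if not term.divides:
                last = [c for c in lin.compartments if c.divides][-1]
                influx = 2.0 * (1.0 - last.a_max * s_a) * last.p_max * div_counts[-1]
                if influx > 0 and term.d <= 0:
                    raise NoSteadyStateError(
                        f"{lineage.label}: terminal pool {term.name!r} receives flux "
                        "but has death rate 0"
                    )
                if term.d > 0 and influx > 0:
                    k_p = fb.k_p if term.in_pb else 0.0

                    def balance(c):
                        return term.d * c * (1.0 + k_p * c) - influx

                    hi = influx / term.d
                    c_term = brentq(balance, 0.0, hi, rtol=1e-15)
                    resid = balance(c_term)
                    if abs(resid) > 1e-6 * max(influx, 1.0):
                        raise NoSteadyStateError(
                            f"terminal-pool root finding failed, residual {resid:.3e}"
                        )
                    counts[off + len(lin.compartments) - 1] = c_term
        off += len(lin.compartments)
    return SystemState(t=0.0, counts=counts)


def takeover_predicate(params: ModelParams) -> bool:
    """Analytic takeover criterion for a two-lineage parameter set.

    The malignant stem compartment grows at the healthy equilibrium iff
    ``2 a_max,MDS * s_a* > 1`` with ``s_a* = 1/(2 a_max,N)``, i.e. iff the
    maximal self-renewal of the MDS stem compartment strictly exceeds that
    of the normal one -- independent of proliferation rates.
    """
    if len(params.lineages) < 2:
        raise ParamError("takeover_predicate requires two lineages (normal and mds)")
    normal = params.lineage("normal")
    mds = params.lineage("mds")
    return mds.compartments[0].a_max > normal.compartments[0].a_max
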