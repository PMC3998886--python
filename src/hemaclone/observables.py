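"""Summaries reported from states and trajectories: bone-marrow composition,
apoptotic-cell percentage, the CD34+-compartment proxy, and a per-sample
trajectory report.

Bone-marrow membership convention: every compartment that is not a mature
peripheral-blood pool (``in_pb=False``) resides in the marrow; mature pools
circulate and are excluded from marrow percentages.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .params import ModelParams, ParamError, SystemState
from .simulate import Trajectory, detect_manifestation

__all__ = [
    "bm_composition",
    "apoptotic_fraction",
    "primitive_fraction",
    "trajectory_summary",
]


def _bm_mask(params: ModelParams) -> np.ndarray:
    return ~params.layout().in_pb


def bm_composition(state: SystemState, params: ModelParams) -> pd.Series:
    """Percentage of bone-marrow cells per marrow compartment.

    Mature peripheral-blood pools are excluded from numerator and
    denominator; the result sums to 100.
    """
    state.check(params)
    mask = _bm_mask(params)
    total = state.counts[mask].sum()
    if total <= 0:
        raise ParamError("bone marrow is empty; composition undefined")
    labels = params.labels()
    index = pd.MultiIndex.from_tuples(
        [lab for lab, m in zip(labels, mask) if m], names=["lineage", "compartment"]
    )
    values = 100.0 * state.counts[mask] / total
    return pd.Series(values, index=index, name="percent_of_bm")


def apoptotic_fraction(
    state: SystemState, params: ModelParams, include_apoptotic_in_total: bool = True
) -> float:
    """Percentage of apoptotic cells in the bone marrow.

    Dying cells remain visible for ``apoptosis_visibility`` days, so the
    apoptotic pool is the instantaneous death flux of marrow compartments
    times that window: ``A = sum(d_i * c_i) * tau``.  Returned as
    ``100 * A / (BM + A)`` (or ``100 * A / BM`` when the apoptotic pool is
    excluded from the denominator).
    """
    state.check(params)
    layout = params.layout()
    mask = _bm_mask(params)
    tau = params.feedback.apoptosis_visibility
    apo = float((layout.d[mask] * state.counts[mask]).sum() * tau)
    bm = float(state.counts[mask].sum())
    denom = bm + apo if include_apoptotic_in_total else bm
    if denom <= 0:
        return 0.0
    return 100.0 * apo / denom


def primitive_fraction(state: SystemState, params: ModelParams) -> float:
    """Percentage of bone-marrow cells in the niche compartments (both
    lineages) -- the model's proxy for the CD34+ fraction."""
    state.check(params)
    layout = params.layout()
    mask = _bm_mask(params)
    bm = float(state.counts[mask].sum())
    if bm <= 0:
        return 0.0
    prim = float(state.counts[layout.in_niche].sum())
    return 100.0 * prim / bm


def trajectory_summary(
    traj: Trajectory, params: Optional[ModelParams] = None
) -> pd.DataFrame:
    """Per-sample report: compartment counts, signals, marrow composition,
    apoptotic and primitive percentages.

    One row per trajectory sample.  The manifestation time (if detected) is
    stored in ``frame.attrs["manifestation_years"]``.
    """
    params = params or traj.params
    frame = traj.to_frame()
    mask = _bm_mask(params)
    bm_counts = traj.counts[:, mask]
    bm_tot = bm_counts.sum(axis=1)
    layout = params.layout()

    with np.errstate(invalid="ignore", divide="ignore"):
        for j, (lab, m) in enumerate(zip(params.labels(), mask)):
            if m:
                col = traj.counts[:, j]
                frame[f"bm_pct:{lab[0]}:{lab[1]}"] = np.where(
                    bm_tot > 0, 100.0 * col / bm_tot, np.nan
                )
    tau = params.feedback.apoptosis_visibility
    apo = (traj.counts[:, mask] * layout.d[mask]).sum(axis=1) * tau
    frame["apoptotic_pct"] = np.where(
        bm_tot + apo > 0, 100.0 * apo / (bm_tot + apo), 0.0
    )
    prim = traj.counts[:, layout.in_niche].sum(axis=1)
    frame["primitive_pct"] = np.where(bm_tot > 0, 100.0 * prim / bm_tot, 0.0)

    frame.attrs["manifestation_years"] = traj.events.get("manifestation_years")
    return frame
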