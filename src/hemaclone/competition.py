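"""Long-run outcome classification and parameter sweeps over the malignant
clone's self-renewal and proliferation.

The sweep's self-renewal axis is the maximal self-renewal of the MDS stem
compartment; the remaining MDS compartments are scaled proportionally so
the clone keeps its internal self-renewal hierarchy (the stem compartment
stays the clone's maximum).  The proliferation axis multiplies every MDS
division rate by a common factor.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import healthy_steady_state, takeover_predicate
from .params import ModelParams, ParamError
from .simulate import ScenarioConfig, SimulationError, Trajectory, simulate
from .observables import _bm_mask

__all__ = [
    "CompetitionOutcome",
    "OutcomeGrid",
    "SweepSpec",
    "scaled_mds_params",
    "classify_outcome",
    "sweep",
    "predicate_concordance",
]


@dataclass(frozen=True)
class CompetitionOutcome:
    """Classification of one simulated competition scenario."""

    label: str                      # takeover | marginal | no_takeover
    normal_mature_fraction: float   # of healthy baseline, at horizon
    mds_bm_share: float             # fraction of bone marrow, at horizon
    manifestation_years: Optional[float]


@dataclass
class SweepSpec:
    """Grid of MDS stem self-renewal values x proliferation scalings."""

    a_mds_values: Sequence[float]
    p_scale_values: Sequence[float]
    variant: str = "baseline"
    horizon_years: float = 100.0
    seed_cells: float = 1.0

    def cells(self):
        for a in self.a_mds_values:          # row-major, reproducible order
            for s in self.p_scale_values:
                yield float(a), float(s)


@dataclass
class OutcomeGrid:
    spec: SweepSpec
    frame: pd.DataFrame  # columns: a_max_mds, p_scale, variant, label, ...

    def outcome(self, a: float, p_scale: float) -> str:
        sel = self.frame[
            (np.isclose(self.frame.a_max_mds, a))
            & (np.isclose(self.frame.p_scale, p_scale))
        ]
        if sel.empty:
            raise KeyError(f"no grid cell at a={a}, p_scale={p_scale}")
        return str(sel.iloc[0].label)


def scaled_mds_params(
    base: ModelParams, a_mds_stem: float, p_scale: float = 1.0
) -> ModelParams:
    """Copy of ``base`` with the MDS self-renewal hierarchy rescaled so the
    stem compartment has ``a_mds_stem``, and all MDS division rates
    multiplied by ``p_scale``."""
    if not 0 < a_mds_stem <= 1:
        raise ParamError(f"a_mds_stem must be in (0, 1], got {a_mds_stem}")
    if p_scale <= 0:
        raise ParamError(f"p_scale must be positive, got {p_scale}")
    params = base.copy()
    mds = params.lineage("mds")
    a0 = mds.compartments[0].a_max
    if a0 <= 0:
        raise ParamError("base MDS stem compartment must have a_max > 0")
    ratio = a_mds_stem / a0
    for c in mds.compartments:
        if c.divides:
            c.a_max = min(1.0, c.a_max * ratio)
            c.p_max = c.p_max * p_scale
    params.validate()
    return params


def classify_outcome(
    traj: Trajectory,
    params: Optional[ModelParams] = None,
    takeover_mature_fraction: float = 0.1,
    takeover_mds_share: float = 0.5,
    decline_mds_share: Optional[float] = None,
    decline_mature_fraction: float = 0.9,
) -> CompetitionOutcome:
    """Classify the end state of a two-lineage trajectory.

    takeover: normal mature output collapsed (< 10% of healthy baseline)
    and the clone dominates the marrow (> 50%).  no_takeover: the clone is
    back at seed level -- within one order of magnitude of its initial
    marrow share (a seeded stem cell populates a handful of downstream
    cells even while dying out), or below ``decline_mds_share`` if given --
    with normal output intact (>= 90%).  Everything else (including clones
    still expanding slowly at the horizon) is marginal.
    """
    params = params or traj.params
    if len(traj.times) < 2:
        raise ParamError("trajectory too short to classify")
    base = healthy_steady_state(params, "normal")
    normal = params.lineage("normal")
    mature_idx = params.index("normal", normal.compartments[-1].name)
    baseline = float(base.counts[mature_idx])

    final = traj.counts[-1]
    mature_frac = float(final[mature_idx] / baseline) if baseline > 0 else np.nan

    mask = _bm_mask(params)
    labels = params.labels()
    mds_mask = mask & np.array([lab[0] == "mds" for lab in labels])
    bm_total = float(final[mask].sum())
    mds_share = float(final[mds_mask].sum() / bm_total) if bm_total > 0 else 0.0

    if decline_mds_share is None:
        first = traj.counts[0]
        bm0 = float(first[mask].sum())
        seed_share = float(first[mds_mask].sum() / bm0) if bm0 > 0 else 0.0
        decline_mds_share = 10.0 * seed_share

    if mature_frac < takeover_mature_fraction and mds_share > takeover_mds_share:
        label = "takeover"
    elif mds_share <= decline_mds_share and mature_frac >= decline_mature_fraction:
        label = "no_takeover"
    else:
        label = "marginal"
    return CompetitionOutcome(
        label=label,
        normal_mature_fraction=mature_frac,
        mds_bm_share=mds_share,
        manifestation_years=traj.events.get("manifestation_years"),
    )


def sweep(
    spec: SweepSpec,
    base_params: ModelParams,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    output_interval_days: float = 90.0,
) -> OutcomeGrid:
    """Classify every grid cell; per-cell solver failures are recorded in
    the ``error`` column rather than aborting the sweep."""
    rows = []
    for a, p_scale in spec.cells():
        row = {"a_max_mds": a, "p_scale": p_scale, "variant": spec.variant}
        try:
            params = scaled_mds_params(base_params, a, p_scale)
            config = ScenarioConfig(
                params=params,
                seed_cells=spec.seed_cells,
                horizon_years=spec.horizon_years,
                output_interval_days=output_interval_days,
                rtol=rtol,
                atol=atol,
            )
            out = classify_outcome(simulate(config), params)
            row.update(
                label=out.label,
                normal_mature_fraction=out.normal_mature_fraction,
                mds_bm_share=out.mds_bm_share,
                manifestation_years=out.manifestation_years,
                error="",
            )
        except (SimulationError, ParamError) as exc:
            row.update(
                label="error",
                normal_mature_fraction=np.nan,
                mds_bm_share=np.nan,
                manifestation_years=None,
                error=str(exc),
            )
        rows.append(row)
    frame = pd.DataFrame(
        rows,
        columns=[
            "a_max_mds", "p_scale", "variant", "label",
            "normal_mature_fraction", "mds_bm_share",
            "manifestation_years", "error",
        ],
    )
    return OutcomeGrid(spec=spec, frame=frame)


def predicate_concordance(
    grid: OutcomeGrid, base_params: ModelParams
) -> dict:
    """Compare simulated classifications with the analytic takeover
    criterion.

    Marginal (and failed) cells are excluded; the report carries the
    concordant fraction over the remaining cells and lists discordant ones.
    ``concordance`` is ``None`` when every cell is marginal.
    """
    decided = grid.frame[grid.frame.label.isin(["takeover", "no_takeover"])]
    discordant = []
    n_match = 0
    for _, row in decided.iterrows():
        params = scaled_mds_params(base_params, row.a_max_mds, row.p_scale)
        predicted = takeover_predicate(params)
        simulated = row.label == "takeover"
        if predicted == simulated:
            n_match += 1
        else:
            discordant.append((float(row.a_max_mds), float(row.p_scale), row.label))
    n = len(decided)
    return {
        "n_cells": len(grid.frame),
        "n_decided": n,
        "concordance": (n_match / n) if n else None,
        "discordant": discordant,
    }
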