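"""Shipped parameterizations and hand-solvable toy fixtures.

Presets are packaged YAML resources; :func:`get_preset` returns a deep copy
so callers can mutate freely.  Provenance of every number is annotated in
the YAML files (``paper`` for values printed in the source study,
``reference-model`` for conventions carried over from the predecessor
hematopoiesis model, ``calibrated`` for values fitted once to the reported
disease course).
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .params import (
    CompartmentParams,
    FeedbackParams,
    LineageParams,
    ModelParams,
    ParamError,
    SystemState,
)

__all__ = ["PRESET_NAMES", "get_preset", "list_presets", "make_toy_fixture"]

PRESET_NAMES = (
    "healthy_default",
    "mds_baseline",
    "mds_full_maturation",
    "toy_two_compartment",
)


def list_presets() -> tuple[str, ...]:
    return PRESET_NAMES


def get_preset(name: str) -> ModelParams:
    """Load a named preset as a fresh :class:`ModelParams`."""
    if name not in PRESET_NAMES:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    ref = resources.files("hemaclone").joinpath(f"presets/{name}.yaml")
    data = yaml.safe_load(ref.read_text())
    return ModelParams.from_dict(data)


_TOY_FAMILIES = ("one_compartment", "two_compartment_chain")

# Gain small enough that signals stay numerically at 1.0 for any realistic
# toy count, making the chain exactly linear while honoring k > 0.
_NEGLIGIBLE_GAIN = 1e-300


def make_toy_fixture(family: str, a_max: float = 0.7, p_max: float = 0.1,
                     k_a: float = 1e-3, d: float = 0.5):
    """Return ``(params, state, expected)`` for a hand-solvable toy model.

    ``one_compartment``: a single self-regulating dividing compartment; the
    positive equilibrium is ``c* = (2 a_max - 1)/k_a`` at signal
    ``s_a* = 1/(2 a_max)``.

    ``two_compartment_chain``: a dividing compartment feeding a terminal
    dying pool with both gains negligible, i.e. a linear ODE
    ``dy/dt = A y``; ``expected["A"]`` is the 2x2 matrix for comparison
    against a matrix-exponential solution.
    """
    if family == "one_compartment":
        if a_max <= 0.5:
            raise ParamError("one-compartment toy needs a_max > 0.5")
        params = ModelParams(
            lineages=[
                LineageParams(
                    label="normal",
                    compartments=[
                        CompartmentParams(
                            name="stem", a_max=a_max, p_max=p_max, in_niche=True
                        )
                    ],
                )
            ],
            feedback=FeedbackParams(k_p=_NEGLIGIBLE_GAIN, k_a=k_a, niche_depth=1),
        )
        c_star = (2.0 * a_max - 1.0) / k_a
        state = SystemState(t=0.0, counts=np.array([c_star]))
        expected = {"steady_count": c_star, "s_a_star": 1.0 / (2.0 * a_max)}
        return params, state, expected

    if family == "two_compartment_chain":
        params = ModelParams(
            lineages=[
                LineageParams(
                    label="normal",
                    compartments=[
                        CompartmentParams(
                            name="stem", a_max=a_max, p_max=p_max, in_niche=True
                        ),
                        CompartmentParams(
                            name="mature", divides=False, d=d, in_pb=True
                        ),
                    ],
                )
            ],
            feedback=FeedbackParams(
                k_p=_NEGLIGIBLE_GAIN, k_a=_NEGLIGIBLE_GAIN, niche_depth=1
            ),
        )
        A = np.array(
            [
                [(2.0 * a_max - 1.0) * p_max, 0.0],
                [2.0 * (1.0 - a_max) * p_max, -d],
            ]
        )
        y0 = np.array([100.0, 0.0])
        state = SystemState(t=0.0, counts=y0.copy())
        expected = {"A": A, "y0": y0}
        return params, state, expected

    raise ParamError(
        f"unknown toy family {family!r}; available: {', '.join(_TOY_FAMILIES)}"
    )
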