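"""Parameter containers and state-vector layout.

The model couples one or two maturation hierarchies ("lineages") through two
shared scalar feedback signals.  Each lineage is an ordered list of
compartments, most primitive first; every compartment except (optionally)
the last one divides.  Terminal compartments (mature blood cells, dysplastic
precursors) do not divide and may die at rate ``d``.

All cell counts are real numbers (cells), time is measured in days, and
rates in 1/day.  The global state vector concatenates lineages in the order
given by :class:`ModelParams`, compartments in maturation order within each
lineage; :class:`Layout` caches the numpy views the ODE right-hand side
needs.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ParamError",
    "LayoutError",
    "FeedbackParams",
    "CompartmentParams",
    "LineageParams",
    "ModelParams",
    "SystemState",
    "Signals",
    "Layout",
]


class ParamError(ValueError):
    """Raised when a parameter set violates a model invariant."""


class LayoutError(ValueError):
    """Raised when a state vector does not match a parameter set's layout."""


@dataclass
class FeedbackParams:
    """Gains and conventions of the two feedback signals.

    ``k_p`` (1/cells) scales the mature peripheral-blood pool in the
    proliferation signal s_p = 1/(1 + k_p * M); ``k_a`` (1/cells) scales the
    niche occupancy in the self-renewal signal s_a = 1/(1 + k_a * W).
    ``niche_depth`` is the number of most-primitive compartments of each
    lineage occupying the bone-marrow niche.  ``apoptosis_visibility`` is
    how long (days) a dying cell remains countable as apoptotic.
    """

    k_p: float
    k_a: float
    niche_depth: int = 3
    apoptosis_visibility: float = 1.0

    def validate(self) -> None:
        if not self.k_p > 0:
            raise ParamError(f"k_p must be > 0, got {self.k_p}")
        if not self.k_a > 0:
            raise ParamError(f"k_a must be > 0, got {self.k_a}")
        if int(self.niche_depth) != self.niche_depth or self.niche_depth < 1:
            raise ParamError(f"niche_depth must be an integer >= 1, got {self.niche_depth}")
        if not self.apoptosis_visibility > 0:
            raise ParamError("apoptosis_visibility must be > 0")


@dataclass
class CompartmentParams:
    """One maturation stage of one lineage.

    ``a_max`` is the maximal self-renewal fraction (probability that a
    daughter cell stays in the compartment), ``p_max`` the maximal division
    rate (1/day), ``d`` the death rate (1/day, nonzero only for terminal
    pools in the default model).  ``in_niche`` marks membership in the
    bone-marrow niche (drives s_a), ``in_pb`` marks mature peripheral-blood
    pools (drive s_p).
    """

    name: str
    a_max: float = 0.0
    p_max: float = 0.0
    d: float = 0.0
    divides: bool = True
    in_niche: bool = False
    in_pb: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.a_max <= 1.0:
            raise ParamError(f"{self.name}: a_max must be in [0, 1], got {self.a_max}")
        if self.p_max < 0:
            raise ParamError(f"{self.name}: p_max must be >= 0, got {self.p_max}")
        if self.d < 0:
            raise ParamError(f"{self.name}: d must be >= 0, got {self.d}")
        if self.in_pb and self.divides:
            raise ParamError(f"{self.name}: peripheral-blood pools are terminal (divides=False)")


@dataclass
class LineageParams:
    label: str
    compartments: list[CompartmentParams]

    def validate(self, niche_depth: int) -> None:
        if not self.compartments:
            raise ParamError(f"lineage {self.label!r} has no compartments")
        for c in self.compartments:
            c.validate()
        n = len(self.compartments)
        for i, c in enumerate(self.compartments):
            if not c.divides and i != n - 1:
                raise ParamError(
                    f"lineage {self.label!r}: only the last compartment may be terminal"
                )
        n_div = sum(c.divides for c in self.compartments)
        if niche_depth > n_div:
            raise ParamError(
                f"lineage {self.label!r}: niche_depth {niche_depth} exceeds "
                f"number of dividing compartments ({n_div})"
            )
        for i, c in enumerate(self.compartments):
            if c.in_niche != (i < niche_depth):
                raise ParamError(
                    f"lineage {self.label!r}: exactly the first {niche_depth} "
                    f"compartments must have in_niche=True"
                )

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]


@dataclass
class ModelParams:
    """Full parameterization of a scenario: lineages plus feedback gains."""

    lineages: list[LineageParams]
    feedback: FeedbackParams
    variant: str = "baseline"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.feedback.validate()
        if not self.lineages:
            raise ParamError("at least one lineage is required")
        labels = [lin.label for lin in self.lineages]
        if len(set(labels)) != len(labels):
            raise ParamError(f"lineage labels must be unique, got {labels}")
        for lin in self.lineages:
            lin.validate(self.feedback.niche_depth)

    # -- layout -----------------------------------------------------------

    @property
    def n_compartments(self) -> int:
        return sum(len(lin.compartments) for lin in self.lineages)

    def lineage(self, label: str) -> LineageParams:
        for lin in self.lineages:
            if lin.label == label:
                return lin
        raise KeyError(f"no lineage labelled {label!r}; have {[l.label for l in self.lineages]}")

    def layout(self) -> "Layout":
        return Layout.from_params(self)

    def index(self, lineage: str, compartment: str) -> int:
        """Global state-vector index of a (lineage, compartment) pair."""
        off = 0
        for lin in self.lineages:
            if lin.label == lineage:
                for i, c in enumerate(lin.compartments):
                    if c.name == compartment:
                        return off + i
                raise KeyError(f"no compartment {compartment!r} in lineage {lineage!r}")
            off += len(lin.compartments)
        raise KeyError(f"no lineage labelled {lineage!r}")

    def labels(self) -> list[tuple[str, str]]:
        """(lineage, compartment) pairs in state-vector order."""
        return [(lin.label, c.name) for lin in self.lineages for c in lin.compartments]

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "feedback": {
                "k_p": float(self.feedback.k_p),
                "k_a": float(self.feedback.k_a),
                "niche_depth": int(self.feedback.niche_depth),
                "apoptosis_visibility": float(self.feedback.apoptosis_visibility),
            },
            "lineages": [
                {
                    "label": lin.label,
                    "compartments": [
                        {
                            "name": c.name,
                            "a_max": float(c.a_max),
                            "p_max": float(c.p_max),
                            "d": float(c.d),
                            "divides": bool(c.divides),
                            "in_niche": bool(c.in_niche),
                            "in_pb": bool(c.in_pb),
                        }
                        for c in lin.compartments
                    ],
                }
                for lin in self.lineages
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        fb = FeedbackParams(**data["feedback"])
        lineages = [
            LineageParams(
                label=ld["label"],
                compartments=[CompartmentParams(**cd) for cd in ld["compartments"]],
            )
            for ld in data["lineages"]
        ]
        return cls(lineages=lineages, feedback=fb, variant=data.get("variant", "baseline"))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelParams":
        """Load from a YAML string, file path, or open file handle."""
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" not in text and not text.strip().startswith("{"):
                with open(text) as fh:
                    data = yaml.safe_load(fh)
            else:
                data = yaml.safe_load(text)
        return cls.from_dict(data)


def make_lineage(
    label: str,
    names: Sequence[str],
    a_max: Sequence[float],
    p_max: Sequence[float],
    niche_depth: int = 3,
    terminal: str | None = None,
    terminal_d: float = 0.0,
    terminal_in_pb: bool = False,
) -> LineageParams:
    """Convenience constructor for a dividing chain plus optional terminal pool.

    ``names``/``a_max``/``p_max`` describe the dividing compartments in
    maturation order; ``terminal`` appends a non-dividing pool with death
    rate ``terminal_d``.
    """
    if not (len(names) == len(a_max) == len(p_max)):
        raise ParamError("names, a_max and p_max must have equal length")
    comps = [
        CompartmentParams(
            name=n, a_max=float(a), p_max=float(p), divides=True, in_niche=(i < niche_depth)
        )
        for i, (n, a, p) in enumerate(zip(names, a_max, p_max))
    ]
    if terminal is not None:
        comps.append(
            CompartmentParams(
                name=terminal,
                divides=False,
                d=float(terminal_d),
                in_niche=len(comps) < niche_depth,
                in_pb=terminal_in_pb,
            )
        )
    return LineageParams(label=label, compartments=comps)


@dataclass(frozen=True)
class Layout:
    """Flat numpy views of a :class:`ModelParams` for the ODE right-hand side.

    ``inflow_src[i]`` is the global index of the dividing compartment whose
    differentiation flux feeds compartment ``i`` (-1 for lineage heads).
    """

    n: int
    a_max: np.ndarray
    p_max: np.ndarray
    d: np.ndarray
    divides: np.ndarray
    in_niche: np.ndarray
    in_pb: np.ndarray
    inflow_src: np.ndarray
    k_p: float
    k_a: float
    labels: tuple

    @classmethod
    def from_params(cls, params: ModelParams) -> "Layout":
        a, p, d, dv, nn, pb, src, labels = [], [], [], [], [], [], [], []
        off = 0
        for lin in params.lineages:
            for i, c in enumerate(lin.compartments):
                a.append(c.a_max)
                p.append(c.p_max)
                d.append(c.d)
                dv.append(c.divides)
                nn.append(c.in_niche)
                pb.append(c.in_pb)
                src.append(off + i - 1 if i > 0 else -1)
                labels.append((lin.label, c.name))
            off += len(lin.compartments)
        return cls(
            n=off,
            a_max=np.asarray(a, float),
            p_max=np.asarray(p, float),
            d=np.asarray(d, float),
            divides=np.asarray(dv, bool),
            in_niche=np.asarray(nn, bool),
            in_pb=np.asarray(pb, bool),
            inflow_src=np.asarray(src, int),
            k_p=float(params.feedback.k_p),
            k_a=float(params.feedback.k_a),
            labels=tuple(labels),
        )


@dataclass
class SystemState:
    """Cell counts per (lineage, compartment) at one time point."""

    t: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)

    def check(self, params: ModelParams) -> None:
        if self.counts.shape != (params.n_compartments,):
            raise LayoutError(
                f"state has {self.counts.shape} counts, params define "
                f"{params.n_compartments} compartments"
            )
        if np.any(self.counts < 0):
            raise ParamError("cell counts must be nonnegative")

    def get(self, params: ModelParams, lineage: str, compartment: str) -> float:
        return float(self.counts[params.index(lineage, compartment)])

    def copy(self) -> "SystemState":
        return SystemState(t=self.t, counts=self.counts.copy())


@dataclass(frozen=True)
class Signals:
    """The proliferation / self-renewal feedback pair, each in (0, 1]."""

    s_p: float
    s_a: float
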