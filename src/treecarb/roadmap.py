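"""Component-aggregation roadmap: interval ADD and OR over envelopes.

Few equations predict whole-tree biomass directly; totals are assembled
from lesser components along a calculation roadmap — a DAG whose
processing steps are addition (``+``) and comparison (``OR``).  Because
envelopes are intervals rather than point estimates, each addition step
must assume something about how components co-vary within a tree:

positive correlation
    extremes co-occur (a tall-for-its-DBH tree is heavy everywhere):
    ``[la, ua] + [lb, ub] = [la + lb, ua + ub]`` — the widest sums;
negative correlation
    one component's maximum pairs with another's minimum (allocation to
    one part at the expense of the others): the sum is the interval
    between the two cross-pairings ``la + ub`` and ``ua + lb``, whose
    width is ``|width_a - width_b|`` — never wider than the positive
    sum.

Neither assumption is claimed realistic; together they bracket the
possibilities.  Negative-mode addition is not associative, so steps are
folded left-to-right in the roadmap's declared order, which is recorded
in the output metadata.

An OR step retains the outer bounds across alternative calculation
pathways (per-class union of the defined alternatives).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import numpy as np

from .envelopes import Envelope

__all__ = [
    "AddStep",
    "OrStep",
    "Roadmap",
    "add_envelopes",
    "union_envelopes",
    "total_tree_envelope",
    "POSITIVE",
    "NEGATIVE",
]

POSITIVE = "positive"
NEGATIVE = "negative"
CORRELATION_MODES = (POSITIVE, NEGATIVE)


@dataclass(frozen=True)
class AddStep:
    inputs: tuple[str, ...]
    output: str


@dataclass(frozen=True)
class OrStep:
    alternatives: tuple[str, ...]
    output: str


Step = Union[AddStep, OrStep]


class Roadmap:
    """Directed acyclic aggregation scheme over component names.

    Leaves are components estimated directly from equations; every other
    node is produced by exactly one ADD or OR step; a single terminal
    node (by default ``"total tree"``) closes the DAG.
    """

    def __init__(self, steps: Sequence[Step], terminal: str = "total tree", name: str = ""):
        self.steps = list(steps)
        self.terminal = terminal
        self.name = name
        self._validate()

    def _validate(self) -> None:
        g = nx.DiGraph()
        outputs = [s.output for s in self.steps]
        if len(set(outputs)) != len(outputs):
            dupes = sorted({o for o in outputs if outputs.count(o) > 1})
            raise ValueError(f"components produced by more than one step: {dupes}")
        for s in self.steps:
            ins = s.inputs if isinstance(s, AddStep) else s.alternatives
            if len(ins) < (2 if isinstance(s, AddStep) else 1):
                raise ValueError(f"step producing {s.output!r} needs more inputs")
            for i in ins:
                g.add_edge(i, s.output)
        if self.terminal not in g:
            raise ValueError(f"terminal component {self.terminal!r} is never produced")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"roadmap contains a cycle: {cycle}")
        sinks = [n for n in g if g.out_degree(n) == 0]
        if sinks != [self.terminal] and set(sinks) != {self.terminal}:
            raise ValueError(f"expected the single terminal {self.terminal!r}, found sinks {sinks}")
        self.graph = g
        order = {n: i for i, n in enumerate(nx.topological_sort(g))}
        self.steps = sorted(self.steps, key=lambda s: order[s.output])

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def leaves(self) -> list[str]:
        produced = {s.output for s in self.steps}
        return [n for n in self.graph.nodes if n not in produced]

    # -- (de)serialisation --------------------------------------------------
    @classmethod
    def from_dict(cls, doc: Mapping) -> "Roadmap":
        steps: list[Step] = []
        for rec in doc.get("steps", []):
            op = rec.get("op")
            if op == "add":
                steps.append(AddStep(tuple(rec["inputs"]), rec["output"]))
            elif op == "or":
                steps.append(OrStep(tuple(rec["alternatives"]), rec["output"]))
            else:
                raise ValueError(f"unknown roadmap op {op!r}")
        return cls(steps, terminal=doc.get("terminal", "total tree"), name=doc.get("name", ""))

    @classmethod
    def from_json(cls, path) -> "Roadmap":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_dict(self) -> dict:
        steps = []
        for s in self.steps:
            if isinstance(s, AddStep):
                steps.append({"op": "add", "inputs": list(s.inputs), "output": s.output})
            else:
                steps.append({"op": "or", "alternatives": list(s.alternatives), "output": s.output})
        return {"name": self.name, "terminal": self.terminal, "steps": steps}

    @classmethod
    def default(cls) -> "Roadmap":
        """The packaged default roadmap.

        stem wood + stem bark -> bole; branches + foliage -> crown (OR a
        direct live-crown equation); bole + crown -> aboveground (OR a
        direct aboveground-total equation); aboveground + coarse roots
        -> total tree.
        """
        text = resources.files("treecarb.data").joinpath("default_roadmap.json").read_text(
            encoding="utf-8"
        )
        return cls.from_dict(json.loads(text))


def _check_compatible(envs: Sequence[Envelope]) -> None:
    first = envs[0]
    for e in envs[1:]:
        if e.units != first.units:
            from .envelopes import UnitError

            raise UnitError(f"unit mismatch: {first.units!r} vs {e.units!r}")
        if e.species != first.species:
            raise ValueError(f"species mismatch: {first.species!r} vs {e.species!r}")
        if e.grid.shape != first.grid.shape or np.any(e.grid != first.grid):
            raise ValueError("grid mismatch between envelopes")


def add_envelopes(
    a: Envelope, b: Envelope, mode: str = POSITIVE, *, name: str | None = None
) -> Envelope:
    """Interval sum of two envelopes under a correlation assumption."""
    if mode not in CORRELATION_MODES:
        raise ValueError(f"unknown correlation mode {mode!r}")
    _check_compatible([a, b])
    defined = a.defined & b.defined
    if mode == POSITIVE:
        lower = a.lower + b.lower
        upper = a.upper + b.upper
    else:
        x1 = a.lower + b.upper
        x2 = a.upper + b.lower
        lower = np.minimum(x1, x2)
        upper = np.maximum(x1, x2)
    return Envelope(
        species=a.species,
        component=name or f"{a.component} + {b.component}",
        units=a.units,
        grid=a.grid.copy(),
        lower=np.where(defined, lower, np.nan),
        upper=np.where(defined, upper, np.nan),
        defined=defined,
        meta={"correlation": mode},
    )


def union_envelopes(
    alternatives: Sequence[Envelope], *, name: str | None = None
) -> Envelope:
    """Outer bounds across alternative pathways (per-class union).

    Defined wherever any alternative is defined; provenance carries over
    from whichever alternative set each bound.
    """
    alternatives = list(alternatives)
    if not alternatives:
        raise ValueError("union of no envelopes")
    _check_compatible(alternatives)
    first = alternatives[0]
    lo = np.vstack([e.lower for e in alternatives])
    hi = np.vstack([e.upper for e in alternatives])
    defined = np.vstack([e.defined for e in alternatives]).any(axis=0)
    lower = np.full(first.grid.shape, np.nan)
    upper = np.full(first.grid.shape, np.nan)
    lower[defined] = np.nanmin(lo[:, defined], axis=0)
    upper[defined] = np.nanmax(hi[:, defined], axis=0)

    def _pick(stack, ids_attr, reduced):
        ids = np.full(first.grid.shape, None, dtype=object)
        cols = np.where(defined)[0]
        which = reduced(np.where(np.isfinite(stack[:, cols]), stack[:, cols], np.nan), axis=0)
        for j, col in enumerate(cols):
            src = alternatives[which[j]]
            src_ids = getattr(src, ids_attr)
            ids[col] = None if src_ids is None else src_ids[col]
        return ids

    lower_id = _pick(lo, "lower_eq_id", np.nanargmin)
    upper_id = _pick(hi, "upper_eq_id", np.nanargmax)
    return Envelope(
        species=first.species,
        component=name or " | ".join(e.component for e in alternatives),
        units=first.units,
        grid=first.grid.copy(),
        lower=lower,
        upper=upper,
        defined=defined,
        lower_eq_id=lower_id,
        upper_eq_id=upper_id,
    )


def total_tree_envelope(
    roadmap: Roadmap,
    component_envelopes: Mapping[str, Envelope],
    mode: str = POSITIVE,
    *,
    strict: bool = True,
) -> tuple[Envelope, dict[str, Envelope]]:
    """Fold the roadmap's ADD/OR steps to the terminal envelope.

    Steps are processed in topological order; ADD folds its inputs
    left-to-right (the fold order matters under negative correlation and
    is recorded in the result metadata).  Returns the terminal envelope
    and every intermediate for inspection.

    With ``strict=True`` every leaf must have an envelope.  With
    ``strict=False``, OR alternatives without an envelope are dropped
    and an ADD with a missing input leaves its output unavailable —
    mirroring species for which no equation exists for some pathway; an
    error is raised only if the terminal itself ends up unavailable.
    """
    if mode not in CORRELATION_MODES:
        raise ValueError(f"unknown correlation mode {mode!r}")
    envs: dict[str, Envelope] = dict(component_envelopes)
    if strict:
        missing = [leaf for leaf in roadmap.leaves() if leaf not in envs]
        if missing:
            raise KeyError(f"missing leaf envelopes: {missing}")
    skipped: list[str] = []
    for step in roadmap.steps:
        if isinstance(step, AddStep):
            if any(i not in envs for i in step.inputs):
                if strict:
                    raise KeyError(
                        f"ADD -> {step.output!r}: missing inputs "
                        f"{[i for i in step.inputs if i not in envs]}"
                    )
                skipped.append(step.output)
                continue
            acc = envs[step.inputs[0]]
            for nxt in step.inputs[1:]:
                acc = add_envelopes(acc, envs[nxt], mode, name=step.output)
            acc.component = step.output
            acc.meta["fold"] = list(step.inputs)
            envs[step.output] = acc
        else:
            present = [envs[a] for a in step.alternatives if a in envs]
            if not present or (strict and len(present) < len(step.alternatives)):
                if strict or not present:
                    if strict:
                        raise KeyError(
                            f"OR -> {step.output!r}: missing alternatives "
                            f"{[a for a in step.alternatives if a not in envs]}"
                        )
                    skipped.append(step.output)
                    continue
            merged = union_envelopes(present, name=step.output)
            merged.meta["alternatives"] = [e.component for e in present]
            envs[step.output] = merged
    if roadmap.terminal not in envs:
        raise KeyError(
            f"terminal {roadmap.terminal!r} unavailable; steps skipped for missing "
            f"inputs: {skipped}"
        )
    total = envs[roadmap.terminal]
    total.meta.update({"correlation": mode, "skipped_steps": skipped})
    return total, envs
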