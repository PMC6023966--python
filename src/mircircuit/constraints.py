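"""Laboratory-feasibility constraints for classifier circuits.

The *core constraints* bound the overall number of gates and inputs and
restrict every gate to one of a small repertoire of assemblable gate
types.  A gate type is described by five bounds: lower/upper bounds on
non-negated and on negated inputs per gate, plus an upper bound on how
many gates of that type one classifier may contain.  Optional extensions
are upper bounds on false-negative/false-positive errors (used by the
relaxation procedure) and the unique-input constraint (no miRNA shared
across gates).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace

from .classifiers import Classifier, Gate

__all__ = [
    "GateTypeSpec",
    "ConstraintProfile",
    "Violation",
    "core_profile",
    "validate_classifier",
    "assign_gate_types",
    "load_constraints",
    "save_constraints",
]


@dataclass(frozen=True)
class GateTypeSpec:
    """One assemblable gate type (five bounds, Fig.-4 style)."""

    type_id: int
    lb_pos: int
    ub_pos: int
    lb_neg: int
    ub_neg: int
    max_occurrences: int

    def __post_init__(self):
        if not (0 <= self.lb_pos <= self.ub_pos):
            raise ValueError(
                f"gate type {self.type_id}: need 0 <= lb_pos <= ub_pos, "
                f"got ({self.lb_pos}, {self.ub_pos})"
            )
        if not (0 <= self.lb_neg <= self.ub_neg):
            raise ValueError(
                f"gate type {self.type_id}: need 0 <= lb_neg <= ub_neg, "
                f"got ({self.lb_neg}, {self.ub_neg})"
            )
        if self.lb_pos + self.lb_neg < 1 and self.ub_pos + self.ub_neg < 1:
            raise ValueError(f"gate type {self.type_id}: gate must admit an input")
        if self.max_occurrences < 0:
            raise ValueError(f"gate type {self.type_id}: max_occurrences < 0")

    def admits(self, gate: Gate) -> bool:
        """Sign-bound check only (occurrence caps are classifier-level)."""
        return (
            self.lb_pos <= gate.n_positive <= self.ub_pos
            and self.lb_neg <= gate.n_negated <= self.ub_neg
        )


@dataclass(frozen=True)
class ConstraintProfile:
    """Global bounds, gate-type repertoire, error bounds and flags."""

    max_gates: int
    max_inputs: int
    gate_types: tuple[GateTypeSpec, ...]
    unique_input: bool = False
    fn_bound: int = 0
    fp_bound: int = 0

    def __init__(self, max_gates, max_inputs, gate_types, unique_input=False,
                 fn_bound=0, fp_bound=0):
        if max_gates < 1:
            raise ValueError(f"max_gates must be >= 1, got {max_gates}")
        if max_inputs < 1:
            raise ValueError(f"max_inputs must be >= 1, got {max_inputs}")
        gate_types = tuple(gate_types)
        if not gate_types:
            raise ValueError("at least one gate type is required")
        ids = [t.type_id for t in gate_types]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate gate type ids: {ids}")
        if fn_bound < 0 or fp_bound < 0:
            raise ValueError("error bounds must be >= 0")
        object.__setattr__(self, "max_gates", int(max_gates))
        object.__setattr__(self, "max_inputs", int(max_inputs))
        object.__setattr__(self, "gate_types", gate_types)
        object.__setattr__(self, "unique_input", bool(unique_input))
        object.__setattr__(self, "fn_bound", int(fn_bound))
        object.__setattr__(self, "fp_bound", int(fp_bound))

    def with_bounds(self, fn_bound: int, fp_bound: int) -> "ConstraintProfile":
        return replace(self, fn_bound=fn_bound, fp_bound=fp_bound)


def core_profile() -> ConstraintProfile:
    """The core laboratory constraints: up to 6 gates with overall up to 8
    inputs; Type 1 (OR gate) takes only non-negated inputs, Type 2 (NOT
    gate) is a single negated input.

    The per-type occurrence caps default to ``max_gates`` (the least
    restrictive reading); override via the config file if tighter caps are
    required.
    """
    max_gates, max_inputs = 6, 8
    return ConstraintProfile(
        max_gates=max_gates,
        max_inputs=max_inputs,
        gate_types=(
            GateTypeSpec(type_id=1, lb_pos=1, ub_pos=max_inputs,
                         lb_neg=0, ub_neg=0, max_occurrences=max_gates),
            GateTypeSpec(type_id=2, lb_pos=0, ub_pos=0,
                         lb_neg=1, ub_neg=1, max_occurrences=max_gates),
        ),
        unique_input=False,
        fn_bound=0,
        fp_bound=0,
    )


@dataclass(frozen=True)
class Violation:
    code: str
    message: str

    def __str__(self):
        return f"[{self.code}] {self.message}"


def assign_gate_types(
    c: Classifier, p: ConstraintProfile
) -> tuple[int, ...] | None:
    """Exact search for an assignment of gates to gate types respecting
    sign bounds and occurrence caps; ``None`` if no assignment exists.

    Greedy assignment can falsely reject feasible classifiers, so this is a
    small backtracking search (gate counts are tiny).
    """
    candidates = [
        [t.type_id for t in p.gate_types if t.admits(g)] for g in c.gates
    ]
    if any(not cand for cand in candidates):
        return None
    caps = {t.type_id: t.max_occurrences for t in p.gate_types}
    order = sorted(range(len(candidates)), key=lambda i: len(candidates[i]))
    assignment: dict[int, int] = {}

    def backtrack(k: int) -> bool:
        if k == len(order):
            return True
        i = order[k]
        for tid in candidates[i]:
            if caps[tid] > 0:
                caps[tid] -= 1
                assignment[i] = tid
                if backtrack(k + 1):
                    return True
                caps[tid] += 1
        return False

    if not backtrack(0):
        return None
    return tuple(assignment[i] for i in range(len(c.gates)))


def validate_classifier(c: Classifier, p: ConstraintProfile) -> list[Violation]:
    """All feasibility violations of *c* under profile *p* (empty = feasible).

    Checks, in order: gate count, total inputs, per-gate sign-bound
    assignability, occurrence caps under an exact type assignment, and the
    unique-input constraint when active.  Violations are data, not
    exceptions.
    """
    out: list[Violation] = []
    if c.n_gates > p.max_gates:
        out.append(Violation(
            "gate_count", f"gate count {c.n_gates} > {p.max_gates}"))
    if c.n_inputs > p.max_inputs:
        out.append(Violation(
            "input_count", f"total inputs {c.n_inputs} > {p.max_inputs}"))
    unassignable = False
    for i, g in enumerate(c.gates, start=1):
        if not any(t.admits(g) for t in p.gate_types):
            unassignable = True
            out.append(Violation(
                "gate_type",
                f"gate {i} {g} ({g.n_positive} positive, {g.n_negated} negated "
                f"inputs) fits no gate type",
            ))
    if not unassignable and assign_gate_types(c, p) is None:
        out.append(Violation(
            "occurrences",
            "no assignment of gates to gate types respects the occurrence caps",
        ))
    if p.unique_input:
        seen: dict[str, int] = {}
        flagged = set()
        for i, g in enumerate(c.gates, start=1):
            for m in sorted(g.markers()):
                if m in seen and m not in flagged:
                    out.append(Violation(
                        "unique_input",
                        f"marker {m} is shared by gates {seen[m]} and {i}",
                    ))
                    flagged.add(m)
                seen.setdefault(m, i)
    return out


# ---------------------------------------------------------------------------
# Config file round-trip (flat key-value, one section per gate type)


def save_constraints(p: ConstraintProfile, path) -> None:
    cfg = configparser.ConfigParser()
    cfg["classifier"] = {
        "max_gates": str(p.max_gates),
        "max_inputs": str(p.max_inputs),
        "unique_input": str(p.unique_input).lower(),
        "fn_bound": str(p.fn_bound),
        "fp_bound": str(p.fp_bound),
    }
    for t in p.gate_types:
        cfg[f"gate_type {t.type_id}"] = {
            "lb_pos": str(t.lb_pos),
            "ub_pos": str(t.ub_pos),
            "lb_neg": str(t.lb_neg),
            "ub_neg": str(t.ub_neg),
            "max_occurrences": str(t.max_occurrences),
        }
    with open(path, "w") as fh:
        cfg.write(fh)


def load_constraints(path) -> ConstraintProfile:
    cfg = configparser.ConfigParser()
    read = cfg.read(path)
    if not read:
        raise FileNotFoundError(path)
    if "classifier" not in cfg:
        raise ValueError("constraint config: missing [classifier] section")
    sec = cfg["classifier"]
    try:
        gate_types = []
        for name in cfg.sections():
            if not name.startswith("gate_type"):
                continue
            tid = int(name.split()[1])
            s = cfg[name]
            gate_types.append(GateTypeSpec(
                type_id=tid,
                lb_pos=int(s["lb_pos"]), ub_pos=int(s["ub_pos"]),
                lb_neg=int(s["lb_neg"]), ub_neg=int(s["ub_neg"]),
                max_occurrences=int(s["max_occurrences"]),
            ))
        return ConstraintProfile(
            max_gates=int(sec["max_gates"]),
            max_inputs=int(sec["max_inputs"]),
            gate_types=sorted(gate_types, key=lambda t: t.type_id),
            unique_input=sec.get("unique_input", "false").lower()
            in ("1", "true", "yes"),
            fn_bound=int(sec.get("fn_bound", "0")),
            fp_bound=int(sec.get("fp_bound", "0")),
        )
    except KeyError as exc:
        raise ValueError(f"constraint config: missing field {exc}") from None
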