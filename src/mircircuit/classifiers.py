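"""CNF cell-classifier data model.

A classifier is a Boolean function f : {0,1}^n -> {0,1} in Conjunctive
Normal Form: a conjunction (AND) of gates, each gate a disjunction (OR)
of possibly negated miRNA literals.  A sample is classified positive
(output 1) iff every gate contains at least one satisfied literal.

The text format accepts both Unicode (``∧ ∨ ¬``) and ASCII
(``& | !``, or the keywords AND/OR/NOT) operators; the formatter emits
ASCII, one parenthesized gate per conjunct, e.g. ``(g1 | g3) & (!g2)``.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Literal",
    "Gate",
    "Classifier",
    "ErrorCount",
    "ClassifierSyntaxError",
    "parse_classifier",
    "format_classifier",
    "evaluate",
    "evaluate_dataset",
    "count_errors",
    "canonicalize",
    "reduce_to_isomorphism_classes",
    "count_isomorphic_labelings",
    "to_dot",
]


@dataclass(frozen=True, order=True)
class Literal:
    """A possibly negated miRNA input; sort order: marker token, then sign
    (non-negated before negated)."""

    mirna_id: str
    negated: bool = False

    def __post_init__(self):
        if not self.mirna_id:
            raise ValueError("literal requires a non-empty miRNA identifier")

    def __str__(self):
        return ("!" if self.negated else "") + self.mirna_id


@dataclass(frozen=True)
class Gate:
    """One CNF clause (disjunction of literals); realized in the lab as an
    OR-of-activators or a single-input NOT construct.

    A marker may not appear twice in one gate: a repeated sign is redundant
    and opposite signs make the clause a tautology.  ``assigned_type`` may
    hold a gate-type id once a constraint profile has been matched.
    """

    literals: tuple[Literal, ...]
    assigned_type: int | None = None

    def __init__(self, literals: Iterable[Literal], assigned_type: int | None = None):
        lits = tuple(literals)
        if not lits:
            raise ValueError("a gate must have at least one literal")
        markers = [l.mirna_id for l in lits]
        if len(set(markers)) != len(markers):
            dup = sorted({m for m in markers if markers.count(m) > 1})
            raise ValueError(f"marker(s) {dup} appear more than once in one gate")
        object.__setattr__(self, "literals", lits)
        object.__setattr__(self, "assigned_type", assigned_type)

    @property
    def n_inputs(self) -> int:
        return len(self.literals)

    @property
    def n_positive(self) -> int:
        return sum(not l.negated for l in self.literals)

    @property
    def n_negated(self) -> int:
        return sum(l.negated for l in self.literals)

    def markers(self) -> set[str]:
        return {l.mirna_id for l in self.literals}

    def sort_key(self) -> tuple:
        return tuple((l.mirna_id, l.negated) for l in sorted(self.literals))

    def __str__(self):
        return "(" + " | ".join(str(l) for l in self.literals) + ")"


@dataclass(frozen=True)
class Classifier:
    """An ordered, non-empty conjunction of gates."""

    gates: tuple[Gate, ...]

    def __init__(self, gates: Iterable[Gate]):
        gates = tuple(gates)
        if not gates:
            raise ValueError("a classifier must have at least one gate")
        object.__setattr__(self, "gates", gates)

    @property
    def n_gates(self) -> int:
        return len(self.gates)

    @property
    def n_inputs(self) -> int:
        return sum(g.n_inputs for g in self.gates)

    def markers(self) -> set[str]:
        return set().union(*(g.markers() for g in self.gates))

    def __str__(self):
        return format_classifier(self)


@dataclass(frozen=True)
class ErrorCount:
    """False-negative / false-positive counts of a classifier on a dataset."""

    fn: int
    fp: int

    @property
    def total(self) -> int:
        return self.fn + self.fp


# ---------------------------------------------------------------------------
# Evaluation


def evaluate(c: Classifier, profile: Mapping[str, int]) -> int:
    """Boolean output of *c* on a single binarized profile (marker → 0/1)."""
    for gate in c.gates:
        sat = False
        for lit in gate.literals:
            try:
                v = profile[lit.mirna_id]
            except KeyError:
                raise KeyError(
                    f"marker {lit.mirna_id!r} missing from profile"
                ) from None
            if bool(v) != lit.negated:
                sat = True
                break
        if not sat:
            return 0
    return 1


def evaluate_dataset(c: Classifier, ds) -> np.ndarray:
    """Vectorized evaluation on every row of a binarized dataset."""
    col = {m: i for i, m in enumerate(ds.mirna_ids)}
    missing = c.markers() - col.keys()
    if missing:
        raise KeyError(f"classifier markers not in dataset: {sorted(missing)}")
    out = np.ones(ds.n_samples, dtype=bool)
    mat = ds.matrix.astype(bool)
    for gate in c.gates:
        gate_val = np.zeros(ds.n_samples, dtype=bool)
        for lit in gate.literals:
            v = mat[:, col[lit.mirna_id]]
            gate_val |= ~v if lit.negated else v
        out &= gate_val
    return out.astype(np.int8)


def count_errors(c: Classifier, ds) -> ErrorCount:
    """FN = positives classified 0, FP = negatives classified 1."""
    pred = evaluate_dataset(c, ds)
    annot = ds.annotations
    fn = int(((annot == 1) & (pred == 0)).sum())
    fp = int(((annot == 0) & (pred == 1)).sum())
    return ErrorCount(fn=fn, fp=fp)


# ---------------------------------------------------------------------------
# Text format

class ClassifierSyntaxError(ValueError):
    def __init__(self, message, position=None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<and>∧|&&?|\bAND\b)|(?P<or>∨|\|\|?|\bOR\b)"
    r"|(?P<not>¬|!|\bNOT\b)|(?P<lp>\()|(?P<rp>\))"
    r"|(?P<tok>[A-Za-z0-9_][A-Za-z0-9_.+-]*))",
    re.IGNORECASE,
)


def _tokenize(text: str):
    pos, out = 0, []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise ClassifierSyntaxError(
                f"unexpected character {text[pos]!r}", pos
            )
        for kind in ("and", "or", "not", "lp", "rp", "tok"):
            if m.group(kind):
                out.append((kind, m.group(kind), m.start(kind)))
                break
        pos = m.end()
    return out


def parse_classifier(text: str) -> Classifier:
    """Parse the gate grammar: AND-separated, optionally parenthesized,
    OR-disjunctions of optionally negated marker tokens."""
    tokens = _tokenize(text)
    if not tokens:
        raise ClassifierSyntaxError("empty classifier text", 0)
    i = 0

    def peek():
        return tokens[i] if i < len(tokens) else (None, None, len(text))

    def literal():
        nonlocal i
        kind, val, pos = peek()
        neg = False
        if kind == "not":
            neg = True
            i += 1
            kind, val, pos = peek()
        if kind != "tok":
            raise ClassifierSyntaxError("expected a marker token", pos)
        i += 1
        return Literal(val, neg)

    def gate():
        nonlocal i
        kind, _, pos = peek()
        if kind == "lp":
            i += 1
            lits = [literal()]
            while peek()[0] == "or":
                i += 1
                lits.append(literal())
            kind, _, pos = peek()
            if kind != "rp":
                raise ClassifierSyntaxError("expected ')'", pos)
            i += 1
            return Gate(lits)
        return Gate([literal()])

    gates = [gate()]
    while peek()[0] == "and":
        i += 1
        gates.append(gate())
    if i != len(tokens):
        raise ClassifierSyntaxError("trailing input", tokens[i][2])
    return Classifier(gates)


def format_classifier(c: Classifier) -> str:
    return " & ".join(str(g) for g in c.gates)


# ---------------------------------------------------------------------------
# Canonical form and isomorphism classes


def canonicalize(c: Classifier) -> Classifier:
    """Deterministic representative of *c*'s isomorphism class.

    Literals within each gate are sorted by (marker token, sign with
    non-negated first); gates are then sorted lexicographically by their
    sorted literal sequences.  Gate identifiers (positions) are thereby
    reassigned in ascending order while each gate keeps its inputs, so the
    Boolean function is unchanged and the map is idempotent.
    """
    gates = [
        Gate(sorted(g.literals), assigned_type=g.assigned_type) for g in c.gates
    ]
    gates.sort(key=Gate.sort_key)
    return Classifier(gates)


def reduce_to_isomorphism_classes(
    solutions: Iterable[Classifier],
) -> list[Classifier]:
    """One canonical representative per isomorphism class, in deterministic
    (lexicographic by formatted text) order."""
    seen: dict[tuple, Classifier] = {}
    for c in solutions:
        canon = canonicalize(c)
        key = tuple(g.sort_key() for g in canon.gates)
        seen.setdefault(key, canon)
    return sorted(seen.values(), key=format_classifier)


def _type_group_key(g: Gate):
    # Interchangeability: same assigned type when known, otherwise the
    # sign signature (which determines type assignability).
    if g.assigned_type is not None:
        return ("type", g.assigned_type)
    return ("sig", g.n_positive, g.n_negated)


def count_isomorphic_labelings(c: Classifier) -> int:
    """Number of distinct labeled representations of *c* reachable by
    permuting gate identifiers among interchangeable (same-type) gates.

    Gates of one type with *distinct* literal sets contribute the factorial
    of the group size; identical gates are indistinguishable and divide out
    (multinomial coefficient per group).
    """
    total = 1
    groups: dict[tuple, list[Gate]] = {}
    for g in c.gates:
        groups.setdefault(_type_group_key(g), []).append(g)
    for members in groups.values():
        total *= math.factorial(len(members))
        for mult in Counter(g.sort_key() for g in members).values():
            total //= math.factorial(mult)
    return total


# ---------------------------------------------------------------------------
# Graph export


def to_dot(c: Classifier, name: str = "classifier") -> str:
    """DOT digraph of the circuit: miRNA inputs → gates → output."""
    lines = [f'digraph "{name}" {{', "  rankdir=LR;"]
    lines.append('  output [shape=doublecircle, label="output"];')
    for m in sorted(c.markers()):
        lines.append(f'  "in_{m}" [shape=plaintext, label="{m}"];')
    for i, g in enumerate(c.gates, start=1):
        kind = "NOT" if (g.n_inputs == 1 and g.n_negated == 1) else "OR"
        lines.append(f'  gate{i} [shape=box, label="gate {i}\\n({kind})"];')
        for lit in g.literals:
            style = ' [arrowhead=tee]' if lit.negated else ""
            lines.append(f'  "in_{lit.mirna_id}" -> gate{i}{style};')
        lines.append(f"  gate{i} -> output;")
    lines.append("}")
    return "\n".join(lines)
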