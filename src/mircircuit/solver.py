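"""Globally optimal classifier synthesis.

The design problem: given a binarized expression table and a constraint
profile, find a CNF classifier that reproduces the sample annotations
within the profile's FN/FP bounds, optimal under one of four
input/gate-minimization hierarchies:

* Opt1 — minimize the number of inputs;
* Opt2 — minimize the number of gates;
* Opt3 — minimize inputs, then gates (bi-level);
* Opt4 — minimize gates, then inputs (bi-level);

plus a plain feasibility mode.  The search is *complete*: a reported
optimum is globally optimal (no feasible classifier under the profile has
a strictly better objective), infeasibility is proved by exhaustion, and
all optima can be enumerated (reduced to isomorphism-class
representatives).

The engine encodes sample sets as machine integers (one bit per sample)
and explores classifiers as lexicographically increasing sequences of
distinct gates, with iterative deepening over the objective.  Soundness
rests on three exact prune rules: (i) a partially built gate is abandoned
once the positives it must still satisfy cannot be satisfied by any
remaining literal within the false-negative budget; (ii) during
feasibility search each gate after the first must reject at least one
negative sample not rejected by its predecessors (any feasible classifier
can be reduced to this form without worsening the objective); (iii) a
gate already true on every accepted positive and assignable to an
occurrence-unlimited gate type is never extended during feasibility
search, because supersets only lose rejection power.  All-optima
enumeration disables (ii) and (iii).

``brute_force_oracle`` is an independent exhaustive enumerator over the
whole structurally valid classifier space, used to verify the engine on
small instances.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from enum import Enum
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classifiers import (
    Classifier,
    Gate,
    Literal,
    canonicalize,
    count_errors,
    format_classifier,
    reduce_to_isomorphism_classes,
)
from .constraints import ConstraintProfile, validate_classifier

__all__ = [
    "Strategy",
    "Objective",
    "SolutionSet",
    "RelaxationPolicy",
    "find_optimal",
    "brute_force_oracle",
    "relaxation_schedule",
    "relax_and_solve",
]


class Strategy(str, Enum):
    """Optimization strategy; bi-level strategies resolve the upper level
    before the lower level."""

    FEASIBLE_ONLY = "feasible"
    OPT1_MIN_INPUTS = "opt1"
    OPT2_MIN_GATES = "opt2"
    OPT3_INPUTS_THEN_GATES = "opt3"
    OPT4_GATES_THEN_INPUTS = "opt4"


@dataclass(frozen=True)
class Objective:
    """Achieved objective; a ``None`` component was not optimized by the
    chosen strategy.  With custom input weights, ``inputs`` holds the
    weighted input cost."""

    inputs: float | None
    gates: int | None

    def as_tuple(self):
        return (self.inputs, self.gates)


@dataclass(frozen=True)
class SolutionSet:
    """Result of one solve: enumerated classifiers (canonical isomorphism-
    class representatives, deterministic lexicographic order), achieved
    objective, solver status and the error bounds in force."""

    classifiers: tuple[Classifier, ...]
    objective: Objective
    status: str  # OPTIMAL | FEASIBLE | INFEASIBLE | TIMEOUT
    bounds_used: tuple[int, int]
    elapsed: float
    strategy: Strategy | None = None

    def __post_init__(self):
        if self.status == "INFEASIBLE" and self.classifiers:
            raise ValueError("INFEASIBLE result cannot carry classifiers")

    def to_text(self) -> str:
        return "\n".join(format_classifier(c) for c in self.classifiers)

    def manifest(self) -> dict:
        return {
            "status": self.status,
            "strategy": self.strategy.value if self.strategy else None,
            "objective": {"inputs": self.objective.inputs,
                          "gates": self.objective.gates},
            "bounds_used": list(self.bounds_used),
            "n_solutions": len(self.classifiers),
            "elapsed_s": round(self.elapsed, 6),
        }


class _Timeout(Exception):
    pass


class _Engine:
    """Bitmask branch-and-bound over lexicographically ordered gate
    sequences.  Literal ids: ``2*marker_index + negated``."""

    def __init__(self, ds, profile: ConstraintProfile, deadline: float | None):
        self.profile = profile
        self.deadline = deadline
        n, nS = ds.n_mirnas, ds.n_samples
        self.n, self.nS = n, nS
        full = (1 << nS) - 1
        self.full = full
        base_mask = []
        for m in range(n):
            col = 0
            for i in np.flatnonzero(ds.matrix[:, m]):
                col |= 1 << int(i)
            base_mask.append(col)          # positive literal, base id 2m
            base_mask.append(col ^ full)   # negated literal, base id 2m+1
        pos = 0
        for i in np.flatnonzero(ds.annotations == 1):
            pos |= 1 << int(i)
        self.pos_mask = pos
        self.neg_mask = full ^ pos
        # Static exploration order: literals covering many positives first.
        # Pure value-ordering heuristic — the search stays complete; it also
        # sharpens the suffix-based FN prune because late suffixes cover
        # few positives.
        order = sorted(range(2 * n),
                       key=lambda l: (-(base_mask[l] & pos).bit_count(), l))
        self.lit_mask = [base_mask[l] for l in order]
        self.lit_marker = [l >> 1 for l in order]
        self.lit_sign = [l & 1 for l in order]
        self.order = order
        # suffix "satisfiable-by-some-remaining-literal" masks, per sign:
        # suf_pos[x] = union of positive-literal masks with index >= x
        suf_pos = [0] * (2 * n + 1)
        suf_neg = [0] * (2 * n + 1)
        for i in range(2 * n - 1, -1, -1):
            m = self.lit_mask[i]
            suf_pos[i] = suf_pos[i + 1] | (0 if self.lit_sign[i] else m)
            suf_neg[i] = suf_neg[i + 1] | (m if self.lit_sign[i] else 0)
        self.suf_pos, self.suf_neg = suf_pos, suf_neg

        types = profile.gate_types
        gmax = min(profile.max_inputs,
                   max(t.ub_pos + t.ub_neg for t in types))
        self.max_gate_size = gmax
        size = gmax + 2
        self.fits_some = [[any(t.lb_pos <= cp <= t.ub_pos and
                               t.lb_neg <= cn <= t.ub_neg for t in types)
                           for cn in range(size)] for cp in range(size)]
        self.fits_unlimited = [[any(t.lb_pos <= cp <= t.ub_pos and
                                    t.lb_neg <= cn <= t.ub_neg and
                                    t.max_occurrences >= profile.max_gates
                                    for t in types)
                                for cn in range(size)] for cp in range(size)]
        self.allow_pos = [[any(t.ub_pos >= cp + 1 and t.ub_neg >= cn
                               for t in types)
                           for cn in range(size)] for cp in range(size)]
        self.allow_neg = [[any(t.ub_pos >= cp and t.ub_neg >= cn + 1
                               for t in types)
                           for cn in range(size)] for cp in range(size)]
        self._types_memo: dict[tuple, bool] = {}

    def _types_ok(self, sigs: tuple) -> bool:
        """Exact assignability of the gate-signature multiset to gate types
        under the occurrence caps (memoized backtracking)."""
        hit = self._types_memo.get(sigs)
        if hit is not None:
            return hit
        types = self.profile.gate_types
        caps = {t.type_id: t.max_occurrences for t in types}
        cand = []
        for cp, cn in sigs:
            c = [t.type_id for t in types
                 if t.lb_pos <= cp <= t.ub_pos and t.lb_neg <= cn <= t.ub_neg]
            cand.append(c)
        cand.sort(key=len)

        def bt(k):
            if k == len(cand):
                return True
            for tid in cand[k]:
                if caps[tid] > 0:
                    caps[tid] -= 1
                    if bt(k + 1):
                        caps[tid] += 1
                        return True
                    caps[tid] += 1
            return False

        ok = bt(0)
        self._types_memo[sigs] = ok
        return ok

    def search(self, budget_i: int, budget_g: int,
               first_only: bool, irredundant: bool) -> list[list[tuple]]:
        """All (or the first) classifiers, as lists of literal-id tuples,
        with total inputs <= budget_i, gates <= budget_g, FN/FP within the
        profile bounds.  ``irredundant`` enables the feasibility-only prune
        rules (sound for existence questions, not for enumeration)."""
        out: list[list[tuple]] = []
        lm = self.lit_mask
        lit_marker, lit_sign = self.lit_marker, self.lit_sign
        n2 = 2 * self.n
        full = self.full
        pos_mask, neg_mask = self.pos_mask, self.neg_mask
        fnb, fpb = self.profile.fn_bound, self.profile.fp_bound
        unique = self.profile.unique_input
        deadline = self.deadline
        tick = [0]  # literal-loop counter for cheap periodic deadline checks
        fits_some, fits_unlim = self.fits_some, self.fits_unlimited
        allow_pos, allow_neg = self.allow_pos, self.allow_neg
        suf_pos, suf_neg = self.suf_pos, self.suf_neg
        used: set[int] = set()  # markers used (unique-input bookkeeping)

        def node(gates, sigs, acc, bi, bg, prev) -> bool:
            if deadline is not None and time.perf_counter() > deadline:
                raise _Timeout
            if gates and (acc & neg_mask).bit_count() <= fpb:
                out.append(list(gates))
                if first_only:
                    return True
            if bg == 0 or bi == 0:
                return False
            return grow(gates, sigs, acc, bi, bg, prev)

        def grow(gates, sigs, acc, bi, bg, prev) -> bool:
            first_gate = not gates
            fn_closed = (pos_mask & (full ^ acc)).bit_count()
            max_len = min(bi, self.max_gate_size)

            def build(lits, gmask, gmk, cp, cn, tight, last_lid) -> bool:
                closed = False
                if lits and not tight and fits_some[cp][cn]:
                    new_sigs = tuple(sorted(sigs + ((cp, cn),)))
                    if self._types_ok(new_sigs):
                        rejected_new = acc & neg_mask & (full ^ gmask)
                        if (not irredundant) or first_gate or rejected_new:
                            acc2 = acc & gmask
                            if (pos_mask & (full ^ acc2)).bit_count() <= fnb:
                                g = tuple(lits)
                                if unique:
                                    gm = [lit_marker[l] for l in g]
                                    used.update(gm)
                                try:
                                    if node(gates + [g], new_sigs, acc2,
                                            bi - len(g), bg - 1, g):
                                        return True
                                finally:
                                    if unique:
                                        used.difference_update(gm)
                                closed = True
                if closed and irredundant and fits_unlim[cp][cn] \
                        and (acc & pos_mask & (full ^ gmask)) == 0:
                    return False  # supersets dominated (prune rule iii)
                if len(lits) >= max_len:
                    return False
                if deadline is not None:
                    tick[0] += 1
                    if not tick[0] % 512 and time.perf_counter() > deadline:
                        raise _Timeout
                plen = len(prev) if prev is not None else -1
                for lid in range(last_lid + 1, n2):
                    if tight and len(lits) < plen:
                        if lid < prev[len(lits)]:
                            continue
                        new_tight = lid == prev[len(lits)]
                    else:
                        # prefix already exceeds prev, or equals it entirely:
                        # any extension is lexicographically greater
                        new_tight = False
                    mk = lit_marker[lid]
                    if (gmk >> mk) & 1:
                        continue  # marker twice in one gate
                    if unique and mk in used:
                        continue
                    neg = lit_sign[lid]
                    ncp, ncn = cp + 1 - neg, cn + neg
                    if neg:
                        if not allow_neg[cp][cn]:
                            continue
                    elif not allow_pos[cp][cn]:
                        continue
                    nmask = gmask | lm[lid]
                    rem = 0
                    if allow_pos[ncp][ncn]:
                        rem |= suf_pos[lid + 1]
                    if allow_neg[ncp][ncn]:
                        rem |= suf_neg[lid + 1]
                    doomed = acc & pos_mask & (full ^ nmask) & (full ^ rem)
                    if fn_closed + doomed.bit_count() > fnb:
                        continue  # prune rule (i)
                    if build(lits + [lid], nmask, gmk | (1 << mk),
                             ncp, ncn, new_tight, lid):
                        return True
                return False

            return build([], 0, 0, 0, 0, prev is not None, -1)

        node([], (), full, budget_i, budget_g, None)
        return out

    def first(self, budget_i, budget_g):
        out = self.search(budget_i, budget_g, first_only=True, irredundant=True)
        return out[0] if out else None

    def enumerate_all(self, budget_i, budget_g):
        return self.search(budget_i, budget_g, first_only=False,
                           irredundant=False)

    def to_classifier(self, gate_lids: Sequence[tuple],
                      mirna_ids: Sequence[str]) -> Classifier:
        gates = [Gate(Literal(mirna_ids[self.lit_marker[l]],
                              bool(self.lit_sign[l])) for l in g)
                 for g in gate_lids]
        return canonicalize(Classifier(gates))

    def weight_cost(self, gate_lids, mirna_ids, wmap) -> float:
        return sum(wmap[mirna_ids[self.lit_marker[l]]]
                   for g in gate_lids for l in g)


def find_optimal(
    ds,
    p: ConstraintProfile,
    s: Strategy | str = Strategy.OPT3_INPUTS_THEN_GATES,
    enumerate_all: bool = False,
    time_limit: float | None = None,
    seed: int = 0,
    input_weights: Mapping[str, float] | None = None,
) -> SolutionSet:
    """Complete, globally optimal solve.

    Parameters
    ----------
    ds : BinarizedDataset
        Training table; every sample must be classified within the
        profile's (fn_bound, fp_bound).
    p : ConstraintProfile
        Structural constraints and error bounds.
    s : Strategy or str
        Optimization strategy (``"opt1"`` … ``"opt4"``, ``"feasible"``).
    enumerate_all : bool
        If true, return *all* optima, reduced to isomorphism-class
        representatives in deterministic lexicographic order; otherwise a
        single witness.
    time_limit : float, optional
        Wall-clock budget in seconds; on expiry the status is ``TIMEOUT``
        and any incumbent found so far is reported.
    seed : int
        Accepted for interface stability; the engine is deterministic and
        uses no randomness.
    input_weights : mapping, optional
        Per-marker positive weights multiplying each input's contribution
        to the input objective (penalize or favor specific miRNAs).

    Notes
    -----
    The optimality contract is global: if the reported optimum uses I
    inputs, no classifier satisfying *p* with fewer than I inputs exists
    for this dataset.
    """
    t0 = time.perf_counter()
    deadline = t0 + time_limit if time_limit is not None else None
    s = Strategy(s)
    if ds.n_mirnas < 1:
        raise ValueError("dataset has no markers")
    eng = _Engine(ds, p, deadline)
    bounds = (p.fn_bound, p.fp_bound)

    def done(classifiers, objective, status):
        return SolutionSet(
            classifiers=tuple(classifiers),
            objective=objective,
            status=status,
            bounds_used=bounds,
            elapsed=time.perf_counter() - t0,
            strategy=s,
        )

    def infeasible():
        return done((), Objective(None, None), "INFEASIBLE")

    witness = None
    try:
        if input_weights and s in (Strategy.OPT1_MIN_INPUTS,
                                   Strategy.OPT3_INPUTS_THEN_GATES,
                                   Strategy.OPT4_GATES_THEN_INPUTS):
            return _find_weighted(ds, p, s, enumerate_all, eng, input_weights,
                                  done, infeasible)

        if s is Strategy.FEASIBLE_ONLY:
            if enumerate_all:
                sols = eng.enumerate_all(p.max_inputs, p.max_gates)
                if not sols:
                    return infeasible()
                reps = reduce_to_isomorphism_classes(
                    eng.to_classifier(g, ds.mirna_ids) for g in sols)
                return done(reps, Objective(None, None), "FEASIBLE")
            w = eng.first(p.max_inputs, p.max_gates)
            if w is None:
                return infeasible()
            return done((eng.to_classifier(w, ds.mirna_ids),),
                        Objective(None, None), "FEASIBLE")

        # upper level
        if s in (Strategy.OPT1_MIN_INPUTS, Strategy.OPT3_INPUTS_THEN_GATES):
            best_i = None
            for i in range(1, p.max_inputs + 1):
                w = eng.first(i, p.max_gates)
                if w is not None:
                    best_i, witness = i, w
                    break
            if best_i is None:
                return infeasible()
            if s is Strategy.OPT1_MIN_INPUTS:
                budgets, obj = (best_i, p.max_gates), Objective(best_i, None)
            else:
                for g in range(1, p.max_gates + 1):
                    w = eng.first(best_i, g)
                    if w is not None:
                        witness = w
                        budgets, obj = (best_i, g), Objective(best_i, g)
                        break
        else:  # OPT2 / OPT4
            best_g = None
            for g in range(1, p.max_gates + 1):
                w = eng.first(p.max_inputs, g)
                if w is not None:
                    best_g, witness = g, w
                    break
            if best_g is None:
                return infeasible()
            if s is Strategy.OPT2_MIN_GATES:
                budgets, obj = (p.max_inputs, best_g), Objective(None, best_g)
            else:
                for i in range(1, p.max_inputs + 1):
                    w = eng.first(i, best_g)
                    if w is not None:
                        witness = w
                        budgets, obj = (i, best_g), Objective(i, best_g)
                        break

        if enumerate_all:
            sols = eng.enumerate_all(*budgets)
            reps = reduce_to_isomorphism_classes(
                eng.to_classifier(g, ds.mirna_ids) for g in sols)
            return done(reps, obj, "OPTIMAL")
        return done((eng.to_classifier(witness, ds.mirna_ids),), obj,
                    "OPTIMAL")

    except _Timeout:
        classifiers = ()
        obj = Objective(None, None)
        if witness is not None:
            c = eng.to_classifier(witness, ds.mirna_ids)
            classifiers = (c,)
            obj = Objective(c.n_inputs, c.n_gates)
        return done(classifiers, obj, "TIMEOUT")


def _find_weighted(ds, p, s, enumerate_all, eng, input_weights,
                   done, infeasible):
    """Weighted-input optimization: scan input-count levels, tracking the
    minimum weighted cost; a level can be skipped once count * min-weight
    exceeds the incumbent cost."""
    wmap = {m: float(input_weights.get(m, 1.0)) for m in ds.mirna_ids}
    if min(wmap.values()) <= 0:
        raise ValueError("input weights must be positive")
    min_w = min(wmap.values())

    budget_g = p.max_gates
    if s is Strategy.OPT4_GATES_THEN_INPUTS:
        best_g = None
        for g in range(1, p.max_gates + 1):
            if eng.first(p.max_inputs, g) is not None:
                best_g = g
                break
        if best_g is None:
            return infeasible()
        budget_g = best_g

    best_cost, best = float("inf"), []
    for i in range(1, p.max_inputs + 1):
        if i * min_w > best_cost + 1e-12:
            break
        for g in eng.enumerate_all(i, budget_g):
            if sum(len(t) for t in g) != i:
                continue
            cost = eng.weight_cost(g, ds.mirna_ids, wmap)
            if cost < best_cost - 1e-12:
                best_cost, best = cost, [g]
            elif cost <= best_cost + 1e-12:
                best.append(g)
    if not best:
        return infeasible()

    gates_dim = None
    if s is Strategy.OPT3_INPUTS_THEN_GATES:
        gates_dim = min(len(g) for g in best)
        best = [g for g in best if len(g) == gates_dim]
    elif s is Strategy.OPT4_GATES_THEN_INPUTS:
        gates_dim = budget_g
    obj = Objective(best_cost, gates_dim)
    reps = reduce_to_isomorphism_classes(
        eng.to_classifier(g, ds.mirna_ids) for g in best)
    if not enumerate_all:
        reps = reps[:1]
    return done(reps, obj, "OPTIMAL")


# ---------------------------------------------------------------------------
# Independent exhaustive oracle


_ORACLE_MAX_MARKERS = 8
_ORACLE_MAX_INPUTS = 4


def brute_force_oracle(ds, p: ConstraintProfile,
                       s: Strategy | str = Strategy.OPT3_INPUTS_THEN_GATES
                       ) -> SolutionSet:
    """Exhaustive reference solver for small instances.

    Enumerates every structurally valid classifier (canonical form,
    distinct gates) by plain combinatorial generation, filters by
    ``validate_classifier`` and the profile's error bounds via
    ``count_errors``, and reports all optima under *s*.  Shares no search
    logic with :func:`find_optimal`; used to verify it.
    """
    s = Strategy(s)
    t0 = time.perf_counter()
    if ds.n_mirnas > _ORACLE_MAX_MARKERS or p.max_inputs > _ORACLE_MAX_INPUTS:
        raise ValueError(
            "oracle refuses large search spaces "
            f"(need <= {_ORACLE_MAX_MARKERS} markers and "
            f"max_inputs <= {_ORACLE_MAX_INPUTS})"
        )
    markers = list(ds.mirna_ids)
    max_gate_size = min(p.max_inputs,
                        max(t.ub_pos + t.ub_neg for t in p.gate_types))
    gate_pool: list[Gate] = []
    for k in range(1, max_gate_size + 1):
        for combo in combinations(range(len(markers)), k):
            for signs in product((False, True), repeat=k):
                gate_pool.append(Gate(
                    Literal(markers[m], neg) for m, neg in zip(combo, signs)
                ))
    # canonical in-pool order so classifiers come out as sorted gate tuples
    gate_pool.sort(key=Gate.sort_key)

    feasible: list[tuple[int, int, Classifier]] = []

    def consider(gate_idx: tuple[int, ...]):
        c = Classifier([gate_pool[i] for i in gate_idx])
        if validate_classifier(c, p):
            return
        e = count_errors(c, ds)
        if e.fn <= p.fn_bound and e.fp <= p.fp_bound:
            feasible.append((c.n_inputs, c.n_gates, c))

    def rec(start: int, chosen: list[int], inputs_left: int):
        if chosen:
            consider(tuple(chosen))
        if len(chosen) == p.max_gates:
            return
        for i in range(start, len(gate_pool)):
            sz = gate_pool[i].n_inputs
            if sz <= inputs_left:
                chosen.append(i)
                rec(i + 1, chosen, inputs_left - sz)
                chosen.pop()

    rec(0, [], p.max_inputs)

    bounds = (p.fn_bound, p.fp_bound)

    def pack(items, obj, status):
        reps = reduce_to_isomorphism_classes(c for _, _, c in items)
        return SolutionSet(tuple(reps), obj, status, bounds,
                           time.perf_counter() - t0, s)

    if not feasible:
        return SolutionSet((), Objective(None, None), "INFEASIBLE", bounds,
                           time.perf_counter() - t0, s)
    if s is Strategy.FEASIBLE_ONLY:
        return pack(feasible, Objective(None, None), "FEASIBLE")
    if s is Strategy.OPT1_MIN_INPUTS:
        best = min(i for i, _, _ in feasible)
        return pack([f for f in feasible if f[0] == best],
                    Objective(best, None), "OPTIMAL")
    if s is Strategy.OPT2_MIN_GATES:
        best = min(g for _, g, _ in feasible)
        return pack([f for f in feasible if f[1] == best],
                    Objective(None, best), "OPTIMAL")
    if s is Strategy.OPT3_INPUTS_THEN_GATES:
        bi = min(i for i, _, _ in feasible)
        bg = min(g for i, g, _ in feasible if i == bi)
        return pack([f for f in feasible if f[0] == bi and f[1] == bg],
                    Objective(bi, bg), "OPTIMAL")
    bg = min(g for _, g, _ in feasible)
    bi = min(i for i, g, _ in feasible if g == bg)
    return pack([f for f in feasible if f[0] == bi and f[1] == bg],
                Objective(bi, bg), "OPTIMAL")


# ---------------------------------------------------------------------------
# Stepwise error-bound relaxation


@dataclass(frozen=True)
class RelaxationPolicy:
    """Order in which FN/FP upper bounds are relaxed.

    Either an explicit ``schedule`` of (fn_bound, fp_bound) pairs starting
    at (0, 0) with non-decreasing totals, or the default rule: totals
    ascending, FN-first within a total (…,(1,0),(0,1),(1,1),…).  The
    ``forbid_fp`` / ``forbid_fn`` switches restrict relaxation to one error
    axis.
    """

    schedule: tuple[tuple[int, int], ...] | None = None
    forbid_fp: bool = False
    forbid_fn: bool = False

    def __post_init__(self):
        if self.schedule is not None:
            sched = tuple((int(a), int(b)) for a, b in self.schedule)
            if not sched or sched[0] != (0, 0):
                raise ValueError("relaxation schedule must start at (0, 0)")
            totals = [a + b for a, b in sched]
            if any(t2 < t1 for t1, t2 in zip(totals, totals[1:])):
                raise ValueError("relaxation totals must be non-decreasing")
            object.__setattr__(self, "schedule", sched)


def relaxation_schedule(policy: RelaxationPolicy | None,
                        max_total: int) -> list[tuple[int, int]]:
    """Bound pairs to try, in order, truncated at total <= ``max_total``.

    Default ordering: total ascending; within a total, FP-count ascending
    (i.e. FN relaxed first), reproducing (0,0),(1,0),(0,1),(1,1),…
    """
    if max_total < 0:
        raise ValueError("max_total must be >= 0")
    policy = policy or RelaxationPolicy()
    if policy.schedule is not None:
        return [b for b in policy.schedule if b[0] + b[1] <= max_total]
    if policy.forbid_fp and policy.forbid_fn and max_total > 0:
        raise ValueError("cannot forbid both error types while relaxing")
    out = []
    for total in range(max_total + 1):
        for fp in range(total + 1):
            fn = total - fp
            if policy.forbid_fp and fp > 0:
                continue
            if policy.forbid_fn and fn > 0:
                continue
            out.append((fn, fp))
    return out


def relax_and_solve(
    ds,
    p: ConstraintProfile,
    s: Strategy | str = Strategy.OPT3_INPUTS_THEN_GATES,
    policy: RelaxationPolicy | None = None,
    time_limit: float | None = None,
    max_total: int | None = None,
    enumerate_all: bool = False,
    seed: int = 0,
) -> SolutionSet:
    """Walk the relaxation schedule; return the first step's optimal
    solution set, with ``bounds_used`` recording the succeeding step.

    A perfect classifier is attempted first (bounds (0, 0)); bounds are
    then raised stepwise until a solution exists or the schedule is
    exhausted (status INFEASIBLE with the last bounds tried).
    ``time_limit`` is the overall wall-clock budget for the walk.
    """
    t0 = time.perf_counter()
    if max_total is None:
        max_total = ds.n_samples
    schedule = relaxation_schedule(policy, max_total)
    last = None
    for fn_b, fp_b in schedule:
        remaining = None
        if time_limit is not None:
            remaining = time_limit - (time.perf_counter() - t0)
            if remaining <= 0:
                return SolutionSet((), Objective(None, None), "TIMEOUT",
                                   (fn_b, fp_b),
                                   time.perf_counter() - t0, Strategy(s))
        sol = find_optimal(ds, p.with_bounds(fn_b, fp_b), s,
                           enumerate_all=enumerate_all,
                           time_limit=remaining, seed=seed)
        last = sol
        if sol.status in ("OPTIMAL", "FEASIBLE", "TIMEOUT"):
            return replace(sol, elapsed=time.perf_counter() - t0)
    return replace(last, elapsed=time.perf_counter() - t0)
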