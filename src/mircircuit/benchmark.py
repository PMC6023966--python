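"""Synthetic benchmark instances and conservative cross-validation.

Benchmark instances are random 0-1 expression matrices (each entry an
independent fair coin) annotated by a hidden *annotation classifier* (a
planted ground-truth Boolean function):

* Setup 1 draws the annotator uniformly gate-by-gate so that it satisfies
  the core laboratory constraints — a solution to the synthesis problem
  is then guaranteed to exist;
* Setup 2 draws up to floor(n/10) gates with up to 5 inputs each, each
  gate and each input kept with probability 1/2 — existence of a
  core-feasible solution is *not* guaranteed, by design.

Cross-validation is conservative: a fold whose solve times out counts its
entire held-out part as mispredicted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import Classifier, Gate, Literal, evaluate_dataset
from .constraints import ConstraintProfile, core_profile, validate_classifier
from .datasets import BinarizedDataset
from .solver import RelaxationPolicy, Strategy, find_optimal, relax_and_solve

__all__ = [
    "BenchmarkConfig",
    "CVResult",
    "generate_matrix",
    "generate_annotation_classifier",
    "annotate",
    "benchmark_grid",
    "run_benchmark",
    "cross_validate",
]

SETUP2_GATE_DIVISOR = 10   # max gates = floor(n_mirnas / 10)
SETUP2_MAX_GATE_INPUTS = 5
SETUP2_INCLUSION_P = 0.5   # fair coin per gate and per input


@dataclass(frozen=True)
class BenchmarkConfig:
    """Grid of matrix dimensions to benchmark.

    The published grid runs both axes 10…500 in steps of 10 (2,500
    instances); any dimension sequences may be supplied.
    """

    row_dims: tuple[int, ...] = tuple(range(10, 501, 10))
    col_dims: tuple[int, ...] = tuple(range(10, 501, 10))
    setup: int = 1
    strategy: Strategy | str = Strategy.FEASIBLE_ONLY
    time_limit: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if any(d < 1 for d in tuple(self.row_dims) + tuple(self.col_dims)):
            raise ValueError("matrix dimensions must be positive")
        if self.setup not in (1, 2):
            raise ValueError("setup must be 1 or 2")
        if self.time_limit <= 0:
            raise ValueError("time_limit must be > 0")
        object.__setattr__(self, "row_dims", tuple(self.row_dims))
        object.__setattr__(self, "col_dims", tuple(self.col_dims))
        object.__setattr__(self, "strategy", Strategy(self.strategy))


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_matrix(n_rows: int, n_cols: int, seed: int) -> np.ndarray:
    """Random 0-1 matrix, each entry i.i.d. fair Bernoulli; reproducible
    given the seed."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("matrix dimensions must be positive")
    return _rng(seed).integers(0, 2, size=(n_rows, n_cols), dtype=np.int8)


def _mirna_names(n: int) -> list[str]:
    return [f"g{i}" for i in range(1, n + 1)]


def generate_annotation_classifier(
    setup: int,
    n_mirnas: int,
    profile: ConstraintProfile | None = None,
    seed: int = 0,
) -> Classifier:
    """Draw a hidden ground-truth annotator.

    Setup 1: rejection-sample per-gate uniform constructions until the
    result passes ``validate_classifier`` against the (core) profile —
    every Setup 1 annotator is itself a feasible zero-error solution for
    the dataset it labels.  Setup 2: binomial construction with at most
    floor(n/10) gates of at most 5 inputs, each gate/input kept with
    probability 1/2, markers assigned uniformly without replacement within
    a gate and literal signs drawn by fair coin; at least one single-input
    gate is enforced if every coin comes up empty.
    """
    if n_mirnas < 1:
        raise ValueError("need at least one miRNA")
    rng = _rng(seed, 1)
    names = _mirna_names(n_mirnas)

    if setup == 1:
        profile = profile or core_profile()
        min_gate = min(max(t.lb_pos + t.lb_neg, 1) for t in profile.gate_types)
        if n_mirnas < min_gate:
            raise ValueError(
                f"{n_mirnas} miRNAs cannot form any gate under the profile")
        for _ in range(10_000):
            n_gates = int(rng.integers(1, profile.max_gates + 1))
            gates = []
            ok = True
            for _ in range(n_gates):
                t = profile.gate_types[int(rng.integers(len(profile.gate_types)))]
                np_hi = min(t.ub_pos, n_mirnas)
                nn_hi = min(t.ub_neg, n_mirnas)
                n_pos = int(rng.integers(t.lb_pos, np_hi + 1)) if np_hi >= t.lb_pos else None
                n_neg = int(rng.integers(t.lb_neg, nn_hi + 1)) if nn_hi >= t.lb_neg else None
                if n_pos is None or n_neg is None or n_pos + n_neg < 1 \
                        or n_pos + n_neg > n_mirnas:
                    ok = False
                    break
                chosen = rng.choice(n_mirnas, size=n_pos + n_neg, replace=False)
                gates.append(Gate(
                    [Literal(names[m], False) for m in chosen[:n_pos]]
                    + [Literal(names[m], True) for m in chosen[n_pos:]]
                ))
            if not ok:
                continue
            try:
                c = Classifier(gates)
            except ValueError:
                continue
            if len({g.sort_key() for g in gates}) != len(gates):
                continue
            if not validate_classifier(c, profile):
                return c
        raise RuntimeError("could not sample a profile-feasible annotator")

    if setup == 2:
        max_gates = n_mirnas // SETUP2_GATE_DIVISOR
        gates = []
        for _ in range(max_gates):
            if rng.random() >= SETUP2_INCLUSION_P:
                continue
            k = int((rng.random(SETUP2_MAX_GATE_INPUTS)
                     < SETUP2_INCLUSION_P).sum())
            k = min(k, n_mirnas)
            if k == 0:
                continue
            chosen = rng.choice(n_mirnas, size=k, replace=False)
            signs = rng.random(k) < 0.5
            gates.append(Gate(
                [Literal(names[m], bool(s)) for m, s in zip(chosen, signs)]))
        if not gates:
            m = int(rng.integers(n_mirnas))
            gates = [Gate([Literal(names[m], bool(rng.random() < 0.5))])]
        return Classifier(gates)

    raise ValueError(f"setup must be 1 or 2, got {setup}")


def annotate(matrix: np.ndarray, annot_classifier: Classifier
             ) -> BinarizedDataset:
    """Label each row of a 0-1 matrix by the annotation classifier's
    Boolean output; the annotator is then a zero-error solution for the
    resulting dataset."""
    matrix = np.asarray(matrix)
    names = _mirna_names(matrix.shape[1])
    missing = annot_classifier.markers() - set(names)
    if missing:
        raise KeyError(
            f"annotator markers beyond matrix columns: {sorted(missing)}")
    ds0 = BinarizedDataset(
        sample_ids=list(range(1, matrix.shape[0] + 1)),
        annotations=np.zeros(matrix.shape[0], dtype=np.int8),
        mirna_ids=names,
        matrix=matrix,
    )
    labels = evaluate_dataset(annot_classifier, ds0)
    return BinarizedDataset(ds0.sample_ids, labels, names, matrix)


def benchmark_grid(cfg: BenchmarkConfig) -> list[tuple[int, int]]:
    """Deterministic (rows, cols) enumeration order of the grid; the full
    published grid yields 50 x 50 = 2,500 instances."""
    return [(r, c) for r in cfg.row_dims for c in cfg.col_dims]


def _instance(cfg: BenchmarkConfig, n_rows: int, n_cols: int):
    """The (matrix, annotator, dataset) for one grid cell; seeded per cell
    so instances are shared across solve modes and reproducible."""
    cell_seed_rng = _rng(cfg.seed, n_rows, n_cols)
    sub = int(cell_seed_rng.integers(0, 2**31 - 1))
    matrix = generate_matrix(n_rows, n_cols, sub)
    annot = generate_annotation_classifier(cfg.setup, n_cols, seed=sub)
    return annotate(matrix, annot)


def run_benchmark(cfg: BenchmarkConfig,
                  profile: ConstraintProfile | None = None,
                  checkpoint: str | Path | None = None) -> pd.DataFrame:
    """Solve every grid instance and record (rows, cols, status, elapsed,
    objective inputs/gates).

    Per-instance failures are recorded, never raised.  With ``checkpoint``
    set, finished cells are appended to the CSV as they complete and are
    skipped on re-run (instance-level resume).
    """
    profile = profile or core_profile()
    done: set[tuple[int, int]] = set()
    records: list[dict] = []
    if checkpoint is not None and Path(checkpoint).exists():
        prev = pd.read_csv(checkpoint)
        records = prev.to_dict("records")
        done = {(int(r["rows"]), int(r["cols"])) for r in records}
    for n_rows, n_cols in benchmark_grid(cfg):
        if (n_rows, n_cols) in done:
            continue
        ds = _instance(cfg, n_rows, n_cols)
        t0 = time.perf_counter()
        try:
            sol = find_optimal(ds, profile, cfg.strategy,
                               time_limit=cfg.time_limit)
            rec = {
                "rows": n_rows, "cols": n_cols, "status": sol.status,
                "elapsed": time.perf_counter() - t0,
                "inputs": sol.objective.inputs, "gates": sol.objective.gates,
            }
        except Exception as exc:  # per-instance failures are data
            rec = {
                "rows": n_rows, "cols": n_cols, "status": f"ERROR: {exc}",
                "elapsed": time.perf_counter() - t0,
                "inputs": None, "gates": None,
            }
        records.append(rec)
        if checkpoint is not None:
            pd.DataFrame(records).to_csv(checkpoint, index=False)
    return pd.DataFrame(records)


@dataclass(frozen=True)
class CVResult:
    """Conservative k-fold cross-validation outcome."""

    generalization_error: float
    fold_mismatches: tuple[int, ...]
    fold_sizes: tuple[int, ...]
    timeout_folds: tuple[bool, ...]

    @property
    def k(self) -> int:
        return len(self.fold_sizes)


def cross_validate(
    ds: BinarizedDataset,
    k: int,
    p: ConstraintProfile | None = None,
    s: Strategy | str = Strategy.FEASIBLE_ONLY,
    time_limit: float | None = None,
    seed: int = 0,
    policy: RelaxationPolicy | None = None,
    stratified: bool = False,
) -> CVResult:
    """Conservative k-fold cross-validation.

    Rows are shuffled by seed and split into k contiguous parts of
    near-equal size (differing by at most one sample; class balance is
    deliberately ignored unless ``stratified``).  For each part a
    classifier is built from the remaining k-1 parts with the full
    relaxation procedure; mismatches between its predictions and the
    given annotations on the held-out part are summed.  A fold whose
    solve exhausts ``time_limit`` contributes its entire held-out size as
    mismatches.  The sum divided by the sample count is the
    generalization error.
    """
    if k < 2 or k > ds.n_samples:
        raise ValueError(f"k must be in [2, {ds.n_samples}], got {k}")
    p = p or core_profile()
    rng = _rng(seed, 99)
    if stratified:
        pos = [i for i in range(ds.n_samples) if ds.annotations[i] == 1]
        neg = [i for i in range(ds.n_samples) if ds.annotations[i] == 0]
        rng.shuffle(pos)
        rng.shuffle(neg)
        order = np.array(pos + neg)
        folds = [list(order[j::k]) for j in range(k)]
    else:
        order = rng.permutation(ds.n_samples)
        bounds = np.linspace(0, ds.n_samples, k + 1).round().astype(int)
        folds = [list(order[bounds[j]:bounds[j + 1]]) for j in range(k)]

    mismatches, sizes, timeouts = [], [], []
    for fold in folds:
        test = sorted(fold)
        train = sorted(set(range(ds.n_samples)) - set(fold))
        train_ds = ds.subset(train)
        test_ds = ds.subset(test)
        sol = relax_and_solve(train_ds, p, s, policy=policy,
                              time_limit=time_limit, seed=seed)
        sizes.append(len(test))
        if sol.status in ("OPTIMAL", "FEASIBLE") and sol.classifiers:
            pred = evaluate_dataset(sol.classifiers[0], test_ds)
            mismatches.append(int((pred != test_ds.annotations).sum()))
            timeouts.append(False)
        else:
            # conservative: a timed-out (or unsolved) fold counts its whole
            # held-out part as false predictions
            mismatches.append(len(test))
            timeouts.append(True)
    return CVResult(
        generalization_error=sum(mismatches) / ds.n_samples,
        fold_mismatches=tuple(mismatches),
        fold_sizes=tuple(sizes),
        timeout_folds=tuple(timeouts),
    )
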