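"""Model/Results facade over the synthesis workflow.

``ClassifierDesign`` bundles a binarized training table, a constraint
profile and (optionally) a continuous table; ``fit`` runs the globally
optimal synthesis (with stepwise error-bound relaxation by default) and
returns a ``DesignResults`` carrying the enumerated optima, the achieved
objective, per-classifier score diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constraints import ConstraintProfile, core_profile
from .datasets import BinarizedDataset, ContinuousDataset, check_consistency
from .scoring import ScoringConfig, rank_solutions, report_frame, score_classifier
from .solver import (
    RelaxationPolicy,
    SolutionSet,
    Strategy,
    find_optimal,
    relax_and_solve,
)

__all__ = ["ClassifierDesign", "DesignResults"]


class ClassifierDesign:
    """Synthesis problem: learn lab-feasible CNF classifiers from a
    binarized miRNA table.

    Parameters
    ----------
    dataset : BinarizedDataset
        Training samples with 0/1 annotations.
    constraints : ConstraintProfile, optional
        Structural feasibility constraints (default: the core laboratory
        constraints, 6 gates / 8 inputs, OR + NOT gate types).
    continuous : ContinuousDataset, optional
        Real-valued expression table (same layout) enabling the
        continuous scores (S_AUC, margins).
    """

    def __init__(self, dataset: BinarizedDataset,
                 constraints: ConstraintProfile | None = None,
                 continuous: ContinuousDataset | None = None):
        self.dataset = dataset
        self.constraints = constraints or core_profile()
        self.continuous = continuous

    @classmethod
    def from_frames(cls, frame: pd.DataFrame, constraints=None,
                    continuous_frame: pd.DataFrame | None = None):
        """Build from DataFrames in the ID/Annots/markers layout."""
        def mk(df, klass):
            return klass(
                sample_ids=list(df["ID"]),
                annotations=df["Annots"].to_numpy(),
                mirna_ids=list(df.columns[2:]),
                matrix=df.iloc[:, 2:].to_numpy(),
            )
        cont = (mk(continuous_frame, ContinuousDataset)
                if continuous_frame is not None else None)
        return cls(mk(frame, BinarizedDataset), constraints, cont)

    def conflicts(self):
        """Label-discordant duplicate profiles (obstructions to a perfect
        classifier)."""
        return check_consistency(self.dataset)

    def fit(self, strategy: Strategy | str = Strategy.OPT3_INPUTS_THEN_GATES,
            relax: bool = True,
            policy: RelaxationPolicy | None = None,
            enumerate_all: bool = True,
            time_limit: float | None = None,
            seed: int = 0,
            input_weights=None,
            scoring: ScoringConfig | None = None) -> "DesignResults":
        """Solve to global optimality.

        With ``relax`` (default) a perfect classifier is attempted first
        and the FN/FP bounds are raised stepwise until a solution exists;
        otherwise the profile's own bounds are used as-is.
        """
        if relax:
            sol = relax_and_solve(self.dataset, self.constraints, strategy,
                                  policy=policy, enumerate_all=enumerate_all,
                                  time_limit=time_limit, seed=seed)
        else:
            sol = find_optimal(self.dataset, self.constraints, strategy,
                               enumerate_all=enumerate_all,
                               time_limit=time_limit, seed=seed,
                               input_weights=input_weights)
        return DesignResults(self, sol, scoring or ScoringConfig())


@dataclass
class DesignResults:
    """Solution set plus evaluation diagnostics for one fit."""

    model: ClassifierDesign
    solution: SolutionSet
    scoring: ScoringConfig

    @property
    def status(self) -> str:
        return self.solution.status

    @property
    def classifiers(self):
        return self.solution.classifiers

    @property
    def objective(self):
        return self.solution.objective

    @property
    def bounds_used(self):
        return self.solution.bounds_used

    def ranked(self):
        """Classifiers ranked by (S_AUC desc, S_m desc); requires the
        model's continuous dataset."""
        if self.model.continuous is None:
            raise ValueError("ranking requires a continuous dataset")
        return rank_solutions(list(self.classifiers), self.model.continuous,
                              self.scoring, ds=self.model.dataset)

    def score_table(self) -> pd.DataFrame:
        """Score report rows, ranked when continuous data is available."""
        if not self.classifiers:
            return report_frame([])
        if self.model.continuous is not None:
            return report_frame(r for _, r in self.ranked())
        return report_frame(
            score_classifier(c, self.model.dataset) for c in self.classifiers)

    def summary(self) -> str:
        """Human-readable account of the fit."""
        sol = self.solution
        lines = [
            "Boolean cell-classifier design",
            "==============================",
            f"Samples:            {self.model.dataset.n_samples} "
            f"({self.model.dataset.n_positive} positive, "
            f"{self.model.dataset.n_negative} negative)",
            f"miRNA markers:      {self.model.dataset.n_mirnas}",
            f"Strategy:           {sol.strategy.value if sol.strategy else '-'}",
            f"Status:             {sol.status}",
            f"Error bounds used:  FN <= {sol.bounds_used[0]}, "
            f"FP <= {sol.bounds_used[1]}",
            f"Objective:          inputs={sol.objective.inputs}, "
            f"gates={sol.objective.gates}",
            f"Optimal classifiers (isomorphism classes): "
            f"{len(sol.classifiers)}",
            "",
        ]
        if sol.classifiers:
            lines.append(self.score_table().to_string(index=False))
        return "\n".join(lines)
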