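"""Boolean-setting rates and continuous-setting circuit scores.

In the Boolean setting a classifier is judged by its false-negative and
false-positive *rates* (errors normalized by class size).  In the
continuous setting, a mechanistic surrogate maps real-valued miRNA levels
through the circuit to a predicted output concentration; from the
per-sample outputs we compute

* ``S_AUC`` — area under the ROC curve of the output as a ranking score
  for the positive class;
* ``Ma`` — average margin, the ratio of the mean output over positive
  samples to the mean output over negative samples;
* ``Mw`` — worst margin, the smallest output ratio among any
  positive/negative sample pair (min over positives / max over
  negatives);
* ``S_m = lambda * Ma + (1 - lambda) * Mw`` — their convex combination.

Optimal solution sets are ranked by (S_AUC desc, S_m desc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .classifiers import Classifier, count_errors, format_classifier

__all__ = [
    "ScoreReport",
    "ScoringConfig",
    "HillOutputModel",
    "boolean_rates",
    "circuit_output",
    "margins",
    "s_m",
    "s_auc",
    "score_classifier",
    "rank_solutions",
    "report_frame",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up rounding used for report presentation (3/11 -> 0.27)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HillOutputModel:
    """Saturating (Hill-type) surrogate of the circuit's biochemistry.

    Each literal responds to its miRNA level x with a Hill function of
    threshold K (expression units) and steepness k: activating literals
    use x^k / (x^k + K^k), repressing (negated) literals the complementary
    K^k / (x^k + K^k).  A gate's activation is the strongest of its
    literals (OR), the circuit output is ``max_output`` times the product
    of gate activations (AND), plus a small basal leak that keeps the
    output strictly positive.  This is a pluggable interface: any object
    with the same ``__call__`` signature can replace it, e.g. a published
    mechanistic ODE model.

    Parameters
    ----------
    threshold : float
        Hill threshold K; a natural default is the dataset's binarization
        threshold.
    steepness : float
        Hill coefficient k (default 4); in the saturating limit the model
        reproduces the Boolean evaluation.
    max_output : float
        Plateau output concentration (default 1.0, arbitrary units).
    leak : float
        Basal output fraction (default 1e-6).
    """

    threshold: float = 1.0
    steepness: float = 4.0
    max_output: float = 1.0
    leak: float = 1e-6

    def __post_init__(self):
        if self.threshold <= 0 or self.steepness <= 0 or self.max_output <= 0:
            raise ValueError("Hill parameters must be positive")

    def _hill(self, x: float) -> float:
        xk = (max(x, 0.0) / self.threshold) ** self.steepness
        return xk / (xk + 1.0)

    def __call__(self, c: Classifier, profile) -> float:
        out = self.max_output
        for gate in c.gates:
            act = 0.0
            for lit in gate.literals:
                try:
                    x = float(profile[lit.mirna_id])
                except KeyError:
                    raise KeyError(
                        f"no expression value for marker {lit.mirna_id!r}"
                    ) from None
                h = self._hill(x)
                act = max(act, 1.0 - h if lit.negated else h)
            out *= act
        return out + self.leak * self.max_output


def _ratio(x: float) -> float:
    return x


_TRANSFORMS: dict[str, Callable[[float], float]] = {
    "ratio": _ratio,
    "log-ratio": np.log,
}


@dataclass(frozen=True)
class ScoringConfig:
    """Continuous-evaluation configuration.

    ``lam`` is the margin weight lambda in [0, 1] (default 0.5, both
    margins equally relevant).  ``margin_transform`` is applied to the raw
    output ratios before combining: ``"ratio"`` (as literally defined) or
    ``"log-ratio"``.
    """

    lam: float = 0.5
    output_model: HillOutputModel = field(default_factory=HillOutputModel)
    margin_transform: str = "ratio"

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if self.margin_transform not in _TRANSFORMS:
            raise ValueError(
                f"margin_transform must be one of {sorted(_TRANSFORMS)}")

    @property
    def transform(self) -> Callable[[float], float]:
        return _TRANSFORMS[self.margin_transform]


@dataclass(frozen=True)
class ScoreReport:
    """Table-2-shaped evaluation row for one classifier.  Continuous
    scores are None when no continuous data was supplied."""

    classifier: str
    fn_rate: float
    fp_rate: float
    s_auc: float | None = None
    ma: float | None = None
    mw: float | None = None
    s_m: float | None = None

    def as_row(self) -> dict:
        fmt = lambda v: None if v is None else round_half_up(v, 2)
        return {
            "Classifier": self.classifier,
            "FN rate": fmt(self.fn_rate),
            "FP rate": fmt(self.fp_rate),
            "S_AUC": fmt(self.s_auc),
            "S_m": fmt(self.s_m),
            "Ma": fmt(self.ma),
            "Mw": fmt(self.mw),
        }


def _require_both_classes(ds):
    if ds.n_positive == 0 or ds.n_negative == 0:
        raise ValueError(
            "rates/margins are undefined when a class is absent "
            f"({ds.n_positive} positive, {ds.n_negative} negative)"
        )


def boolean_rates(c: Classifier, ds) -> tuple[float, float]:
    """(FN rate, FP rate) = errors normalized by class sizes, full
    precision (presentation rounds to 2 decimals, half-up)."""
    _require_both_classes(ds)
    e = count_errors(c, ds)
    return e.fn / ds.n_positive, e.fp / ds.n_negative


def circuit_output(c: Classifier, profile, cfg: ScoringConfig) -> float:
    """Predicted output concentration for one continuous profile."""
    return cfg.output_model(c, profile)


def _outputs(c: Classifier, cds, cfg) -> tuple[np.ndarray, np.ndarray]:
    _require_both_classes(cds)
    vals = np.array([
        circuit_output(c, cds.profile(i), cfg) for i in range(cds.n_samples)
    ])
    ann = np.asarray(cds.annotations)
    return vals[ann == 1], vals[ann == 0]


def margins(c: Classifier, cds, cfg: ScoringConfig) -> tuple[float, float]:
    """(Ma, Mw): class-mean output ratio and worst positive/negative pair
    ratio, after the configured transform.  For positive outputs and the
    ratio transform, Mw <= Ma always."""
    pos, neg = _outputs(c, cds, cfg)
    ma = cfg.transform(float(pos.mean() / neg.mean()))
    mw = cfg.transform(float(pos.min() / neg.max()))
    return ma, mw


def s_m(ma: float, mw: float, lam: float = 0.5) -> float:
    """Weighted margin score: lam * Ma + (1 - lam) * Mw."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return lam * ma + (1.0 - lam) * mw


def s_auc(c: Classifier, cds, cfg: ScoringConfig) -> float:
    """AUC of the continuous circuit output as a ranking score for the
    positive class (midpoint tie convention)."""
    pos, neg = _outputs(c, cds, cfg)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return float(roc_auc_score(y, np.concatenate([pos, neg])))


def score_classifier(c: Classifier, ds, cds=None,
                     cfg: ScoringConfig | None = None) -> ScoreReport:
    """Full evaluation of one classifier; continuous scores are omitted,
    never fabricated, when no continuous dataset is given."""
    cfg = cfg or ScoringConfig()
    fn_rate, fp_rate = boolean_rates(c, ds)
    if cds is None:
        return ScoreReport(format_classifier(c), fn_rate, fp_rate)
    ma, mw = margins(c, cds, cfg)
    return ScoreReport(
        classifier=format_classifier(c),
        fn_rate=fn_rate,
        fp_rate=fp_rate,
        s_auc=s_auc(c, cds, cfg),
        ma=ma,
        mw=mw,
        s_m=s_m(ma, mw, cfg.lam),
    )


def rank_solutions(solutions: Sequence[Classifier], cds,
                   cfg: ScoringConfig | None = None,
                   ds=None) -> list[tuple[Classifier, ScoreReport]]:
    """Stable sort of optimal classifiers by (S_AUC desc, S_m desc,
    canonical text asc), each with its full score report attached.

    Boolean rates require a binarized table: pass one as ``ds`` to fill
    them in; without it the FN/FP rate fields are NaN.
    """
    if not solutions:
        raise ValueError("no solutions to rank")
    cfg = cfg or ScoringConfig()
    scored = []
    for c in solutions:
        if ds is not None:
            rep = score_classifier(c, ds, cds, cfg)
        else:
            ma, mw = margins(c, cds, cfg)
            rep = ScoreReport(
                classifier=format_classifier(c),
                fn_rate=float("nan"), fp_rate=float("nan"),
                s_auc=s_auc(c, cds, cfg), ma=ma, mw=mw,
                s_m=s_m(ma, mw, cfg.lam),
            )
        scored.append((c, rep))
    scored.sort(key=lambda t: (-t[1].s_auc, -t[1].s_m, t[1].classifier))
    return scored


def report_frame(reports: Iterable[ScoreReport]) -> pd.DataFrame:
    """Reports as a DataFrame mirroring the published score-table columns
    (Classifier, FN rate, FP rate, S_AUC, S_m, plus Ma/Mw)."""
    return pd.DataFrame([r.as_row() for r in reports])
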