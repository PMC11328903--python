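"""Random-forest model selection on coalescent reference tables.

Model choice is cast as classification: a forest is trained on simulated
summary vectors labelled by generating model, the observed vector is
passed through every tree, and the majority vote selects the model.  The
posterior probability of the selection is approximated by a secondary
regression forest fit to the out-of-bag misclassification indicator.
Power is assessed by treating every reference-table row as a
pseudo-observed dataset (POD) and scoring it with the trees that did not
train on it (out-of-bag), yielding per-model classification error (CE)
and a confusion matrix.  A Fisher linear discriminant projection of the
simulations and the observed point onto M-1 axes provides a visual
goodness-of-fit check.  The step-wise protocol first selects within
categories of broadly similar models, then contrasts the category
winners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalescent import ReferenceTable, validate_alignment
from .demography import DEFAULT_CATEGORIES

__all__ = [
    "TrainedClassifier",
    "ModelSelectionResult",
    "PowerTestResult",
    "LDAProjection",
    "StepResult",
    "StepwiseReport",
    "train_forest",
    "classify_observed",
    "posterior_probability",
    "power_test",
    "lda_project",
    "select_model",
    "stepwise_select",
    "simultaneous_select",
]


@dataclass
class TrainedClassifier:
    """A fitted classification forest plus its out-of-bag bookkeeping."""

    forest: RandomForestClassifier
    rt: ReferenceTable
    seed: int | None
    oob_predictions: np.ndarray  # per row; -1 where the row was never OOB
    oob_valid: np.ndarray        # bool per row
    hyperparameters: dict

    @property
    def n_trees(self) -> int:
        return self.forest.n_estimators

    @property
    def models(self) -> list[int]:
        return [int(c) for c in self.forest.classes_]


@dataclass
class ModelSelectionResult:
    votes: dict[int, int]
    selected_model: int
    posterior_probability: float | None
    n_trees: int
    prior_expectation_pct: float
    tie: bool = False

    def __post_init__(self):
        if sum(self.votes.values()) != self.n_trees:
            raise ValueError("votes must sum to the number of trees")


@dataclass
class PowerTestResult:
    classification_error: dict[int, float]   # CE per model
    true_positive_rate: dict[int, float]     # 1 - CE
    confusion: pd.DataFrame                  # rows true, cols predicted
    prior_error_rate: float
    n_oob: int


@dataclass
class LDAProjection:
    coordinates: np.ndarray        # rows x (M-1)
    observed_coordinates: np.ndarray | None
    model_ids: np.ndarray
    axes: np.ndarray               # loadings, features x (M-1)
    mean: np.ndarray


@dataclass
class StepResult:
    name: str
    models: tuple[int, ...]
    selection: ModelSelectionResult
    power: PowerTestResult


@dataclass
class StepwiseReport:
    steps: dict[str, StepResult]
    final: StepResult | None
    selected_model: int

    def summary(self) -> str:
        lines = []
        for name, step in {**self.steps, **({"final": self.final} if self.final else {})}.items():
            sel = step.selection
            ces = ", ".join(
                f"{m}: {step.power.classification_error[m]:.0%}"
                for m in step.models
            )
            lines.append(
                f"[{name}] models {list(step.models)} -> selected {sel.selected_model} "
                f"(votes {sel.votes}, posterior "
                f"{sel.posterior_probability:.2f}, prior expectation "
                f"{sel.prior_expectation_pct:.0f}%); CE {{{ces}}}"
            )
        lines.append(f"overall selected model: {self.selected_model}")
        return "\n".join(lines)


def train_forest(
    rt: ReferenceTable,
    n_trees: int = 1000,
    seed: int | None = None,
    max_features: str | float = "sqrt",
) -> TrainedClassifier:
    """Fit a classification forest to (summary vector -> model index).

    Out-of-bag predictions are retained per row for the power test and
    the posterior-probability regression.  Hyperparameters beyond the
    tree count follow common classification-forest defaults (sqrt(p)
    candidate features per split, unlimited depth) and are recorded in
    the result for reproducibility.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if len(rt.models) < 2:
        raise ValueError("reference table must contain at least two models")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    import warnings

    with warnings.catch_warnings():
        # a few rows may never be out-of-bag for small forests
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        forest.fit(rt.summaries, rt.model_ids)
    dec = forest.oob_decision_function_
    valid = ~np.isnan(dec).any(axis=1) & (dec.sum(axis=1) > 0)
    preds = np.full(rt.n_rows, -1, dtype=int)
    preds[valid] = forest.classes_[np.argmax(dec[valid], axis=1)].astype(int)
    return TrainedClassifier(
        forest=forest,
        rt=rt,
        seed=seed,
        oob_predictions=preds,
        oob_valid=valid,
        hyperparameters={
            "n_trees": n_trees,
            "max_features": max_features,
            "max_depth": None,
            "bootstrap": True,
        },
    )


def _check_observed(clf: TrainedClassifier, observed, layout) -> np.ndarray:
    observed = np.asarray(observed, float)
    if layout is not None:
        report = validate_alignment(clf.rt, observed, layout)
        if not report:
            raise ValueError(
                "observed vector is not aligned with the reference table: "
                + "; ".join(report.problems)
            )
    elif observed.shape != (clf.rt.summaries.shape[1],):
        raise ValueError(
            f"observed vector length {observed.shape} does not match the "
            f"reference table ({clf.rt.summaries.shape[1]} columns)"
        )
    return observed


def classify_observed(
    clf: TrainedClassifier,
    observed: Sequence[float],
    layout=None,
) -> ModelSelectionResult:
    """Majority classification vote for the observed summary vector.

    Vote ties are broken toward the lowest model id and flagged.
    """
    observed = _check_observed(clf, observed, layout)
    x = observed.reshape(1, -1)
    votes = {m: 0 for m in clf.models}
    classes = clf.forest.classes_
    for tree in clf.forest.estimators_:
        # sub-estimators predict encoded class indices
        votes[int(classes[int(tree.predict(x)[0])])] += 1
    top = max(votes.values())
    winners = sorted(m for m, v in votes.items() if v == top)
    return ModelSelectionResult(
        votes=votes,
        selected_model=winners[0],
        posterior_probability=None,
        n_trees=clf.n_trees,
        prior_expectation_pct=100.0 / len(votes),
        tie=len(winners) > 1,
    )


def posterior_probability(
    clf: TrainedClassifier,
    observed: Sequence[float],
    layout=None,
    seed: int | None = None,
) -> float:
    """Posterior probability of the majority-vote model.

    A regression forest (same tree count as the classifier) regresses the
    out-of-bag misclassification indicator on the summary vectors; the
    posterior is one minus the predicted selection error at the observed
    point, clipped to [0, 1].
    """
    if not clf.oob_valid.any():
        raise ValueError("classifier has no out-of-bag records")
    observed = _check_observed(clf, observed, layout)
    mask = clf.oob_valid
    wrong = (clf.oob_predictions[mask] != clf.rt.model_ids[mask]).astype(float)
    reg = RandomForestRegressor(
        n_estimators=clf.n_trees,
        random_state=clf.seed if seed is None else seed,
        n_jobs=1,
    )
    reg.fit(clf.rt.summaries[mask], wrong)
    err = float(reg.predict(observed.reshape(1, -1))[0])
    return float(np.clip(1.0 - err, 0.0, 1.0))


def power_test(clf: TrainedClassifier) -> PowerTestResult:
    """Out-of-bag power test: every reference-table row is a POD.

    Each row is classified by the trees that did not train on it, which
    is equivalent to refitting per POD at a fraction of the cost.
    """
    mask = clf.oob_valid
    y_true = clf.rt.model_ids[mask]
    y_pred = clf.oob_predictions[mask]
    models = clf.models
    confusion = (
        pd.crosstab(pd.Series(y_true, name="true"), pd.Series(y_pred, name="predicted"))
        .reindex(index=models, columns=models, fill_value=0)
    )
    ce = {}
    tpr = {}
    for m in models:
        row = confusion.loc[m]
        total = int(row.sum())
        correct = int(row[m])
        ce[m] = 1.0 - correct / total if total else np.nan
        tpr[m] = 1.0 - ce[m] if total else np.nan
    prior_error = float((y_true != y_pred).mean()) if len(y_true) else np.nan
    return PowerTestResult(
        classification_error=ce,
        true_positive_rate=tpr,
        confusion=confusion,
        prior_error_rate=prior_error,
        n_oob=int(mask.sum()),
    )


def lda_project(
    rt: ReferenceTable,
    observed: Sequence[float] | None = None,
    ridge: float = 1e-6,
) -> LDAProjection:
    """Fisher discriminant projection onto M-1 axes.

    The within-class scatter is ridge-regularized (``ridge`` x trace
    added to the diagonal) when singular; the observed point is projected
    with the same loadings as the simulations.
    """
    X = rt.summaries
    y = rt.model_ids
    models = rt.models
    if len(models) < 2:
        raise ValueError("need at least two models")
    n_axes = len(models) - 1
    if X.shape[1] < n_axes:
        raise ValueError("summary dimension smaller than M-1")
    mean = X.mean(axis=0)
    p = X.shape[1]
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    for m in models:
        Xm = X[y == m]
        mu = Xm.mean(axis=0)
        d = Xm - mu
        sw += d.T @ d
        diff = (mu - mean).reshape(-1, 1)
        sb += len(Xm) * (diff @ diff.T)
    try:
        vals, vecs = linalg.eigh(sb, sw)
    except linalg.LinAlgError:
        sw = sw + ridge * np.trace(sw) * np.eye(p)
        vals, vecs = linalg.eigh(sb, sw)
    order = np.argsort(vals)[::-1][:n_axes]
    axes = vecs[:, order]
    coords = (X - mean) @ axes
    obs_coords = None
    if observed is not None:
        obs_coords = (np.asarray(observed, float) - mean) @ axes
    return LDAProjection(
        coordinates=coords,
        observed_coordinates=obs_coords,
        model_ids=y.copy(),
        axes=axes,
        mean=mean,
    )


def select_model(
    rt: ReferenceTable,
    observed: Sequence[float],
    n_trees: int = 1000,
    seed: int | None = None,
    name: str = "contrast",
) -> StepResult:
    """Train, power-test, classify and attach the posterior for one
    contrast over all models in ``rt``."""
    clf = train_forest(rt, n_trees=n_trees, seed=seed)
    power = power_test(clf)
    sel = classify_observed(clf, observed)
    sel.posterior_probability = posterior_probability(clf, observed)
    return StepResult(
        name=name, models=tuple(rt.models), selection=sel, power=power
    )


def stepwise_select(
    rt: ReferenceTable,
    observed: Sequence[float],
    categories: Mapping[str, Sequence[int]] | None = None,
    n_trees: int = 1000,
    seed: int | None = None,
) -> StepwiseReport:
    """Step-wise model selection: within-category contrasts, then a final
    contrast of the category winners.

    ``categories`` defaults to the three scenario families (Continuity,
    DiscontinuityWest, DiscontinuityEast), intersected with the models
    actually present in the reference table.  With a single category the
    within-category winner is final.
    """
    if categories is None:
        present = set(rt.models)
        categories = {
            name: tuple(m for m in ms if m in present)
            for name, ms in DEFAULT_CATEGORIES.items()
        }
        categories = {n: ms for n, ms in categories.items() if ms}
    steps: dict[str, StepResult] = {}
    winners: list[int] = []
    for i, (name, model_ids) in enumerate(categories.items()):
        if not model_ids:
            raise ValueError(f"category {name!r} is empty")
        if len(model_ids) == 1:
            winners.append(int(model_ids[0]))
            continue
        sub = rt.subset(model_ids)
        step = select_model(
            sub, observed, n_trees=n_trees,
            seed=None if seed is None else seed + i, name=name,
        )
        steps[name] = step
        winners.append(step.selection.selected_model)
    winners = sorted(set(winners))
    final = None
    if len(winners) > 1:
        final = select_model(
            rt.subset(winners), observed, n_trees=n_trees,
            seed=None if seed is None else seed + len(categories), name="final",
        )
        selected = final.selection.selected_model
    else:
        selected = winners[0]
    return StepwiseReport(steps=steps, final=final, selected_model=selected)


def simultaneous_select(
    rt: ReferenceTable,
    observed: Sequence[float],
    n_trees: int = 5000,
    seed: int | None = None,
) -> StepResult:
    """Single-step contrast over every model in the reference table."""
    return select_model(rt, observed, n_trees=n_trees, seed=seed, name="simultaneous")


# ---------------------------------------------------------------------------
# Plots (optional reporting)
# ---------------------------------------------------------------------------


def plot_votes(result: ModelSelectionResult, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    models = sorted(result.votes)
    ax.bar([str(m) for m in models], [result.votes[m] for m in models])
    ax.set_xlabel("model")
    ax.set_ylabel("votes")
    ax.set_title(f"selected: model {result.selected_model}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lda(projection: LDAProjection, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    coords = projection.coordinates
    second = coords[:, 1] if coords.shape[1] > 1 else np.zeros(len(coords))
    for m in np.unique(projection.model_ids):
        sel = projection.model_ids == m
        ax.scatter(coords[sel, 0], second[sel], s=4, alpha=0.4, label=f"model {m}")
    if projection.observed_coordinates is not None:
        oc = projection.observed_coordinates
        oy = oc[1] if len(oc) > 1 else 0.0
        ax.scatter([oc[0]], [oy], marker="*", s=160, c="black", label="observed")
    ax.set_xlabel("LD1")
    ax.set_ylabel("LD2" if coords.shape[1] > 1 else "")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
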