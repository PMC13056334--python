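"""Cross-taskset transfer analysis of the parametric state-value heuristic.

The heuristic is ``v(s, g) = expit(beta0 + sum_i beta_i * f_i(s, g))`` over the
13 rule-independent features of :mod:`rewritelab.features`.  Ground truth
"value" of a state is binary reachability: 1 if the task's goal can be reached
from the state, 0 otherwise.  A logistic model is fitted to a class-balanced
sample of labelled states from one taskset and evaluated both on held-out
folds of that taskset (test accuracy) and on the entire labelled sample from
the other taskset (generalisation accuracy).  Similar accuracy on both is the
signature that a state-value heuristic could carry learning across tasksets
that share no transformation rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .engine import INFINITY
from .features import FEATURE_NAMES, GOAL_ONLY, STATE_ONLY, feature_matrix
from .taskgen import Taskset, task_graph

__all__ = [
    "LabeledState",
    "HeuristicModel",
    "TransferReport",
    "label_reachability",
    "sample_balanced",
    "fit_value_model",
    "evaluate_transfer",
    "FEATURE_SUBSETS",
]

FEATURE_SUBSETS: dict[str, tuple[str, ...]] = {
    "all": FEATURE_NAMES,
    "state_only": STATE_ONLY,
    "goal_only": GOAL_ONLY,
}


@dataclass(frozen=True)
class LabeledState:
    """A (state, goal) pair labelled with binary reachability."""

    state: str
    goal: str
    value: int


@dataclass
class HeuristicModel:
    """A fitted logistic state-value model over a feature subset."""

    beta0: float
    betas: np.ndarray
    feature_subset: str = "all"
    pvalues: np.ndarray | None = None
    ridged: bool = False  # True when a perfect-separation fallback was used

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.beta0 + X @ self.betas)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


@dataclass
class TransferReport:
    """Per-fold accuracies and their summaries for one train/transfer run."""

    feature_subset: str
    n_folds: int
    test_accuracy: dict[str, float]
    generalisation_accuracy: dict[str, float]
    fold_test_accuracy: list[float] = field(default_factory=list)
    fold_generalisation_accuracy: list[float] = field(default_factory=list)
    coefficients: list[np.ndarray] = field(default_factory=list)
    coefficient_pvalues: list[np.ndarray] = field(default_factory=list)
    any_fold_ridged: bool = False

    def significant_in_all_folds(self, alpha: float = 0.01) -> list[str]:
        """Feature names (plus intercept) with Wald p < alpha in every fold."""
        names = ("intercept",) + FEATURE_SUBSETS[self.feature_subset]
        P = np.vstack(self.coefficient_pvalues)
        return [n for i, n in enumerate(names) if bool((P[:, i] < alpha).all())]


def _quartiles(values: list[float]) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"q1": float(q1), "median": float(med), "q3": float(q3)}


def label_reachability(taskset: Taskset, max_nodes: int = 100_000) -> list[LabeledState]:
    """Label every enumerable state of every task by goal reachability.

    Each state reachable from a task's start is paired with that task's goal
    and labelled 1 when the goal is reachable from it, 0 otherwise.  Labels
    are de-duplicated on (state, goal) and returned in sorted order for
    reproducibility.  Raises if any task's graph hits an enumeration cap,
    naming the offending tasks: a truncated graph cannot provide sound labels.
    """
    seen: dict[tuple[str, str], int] = {}
    truncated: list[str] = []
    for task in taskset.tasks:
        g = task_graph(task, taskset.ruleset, max_nodes=max_nodes)
        if g.truncated:
            truncated.append(f"{task.start}->{task.goal}")
            continue
        for n in g.nodes:
            key = (n, task.goal)
            label = int(g.distance_to_goal[n] < INFINITY)
            prev = seen.get(key)
            if prev is None:
                seen[key] = label
            elif prev != label:
                # cannot happen on exact graphs: reachability of (state, goal)
                # is a property of the ruleset alone
                raise AssertionError(f"inconsistent labels for {key}")
    if truncated:
        raise ValueError(
            "enumeration caps truncated the state graphs of tasks: "
            + ", ".join(truncated)
        )
    return [
        LabeledState(s, g, v) for (s, g), v in sorted(seen.items())
    ]


def sample_balanced(
    labeled: list[LabeledState],
    n_pos: int = 400,
    n_neg: int = 400,
    rng: Random | None = None,
) -> list[LabeledState]:
    """Uniform sample without replacement of ``n_pos`` positives and ``n_neg`` negatives."""
    rng = rng or Random(0)
    pos = [l for l in labeled if l.value == 1]
    neg = [l for l in labeled if l.value == 0]
    if len(pos) < n_pos or len(neg) < n_neg:
        raise ValueError(
            f"insufficient labelled states: need {n_pos} positives and {n_neg} "
            f"negatives, have {len(pos)} and {len(neg)}"
        )
    return rng.sample(pos, n_pos) + rng.sample(neg, n_neg)


def _design(sample: list[LabeledState], subset: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    X = feature_matrix([(l.state, l.goal) for l in sample], subset)
    y = np.array([l.value for l in sample], dtype=float)
    return X, y


def fit_value_model(
    X: np.ndarray,
    y: np.ndarray,
    feature_subset: str = "all",
    ridge_on_failure: float = 1e-6,
) -> HeuristicModel:
    """Maximum-likelihood logistic fit; tiny-ridge fallback on separation.

    The fit is unpenalised by default.  If the likelihood is unbounded
    (perfect separation) or otherwise fails to converge, the model is refitted
    with an L2 penalty of ``ridge_on_failure`` and flagged ``ridged`` (no Wald
    p-values are reported for such fits).
    """
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e4:
            raise ValueError("diverged")
        return HeuristicModel(
            beta0=float(params[0]),
            betas=params[1:],
            feature_subset=feature_subset,
            pvalues=np.asarray(res.pvalues),
        )
    except Exception:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0 / ridge_on_failure, max_iter=2000, tol=1e-8)
        clf.fit(X, y)
        return HeuristicModel(
            beta0=float(clf.intercept_[0]),
            betas=clf.coef_[0].copy(),
            feature_subset=feature_subset,
            ridged=True,
        )


def evaluate_transfer(
    train: list[LabeledState],
    transfer: list[LabeledState],
    n_folds: int = 30,
    feature_subset: str = "all",
    seed: int = 0,
) -> TransferReport:
    """Cross-validated test and generalisation accuracy of the value model.

    For each of ``n_folds`` label-stratified folds: fit the logistic model on
    the training portion of ``train``, record accuracy (0.5 threshold) on the
    held-out fold, and record generalisation accuracy on the *entire*
    ``transfer`` sample.  Reports the median and quartiles of both accuracy
    series across folds, plus per-fold coefficients and Wald p-values.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    subset = FEATURE_SUBSETS[feature_subset]
    X_tr, y_tr = _design(train, subset)
    X_xf, y_xf = _design(transfer, subset)
    folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    report = TransferReport(
        feature_subset=feature_subset,
        n_folds=n_folds,
        test_accuracy={},
        generalisation_accuracy={},
    )
    for fit_idx, held_idx in folds.split(X_tr, y_tr):
        model = fit_value_model(X_tr[fit_idx], y_tr[fit_idx], feature_subset)
        report.fold_test_accuracy.append(
            float((model.predict(X_tr[held_idx]) == y_tr[held_idx]).mean())
        )
        report.fold_generalisation_accuracy.append(
            float((model.predict(X_xf) == y_xf).mean())
        )
        report.coefficients.append(np.insert(model.betas, 0, model.beta0))
        if model.ridged:
            report.any_fold_ridged = True
            report.coefficient_pvalues.append(
                np.ones(len(subset) + 1)  # no Wald test under the ridge fallback
            )
        else:
            report.coefficient_pvalues.append(model.pvalues)
    report.test_accuracy = _quartiles(report.fold_test_accuracy)
    report.generalisation_accuracy = _quartiles(report.fold_generalisation_accuracy)
    return report


def transfer_report_to_json(report: TransferReport) -> dict:
    """JSON-ready summary mirroring :class:`TransferReport`."""
    return {
        "feature_subset": report.feature_subset,
        "n_folds": report.n_folds,
        "test_accuracy": report.test_accuracy,
        "generalisation_accuracy": report.generalisation_accuracy,
        "fold_test_accuracy": report.fold_test_accuracy,
        "fold_generalisation_accuracy": report.fold_generalisation_accuracy,
        "significant_in_all_folds": report.significant_in_all_folds(),
        "any_fold_ridged": report.any_fold_ridged,
    }
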