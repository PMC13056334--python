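"""Inferential layer: participant-level bootstrap tests and learning contrasts.

The study's block-level conclusions rest on two-sided participant-level
bootstrap hypothesis tests of paired block differences; the trial-level
probe-vs-training comparison is implemented here as a two-stage surrogate — a
per-participant logistic learning slope per condition, contrasted with a
participant-level percentile bootstrap — rather than the hierarchical
Bayesian model, whose fitting is left to external tooling via the exported
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import StrategyReport

__all__ = [
    "BootstrapResult",
    "ContrastResult",
    "bootstrap_diff_test",
    "fit_logistic_slope",
    "learning_rate_contrast",
    "build_block_table",
    "detect_transfer",
]

# block coding used in the regression tables: training blocks 2..7, probes 0/1
BLOCK_CODES = {
    "p1": 0, "p2": 1,
    "t1": 2, "t2": 3, "t3": 4, "t4": 5, "t5": 6, "t6": 7,
}


@dataclass
class BootstrapResult:
    statistic: str
    observed: float
    boot_median: float
    p_value: float
    n_resamples: int
    seed: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _stat_fn(name: str):
    if name == "mean":
        return lambda x: np.mean(x, axis=-1)
    if name == "median":
        return lambda x: np.median(x, axis=-1)
    raise ValueError(f"unknown statistic {name!r}")


def bootstrap_diff_test(
    a: np.ndarray,
    b: np.ndarray,
    statistic: str = "mean",
    paired: bool = True,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Two-sided percentile-bootstrap test for a difference ``b - a``.

    Participants are the resampling unit.  In paired mode the per-participant
    differences are resampled with replacement; unpaired mode resamples the
    two groups independently.  The two-sided p-value is
    ``min(1, 2 * min(P(diff* <= 0), P(diff* >= 0)))`` over the bootstrap
    distribution of the statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and a.shape != b.shape:
        raise ValueError("paired mode requires aligned equal-length vectors")
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 participants per sample")
    rng = np.random.default_rng(seed)
    fn = _stat_fn(statistic)
    if paired:
        d = b - a
        observed = float(fn(d))
        idx = rng.integers(0, len(d), size=(n_resamples, len(d)))
        boot = fn(d[idx])
    else:
        observed = float(fn(b) - fn(a))
        ia = rng.integers(0, len(a), size=(n_resamples, len(a)))
        ib = rng.integers(0, len(b), size=(n_resamples, len(b)))
        boot = fn(b[ib]) - fn(a[ia])
    # add-one correction (Davison & Hinkley) keeps the finite-resample test
    # from being anti-conservative
    n_le = int((boot <= 0).sum())
    n_ge = int((boot >= 0).sum())
    p = min(
        1.0,
        2.0 * min((1 + n_le) / (n_resamples + 1), (1 + n_ge) / (n_resamples + 1)),
    )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return BootstrapResult(
        statistic=statistic,
        observed=observed,
        boot_median=float(np.median(boot)),
        p_value=p,
        n_resamples=n_resamples,
        seed=seed,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """L2-penalised logistic fit by direct minimisation; handles one-class data."""
    from scipy.optimize import minimize
    from scipy.special import expit

    def nll(beta):
        eta = X @ beta
        # log(1 + exp(eta)) - y*eta, numerically stable
        return float(
            np.sum(np.logaddexp(0.0, eta) - y * eta) + alpha * beta @ beta
        )

    def grad(beta):
        return X.T @ (expit(X @ beta) - y) + 2 * alpha * beta

    res = minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS")
    return res.x


def fit_logistic_slope(success: np.ndarray, trial_number: np.ndarray) -> tuple[float, bool]:
    """Per-participant logistic slope of success on cumulative trial number.

    Returns (slope in logits per trial, flagged).  All-success or all-failure
    cells — where the maximum-likelihood slope is unbounded — are refitted
    with a small ridge penalty and flagged.
    """
    y = np.asarray(success, dtype=float)
    X = sm.add_constant(np.asarray(trial_number, dtype=float))
    if y.all() or not y.any():
        return float(_ridge_logit(X, y, alpha=1e-3)[1]), True
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        slope = float(res.params[1])
        if not np.isfinite(slope) or abs(slope) > 50:
            raise ValueError("diverged")
        return slope, False
    except Exception:
        return float(_ridge_logit(X, y, alpha=1e-3)[1]), True


@dataclass
class ContrastResult:
    """Probe-minus-training learning-rate contrast with its bootstrap interval."""

    slopes: pd.DataFrame  # participant, condition, slope, flagged
    training_slope: float
    probe_slope: float
    difference: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int
    flagged_cells: int = 0

    @property
    def interval_excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def learning_rate_contrast(
    trials: pd.DataFrame,
    n_resamples: int = 5_000,
    seed: int = 0,
) -> ContrastResult:
    """Contrast per-trial learning rates between probe and training conditions.

    ``trials`` needs columns ``participant``, ``condition`` ("training" or
    "probe"), ``trial_number`` (cumulative within condition) and ``success``.
    Per participant and condition a logistic slope is fitted; the contrast is
    the mean probe slope minus mean training slope, with a participant-level
    percentile-bootstrap interval.
    """
    required = {"participant", "condition", "trial_number", "success"}
    if not required <= set(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    participants = sorted(trials["participant"].unique())
    if len(participants) < 2:
        raise ValueError("participant-level bootstrap needs >= 2 participants")
    rows = []
    flagged = 0
    for p in participants:
        for cond in ("training", "probe"):
            sub = trials[(trials["participant"] == p) & (trials["condition"] == cond)]
            if len(sub) < 2:
                raise ValueError(f"participant {p} has < 2 {cond} trials")
            slope, flag = fit_logistic_slope(
                sub["success"].to_numpy(), sub["trial_number"].to_numpy()
            )
            flagged += int(flag)
            rows.append(
                {"participant": p, "condition": cond, "slope": slope, "flagged": flag}
            )
    slopes = pd.DataFrame(rows)
    wide = slopes.pivot(index="participant", columns="condition", values="slope")
    diffs = (wide["probe"] - wide["training"]).to_numpy()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diffs), size=(n_resamples, len(diffs)))
    boot = diffs[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ContrastResult(
        slopes=slopes,
        training_slope=float(wide["training"].mean()),
        probe_slope=float(wide["probe"].mean()),
        difference=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        seed=seed,
        flagged_cells=flagged,
    )


def build_block_table(
    block_measures: pd.DataFrame,
    strategy: dict[tuple[str, str], StrategyReport],
    wm_scores: dict[tuple[str, int], float],
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Model-ready table: one row per participant x block.

    Joins the per-block behavioural summaries with strategy weights and the
    per-session working-memory score, adds the block codes used in the
    regression models (training blocks 2-7, probes 0 and 1) and the
    block x strategy interaction columns.  Rows with no strategy report are
    flagged via ``has_strategy`` so strategy-bearing models can exclude them.
    """
    df = block_measures.copy()
    df["block_code"] = df["block"].map(BLOCK_CODES)
    df["is_probe"] = df["block"].str.startswith("p")
    if groups:
        df["group"] = df["participant"].map(groups)
    df["wm_score"] = [
        wm_scores.get((p, s), np.nan)
        for p, s in zip(df["participant"], df["session"])
    ]
    for col, attr in (("w_tryandsee", "w_t"), ("w_workitout", "w_w"), ("w_intuition", "w_i")):
        df[col] = [
            getattr(strategy[(p, b)], attr) if (p, b) in strategy else np.nan
            for p, b in zip(df["participant"], df["block"])
        ]
    df["has_strategy"] = ~df["w_tryandsee"].isna()
    for col in ("w_tryandsee", "w_workitout", "w_intuition"):
        df[f"block_x_{col}"] = df["block_code"] * df[col]
    return df


def detect_transfer(
    block_table: pd.DataFrame,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Test for an elevated post-training probe baseline beyond direct practice.

    Statistic: per-participant (p2 - p1) - (t2 - t1) difference in solved
    proportion — the probe-block improvement in excess of the improvement
    seen over the first two training blocks, which bounds what direct
    practice alone provides.  Transfer is flagged when the two-sided
    bootstrap test is significant with a positive observed difference.
    """
    piv = block_table.pivot_table(
        index="participant", columns="block", values="solved_proportion"
    )
    for col in ("p1", "p2", "t1", "t2"):
        if col not in piv:
            raise ValueError(f"block table lacks block {col}")
    probe_change = (piv["p2"] - piv["p1"]).to_numpy()
    training_change = (piv["t2"] - piv["t1"]).to_numpy()
    return bootstrap_diff_test(
        training_change, probe_change, statistic="mean", paired=True,
        n_resamples=n_resamples, seed=seed,
    )
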