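"""Cross-validated ridge decoding of figure position from population activity.

The decoder reads the figure's azimuth bin (1-16, treated as a continuous
regression target) from a neurons x trials response matrix with ridge
regression.  Each iteration resamples both the trial split (50/50
train/test) and, when a subset size is requested, the neuron subset; the
ridge penalty is chosen on the training half by internal cross-validation
(scikit-learn ``RidgeCV`` over a log-spaced grid).  Performance is the
held-out coefficient of determination r^2 = 1 - SS_res/SS_tot (which can be
negative), averaged over iterations with a 95% confidence interval.

A pattern-generalization observer mirrors the behavioral side report: a
linear classifier trained to report figure side (left/right) on one set of
patterns is tested on novel patterns of the same condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, RidgeCV
from sklearn.metrics import r2_score

from .population import ResponseMatrix

__all__ = ["DecodingConfig", "DecodingResult", "fit_position_decoder",
           "decode_feature_matrix", "decoding_curve",
           "side_generalization_test", "permuted_label_null"]


@dataclass(frozen=True)
class DecodingConfig:
    """Decoder settings; defaults follow the neural-data analysis."""

    train_fraction: float = 0.5
    n_iterations: int = 100
    penalty_grid: tuple[float, ...] = tuple(np.logspace(-3, 3, 10))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")


@dataclass
class DecodingResult:
    """Iteration-wise held-out r^2 with summary statistics."""

    r2_per_iteration: np.ndarray
    condition: str | None = None
    n_neurons: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def variance_explained(self) -> float:
        return float(np.mean(self.r2_per_iteration))

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.r2_per_iteration, [2.5, 97.5])
        return float(lo), float(hi)

    def summary(self) -> str:
        lo, hi = self.ci95
        parts = [f"r2 = {self.variance_explained:.4f}",
                 f"95% CI [{lo:.4f}, {hi:.4f}]",
                 f"{len(self.r2_per_iteration)} iterations"]
        if self.condition:
            parts.insert(0, self.condition)
        if self.n_neurons:
            parts.append(f"{self.n_neurons} neurons")
        return ", ".join(parts)


def _one_iteration(x: np.ndarray, y: np.ndarray, config: DecodingConfig,
                   rng: np.random.Generator,
                   n_neurons: int | None) -> float:
    n_units, n_trials = x.shape
    if n_neurons is not None:
        if n_neurons > n_units:
            raise ValueError("requested more neurons than available")
        units = rng.choice(n_units, size=n_neurons, replace=False)
        x = x[units]
    order = rng.permutation(n_trials)
    n_train = int(round(config.train_fraction * n_trials))
    train, test = order[:n_train], order[n_train:]
    if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
        raise ValueError("need >= 2 target values in both splits")
    model = RidgeCV(alphas=config.penalty_grid)
    model.fit(x[:, train].T, y[train])
    return float(r2_score(y[test], model.predict(x[:, test].T)))


def decode_feature_matrix(features: np.ndarray, labels: np.ndarray,
                          config: DecodingConfig = DecodingConfig(),
                          n_neurons: int | None = None,
                          condition: str | None = None) -> DecodingResult:
    """Ridge-decode a continuous label from any units x trials matrix."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 2 or x.shape[1] != y.shape[0]:
        raise ValueError("features must be (units, trials) matching labels")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    rng = np.random.default_rng(config.seed)
    r2 = np.array([_one_iteration(x, y, config, rng, n_neurons)
                   for _ in range(config.n_iterations)])
    return DecodingResult(r2, condition, n_neurons or x.shape[0])


def fit_position_decoder(responses: ResponseMatrix | np.ndarray,
                         azimuth_labels: np.ndarray | None = None,
                         config: DecodingConfig = DecodingConfig(),
                         n_neurons: int | None = None,
                         condition: str | None = None) -> DecodingResult:
    """Decode figure azimuth bin from trial responses.

    Given a :class:`ResponseMatrix`, labels default to the trial table's
    ``az_bin`` column; ``condition`` restricts to that condition's trials
    (pooling its two variants, as in the source analysis).
    """
    if isinstance(responses, ResponseMatrix):
        trials = responses.trials
        keep = np.ones(responses.n_trials, dtype=bool)
        if condition is not None:
            keep = (trials["condition"] == condition).to_numpy()
        x = responses.responses[:, keep]
        y = trials.loc[keep, "az_bin"].to_numpy(dtype=float)
    else:
        if azimuth_labels is None:
            raise ValueError("labels required with a bare matrix")
        x = np.asarray(responses, dtype=float)
        y = np.asarray(azimuth_labels, dtype=float)
    return decode_feature_matrix(x, y, config, n_neurons, condition)


def permuted_label_null(responses: ResponseMatrix | np.ndarray,
                        azimuth_labels: np.ndarray | None = None,
                        config: DecodingConfig = DecodingConfig(),
                        n_neurons: int | None = None,
                        condition: str | None = None) -> DecodingResult:
    """Decoder performance with labels randomly permuted (chance floor)."""
    if isinstance(responses, ResponseMatrix):
        trials = responses.trials
        keep = (np.ones(responses.n_trials, dtype=bool)
                if condition is None
                else (trials["condition"] == condition).to_numpy())
        x = responses.responses[:, keep]
        y = trials.loc[keep, "az_bin"].to_numpy(dtype=float)
    else:
        x = np.asarray(responses, dtype=float)
        y = np.asarray(azimuth_labels, dtype=float)
    rng = np.random.default_rng(config.seed + 1)
    y = rng.permutation(y)
    res = decode_feature_matrix(x, y, config, n_neurons, condition)
    res.extra["null"] = True
    return res


def decoding_curve(responses: ResponseMatrix,
                   conditions: list[str],
                   neuron_counts: list[int],
                   config: DecodingConfig = DecodingConfig()) -> pd.DataFrame:
    """Held-out r^2 vs number of neurons for each texture condition.

    Within each condition the two pattern variants are pooled before the
    trial split.  Returns a tidy frame (condition, n_neurons, r2_mean,
    ci_lo, ci_hi, plus per-iteration rows in ``r2_iterations``).
    """
    present = set(responses.trials["condition"])
    missing = [c for c in conditions if c not in present]
    if missing:
        raise ValueError(f"session lacks conditions {missing}")
    rows = []
    for cond in conditions:
        for k, n in enumerate(neuron_counts):
            cfg = DecodingConfig(config.train_fraction, config.n_iterations,
                                 config.penalty_grid,
                                 config.seed + 1000 * k)
            res = fit_position_decoder(responses, config=cfg, n_neurons=n,
                                       condition=cond)
            lo, hi = res.ci95
            rows.append({"condition": cond, "n_neurons": n,
                         "r2_mean": res.variance_explained,
                         "ci_lo": lo, "ci_hi": hi,
                         "r2_iterations": res.r2_per_iteration})
    return pd.DataFrame(rows)


def side_generalization_test(train_responses: np.ndarray,
                             train_sides: np.ndarray,
                             test_responses: np.ndarray,
                             test_sides: np.ndarray,
                             train_patterns: np.ndarray | None = None,
                             test_patterns: np.ndarray | None = None,
                             seed: int = 0) -> float:
    """Left/right readout trained on some patterns, tested on novel ones.

    ``*_responses`` are units x trials; ``*_sides`` are binary side labels.
    If pattern identities are supplied the train and test pattern sets must
    be disjoint (the point of the generalization test).  Returns held-out
    accuracy; chance is 0.5.
    """
    if train_patterns is not None and test_patterns is not None:
        overlap = set(np.unique(train_patterns)) & set(np.unique(test_patterns))
        if overlap:
            raise ValueError(f"train/test pattern sets overlap: {overlap}")
    clf = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    clf.fit(np.asarray(train_responses, dtype=float).T,
            np.asarray(train_sides))
    acc = clf.score(np.asarray(test_responses, dtype=float).T,
                    np.asarray(test_sides))
    return float(acc)
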