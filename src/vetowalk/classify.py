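"""Time-resolved leave-one-pair-out linear-SVM classification.

At each time point the feature is the single scalar walker position, so
the fitted linear SVM reduces to a learned threshold plus orientation.
Cross-validation holds out one left/right pair per fold: each fold
contributes 0, 50 or 100 percent depending on how many of the two test
trials are labelled correctly, and the fold mean is the per-participant
accuracy ``a_t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .chains import MarkovChain, t_step_matrix, time_reversed_chain
from .trials import TrialSet

__all__ = [
    "AccuracyCurve",
    "loo_pair_accuracy_at_t",
    "accuracy_timecourse",
    "bayes_accuracy_curve",
]


@dataclass(frozen=True)
class AccuracyCurve:
    """Per-participant and grand-mean accuracy (percent) per time point."""

    times: np.ndarray
    per_participant: np.ndarray  # (k, len(times)) in [0, 100]
    config: dict = field(default_factory=dict)

    @property
    def grand_mean(self) -> np.ndarray:
        return self.per_participant.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        k, T = self.per_participant.shape
        return pd.DataFrame(
            {
                "t": np.tile(self.times, k),
                "participant": np.repeat(np.arange(k), T),
                "accuracy": self.per_participant.ravel(),
            }
        )

    def grand_mean_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "accuracy": self.grand_mean})

    def to_csv(self, path: Union[str, Path], grand_path: Union[str, Path, None] = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if grand_path is not None:
            self.grand_mean_frame().to_csv(grand_path, index=False)


def _fit_predict(train_x: np.ndarray, train_y: np.ndarray,
                 test_x: np.ndarray, C: float) -> np.ndarray:
    """Linear SVM on scalar features; deterministic degenerate fallback.

    If every training feature is identical the margin is undefined; the
    contract is to predict the class of the first training example.  Ties
    of the decision function (possible on integer features) go to "right".
    """
    if np.ptp(train_x) == 0:
        return np.full(test_x.shape[0], train_y[0])
    model = SVC(kernel="linear", C=C)
    model.fit(train_x.reshape(-1, 1), train_y)
    d = model.decision_function(test_x.reshape(-1, 1))
    return np.where(d >= 0, model.classes_[1], model.classes_[0])


def loo_pair_accuracy_at_t(
    left: np.ndarray, right: np.ndarray, svm_penalty: float = 1.0
) -> float:
    """Leave-one-pair-out accuracy (percent) for one participant, one t.

    ``left`` and ``right`` are the M scalar features per class; fold ``i``
    tests on ``(left[i], right[i])`` and trains on the remaining ``2M - 2``
    trials, so train and test stay exactly class-balanced.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.ndim != 1 or right.ndim != 1 or left.size != right.size:
        raise ValueError("need equally many left and right scalar features")
    if left.size < 2:
        raise ValueError("need at least M=2 trials per class")
    if svm_penalty <= 0:
        raise ValueError(f"svm_penalty must be positive, got {svm_penalty}")
    M = left.size
    y = np.concatenate([np.zeros(M - 1, dtype=int), np.ones(M - 1, dtype=int)])
    mask = np.ones(M, dtype=bool)
    total = 0.0
    for i in range(M):
        mask[i] = False
        train_x = np.concatenate([left[mask], right[mask]])
        mask[i] = True
        pred = _fit_predict(train_x, y, np.array([left[i], right[i]]), svm_penalty)
        total += 50.0 * (int(pred[0] == 0) + int(pred[1] == 1))
    return total / M


def accuracy_timecourse(
    trials: TrialSet,
    svm_penalty: float = 1.0,
    times: Optional[Sequence[int]] = None,
    pair_seed: Optional[int] = None,
    labels: Optional[np.ndarray] = None,
) -> AccuracyCurve:
    """Apply :func:`loo_pair_accuracy_at_t` at every time point.

    Within each class the trial order is shuffled once per participant with
    a seeded RNG before pairing (the pairing is exchangeable, so this only
    affects which left meets which right in a fold).  ``times`` restricts
    the evaluation to a subset of time points; ``labels`` substitutes the
    trial labels (used for permutation null checks).
    """
    cfg = trials.config
    all_times = trials.times
    if times is None:
        times = all_times
    times = np.asarray(times, dtype=int)
    t_index = {int(t): j for j, t in enumerate(all_times)}
    cols = [t_index[int(t)] for t in times]

    lab = trials.labels if labels is None else np.asarray(labels)
    if lab.shape != trials.labels.shape:
        raise ValueError("labels shape mismatch")
    if np.any((lab == 0).sum(axis=1) != cfg.M):
        raise ValueError("labels must keep the M/M class balance")

    seed = cfg.seed if pair_seed is None else pair_seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xACC,)))

    k = trials.n_participants
    per = np.empty((k, times.size))
    for p in range(k):
        li = rng.permutation(np.flatnonzero(lab[p] == 0))
        ri = rng.permutation(np.flatnonzero(lab[p] == 1))
        for j, c in enumerate(cols):
            per[p, j] = loo_pair_accuracy_at_t(
                trials.positions[p, li, c],
                trials.positions[p, ri, c],
                svm_penalty,
            )
    return AccuracyCurve(
        times=times,
        per_participant=per,
        config={"svm_penalty": svm_penalty, **cfg.to_dict()},
    )


def bayes_accuracy_curve(chain: MarkovChain, N: int) -> np.ndarray:
    """Bayes-optimal accuracy (percent) from the single scalar position.

    At lag ``|t|`` the class-conditional laws are the boundary rows of the
    reversed chain's ``|t|``-step matrix; the optimal rule picks the larger
    posterior, giving ``100 * sum_k max(row0, row_n+1)/2``.  Upper-bounds
    any classifier's expected accuracy, which makes it a test oracle.
    """
    rev = time_reversed_chain(chain)
    out = np.empty(N)
    for j, lag in enumerate(range(N - 1, -1, -1)):
        Pt = t_step_matrix(rev, lag)
        out[j] = 100.0 * np.maximum(0.5 * Pt[0], 0.5 * Pt[-1]).sum()
    return out
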