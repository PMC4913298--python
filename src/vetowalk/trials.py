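"""Generation of time-locked "left"/"right" trials.

A trial is the ``N``-step window of a walker trajectory ending at a flash:
a step at which the walker sits on a boundary state while the independent
veto switch happens to be on.  Trials are time-locked so the flash occurs
at ``t = 0``; earlier positions sit at ``t = -1, ..., -(N-1)``.

Two generators are provided and are statistically equivalent:

* ``literal`` — simulate long stationary series with an explicit Bernoulli
  switch, pick one qualifying flash uniformly at random, store the window.
* ``reversed`` — place the walker on the required boundary at ``t = 0``
  and run the time-reversed chain backwards for ``N - 1`` steps.  This is
  the fast production method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .chains import (
    MarkovChain,
    spectral_summary,
    stationary_distribution,
    t_step_matrix,
    time_reversed_chain,
)
from .errors import GenerationExhaustedError

LABELS = ("left", "right")

__all__ = [
    "LABELS",
    "GeneratorConfig",
    "TrialSet",
    "simulate_veto_switch",
    "generate_trials",
    "generate_trials_literal",
    "generate_trials_reversed",
    "average_position_curve",
    "expected_position_curve",
    "flash_next_step_probability",
    "estimate_flash_next_step_probability",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of a trial-generation run.

    ``N`` is the trial length in steps (window includes the flash step at
    ``t = 0``), ``M`` the number of trials per class per participant, ``k``
    the number of participants and ``p_switch`` the per-step probability
    that the veto switch is on.  ``mode`` selects the generator.

    The defaults ``N=100, M=50, p_switch=0.001, k=500`` are nominal
    full-scale values; desk-scale runs override them.
    """

    chain: MarkovChain
    N: int = 100
    M: int = 50
    k: int = 500
    p_switch: float = 0.001
    seed: int = 0
    mode: str = "reversed"
    #: literal mode: minimum qualifying flashes to choose among per trial
    min_flash_events: int = 50
    #: literal mode: hard cap on the series length before erroring
    max_series_steps: int = 10**7

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.M < 2:
            raise ValueError(f"M must be >= 2, got {self.M}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not (0.0 < self.p_switch < 1.0):
            raise ValueError(f"p_switch must be in (0, 1), got {self.p_switch}")
        if self.mode not in ("literal", "reversed"):
            raise ValueError(f"mode must be 'literal' or 'reversed', got {self.mode!r}")

    def to_dict(self) -> dict:
        return {
            "chain": self.chain.to_dict(),
            "N": self.N,
            "M": self.M,
            "k": self.k,
            "p_switch": self.p_switch,
            "seed": self.seed,
            "mode": self.mode,
            "min_flash_events": self.min_flash_events,
            "max_series_steps": self.max_series_steps,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneratorConfig":
        doc = dict(doc)
        doc["chain"] = MarkovChain.from_dict(doc["chain"])
        return cls(**doc)


@dataclass(frozen=True)
class TrialSet:
    """k participants x 2M labelled trials x N time-locked positions.

    ``positions[p, i, j]`` is the walker state of trial ``i`` of
    participant ``p`` at time ``times[j]``; ``times`` runs from ``-(N-1)``
    to 0 and ``labels[p, i]`` is 0 for "left", 1 for "right".
    """

    positions: np.ndarray
    labels: np.ndarray
    config: GeneratorConfig
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        lab = np.asarray(self.labels)
        if pos.ndim != 3:
            raise ValueError("positions must be (participants, trials, time)")
        k, n_trials, N = pos.shape
        if lab.shape != (k, n_trials):
            raise ValueError("labels shape must match positions")
        if n_trials != 2 * self.config.M or k != self.config.k or N != self.config.N:
            raise ValueError("positions shape inconsistent with config")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", lab)

    @property
    def times(self) -> np.ndarray:
        return np.arange(-(self.config.N - 1), 1)

    @property
    def n_participants(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        """Check the structural invariants; raises ``ValueError`` on breach."""
        chain = self.config.chain
        m = chain.n_states
        pos, lab = self.positions, self.labels
        if pos.min() < 0 or pos.max() >= m:
            raise ValueError("positions outside state space")
        final = pos[:, :, -1]
        if np.any(final[lab == 0] != 0) or np.any(final[lab == 1] != m - 1):
            raise ValueError("t=0 position does not match the trial label")
        counts = (lab == 0).sum(axis=1)
        if np.any(counts != self.config.M):
            raise ValueError("unbalanced left/right quota in some participant")
        steps = chain.transition[pos[:, :, :-1], pos[:, :, 1:]]
        if np.any(steps <= 0):
            raise ValueError("consecutive positions not reachable under the chain")

    # -- persistence -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        k, n_trials, N = self.positions.shape
        t = self.times
        return pd.DataFrame(
            {
                "participant": np.repeat(np.arange(k), n_trials * N),
                "trial": np.tile(np.repeat(np.arange(n_trials), N), k),
                "label": np.repeat(
                    np.asarray(LABELS)[self.labels.ravel()], N
                ),
                "t": np.tile(t, k * n_trials),
                "position": self.positions.ravel(),
            }
        )

    def _meta(self) -> dict:
        return {"config": self.config.to_dict(), "provenance": self.provenance}

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the long-format CSV plus a ``.meta.json`` sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self._meta(), indent=1)
        )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "TrialSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        config = GeneratorConfig.from_dict(meta["config"])
        df = pd.read_csv(path)
        k, n_trials, N = config.k, 2 * config.M, config.N
        df = df.sort_values(["participant", "trial", "t"], kind="stable")
        positions = df["position"].to_numpy().reshape(k, n_trials, N)
        lab_idx = df.loc[df["t"] == 0, "label"].map(
            {lbl: i for i, lbl in enumerate(LABELS)}
        )
        labels = lab_idx.to_numpy().reshape(k, n_trials)
        return cls(positions, labels, config, provenance=meta["provenance"])

    def to_npz(self, path: Union[str, Path]) -> None:
        """Compact array container plus a JSON sidecar (exact round-trip)."""
        path = Path(path)
        np.savez(path, positions=self.positions, labels=self.labels)
        path.with_suffix(".meta.json").write_text(json.dumps(self._meta(), indent=1))

    @classmethod
    def from_npz(cls, path: Union[str, Path]) -> "TrialSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as f:
            positions, labels = f["positions"], f["labels"]
        return cls(positions, labels, GeneratorConfig.from_dict(meta["config"]),
                   provenance=meta["provenance"])


def simulate_veto_switch(
    length: int, p_switch: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean on/off series of the veto switch: iid Bernoulli(p_switch).

    On-events last exactly one step and are independent of everything else.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not (0.0 < p_switch < 1.0):
        raise ValueError(f"p_switch must be in (0, 1), got {p_switch}")
    return rng.random(length) < p_switch


def _cumulative_rows(P: np.ndarray) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    return cum


def _step_batch(cum: np.ndarray, pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Advance a batch of walkers one step via inverse-CDF sampling."""
    u = rng.random(pos.size)
    nxt = (cum[pos] <= u[:, None]).sum(axis=1)
    return np.minimum(nxt, cum.shape[1] - 1)


def _participant_rng(seed: int, participant: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(participant,)))


def _targets(chain: MarkovChain, M: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial target boundary state and label index (M left then M right)."""
    labels = np.repeat(np.array([0, 1], dtype=np.int8), M)
    targets = np.where(labels == 0, 0, chain.n_states - 1)
    return targets, labels


def _literal_participant(
    config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Simulate 2M independent stationary series and cut one window each."""
    chain, N = config.chain, config.N
    m = chain.n_states
    B = 2 * config.M
    targets, _ = _targets(chain, config.M)
    cum = _cumulative_rows(chain.transition)

    if chain.topology in ("line", "complete"):
        pos = rng.integers(0, m, size=B)  # uniform == stationary for built-ins
    else:
        pi = stationary_distribution(chain)
        pos = rng.choice(m, size=B, p=pi)
        burn = int(np.ceil(100 * max(spectral_summary(chain).relaxation_time, 1.0)))
        for _ in range(burn):
            pos = _step_batch(cum, pos, rng)

    block = 2048
    series_blocks: list[np.ndarray] = []
    qual_blocks: list[np.ndarray] = []
    counts = np.zeros(B, dtype=np.int64)
    total = 0
    while np.any(counts < config.min_flash_events):
        if total >= config.max_series_steps:
            raise GenerationExhaustedError(
                f"no {config.min_flash_events} qualifying flashes within "
                f"{config.max_series_steps} steps (N={N}, M={config.M}, "
                f"p_switch={config.p_switch}, topology={chain.topology}, "
                f"n={chain.n_interior})"
            )
        sb = np.empty((B, block), dtype=np.int16)
        for j in range(block):
            pos = _step_batch(cum, pos, rng)
            sb[:, j] = pos
        on = rng.random((B, block)) < config.p_switch
        qual = (sb == targets[:, None]) & on
        # a window needs N-1 predecessors: mask early global indices
        if total < N - 1:
            qual[:, : max(0, N - 1 - total)] = False
        counts += qual.sum(axis=1)
        series_blocks.append(sb)
        qual_blocks.append(qual)
        total += block

    series = np.concatenate(series_blocks, axis=1)
    qual = np.concatenate(qual_blocks, axis=1)
    out = np.empty((B, N), dtype=np.int16)
    for b in range(B):
        events = np.flatnonzero(qual[b])
        pick = events[rng.integers(events.size)]
        out[b] = series[b, pick - N + 1 : pick + 1]
    return out


def _reversed_participant(
    config: GeneratorConfig, rev_cum: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Grow each trial backwards from its boundary state at t=0."""
    chain, N = config.chain, config.N
    B = 2 * config.M
    targets, _ = _targets(chain, config.M)
    out = np.empty((B, N), dtype=np.int16)
    pos = targets.astype(np.int64)
    out[:, N - 1] = pos
    for j in range(N - 2, -1, -1):
        pos = _step_batch(rev_cum, pos, rng)
        out[:, j] = pos
    return out


def generate_trials(config: GeneratorConfig) -> TrialSet:
    """Dispatch on ``config.mode`` to the literal or reversed generator."""
    if config.mode == "literal":
        return generate_trials_literal(config)
    return generate_trials_reversed(config)


def generate_trials_literal(config: GeneratorConfig) -> TrialSet:
    """Long-series generator: stationary walk + explicit veto switch.

    Each trial comes from an independent stationary series.  A flash is a
    step where the walker occupies the trial's target boundary while the
    switch is on; one qualifying flash is chosen uniformly at random and
    the ``N`` positions ending at (and including) it form the trial.
    """
    if config.mode != "literal":
        config = replace(config, mode="literal")
    _, labels = _targets(config.chain, config.M)
    k = config.k
    positions = np.empty((k, 2 * config.M, config.N), dtype=np.int16)
    for p in range(k):
        positions[p] = _literal_participant(config, _participant_rng(config.seed, p))
    return TrialSet(
        positions,
        np.tile(labels, (k, 1)),
        config,
        provenance={"mode": "literal", "seed": config.seed},
    )


def generate_trials_reversed(config: GeneratorConfig) -> TrialSet:
    """Fast generator exploiting time reversal.

    Sets the t=0 position to the labelled boundary and simulates ``N - 1``
    steps of the time-reversed chain, written at ``t = -1, ..., -(N-1)``.
    Statistically indistinguishable from the literal generator.
    """
    if config.mode != "reversed":
        config = replace(config, mode="reversed")
    rev_cum = _cumulative_rows(time_reversed_chain(config.chain).transition)
    _, labels = _targets(config.chain, config.M)
    k = config.k
    positions = np.empty((k, 2 * config.M, config.N), dtype=np.int16)
    for p in range(k):
        positions[p] = _reversed_participant(
            config, rev_cum, _participant_rng(config.seed, p)
        )
    return TrialSet(
        positions,
        np.tile(labels, (k, 1)),
        config,
        provenance={"mode": "reversed", "seed": config.seed},
    )


def average_position_curve(trials: TrialSet) -> pd.DataFrame:
    """Mean walker position vs time per label, participants pooled.

    Returns a DataFrame indexed by ``t`` with one column per label.
    """
    out = {}
    lab = trials.labels
    for i, name in enumerate(LABELS):
        sel = trials.positions[lab == i]
        if sel.size == 0:
            raise ValueError(f"no {name} trials present")
        out[name] = sel.mean(axis=0)
    return pd.DataFrame(out, index=pd.Index(trials.times, name="t"))


def expected_position_curve(chain: MarkovChain, N: int) -> pd.DataFrame:
    """Analytic counterpart of :func:`average_position_curve`.

    For left trials the mean position ``|t|`` steps before the flash is
    ``sum_k k * Ptilde^(|t|)[0, k]`` with ``Ptilde`` the reversed chain.
    """
    rev = time_reversed_chain(chain)
    states = np.arange(chain.n_states)
    rows = {name: np.empty(N) for name in LABELS}
    for j, lag in enumerate(range(N - 1, -1, -1)):
        Pt = t_step_matrix(rev, lag)
        rows["left"][j] = states @ Pt[0]
        rows["right"][j] = states @ Pt[-1]
    return pd.DataFrame(rows, index=pd.Index(np.arange(-(N - 1), 1), name="t"))


def flash_next_step_probability(
    chain: MarkovChain, state: int, conditioned: bool = False
) -> float:
    """Probability that the LEFT light flashes at the next step.

    The walker sits at ``state`` with the buttons permanently powered, so a
    flash occurs whenever a boundary state is entered.  Unconditioned, the
    answer is the one-step probability into state 0.  With
    ``conditioned=True`` the probability is taken given that *some* flash
    occurs at the next step (the next step is a decision time).
    """
    m = chain.n_states
    if not (0 <= state < m):
        raise ValueError(f"state {state} outside state space")
    row = chain.transition[state]
    p_left = float(row[0])
    if not conditioned:
        return p_left
    p_any = float(row[0] + row[m - 1])
    if p_any == 0.0:
        raise ValueError("no boundary reachable in one step from this state")
    return p_left / p_any


def estimate_flash_next_step_probability(
    chain: MarkovChain,
    state: int,
    n_draws: int,
    rng: np.random.Generator,
    conditioned: bool = False,
) -> float:
    """Monte-Carlo companion of :func:`flash_next_step_probability`."""
    cum = _cumulative_rows(chain.transition)
    pos = np.full(n_draws, state, dtype=np.int64)
    nxt = _step_batch(cum, pos, rng)
    left = nxt == 0
    if not conditioned:
        return float(left.mean())
    any_flash = left | (nxt == chain.n_states - 1)
    if not any_flash.any():
        raise ValueError("no flash observed; cannot condition")
    return float(left[any_flash].sum() / any_flash.sum())
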