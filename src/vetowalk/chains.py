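"""Discrete-time random-walk chains on ``{0, ..., n+1}`` and their analysis.

The state space has ``n`` interior states plus two boundary ("button")
states 0 and ``n+1``.  Two built-in topologies are provided:

* ``line`` — nearest-neighbour walk with lazy-reflecting boundaries
  (``P[0,0] = P[0,1] = 1/2`` and symmetrically at ``n+1``).  The matrix is
  symmetric, hence doubly stochastic, which forces a uniform stationary
  distribution.
* ``complete`` — every entry equals ``1/(n+2)``, including self-loops; the
  walk mixes in a single step.

Arbitrary row-stochastic matrices are supported through the ``custom``
topology, loadable from JSON or header-free CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .errors import DegenerateChainError

#: entrywise tolerance for stochasticity checks
STOCHASTIC_ATOL = 1e-12
#: tolerance for spectral quantities (unit eigenvalue detection etc.)
SPECTRAL_ATOL = 1e-10

__all__ = [
    "MarkovChain",
    "SpectralSummary",
    "build_line_chain",
    "build_complete_graph_chain",
    "stationary_distribution",
    "t_step_matrix",
    "spectral_summary",
    "time_reversed_chain",
    "validate_pmf",
]


def _check_positive_int(n, name: str = "n") -> int:
    if isinstance(n, bool) or not isinstance(n, (int, np.integer)):
        raise ValueError(f"{name} must be an integer, got {n!r}")
    if n < 1:
        raise ValueError(f"{name} must be >= 1, got {n}")
    return int(n)


def validate_pmf(pmf: np.ndarray, atol: float = STOCHASTIC_ATOL) -> np.ndarray:
    """Validate and return a probability mass function as a 1-D float array.

    Raises ``ValueError`` on negative entries or if the entries do not sum
    to 1 within ``atol``.
    """
    p = np.asarray(pmf, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"pmf must be 1-D, got shape {p.shape}")
    if np.any(p < -atol):
        raise ValueError("pmf has negative entries")
    total = p.sum()
    if abs(total - 1.0) > max(atol, 1e-9 * p.size):
        raise ValueError(f"pmf entries sum to {total}, expected 1")
    return np.clip(p, 0.0, None)


@dataclass(frozen=True)
class MarkovChain:
    """A row-stochastic transition matrix on states ``{0, ..., n+1}``.

    Parameters
    ----------
    transition
        ``(n+2, n+2)`` row-stochastic matrix; ``transition[i, j]`` is the
        one-step probability of moving from state ``i`` to state ``j``.
    topology
        One of ``"line"``, ``"complete"``, ``"custom"``.  For the two
        built-ins the matrix is additionally required to be doubly
        stochastic (columns summing to 1), which guarantees a uniform
        stationary distribution.
    """

    transition: np.ndarray
    topology: str = "custom"

    def __post_init__(self) -> None:
        P = np.array(self.transition, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError(f"transition must be square, got shape {P.shape}")
        if P.shape[0] < 2:
            raise ValueError("need at least the two boundary states")
        if np.any(P < -STOCHASTIC_ATOL) or np.any(P > 1 + STOCHASTIC_ATOL):
            raise ValueError("transition entries must lie in [0, 1]")
        rows = P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError(f"rows must sum to 1, got sums {rows}")
        if self.topology not in ("line", "complete", "custom"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology in ("line", "complete"):
            cols = P.sum(axis=0)
            if not np.allclose(cols, 1.0, atol=1e-9):
                raise ValueError(
                    f"{self.topology} chain must be doubly stochastic"
                )
        P.flags.writeable = False
        object.__setattr__(self, "transition", P)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkovChain):
            return NotImplemented
        return self.topology == other.topology and np.array_equal(
            self.transition, other.transition
        )

    def __hash__(self) -> int:
        return hash((self.topology, self.transition.shape))

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_interior(self) -> int:
        return self.n_states - 2

    @property
    def boundary_states(self) -> tuple[int, int]:
        """The two designated button states (left wall, right wall)."""
        return 0, self.n_states - 1

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n": self.n_interior,
            "topology_label": self.topology,
            "transition": self.transition.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MarkovChain":
        chain = cls(np.asarray(doc["transition"], dtype=float),
                    topology=doc.get("topology_label", "custom"))
        n = doc.get("n")
        if n is not None and int(n) != chain.n_interior:
            raise ValueError(
                f"declared n={n} inconsistent with matrix size {chain.n_states}"
            )
        return chain

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "MarkovChain":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "MarkovChain":
        """Load a custom chain from a header-free CSV, one row per state."""
        P = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(P, topology="custom")


@dataclass(frozen=True)
class SpectralSummary:
    """Eigen-spectrum of a chain and the derived relaxation timescales.

    ``eigenvalues`` are sorted by descending modulus with the unit
    eigenvalue first.  ``timescales[i-1] = -1/log|lambda_i|`` for ``i >= 1``
    (0 when ``lambda_i = 0``, the continuity limit).  ``relaxation_time``
    is the leading timescale tau_1.
    """

    eigenvalues: np.ndarray
    timescales: np.ndarray
    relaxation_time: float
    defective: bool = field(default=False)

    def to_dict(self) -> dict:
        return {
            "eigenvalues_abs": np.abs(self.eigenvalues).tolist(),
            "timescales": self.timescales.tolist(),
            "relaxation_time": self.relaxation_time,
            "defective": self.defective,
        }


def build_line_chain(n: int) -> MarkovChain:
    """Nearest-neighbour walk on ``{0, ..., n+1}`` with lazy-reflecting walls.

    Interior states move left or right with probability 1/2 each; each wall
    self-loops with probability 1/2 and steps inward with probability 1/2.
    The resulting matrix is symmetric tridiagonal, hence doubly stochastic.
    """
    n = _check_positive_int(n)
    m = n + 2
    P = np.zeros((m, m))
    idx = np.arange(m)
    P[idx[:-1], idx[1:]] = 0.5
    P[idx[1:], idx[:-1]] = 0.5
    P[0, 0] = 0.5
    P[m - 1, m - 1] = 0.5
    return MarkovChain(P, topology="line")


def build_complete_graph_chain(n: int) -> MarkovChain:
    """Walk on the complete graph: every entry equals ``1/(n+2)``.

    The one-step law from any state already equals the stationary
    distribution, so the chain mixes in a single step.
    """
    n = _check_positive_int(n)
    m = n + 2
    return MarkovChain(np.full((m, m), 1.0 / m), topology="complete")


def stationary_distribution(chain: MarkovChain) -> np.ndarray:
    """Stationary pmf ``pi`` with ``pi @ P = pi``.

    Computed from the left unit eigenvector (never by assuming uniformity),
    so for the built-ins it doubles as a correctness check of the
    doubly-stochastic construction.

    Raises
    ------
    DegenerateChainError
        If more than one eigenvalue lies within tolerance of 1.
    """
    P = chain.transition
    vals, vecs = np.linalg.eig(P.T)
    unit = np.flatnonzero(np.abs(vals - 1.0) < SPECTRAL_ATOL)
    if unit.size == 0:
        # row-stochastic matrices always have eigenvalue 1; loosen slightly
        unit = np.array([int(np.argmin(np.abs(vals - 1.0)))])
        if abs(vals[unit[0]] - 1.0) > 1e-8:
            raise ValueError("matrix has no unit eigenvalue; not stochastic")
    if unit.size > 1:
        raise DegenerateChainError(
            f"{unit.size} unit eigenvalues: stationary state is not unique"
        )
    v = np.real(vecs[:, unit[0]])
    v = v / v.sum()
    if np.any(v < -1e-10):
        raise DegenerateChainError("stationary vector has negative entries")
    pi = np.clip(v, 0.0, None)
    return pi / pi.sum()


def t_step_matrix(chain: MarkovChain, t: int) -> np.ndarray:
    """The t-step transition matrix ``P^(t) = P**t`` (identity at t=0).

    Negative ``t`` is rejected: backward time is handled by
    :func:`time_reversed_chain`, not by negative powers.
    """
    if isinstance(t, bool) or not isinstance(t, (int, np.integer)):
        raise ValueError(f"t must be an integer, got {t!r}")
    if t < 0:
        raise ValueError("t must be >= 0; use time_reversed_chain for backward time")
    return np.linalg.matrix_power(chain.transition, int(t))


def spectral_summary(chain: MarkovChain) -> SpectralSummary:
    """Eigenvalues sorted by descending modulus and timescales ``-1/log|l|``.

    Complex eigenvalues (possible for custom chains) enter through their
    modulus, which is what governs geometric convergence.  Defectiveness of
    the eigenvector basis is reported via the ``defective`` flag rather
    than silently ignored.
    """
    P = chain.transition
    vals, vecs = np.linalg.eig(P)
    order = np.argsort(-np.abs(vals), kind="stable")
    vals = vals[order]
    if abs(np.abs(vals[0]) - 1.0) > SPECTRAL_ATOL:
        raise ValueError("leading eigenvalue is not 1; matrix not stochastic")
    mods = np.abs(vals[1:])
    with np.errstate(divide="ignore"):
        taus = np.where(mods > SPECTRAL_ATOL, -1.0 / np.log(mods), 0.0)
    # |lambda| >= 1 beyond the leading one means no unique stationary state
    if np.any(mods > 1.0 - SPECTRAL_ATOL):
        raise DegenerateChainError(
            "sub-leading eigenvalue has modulus 1: no unique stationary state"
        )
    taus = np.maximum(taus, 0.0)
    defective = bool(np.linalg.matrix_rank(vecs, tol=1e-8) < P.shape[0])
    return SpectralSummary(
        eigenvalues=vals,
        timescales=taus,
        relaxation_time=float(taus[0]) if taus.size else 0.0,
        defective=defective,
    )


def time_reversed_chain(chain: MarkovChain) -> MarkovChain:
    """The time-reversed chain ``P-[i,j] = pi[j] * P[j,i] / pi[i]``.

    Shares the stationary distribution of the forward chain; for both
    built-in topologies the reversed matrix coincides with the forward one
    (the walks are reversible).
    """
    pi = stationary_distribution(chain)
    if np.any(pi <= STOCHASTIC_ATOL):
        raise ValueError("stationary distribution has zero mass on some state")
    P = chain.transition
    rev = (pi[None, :] * P.T) / pi[:, None]
    # renormalize away float round-off so the invariant holds at 1e-12
    rev = rev / rev.sum(axis=1, keepdims=True)
    return MarkovChain(rev, topology=chain.topology)
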