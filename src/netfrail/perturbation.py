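"""Environment-node perturbations of the master equation.

A set of altered nodes (the *query nodes* ``S``, ``|S| = Q``) is coupled to an
auxiliary *environment* node (extended index 0) that injects and absorbs
information with intensity ``epsilon``.  All non-trivial environment rates
are equal, the reverse rates are set symmetric (``pi_0k := pi_k0``), and
compensating diagonal terms keep both the perturbation matrix ``delta_L``
and the perturbed operator ``L0 + delta_L`` Laplacian (zero column sums).

Two conventions relate ``epsilon`` to the individual rates:

- ``rate="per_node"`` (default): ``pi_k0 = epsilon`` for every ``k`` in
  ``S``.  Under this convention the projected perturbation is a Gram form
  that grows monotonically with the query set, which makes the structural
  properties of the frailness measure exact: adding a query node never
  decreases frailness, the all-node query saturates the bound ``mu =
  lambda_F``, and no configuration can destabilize the walk below
  ``lambda_F``.
- ``rate="shared"``: ``pi_k0 = epsilon / Q``, splitting the intensity over
  the query nodes so that at ``epsilon = 1`` the environment column of the
  perturbed transition matrix is stochastic.  Convenient for fixed-budget
  comparisons, but frailness is then diluted by ``1/Q`` and the structural
  guarantees above hold only up to that factor.

In the extended ``(M+1) x (M+1)`` index convention the environment is slot 0
and the network nodes occupy slots ``1..M``.  ``L0`` embeds the unperturbed
Laplacian with the environment decoupled; its kernel is two-dimensional,
spanned by ``e0`` and ``v1 = (0, p_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network import NetworkError, TransitionSystem

__all__ = ["Perturbation", "build_perturbation", "build_delta_L", "extend_laplacian",
           "extended_basis"]


RateConvention = Literal["per_node", "shared"]


@dataclass(frozen=True)
class Perturbation:
    """A query-node set coupled to the environment at intensity ``epsilon``.

    ``delta_L = r * sum_{k in S} (e0 - e_k)(e0 - e_k)^T`` with the per-node
    rate ``r``; it is symmetric with support on ``{0} ∪ S`` only, and for
    ``Q = 1`` it is rank one — which is why single alterations can never
    destabilize the walk.
    """

    ts: TransitionSystem
    query_labels: tuple[str, ...]
    epsilon: float
    delta_L: np.ndarray  # (M+1) x (M+1)
    L0: np.ndarray       # (M+1) x (M+1)
    rate: RateConvention = "per_node"

    @property
    def Q(self) -> int:
        return len(self.query_labels)

    @property
    def query_indices_ext(self) -> np.ndarray:
        """Extended indices (1-based network slots) of the query nodes."""
        return np.array(self.ts.network.indices(self.query_labels)) + 1

    @property
    def e0(self) -> np.ndarray:
        e = np.zeros(self.ts.M + 1)
        e[0] = 1.0
        return e

    @property
    def v1(self) -> np.ndarray:
        """Extended zero mode ``(0, p_s)``."""
        return np.concatenate([[0.0], self.ts.p_s])

    def perturbed_operator(self) -> np.ndarray:
        """``L0 + delta_L``, the Laplacian of the environment-coupled walk."""
        return self.L0 + self.delta_L


def extend_laplacian(ts: TransitionSystem) -> np.ndarray:
    """Extend ``L`` with a decoupled environment node in slot 0."""
    m = ts.M
    L0 = np.zeros((m + 1, m + 1))
    L0[1:, 1:] = ts.L
    return L0


def build_perturbation(
    ts: TransitionSystem,
    query: "list[str] | tuple[str, ...] | set[str]",
    epsilon: float = 1.0,
    rate: RateConvention = "per_node",
) -> Perturbation:
    """Build ``delta_L`` for query set ``S`` at intensity ``epsilon``.

    Nonzero entries (extended indices, ``k`` ranging over ``S``; the per-node
    rate ``r`` is ``epsilon`` for ``rate="per_node"``, ``epsilon / Q`` for
    ``rate="shared"``):

    - ``delta_L[k, 0] = delta_L[0, k] = -r``   (exchange rates)
    - ``delta_L[0, 0] = Q * r``                (environment outflow)
    - ``delta_L[k, k] = r``                    (node outflow to environment)
    """
    labels = tuple(dict.fromkeys(str(q) for q in query))
    if not labels:
        raise NetworkError("query set must be nonempty")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    idx = np.array(ts.network.indices(labels)) + 1  # validates labels

    q = len(labels)
    m = ts.M
    r = epsilon if rate == "per_node" else epsilon / q
    if rate not in ("per_node", "shared"):
        raise ValueError(f"unknown rate convention: {rate!r}")
    dl = np.zeros((m + 1, m + 1))
    dl[idx, 0] = -r
    dl[0, idx] = -r
    dl[0, 0] = q * r
    dl[idx, idx] = r
    return Perturbation(ts=ts, query_labels=labels, epsilon=float(epsilon),
                        delta_L=dl, L0=extend_laplacian(ts), rate=rate)


# alias named after the matrix the operation builds
build_delta_L = build_perturbation


def extended_basis(ts: TransitionSystem, g00: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Extended decomposition basis and the extended metric diagonal.

    Returns ``(V, g_ext)`` where column 0 of ``V`` is ``e0`` itself (the
    stationary ansatz fixes its coefficient to exactly 1, so it is kept
    unnormalized; ``<e0, e0>_G = g00``), column 1 is ``(0, p_s)`` and columns
    ``2..M`` are the extended non-zero modes, all G-orthonormal.  The
    environment metric weight ``g00`` defaults to 1 and only scales row 0 of
    projected quantities, which the iterative scheme never uses — solver
    results are insensitive to its (positive) value.
    """
    if g00 <= 0:
        raise ValueError("g00 must be positive")
    m = ts.M
    V = np.zeros((m + 1, m + 1))
    V[0, 0] = 1.0
    V[1:, 1:] = ts.eigvecs
    g_ext = np.concatenate([[g00], ts.g])
    return V, g_ext
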