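"""Network frailness and the network-efficiency comparison.

Frailness quantifies how strongly a query-node configuration destabilizes the
information flow.  It is read off the convergence condition of the
perturbative scheme: with the transformed perturbation

    dLprime_kj = dLbar_kj - (dLbar_k1 / dLbar_11) * dLbar_1j

(the detailed-balance reduction that eliminates the zero mode), the frailness
of a query configuration is

    rho = ||dLprime_epsilon|| / lambda_F

with the spectral norm (largest singular value) of the full extended matrix
``dLprime`` — environment row and column included.  Exact structural
properties:

- ``rho = 0`` iff ``Q = 1`` or ``epsilon = 0`` (the transform annihilates
  rank-one forms: a single alteration cannot macroscopically perturb the
  flow);
- ``rho`` is linear in ``epsilon``;
- adding a query node never decreases ``rho`` (monotonicity; provable via
  Schur-complement monotonicity on the self-adjoint part and hard-asserted
  by exhaustive tests for the full matrix);
- ``rho >= epsilon / lambda_F`` for every multi-node query — at intensity
  ``lambda_F`` every co-occurring configuration is already flagged critical
  by the bound, so ``mu = epsilon / rho`` is a conservative (sufficient
  convergence) threshold.

The scheme's exact stability boundary is the eigenvalue-weighted variant
``norm="operator"``, ``specrad(Lambda^{-1} dLprime)`` on the non-zero modes:
it satisfies ``lambda_F <= mu_op``, with equality reached by the all-node
query, and the spectral and operator forms coincide when the non-zero
spectrum is flat (complete graphs).  Low-degree (marginal) query nodes carry
metric weight ``1 / p_s = 2E / deg``, which is why configurations combining
central and marginal nodes score as the most frail under the default norm.

The classical comparison point is the global network efficiency (mean inverse
shortest-path length); ``NNE = NE' / NE`` after deleting the query nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .network import Network, TransitionSystem
from .perturbation import build_perturbation
from .solver import ProjectedPerturbation, project_perturbation

__all__ = [
    "FrailnessResult",
    "EfficiencyResult",
    "delta_L_prime",
    "frailness",
    "network_efficiency",
]

NormKind = Literal["operator", "spectral", "frobenius"]


def delta_L_prime(proj: ProjectedPerturbation) -> np.ndarray:
    """Transformed perturbation ``dLprime`` (row and column 1 vanish identically).

    For a single query node ``dLbar`` is the rank-one bilinear form
    ``a_k b_j``, which the transform annihilates identically — returned as an
    exact zero matrix rather than leaving the cancellation to roundoff.
    """
    bar = proj.bar
    if proj.Q == 1:
        return np.zeros_like(bar)
    pivot = bar[1, 1]
    if proj.epsilon > 0 and abs(pivot) < 1e-14:
        raise ValueError(
            "inconsistent perturbation: dLbar_11 vanishes at epsilon > 0 "
            "(no query mass on the stationary state)"
        )
    if pivot == 0.0:
        return np.zeros_like(bar)
    prime = bar - np.outer(bar[:, 1], bar[1, :]) / pivot
    prime[1, :] = 0.0
    prime[:, 1] = 0.0
    return prime


def _rho(prime: np.ndarray, ts, norm: NormKind) -> float:
    """Frailness magnitude of the transformed perturbation.

    ``spectral`` (default): largest singular value of the full extended
    ``dLprime`` over ``lambda_F``.  ``operator``: spectral radius of
    ``Lambda^{-1} dLprime`` on the non-zero-mode block — the scheme's exact
    stability radius.  ``frobenius``: Frobenius analogue of ``spectral``.
    """
    if norm == "operator":
        lam = ts.eigvals[1:]
        block = prime[2:, 2:] / lam[:, None]
        if not block.size:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(block))))
    if norm == "spectral":
        return float(np.linalg.norm(prime, 2)) / ts.lambda_F
    if norm == "frobenius":
        return float(np.linalg.norm(prime, "fro")) / ts.lambda_F
    raise ValueError(f"unknown norm: {norm!r}")


@dataclass(frozen=True)
class FrailnessResult:
    """Frailness ``rho`` of a query configuration and its critical intensity."""

    rho: float
    delta_L_prime: np.ndarray
    mu_analytic: float       # epsilon / rho; +inf when rho == 0
    lambda_F: float
    epsilon: float
    query_labels: tuple[str, ...]
    norm: NormKind = "spectral"

    @property
    def Q(self) -> int:
        return len(self.query_labels)


def frailness(
    ts: TransitionSystem,
    query: Sequence[str],
    epsilon: float = 1.0,
    norm: NormKind = "spectral",
) -> FrailnessResult:
    """Frailness ``rho = ||dLprime_epsilon|| / lambda_F`` of a query set.

    Small ``rho`` marks a resilient configuration, large ``rho`` a frail one.
    The default is the spectral norm of the full transformed perturbation
    (monotone in the query set, sensitive to marginal nodes);
    ``norm="operator"`` gives the scheme's exact stability radius (equal to
    the default on flat-spectrum networks), ``norm="frobenius"`` a
    sensitivity variant.
    """
    pert = build_perturbation(ts, query, epsilon)
    prime = delta_L_prime(project_perturbation(pert))
    rho = _rho(prime, ts, norm)
    mu = epsilon / rho if rho > 0 else np.inf
    return FrailnessResult(
        rho=float(rho),
        delta_L_prime=prime,
        mu_analytic=float(mu),
        lambda_F=ts.lambda_F,
        epsilon=float(epsilon),
        query_labels=pert.query_labels,
        norm=norm,
    )


@dataclass(frozen=True)
class EfficiencyResult:
    """Global network efficiency before/after removing the query nodes."""

    NE: float
    NE_prime: float
    NNE: float
    m_star: int  # number of removed (query) nodes


def network_efficiency(network: Network, removed: Sequence[str] = ()) -> EfficiencyResult:
    """``NE`` of the intact network, ``NE'`` of the survivor-induced subgraph, and their ratio.

    ``NE = (1 / (M (M-1))) * sum_{i != j} 1 / d(i, j)`` with disconnected pairs
    contributing zero; ``NE'`` uses the surviving subgraph's own size
    normalization.  Fewer than two survivors give ``NE' = 0`` with a warning.
    """
    removed = tuple(dict.fromkeys(str(r) for r in removed))
    network.indices(removed)  # validate labels
    g = network.to_networkx()
    ne = nx.global_efficiency(g)
    survivors = [n for n in network.labels if n not in removed]
    if len(survivors) < 2:
        warnings.warn("fewer than 2 surviving nodes; NE' set to 0", stacklevel=2)
        ne_prime = 0.0
    else:
        ne_prime = nx.global_efficiency(g.subgraph(survivors))
    return EfficiencyResult(
        NE=float(ne),
        NE_prime=float(ne_prime),
        NNE=float(ne_prime / ne) if ne > 0 else 0.0,
        m_star=len(removed),
    )
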