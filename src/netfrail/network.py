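"""Master-equation operators on undirected, unweighted networks.

The exchange of an ideal substance ("information") between the nodes of a
connected network is modelled as a continuous-time random walk,

    dp/dt + L p = 0,        L = D - Pi,

where ``Pi`` is the column-stochastic transition matrix obtained by
column-normalizing the adjacency matrix and ``D`` is the diagonal matrix of
column outflows (the identity, once ``Pi`` is column-stochastic).  The
stationary state ``p_s`` spans the kernel of ``L``; for an undirected walk it
is the degree distribution, ``(p_s)_k = deg(k) / (2 |E|)``.

The walk satisfies detailed balance, so ``L`` is self-adjoint under the scalar
product ``<u, w> = sum_k u_k g_k w_k`` with the reversible-chain metric
``g_k = 1 / (p_s)_k``.  This yields a real spectrum ``0 = lambda_1 <
lambda_2 <= ... <= lambda_M`` and a G-orthonormal eigenbasis; ``lambda_2`` is
the Fiedler number ``lambda_F`` of the walk Laplacian.  Every downstream
quantity (perturbation projections, frailness, critical thresholds) is
computed in this basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

__all__ = [
    "Network",
    "TransitionSystem",
    "NetworkError",
    "column_normalize",
    "build_transition_system",
    "check_self_adjoint",
    "is_self_adjoint",
]


class NetworkError(ValueError):
    """Raised for invalid network structure (asymmetry, isolation, disconnection)."""


@dataclass(frozen=True)
class Network:
    """An undirected, unweighted, connected network.

    Parameters
    ----------
    labels
        Ordered node identifiers (strings).
    adjacency
        Symmetric binary matrix with zero diagonal, shape ``(M, M)``.
    """

    labels: tuple[str, ...]
    adjacency: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        m = len(self.labels)
        if m < 2:
            raise NetworkError("a network needs at least 2 nodes")
        if len(set(self.labels)) != m:
            raise NetworkError("duplicate node labels")
        if a.shape != (m, m):
            raise NetworkError(f"adjacency shape {a.shape} != ({m}, {m})")
        if not np.array_equal(a, a.T):
            raise NetworkError("adjacency must be symmetric (undirected network)")
        if np.any(np.diag(a) != 0):
            raise NetworkError("adjacency must have a zero diagonal")
        if not np.isin(a, (0.0, 1.0)).all():
            raise NetworkError("adjacency must be binary (unweighted network)")
        deg = a.sum(axis=0)
        if np.any(deg == 0):
            isolated = [self.labels[i] for i in np.flatnonzero(deg == 0)]
            raise NetworkError(f"isolated node(s): {isolated}")
        n_comp = scipy.sparse.csgraph.connected_components(
            scipy.sparse.csr_matrix(a), directed=False, return_labels=False
        )
        if n_comp != 1:
            raise NetworkError(f"network is disconnected ({n_comp} components)")
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    # -- basic accessors ---------------------------------------------------
    @property
    def M(self) -> int:
        """Node count."""
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise NetworkError(f"unknown node label: {label!r}") from None

    def indices(self, labels: Iterable[str]) -> list[int]:
        return [self.index(l) for l in labels]

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "Network":
        """Build from an iterable of undirected edges (duplicates/reversals deduplicated)."""
        seen: dict[str, None] = {}
        pairs: set[frozenset[str]] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                continue  # self-loops are meaningless for the walk
            seen.setdefault(u)
            seen.setdefault(v)
            pairs.add(frozenset((u, v)))
        labels = tuple(seen)
        idx = {l: i for i, l in enumerate(labels)}
        a = np.zeros((len(labels), len(labels)))
        for pair in pairs:
            u, v = tuple(pair)
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
        return cls(labels, a)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        labels = tuple(str(n) for n in g.nodes)
        a = nx.to_numpy_array(g, nodelist=list(g.nodes), weight=None)
        np.fill_diagonal(a, 0.0)
        return cls(labels, (a > 0).astype(float))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        ii, jj = np.nonzero(np.triu(self.adjacency))
        g.add_edges_from((self.labels[i], self.labels[j]) for i, j in zip(ii, jj))
        return g

    def subnetwork(self, keep: Sequence[str]) -> "Network":
        """Induced subnetwork on ``keep`` (must remain connected and have >= 2 nodes)."""
        idx = self.indices(keep)
        return Network(tuple(self.labels[i] for i in idx), self.adjacency[np.ix_(idx, idx)])


def column_normalize(network: Network) -> np.ndarray:
    """Column-stochastic transition matrix ``Pi`` with ``pi_kj = A_kj / deg(j)``."""
    deg = network.degrees()
    if np.any(deg == 0):  # unreachable for a valid Network; kept for raw callers
        raise NetworkError("isolated node: zero-degree column cannot be normalized")
    return network.adjacency / deg[np.newaxis, :]


def is_self_adjoint(L: np.ndarray, g: np.ndarray, tol: float = 1e-8) -> bool:
    """True iff ``L`` is self-adjoint under ``<u,w> = sum u_k g_k w_k``.

    Equivalent to symmetry of ``diag(g) @ L``, which for a walk Laplacian is the
    detailed-balance condition of the stationary state.
    """
    gl = np.asarray(g)[:, None] * np.asarray(L)
    return bool(np.max(np.abs(gl - gl.T)) <= tol)


@dataclass(frozen=True)
class TransitionSystem:
    """The master-equation operator of a network, spectrally decomposed.

    Attributes
    ----------
    network : Network
    pi : ndarray
        Column-stochastic transition matrix.
    L : ndarray
        Walk Laplacian ``I - Pi``.
    p_s : ndarray
        Stationary distribution (degree law), sums to 1.
    g : ndarray
        Diagonal of the detailed-balance metric, ``g_k = 1/(p_s)_k``.
    eigvals : ndarray
        Ascending eigenvalues, ``eigvals[0] = 0``.
    eigvecs : ndarray
        Columns ``v_k``, G-orthonormal; ``eigvecs[:, 0]`` is ``p_s`` itself
        (the zero mode is stored unnormalized in the Euclidean sense, but note
        ``<p_s, p_s>_G = sum p_s = 1`` so it is G-orthonormal as well).
    lambda_F : float
        Fiedler number, the smallest non-zero eigenvalue.
    """

    network: Network
    pi: np.ndarray
    L: np.ndarray
    p_s: np.ndarray
    g: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    lambda_F: float

    @property
    def M(self) -> int:
        return self.network.M

    @property
    def D(self) -> np.ndarray:
        """Diagonal matrix of column outflows (identity for a stochastic ``Pi``)."""
        return np.diag(self.pi.sum(axis=0))


def build_transition_system(
    network: Network,
    *,
    kernel_tol: float = 1e-10,
    sym_tol: float = 1e-8,
) -> TransitionSystem:
    """Build ``Pi``, ``L``, the stationary state, the metric and the eigenbasis.

    The eigenproblem is solved through the symmetrizing similarity
    ``B = G^{1/2} L G^{-1/2}`` (symmetric by detailed balance), so the spectrum
    is real and the recovered ``v_k = G^{-1/2} u_k`` are G-orthonormal even
    inside degenerate eigenspaces.

    Raises
    ------
    NetworkError
        If the network is disconnected or the detailed-balance symmetry check
        fails beyond ``sym_tol``.
    """
    pi = column_normalize(network)
    m = network.M
    L = np.eye(m) - pi

    deg = network.degrees()
    p_s = deg / deg.sum()
    g = 1.0 / p_s

    if not is_self_adjoint(L, g, tol=sym_tol):
        raise NetworkError("Laplacian is not self-adjoint in the detailed-balance metric")

    sqrt_p = np.sqrt(p_s)
    B = L * (sqrt_p[np.newaxis, :] / sqrt_p[:, None])  # G^{1/2} L G^{-1/2}
    B = 0.5 * (B + B.T)  # symmetrize roundoff
    eigvals, U = scipy.linalg.eigh(B)

    n_zero = int(np.sum(np.abs(eigvals) < kernel_tol))
    if n_zero != 1:
        raise NetworkError(
            f"expected a simple zero eigenvalue, found {n_zero} (disconnected network?)"
        )
    eigvals = eigvals.copy()
    eigvals[0] = 0.0

    V = sqrt_p[:, None] * U  # v_k = G^{-1/2} u_k, G-orthonormal
    # Store the zero mode as p_s itself (it is G-normalized: <p_s,p_s>_G = 1).
    V[:, 0] = p_s

    return TransitionSystem(
        network=network,
        pi=pi,
        L=L,
        p_s=p_s,
        g=g,
        eigvals=eigvals,
        eigvecs=V,
        lambda_F=float(eigvals[1]),
    )


def check_self_adjoint(ts: TransitionSystem, tol: float = 1e-8) -> bool:
    """Verify ``u . (L w) = w . (L u)`` under the system's metric (Boolean, never raises)."""
    return is_self_adjoint(ts.L, ts.g, tol=tol)
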