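"""Cohort-level frailness analysis of mutation data on pathway subnetworks.

Pipeline: induce each pathway gene set on the protein-protein interaction
(PPI) network and keep the largest connected component (size-filtered);
interpret each sample's mutated genes on that subnetwork as the query set of
a perturbed master equation and score its frailness ``rho``; aggregate into
gene-pair co-occurrence tables, the Gene Frailness Index, and a
hypergeometric test for the enrichment of marginal (degree-1) mutations
among the least resilient samples.

Naming follows the field: ``W`` a pathway gene network, ``m*`` the number of
co-occurring mutations (per sample: its mutated genes on ``W``; per gene:
the samples where it is mutated together with at least one other gene of
``W``), ``sigma = m*/n_samples`` the co-occurrence fraction, ``rho_tilde``
the median frailness of the samples carrying a gene, and ``GFI = (sigma,
rho_tilde / max rho_tilde)`` the two-component gene score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .frailness import frailness
from .network import Network, build_transition_system
from .synthetic import MutationMatrix

__all__ = [
    "PathwayNetwork",
    "EnrichmentResult",
    "CohortResult",
    "extract_pathway_networks",
    "sample_frailness",
    "pair_cooccurrence",
    "candidate_pair_count",
    "gene_frailness_index",
    "marginal_enrichment",
    "analyze_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayNetwork:
    """Largest connected component of a pathway gene set induced on the PPI."""

    name: str
    member_genes: frozenset[str]
    network: Network

    @property
    def size(self) -> int:
        return self.network.M

    def transition_system(self):
        return build_transition_system(self.network)


def extract_pathway_networks(
    ppi: Network,
    gene_sets: Mapping[str, Iterable[str]],
    min_size: int = 10,
    max_size: int = 500,
    exclude: Sequence[str] = (),
) -> list[PathwayNetwork]:
    """Induce each gene set on the PPI; keep largest components within size bounds.

    ``exclude`` holds case-insensitive substrings of pathway names to drop
    (e.g. disease pathways whose membership is circular for the analysis).
    Pathways with no usable component are dropped silently (logged).
    """
    g = ppi.to_networkx()
    out: list[PathwayNetwork] = []
    patterns = [p.lower() for p in exclude]
    for name, genes in gene_sets.items():
        if any(p in name.lower() for p in patterns):
            logger.info("pathway %s excluded by name pattern", name)
            continue
        members = {str(x) for x in genes} & set(ppi.labels)
        if not members:
            logger.info("pathway %s has no genes on the PPI; dropped", name)
            continue
        sub = g.subgraph(members)
        component = max(nx.connected_components(sub), key=len)
        if not (min_size <= len(component) <= max_size):
            logger.info("pathway %s component size %d outside [%d, %d]; dropped",
                        name, len(component), min_size, max_size)
            continue
        ordered = [l for l in ppi.labels if l in component]
        out.append(PathwayNetwork(name=name, member_genes=frozenset(members),
                                  network=ppi.subnetwork(ordered)))
    return out


def sample_frailness(
    pathway: PathwayNetwork,
    muts: MutationMatrix,
    epsilon: float = 1.0,
    ts=None,
) -> pd.DataFrame:
    """Per-sample frailness of the mutation configurations on one gene network.

    Samples with no mutated gene on the network are excluded; samples with a
    single mutated gene are recorded with ``rho = 0`` and ``null_frailness =
    True`` (one alteration cannot macroscopically alter the information
    flow).  Columns: ``sample``, ``m_star``, ``rho``, ``null_frailness``,
    ``query_genes`` (semicolon-joined).
    """
    ts = ts if ts is not None else pathway.transition_system()
    nodes = set(pathway.network.labels)
    rows = []
    mat = muts.a.loc[[g for g in muts.a.index if g in nodes]]
    for sample in mat.columns:
        genes = sorted(mat.index[mat[sample] == 1])
        if not genes:
            continue
        if len(genes) >= 2:
            rho = frailness(ts, genes, epsilon=epsilon).rho
            null = False
        else:
            rho, null = 0.0, True
        rows.append((str(sample), len(genes), rho, null, ";".join(genes)))
    return pd.DataFrame(rows, columns=["sample", "m_star", "rho",
                                       "null_frailness", "query_genes"])


def candidate_pair_count(pathway: PathwayNetwork) -> int:
    """Number of possible unordered gene pairs on the network, ``G(G-1)/2``."""
    g = pathway.size
    return g * (g - 1) // 2


def pair_cooccurrence(
    pathway: PathwayNetwork,
    muts: MutationMatrix,
    sample_rho: pd.DataFrame,
) -> pd.DataFrame:
    """Mean frailness per co-mutated gene pair.

    For every unordered pair of network genes simultaneously mutated in at
    least one sample: the number of such samples and the mean ``rho`` across
    them (samples with additional mutations beyond the pair are included).
    Pairs never co-mutated are absent.
    """
    stats: dict[tuple[str, str], list[float]] = {}
    for _, row in sample_rho.iterrows():
        genes = row.query_genes.split(";") if row.query_genes else []
        for a, b in itertools.combinations(sorted(genes), 2):
            stats.setdefault((a, b), []).append(row.rho)
    rows = [(a, b, len(v), float(np.mean(v))) for (a, b), v in sorted(stats.items())]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_samples", "mean_rho"])


def gene_frailness_index(
    pathway: PathwayNetwork,
    muts: MutationMatrix,
    sample_rho: pd.DataFrame,
    n_samples: int | None = None,
    include_null: bool = False,
) -> pd.DataFrame:
    """Gene Frailness Index table for one gene network.

    Per gene ``g``: ``m_star`` (samples where ``g`` is mutated together with
    at least one other network gene), ``sigma = m_star / n_samples``,
    ``rho_tilde`` (median ``rho`` over the samples carrying ``g``, restricted
    to non-null-frailness samples unless ``include_null``), and ``rho_prime =
    rho_tilde / max_i rho_tilde`` — normalized per network so the index is
    comparable across gene networks.  ``n_samples`` defaults to the full
    cohort size.
    """
    n_samples = muts.n_samples if n_samples is None else n_samples
    co = sample_rho[sample_rho.m_star >= 2]
    pool = co if not include_null else sample_rho
    m_star: dict[str, int] = {}
    rhos: dict[str, list[float]] = {}
    for _, row in co.iterrows():
        for gene in row.query_genes.split(";"):
            m_star[gene] = m_star.get(gene, 0) + 1
    for _, row in pool.iterrows():
        for gene in row.query_genes.split(";"):
            rhos.setdefault(gene, []).append(row.rho)
    genes = sorted(m_star)
    rho_tilde = {g: float(np.median(rhos.get(g, [0.0]))) for g in genes}
    top = max(rho_tilde.values(), default=0.0)
    if top <= 0:
        logger.info("all median frailness values are zero on %s; rho_prime set to 0",
                    pathway.name)
    rows = [
        (g, m_star[g], m_star[g] / n_samples, rho_tilde[g],
         rho_tilde[g] / top if top > 0 else 0.0)
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene", "m_star", "sigma",
                                       "rho_tilde", "rho_prime"])


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric test for marginal mutations among the least resilient samples."""

    pathway: str
    p_value: float | None
    N: int          # samples with non-null frailness
    K: int          # of those, samples carrying >= 1 marginal mutation
    n: int          # top samples drawn (least resilient)
    x: int          # marginal-mutation carriers among the top samples
    status: str     # "ok" | "skipped_min_patients"


def marginal_enrichment(
    pathway: PathwayNetwork,
    sample_rho: pd.DataFrame,
    top_n: int = 10,
    min_patients: int = 20,
    marginal_degree: int = 1,
) -> EnrichmentResult:
    """Upper-tail hypergeometric test ``P(X >= x)``.

    Population: the samples with non-null frailness on the network.  Success:
    the sample's query set contains at least one gene whose degree within the
    gene network is exactly ``marginal_degree``.  Draw: the ``top_n`` samples
    with the highest ``rho`` ("least resilient"; ties broken by sample label
    for determinism).  Networks with fewer than ``min_patients`` non-null
    samples are skipped.
    """
    co = sample_rho[~sample_rho.null_frailness]
    N = len(co)
    if N < min_patients:
        return EnrichmentResult(pathway.name, None, N, 0, 0, 0,
                                "skipped_min_patients")
    degrees = dict(zip(pathway.network.labels, pathway.network.degrees()))
    marginal = {g for g, d in degrees.items() if d == marginal_degree}
    has_marginal = co.query_genes.map(
        lambda s: bool(set(s.split(";")) & marginal))
    K = int(has_marginal.sum())
    ranked = co.assign(_m=has_marginal).sort_values(
        ["rho", "sample"], ascending=[False, True], kind="stable")
    n = min(top_n, N)
    x = int(ranked._m.iloc[:n].sum())
    p = float(hypergeom.sf(x - 1, N, K, n))
    return EnrichmentResult(pathway.name, p, N, K, n, x, "ok")


@dataclass
class CohortResult:
    """All per-pathway tables of a cohort run plus the summary records."""

    pathways: list[PathwayNetwork]
    sample_rho: dict[str, pd.DataFrame]
    pair_tables: dict[str, pd.DataFrame]
    gfi: dict[str, pd.DataFrame]
    enrichment: dict[str, EnrichmentResult]
    summary: pd.DataFrame = field(default=None)


def analyze_cohort(
    ppi: Network,
    gene_sets: Mapping[str, Iterable[str]],
    muts: MutationMatrix,
    min_size: int = 10,
    max_size: int = 500,
    exclude: Sequence[str] = (),
    epsilon: float = 1.0,
    top_n: int = 10,
    min_patients: int = 20,
    marginal_degree: int = 1,
) -> CohortResult:
    """End-to-end cohort analysis over all eligible pathway networks."""
    pathways = extract_pathway_networks(ppi, gene_sets, min_size=min_size,
                                        max_size=max_size, exclude=exclude)
    res = CohortResult(pathways=pathways, sample_rho={}, pair_tables={},
                       gfi={}, enrichment={})
    summary_rows = []
    for pw in pathways:
        ts = pw.transition_system()
        sr = sample_frailness(pw, muts, epsilon=epsilon, ts=ts)
        res.sample_rho[pw.name] = sr
        res.pair_tables[pw.name] = pair_cooccurrence(pw, muts, sr)
        non_null = int((~sr.null_frailness).sum()) if len(sr) else 0
        if non_null:
            res.gfi[pw.name] = gene_frailness_index(pw, muts, sr)
        enr = marginal_enrichment(pw, sr, top_n=top_n,
                                  min_patients=min_patients,
                                  marginal_degree=marginal_degree)
        res.enrichment[pw.name] = enr
        logger.info("pathway %s: size=%d samples_with_signal=%d",
                    pw.name, pw.size, non_null)
        summary_rows.append((pw.name, pw.size, len(sr), non_null,
                             enr.p_value if enr.p_value is not None else np.nan,
                             enr.status))
    res.summary = pd.DataFrame(
        summary_rows,
        columns=["pathway", "size", "samples_hit", "samples_non_null",
                 "enrichment_p", "enrichment_status"],
    )
    return res
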