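"""Component topology profiling and family-wise regression comparison.

For every per-orthogroup component a set of topology parameters is
computed (path lengths, centralities, strength, Burt's constraint, ...).
Per family, each parameter is regressed on the component node count by
ordinary least squares; the coefficient distributions are obtained by
bootstrap resampling of components; and the two families are compared per
parameter and coefficient with Welch's unequal-variance t-test
(Satterthwaite degrees of freedom) followed by Benjamini-Hochberg FDR
adjustment, applied separately within the slope family and within the
intercept family.

Path-based metrics run on the binarized graph: edge weights encode
evidence support, not distance, and treating a well-supported edge
(weight 1.0) as a longer path than a weakly supported one (0.25) would
invert their meaning. Strength, Burt's constraint and the eigenvector
quantities use the weights. ``weighted_paths=True`` toggles the
alternative convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PARAMETERS",
    "TopologyRecord",
    "CoefficientComparison",
    "component_topology",
    "fit_family_regressions",
    "bootstrap_coefficients",
    "compare_coefficients",
]

#: The topology parameters computed per component.
PARAMETERS = (
    "mean_distance",
    "diameter",
    "degree_norm_min",
    "degree_norm_median",
    "degree_norm_max",
    "closeness_norm_min",
    "closeness_norm_max",
    "betweenness_norm_max",
    "edge_betweenness_max",
    "eccentricity_min",
    "eccentricity_max",
    "eigen_centrality_min",
    "eigen_centrality_median",
    "eigen_centrality_max",
    "eigen_value",
    "strength_min",
    "strength_median",
    "neighborhood_size_max",
    "constraint_median",
    "distances_median",
    "distances_max",
)


@dataclass
class TopologyRecord:
    """One component's node count and named topology-parameter values."""

    component_id: str
    family: str
    n_nodes: int
    n_edges: int
    parameters: dict[str, float] = field(default_factory=dict)


@dataclass
class CoefficientComparison:
    """Welch comparison of one regression coefficient between families."""

    parameter: str
    coefficient: str  # "intercept" or "slope"
    t_statistic: float
    welch_df: float
    p_value: float
    adj_p_value: float = float("nan")
    significant: bool = False


def component_topology(
    component: nx.Graph,
    component_id: str = "",
    family: str = "",
    weighted_paths: bool = False,
    neighborhood_order: int = 1,
) -> TopologyRecord:
    """Compute the full topology-parameter set for one connected component.

    Requires a connected graph with at least 3 nodes. Normalizations:
    degree by ``n - 1``; closeness as ``(n - 1) / sum(distances)``;
    betweenness by ``(n - 1)(n - 2) / 2``; eigenvector centrality scaled
    to maximum 1, with ``eigen_value`` the leading eigenvalue of the
    weighted adjacency. ``neighborhood_size`` counts the order-1
    neighborhood including the node itself.
    """
    n = component.number_of_nodes()
    if n < 3:
        raise ValueError("component must have at least 3 nodes")
    if not nx.is_connected(component):
        raise ValueError("component must be connected")
    nodes = sorted(component.nodes)
    path_weight = "weight" if weighted_paths else None

    lengths = dict(
        nx.all_pairs_dijkstra_path_length(component, weight=path_weight)
        if weighted_paths
        else nx.all_pairs_shortest_path_length(component)
    )
    dist_pairs = [
        lengths[a][b]
        for i, a in enumerate(nodes)
        for b in nodes[i + 1:]
    ]
    dist_pairs = np.asarray(dist_pairs, dtype=float)
    eccentricity = np.array(
        [max(lengths[a].values()) for a in nodes], dtype=float
    )
    closeness = np.array(
        [(n - 1) / sum(lengths[a].values()) for a in nodes], dtype=float
    )
    degree = np.array([component.degree(a) for a in nodes], dtype=float)
    betweenness = nx.betweenness_centrality(
        component, normalized=True, weight=path_weight
    )
    edge_betweenness = nx.edge_betweenness_centrality(
        component, normalized=True, weight=path_weight
    )

    adjacency = nx.to_numpy_array(component, nodelist=nodes, weight="weight")
    eigvals, eigvecs = np.linalg.eigh(adjacency)
    lead = int(np.argmax(eigvals))
    vec = np.abs(eigvecs[:, lead])
    vec = vec / vec.max()
    strength = adjacency.sum(axis=1)
    constraint = nx.constraint(component, weight="weight")
    constraint_vals = np.array(
        [constraint[a] for a in nodes], dtype=float
    )

    params = {
        "mean_distance": float(dist_pairs.mean()),
        "diameter": float(dist_pairs.max()),
        "degree_norm_min": float(degree.min() / (n - 1)),
        "degree_norm_median": float(np.median(degree) / (n - 1)),
        "degree_norm_max": float(degree.max() / (n - 1)),
        "closeness_norm_min": float(closeness.min()),
        "closeness_norm_max": float(closeness.max()),
        "betweenness_norm_max": float(max(betweenness.values())),
        "edge_betweenness_max": float(max(edge_betweenness.values())),
        "eccentricity_min": float(eccentricity.min()),
        "eccentricity_max": float(eccentricity.max()),
        "eigen_centrality_min": float(vec.min()),
        "eigen_centrality_median": float(np.median(vec)),
        "eigen_centrality_max": float(vec.max()),
        "eigen_value": float(eigvals[lead]),
        "strength_min": float(strength.min()),
        "strength_median": float(np.median(strength)),
        "neighborhood_size_max": float(
            max(
                len(nx.single_source_shortest_path_length(
                    component, a, cutoff=neighborhood_order
                ))
                for a in nodes
            )
        ),
        "constraint_median": float(np.nanmedian(constraint_vals)),
        "distances_median": float(np.median(dist_pairs)),
        "distances_max": float(dist_pairs.max()),
    }
    return TopologyRecord(
        component_id=component_id,
        family=family,
        n_nodes=n,
        n_edges=component.number_of_edges(),
        parameters=params,
    )


def _design(records: Sequence[TopologyRecord], parameter: str):
    xy = [
        (r.n_nodes, r.parameters[parameter])
        for r in records
        if np.isfinite(r.parameters.get(parameter, np.nan))
    ]
    skipped = len(records) - len(xy)
    if skipped:
        logger.info(
            "%s: skipped %d records with undefined values", parameter, skipped
        )
    x = np.array([p[0] for p in xy], dtype=float)
    y = np.array([p[1] for p in xy], dtype=float)
    return x, y


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all node counts identical")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def fit_family_regressions(
    records: Sequence[TopologyRecord],
    family: str | None = None,
) -> dict[str, tuple[float, float]]:
    """OLS of each topology parameter on component node count.

    Returns ``{parameter: (intercept, slope)}``. Requires at least 3
    components; records with an undefined parameter value are skipped with
    a logged count.
    """
    if family is not None:
        records = [r for r in records if r.family == family]
    if len(records) < 3:
        raise ValueError("need at least 3 components to fit regressions")
    out: dict[str, tuple[float, float]] = {}
    for parameter in PARAMETERS:
        x, y = _design(records, parameter)
        if len(x) < 3:
            continue
        out[parameter] = _ols(x, y)
    return out


def bootstrap_coefficients(
    records: Sequence[TopologyRecord],
    family: str | None = None,
    n_boot: int | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
) -> dict[str, np.ndarray]:
    """Bootstrap the OLS coefficients by resampling components.

    Each replicate resamples the family's components with replacement (same
    size) and refits every parameter's regression. ``n_boot`` defaults to
    the component count of the family, matching the convention of one
    resampling per data point. Degenerate replicates (all resampled node
    counts identical) are redrawn, up to ``max_retries`` times each.

    Returns ``{parameter: array of shape (n_boot, 2)}`` with columns
    (intercept, slope).
    """
    if family is not None:
        records = [r for r in records if r.family == family]
    m = len(records)
    if m < 3:
        raise ValueError("need at least 3 components to bootstrap")
    if n_boot is None:
        n_boot = m
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    node_counts = np.array([r.n_nodes for r in records], dtype=float)
    if np.ptp(node_counts) == 0:
        raise ValueError("degenerate design: all node counts identical")

    samples: dict[str, list[tuple[float, float]]] = {
        p: [] for p in PARAMETERS
    }
    redrawn = 0
    for _ in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(m, size=m)
            if np.ptp(node_counts[idx]) > 0:
                break
            redrawn += 1
        else:
            raise ValueError("persistent degenerate bootstrap replicates")
        replicate = [records[i] for i in idx]
        for parameter in PARAMETERS:
            x, y = _design(replicate, parameter)
            if len(x) < 2 or np.ptp(x) == 0:
                samples[parameter].append((np.nan, np.nan))
            else:
                samples[parameter].append(_ols(x, y))
    if redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", redrawn)
    return {p: np.array(v, dtype=float) for p, v in samples.items()}


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan, np.nan
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        # t is 0/0: undefined, reported as such
        return np.nan, np.nan, np.nan
    res = stats.ttest_ind(a, b, equal_var=False)
    df = getattr(res, "df", None)
    if df is None:
        na, nb = len(a), len(b)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    return float(res.statistic), float(df), float(res.pvalue)


def compare_coefficients(
    samples_a: Mapping[str, np.ndarray],
    samples_b: Mapping[str, np.ndarray],
    alpha: float = 0.05,
) -> list[CoefficientComparison]:
    """Welch t-tests on bootstrap coefficient samples, BH-adjusted.

    One test per (parameter, coefficient). The Benjamini-Hochberg step-up
    adjustment is applied separately across parameters within the slope
    family and within the intercept family; ``significant`` flags adjusted
    p-values below ``alpha``.
    """
    comparisons: list[CoefficientComparison] = []
    parameters = sorted(set(samples_a) & set(samples_b))
    for ci, coefficient in enumerate(("intercept", "slope")):
        batch: list[CoefficientComparison] = []
        for parameter in parameters:
            t, df, p = _welch(
                samples_a[parameter][:, ci], samples_b[parameter][:, ci]
            )
            batch.append(
                CoefficientComparison(parameter, coefficient, t, df, p)
            )
        pvals = np.array([c.p_value for c in batch])
        ok = np.isfinite(pvals)
        if ok.any():
            rejected, adjusted, *_ = multipletests(
                pvals[ok], alpha=alpha, method="fdr_bh"
            )
            for c, adj, rej in zip(
                (b for b, keep in zip(batch, ok) if keep), adjusted, rejected
            ):
                c.adj_p_value = float(adj)
                c.significant = bool(rej)
        comparisons.extend(batch)
    return comparisons
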