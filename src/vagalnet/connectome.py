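"""Functional brain networks from region-averaged BOLD time series.

Region time series are cleaned (nuisance regression, 0.009-0.08 Hz
band-pass, censoring), correlated pairwise (Pearson), and negatives are set
to zero, yielding unthresholded positive-weight adjacency matrices. From
those, the graph quantities entering the dyadic edge-strength model are
computed: weighted clustering coefficient (local segregation), global
efficiency (integration), degree/strength, and Louvain modularity.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .rsa import bandpass_filter

__all__ = [
    "RegionTimeSeriesMatrix",
    "ConnectivityMatrix",
    "NodalMetrics",
    "clean_timeseries",
    "correlation_network",
    "nodal_clustering",
    "nodal_efficiency",
    "degree_and_strength",
    "modularity",
    "compute_nodal_metrics",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "write_adjacency_csv",
    "read_adjacency_csv",
    "write_metrics_csv",
]

#: BOLD low-frequency band (Hz) for resting-state cleaning
BOLD_BAND = (0.009, 0.08)


@dataclasses.dataclass
class RegionTimeSeriesMatrix:
    """Region-averaged time series: rows are timepoints, columns regions."""

    values: np.ndarray  # time x region
    tr: float  # repetition time, seconds
    region_ids: list[str]
    censor_mask: np.ndarray | None = None  # True = keep timepoint

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("need a 2-D time x region matrix with >= 2 regions")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(self.region_ids) != self.values.shape[1]:
            raise ValueError("region_ids length must match column count")
        if self.censor_mask is not None:
            self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
            if self.censor_mask.size != self.values.shape[0]:
                raise ValueError("censor_mask length must match timepoints")
        if self.n_retained < 30:
            raise ValueError("fewer than 30 retained timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_retained(self) -> int:
        if self.censor_mask is None:
            return self.values.shape[0]
        return int(self.censor_mask.sum())

    @property
    def fs(self) -> float:
        return 1.0 / self.tr


@dataclasses.dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency (truncated correlations)."""

    weights: np.ndarray  # region x region, in [0, 1], zero diagonal
    region_ids: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        if len(self.region_ids) != w.shape[0]:
            raise ValueError("region_ids length must match matrix size")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclasses.dataclass
class NodalMetrics:
    clustering: np.ndarray  # C_i in [0, 1]
    efficiency: np.ndarray  # E_i in [0, 1]
    degree: np.ndarray  # k_i, count of positive-weight neighbors
    strength: np.ndarray  # sum of incident weights
    modularity_q: float
    partition: dict  # node index -> community label


def clean_timeseries(
    m: RegionTimeSeriesMatrix,
    nuisance: np.ndarray | None = None,
    band: tuple[float, float] = BOLD_BAND,
) -> RegionTimeSeriesMatrix:
    """Nuisance regression then zero-phase band-pass, then censoring.

    Each region is replaced by its OLS residual against an intercept plus
    the nuisance columns (e.g. grey/white/CSF mean signals), band-passed to
    the stated band, and finally censored timepoints are dropped (filtering
    requires the contiguous grid, so censoring comes last).
    """
    nyq = m.fs / 2.0
    if not (0.0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} infeasible for tr={m.tr}s (Nyquist {nyq:.4g} Hz)")
    y = m.values
    design = np.ones((y.shape[0], 1))
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, float))
        if nuis.shape[0] != y.shape[0]:
            nuis = nuis.T
        if nuis.shape[0] != y.shape[0]:
            raise ValueError("nuisance rows must match timepoints")
        design = np.hstack([design, nuis])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    filt = bandpass_filter(resid, band[0], band[1], fs=m.fs)
    if m.censor_mask is not None:
        filt = filt[m.censor_mask]
    return RegionTimeSeriesMatrix(values=filt, tr=m.tr, region_ids=list(m.region_ids))


def correlation_network(m: RegionTimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlations per region pair; negatives truncated to 0.

    The graph metrics downstream cannot accommodate negative weights, so
    analysis is restricted to the unthresholded positive correlations.
    """
    y = m.values if m.censor_mask is None else m.values[m.censor_mask]
    sd = y.std(axis=0)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = ", ".join(m.region_ids[i] for i in dead)
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(y, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    w = np.where(r > 0, r, 0.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(weights=w, region_ids=list(m.region_ids))


def nodal_clustering(w: ConnectivityMatrix) -> np.ndarray:
    """Weighted clustering coefficient, geometric-mean triangle form.

    Weights are rescaled by the network-wide maximum, triangle intensity is
    the geometric mean of the three rescaled edge weights, and the sum over
    neighbor pairs is normalized by k_i(k_i - 1) with k_i the count of
    positive-weight neighbors. Nodes with k_i < 2 get C_i = 0.
    """
    W = w.weights
    wmax = W.max()
    if wmax == 0:
        return np.zeros(w.n_nodes)
    a = np.cbrt(W / wmax)
    tri = np.diagonal(a @ a @ a).copy()  # ordered (j, h) pairs, counts each twice
    k = (W > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    out = np.zeros(w.n_nodes)
    ok = denom > 0
    out[ok] = tri[ok] / denom[ok]
    return out


def nodal_efficiency(w: ConnectivityMatrix) -> tuple[np.ndarray, float]:
    """Nodal and global efficiency on 1/weight edge lengths.

    Edge length is the reciprocal weight (strong correlation = short path);
    E_i is the mean inverse shortest-path length from i to every other node,
    with unreachable pairs contributing zero.
    """
    W = w.weights
    n = w.n_nodes
    lengths = np.where(W > 0, np.divide(1.0, W, out=np.zeros_like(W), where=W > 0), 0.0)
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    inv = np.zeros_like(d)
    np.divide(1.0, d, out=inv, where=(d > 0) & np.isfinite(d))
    e = inv.sum(axis=1) / (n - 1)
    return e, float(e.mean())


def degree_and_strength(w: ConnectivityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Binary degree (count of positive-weight edges) and nodal strength."""
    k = (w.weights > 0).sum(axis=1)
    s = w.weights.sum(axis=1)
    return k, s


def modularity(
    w: ConnectivityMatrix, seed: int = 0, resolution: float = 1.0
) -> tuple[float, dict]:
    """Louvain-optimized weighted Newman modularity Q and its partition.

    Q = sum over communities of (within-community weight fraction minus the
    squared fraction of total degree in the community). The Louvain greedy
    search is randomized; a fixed seed makes it reproducible.
    """
    W = w.weights
    if W.sum() <= 0:
        raise ValueError("network has no positive weight")
    g = nx.Graph()
    g.add_nodes_from(range(w.n_nodes))
    ii, jj = np.nonzero(np.triu(W, k=1))
    g.add_weighted_edges_from((int(i), int(j), float(W[i, j])) for i, j in zip(ii, jj))
    comms = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=seed)
    q = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
    partition = {node: ci for ci, c in enumerate(comms) for node in c}
    return float(q), partition


def compute_nodal_metrics(w: ConnectivityMatrix, seed: int = 0, resolution: float = 1.0) -> NodalMetrics:
    """All nodal/network metrics needed by the dyadic strength model."""
    c = nodal_clustering(w)
    e, _ = nodal_efficiency(w)
    k, s = degree_and_strength(w)
    q, part = modularity(w, seed=seed, resolution=resolution)
    return NodalMetrics(
        clustering=c, efficiency=e, degree=k, strength=s, modularity_q=q, partition=part
    )


# -- I/O -----------------------------------------------------------------------

def write_timeseries_tsv(m: RegionTimeSeriesMatrix, path) -> None:
    df = pd.DataFrame(m.values, columns=m.region_ids)
    df.insert(0, "time_s", np.arange(m.values.shape[0]) * m.tr)
    df.to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path, tr: float | None = None) -> RegionTimeSeriesMatrix:
    """Read a time x region TSV with a leading ``time_s`` column."""
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: expected a 'time_s' column")
    t = df.pop("time_s").to_numpy(float)
    if tr is None:
        if t.size < 2:
            raise ValueError("cannot infer tr from a single timepoint")
        tr = float(t[1] - t[0])
    return RegionTimeSeriesMatrix(values=df.to_numpy(float), tr=tr, region_ids=list(df.columns))


def write_adjacency_csv(w: ConnectivityMatrix, path) -> None:
    pd.DataFrame(w.weights, index=w.region_ids, columns=w.region_ids).to_csv(path)


def read_adjacency_csv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(weights=df.to_numpy(float), region_ids=list(df.columns))


def write_metrics_csv(metrics: NodalMetrics, region_ids: list[str], path) -> None:
    """Per-node metric table plus a network-summary row."""
    df = pd.DataFrame(
        {
            "region": region_ids,
            "clustering": metrics.clustering,
            "efficiency": metrics.efficiency,
            "degree": metrics.degree,
            "strength": metrics.strength,
            "community": [metrics.partition[i] for i in range(len(region_ids))],
        }
    )
    summary = pd.DataFrame(
        {
            "region": ["__network__"],
            "clustering": [float(np.mean(metrics.clustering))],
            "efficiency": [float(np.mean(metrics.efficiency))],
            "degree": [float(np.mean(metrics.degree))],
            "strength": [float(np.mean(metrics.strength))],
            "community": [metrics.modularity_q],
        }
    )
    pd.concat([df, summary], ignore_index=True).to_csv(path, index=False)
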