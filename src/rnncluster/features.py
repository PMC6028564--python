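"""Connectome feature engineering: Pearson connectivity, thresholded binary
graphs, and the four graph-theoretic indicators used as subject features.

For a parcellation into ``R`` regions each subject contributes a feature
vector of length ``3R + R(R-1)/2``::

    [ degree (R) | clustering (R) | shortest paths, upper triangle i<j
      (R(R-1)/2) | local efficiency (R) ]

With the 90-region AAL parcellation this is 4275 features per subject, of
which 4005 are region-pair (shortest path) features.

All indices are 0-based internally; region label tables carry the 1-based
atlas numbering for reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "FeatureLayout",
    "ConnectivityMatrix",
    "BrainGraph",
    "GraphMetrics",
    "FeatureTable",
    "correlation_matrix",
    "binarize",
    "graph_metrics",
    "assemble_features",
    "extract_cohort_features",
    "ConnectomeFeatures",
]

#: Order of the four indicator blocks in the feature vector. Versioned
#: metadata: any change to this order is a change of layout version.
LAYOUT_VERSION = 1
BLOCK_ORDER = ("degree", "clustering", "shortest_path", "local_efficiency")


@dataclass(frozen=True)
class FeatureLayout:
    """Bijective map between feature indices and (indicator, region(s)).

    Parameters
    ----------
    n_regions : int
        Number of parcellation regions R. The vector layout is
        ``[degree (R)] [clustering (R)] [shortest-path upper triangle,
        row-major i<j (R(R-1)/2)] [local efficiency (R)]``.
    """

    n_regions: int

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")

    @property
    def n_pairs(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2

    @property
    def n_features(self) -> int:
        return 3 * self.n_regions + self.n_pairs

    @property
    def block_slices(self) -> dict[str, slice]:
        r = self.n_regions
        return {
            "degree": slice(0, r),
            "clustering": slice(r, 2 * r),
            "shortest_path": slice(2 * r, 2 * r + self.n_pairs),
            "local_efficiency": slice(2 * r + self.n_pairs, self.n_features),
        }

    def pair_of(self, offset: int) -> tuple[int, int]:
        """Region pair (i, j), i<j, for the ``offset``-th shortest-path slot."""
        r = self.n_regions
        if not 0 <= offset < self.n_pairs:
            raise IndexError(f"pair offset {offset} out of range")
        # row-major upper triangle: row i owns r-1-i slots
        i = 0
        remaining = offset
        while remaining >= r - 1 - i:
            remaining -= r - 1 - i
            i += 1
        return i, i + 1 + remaining

    def pair_offset(self, i: int, j: int) -> int:
        r = self.n_regions
        if not (0 <= i < j < r):
            raise IndexError(f"invalid region pair ({i}, {j})")
        return i * (2 * r - i - 1) // 2 + (j - i - 1)

    def describe(self, index: int) -> tuple[str, tuple[int, ...]]:
        """Return (indicator, region indices) for a feature index."""
        if not 0 <= index < self.n_features:
            raise IndexError(
                f"feature index {index} out of range [0, {self.n_features})"
            )
        for name, sl in self.block_slices.items():
            if sl.start <= index < sl.stop:
                off = index - sl.start
                if name == "shortest_path":
                    return name, self.pair_of(off)
                return name, (off,)
        raise AssertionError("unreachable")

    def feature_names(self) -> list[str]:
        names = []
        for k in range(self.n_features):
            ind, regs = self.describe(k)
            names.append(f"{ind}__" + "_".join(f"r{r}" for r in regs))
        return names

    def to_dict(self) -> dict:
        return {
            "layout_version": LAYOUT_VERSION,
            "n_regions": self.n_regions,
            "n_features": self.n_features,
            "block_order": list(BLOCK_ORDER),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureLayout":
        return cls(n_regions=int(d["n_regions"]))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Pearson correlation matrix over regions; symmetric, unit diagonal."""

    values: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BrainGraph:
    """Binary undirected graph from thresholded absolute correlation."""

    adjacency: np.ndarray
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class GraphMetrics:
    degree: np.ndarray
    clustering: np.ndarray
    shortest_path: np.ndarray
    local_efficiency: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.degree.shape[0]


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels and the feature-index map."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]
    layout: FeatureLayout | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if len(self.y) != self.X.shape[0] or len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("labels/ids must match number of rows")
        if not self.feature_names:
            if self.layout is not None:
                self.feature_names = self.layout.feature_names()
            else:
                self.feature_names = [f"f{k}" for k in range(self.X.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path, layout_path=None) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.y)
        df.to_csv(path, index=False)
        if layout_path is not None and self.layout is not None:
            with open(layout_path, "w") as fh:
                json.dump(self.layout.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path, layout_path=None) -> "FeatureTable":
        df = pd.read_csv(path)
        layout = None
        if layout_path is not None:
            with open(layout_path) as fh:
                layout = FeatureLayout.from_dict(json.load(fh))
        return cls(
            X=df.drop(columns=["subject_id", "label"]).to_numpy(dtype=float),
            y=df["label"].to_numpy(),
            subject_ids=df["subject_id"].astype(str).tolist(),
            layout=layout,
            feature_names=[c for c in df.columns if c not in ("subject_id", "label")],
        )


def correlation_matrix(ts: np.ndarray) -> ConnectivityMatrix:
    """Pearson correlation between all region pairs of one subject.

    Parameters
    ----------
    ts : ndarray of shape (T, R)
        Time series, one column per region, T >= 3 timepoints.

    Raises
    ------
    ValueError
        If a region's series is constant (correlation undefined), naming
        the offending region.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be 2-D (timepoints x regions)")
    t, r = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints, got {t}")
    if r < 2:
        raise ValueError(f"need at least 2 regions, got {r}")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contains non-finite values")
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant time series in region(s) {constant.tolist()}: "
            "Pearson correlation undefined"
        )
    c = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    return ConnectivityMatrix(values=c)


def binarize(c: ConnectivityMatrix | np.ndarray, threshold: float = 0.25) -> BrainGraph:
    """Threshold |r| to a binary adjacency matrix.

    An edge is present iff ``|r_ij| > threshold`` (strictly), ``i != j``;
    the diagonal is removed. The default threshold is 0.25.
    """
    values = c.values if isinstance(c, ConnectivityMatrix) else np.asarray(c, float)
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    adj = (np.abs(values) > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj = np.maximum(adj, adj.T)  # guard asymmetric numerical input
    return BrainGraph(adjacency=adj, threshold=float(threshold))


def _hop_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted hop distances; inf for disconnected pairs."""
    if adj.shape[0] == 0:
        return np.zeros((0, 0))
    return _csgraph_shortest_path(adj.astype(float), method="D", unweighted=True)


def graph_metrics(
    g: BrainGraph | np.ndarray,
    local_efficiency_distances: str = "subgraph",
) -> GraphMetrics:
    """Degree, clustering coefficient, hop distances and local efficiency.

    * ``degree[i]`` — number of edges at node i (row sum), N_i.
    * ``clustering[i]`` — C_i = 2e / (N_i (N_i - 1)) where e is the number
      of edges among the neighbours of i; 0 when N_i < 2.
    * ``shortest_path`` — all-pairs unweighted hop counts on the binary
      graph; a disconnected pair gets the sentinel value R (one more than
      the largest possible hop distance), keeping features finite.
    * ``local_efficiency[i]`` — E(i) = (1 / (N_i (N_i - 1))) * sum of 1/d
      over ordered neighbour pairs, where d is measured either within the
      subgraph induced by the neighbours of i
      (``local_efficiency_distances="subgraph"``, the Latora–Marchiori
      form, default) or in the full graph (``"global"``). Disconnected
      neighbour pairs contribute 0; E(i) = 0 when N_i < 2.
    """
    adj = g.adjacency if isinstance(g, BrainGraph) else np.asarray(g)
    adj = np.asarray(adj, dtype=np.int8)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if local_efficiency_distances not in ("subgraph", "global"):
        raise ValueError(
            "local_efficiency_distances must be 'subgraph' or 'global'"
        )
    r = adj.shape[0]
    degree = adj.sum(axis=1).astype(int)

    dist = _hop_distances(adj)
    if local_efficiency_distances == "global":
        global_dist = dist

    sentinel = float(r)
    sp = dist.copy()
    sp[np.isinf(sp)] = sentinel
    np.fill_diagonal(sp, 0.0)

    clustering = np.zeros(r)
    local_eff = np.zeros(r)
    adj_bool = adj.astype(bool)
    for i in range(r):
        ni = degree[i]
        if ni < 2:
            continue
        nbrs = np.flatnonzero(adj_bool[i])
        sub = adj[np.ix_(nbrs, nbrs)]
        e = sub.sum() // 2
        clustering[i] = 2.0 * e / (ni * (ni - 1))
        if local_efficiency_distances == "subgraph":
            d = _hop_distances(sub)
        else:
            d = global_dist[np.ix_(nbrs, nbrs)]
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        local_eff[i] = inv.sum() / (ni * (ni - 1))

    return GraphMetrics(
        degree=degree,
        clustering=clustering,
        shortest_path=sp,
        local_efficiency=local_eff,
    )


def assemble_features(m: GraphMetrics) -> np.ndarray:
    """Flatten graph metrics into the declared feature-vector layout."""
    r = m.n_nodes
    layout = FeatureLayout(n_regions=r)
    iu = np.triu_indices(r, k=1)
    vec = np.concatenate(
        [
            m.degree.astype(float),
            m.clustering,
            m.shortest_path[iu],
            m.local_efficiency,
        ]
    )
    assert vec.shape[0] == layout.n_features
    return vec


def extract_cohort_features(
    subjects,
    threshold: float = 0.25,
    local_efficiency_distances: str = "subgraph",
) -> FeatureTable:
    """Run the full per-subject pipeline over a cohort.

    ``subjects`` is a list of :class:`rnncluster.synthetic.SubjectRecord`
    (anything with ``subject_id``, ``label``, ``timeseries`` attributes).
    Manifest order is preserved. Errors in one subject are re-raised with
    the subject id attached.
    """
    rows, labels, ids = [], [], []
    n_regions = None
    for s in subjects:
        ts = np.asarray(s.timeseries, dtype=float)
        if n_regions is None:
            n_regions = ts.shape[1]
        elif ts.shape[1] != n_regions:
            raise ValueError(
                f"subject {s.subject_id}: expected {n_regions} regions, "
                f"got {ts.shape[1]}"
            )
        try:
            c = correlation_matrix(ts)
            g = binarize(c, threshold=threshold)
            m = graph_metrics(g, local_efficiency_distances)
            rows.append(assemble_features(m))
        except ValueError as err:
            raise ValueError(f"subject {s.subject_id}: {err}") from err
        labels.append(s.label)
        ids.append(s.subject_id)
    if n_regions is None:
        # empty cohort: layout unknown, emit an empty 2-region table shell
        return FeatureTable(
            X=np.zeros((0, 0)), y=np.array([]), subject_ids=[], layout=None
        )
    return FeatureTable(
        X=np.vstack(rows),
        y=np.asarray(labels),
        subject_ids=ids,
        layout=FeatureLayout(n_regions=n_regions),
    )


class ConnectomeFeatures:
    """Transformer from ROI time series to graph-metric feature vectors.

    scikit-learn compatible: ``fit`` records the layout, ``transform`` maps
    a sequence of (T, R) arrays (or one 3-D array) to an (n, 3R + R(R-1)/2)
    feature matrix.
    """

    def __init__(self, threshold: float = 0.25,
                 local_efficiency_distances: str = "subgraph"):
        self.threshold = threshold
        self.local_efficiency_distances = local_efficiency_distances

    def get_params(self, deep: bool = True) -> dict:
        return {
            "threshold": self.threshold,
            "local_efficiency_distances": self.local_efficiency_distances,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        first = np.asarray(X[0], dtype=float)
        self.n_regions_ = first.shape[1]
        self.layout_ = FeatureLayout(n_regions=self.n_regions_)
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for ts in X:
            c = correlation_matrix(np.asarray(ts, dtype=float))
            g = binarize(c, threshold=self.threshold)
            m = graph_metrics(g, self.local_efficiency_distances)
            rows.append(assemble_features(m))
        return np.vstack(rows)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
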