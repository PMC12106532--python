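"""Self-organising-map clustering, metacluster merging, mixed-cluster
exclusion, and subset-frequency computation.

Pooled asinh5-transformed events are clustered onto a 10 x 10 SOM grid
(100 nodes), the node codebook vectors are merged by hierarchical
agglomerative clustering into 47 metaclusters, metaclusters co-expressing
mutually exclusive lineage markers (doublet-like mixtures) are excluded,
and per-subject subset frequencies are reported as percentages of all
CD45+ events (the excluded clusters stay in the denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from ._utils import as_rng
from .preprocess import _LABEL_COLUMN

_META_COLUMNS = ("subject_id", "group", _LABEL_COLUMN)

#: mutually exclusive lineage-marker pairs used by the mixed-cluster rule
DEFAULT_EXCLUSIVE_PAIRS = (("CD3", "CD19"), ("CD3", "CD14"), ("CD14", "CD56"))


@dataclass(frozen=True)
class ClusteringConfig:
    grid_rows: int = 10
    grid_cols: int = 10
    n_metaclusters: int = 47
    som_epochs: int = 20
    som_neighborhood: tuple[float | None, float] = (None, 0.4)  # initial (None=grid/2), final
    linkage: str = "average"
    repeats: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows * self.grid_cols < self.n_metaclusters:
            raise ValueError("grid must have at least n_metaclusters nodes")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.linkage not in ("average", "ward", "complete"):
            raise ValueError(f"unsupported linkage {self.linkage!r}")

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols


def _nearest_node(values: np.ndarray, codebook: np.ndarray, chunk: int = 200_000):
    """Nearest-codebook assignment (Euclidean; ties -> lowest node index)."""
    out = np.empty(len(values), dtype=int)
    c2 = (codebook**2).sum(axis=1)
    for start in range(0, len(values), chunk):
        x = values[start : start + chunk]
        d2 = c2[None, :] - 2.0 * (x @ codebook.T)
        out[start : start + chunk] = np.argmin(d2, axis=1)
    return out


class SelfOrganizingMap:
    """Batch-trained SOM on a rectangular grid.

    Deterministic given the seed: codebook initialised from a random
    sample of events, then batch updates with a Gaussian neighbourhood
    whose width decays linearly from ``sigma_initial`` (default half the
    grid) to ``sigma_final`` over the epochs.
    """

    def __init__(self, rows=10, cols=10, epochs=20, sigma_initial=None, sigma_final=0.4):
        self.rows, self.cols = rows, cols
        self.epochs = epochs
        self.sigma_initial = sigma_initial or max(rows, cols) / 2.0
        self.sigma_final = sigma_final
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        diff = coords[:, None, :] - coords[None, :, :]
        self._grid_d2 = (diff**2).sum(axis=-1)
        self.codebook = None

    @property
    def n_nodes(self):
        return self.rows * self.cols

    def fit(self, values: np.ndarray, rng) -> "SelfOrganizingMap":
        rng = as_rng(rng)
        n = len(values)
        if n < self.n_nodes:
            raise ValueError(f"need at least {self.n_nodes} events, got {n}")
        init_idx = rng.choice(n, size=self.n_nodes, replace=False)
        codebook = values[init_idx].copy()
        sigmas = np.linspace(self.sigma_initial, self.sigma_final, self.epochs)
        for sigma in sigmas:
            bmu = _nearest_node(values, codebook)
            counts = np.bincount(bmu, minlength=self.n_nodes).astype(float)
            sums = np.zeros_like(codebook)
            np.add.at(sums, bmu, values)
            h = np.exp(-self._grid_d2 / (2.0 * sigma**2))
            denom = h @ counts
            numer = h @ sums
            ok = denom > 1e-12
            codebook[ok] = numer[ok] / denom[ok, None]
        self.codebook = codebook
        return self

    def predict(self, values: np.ndarray) -> np.ndarray:
        if self.codebook is None:
            raise RuntimeError("SOM is not fitted")
        return _nearest_node(values, self.codebook)


@dataclass
class ClusterModel:
    """Fitted clustering: codebook, node->metacluster map, exclusions."""

    codebook: np.ndarray
    config: ClusteringConfig
    markers: list[str]
    node_assignments: np.ndarray          # per pooled event
    subject_ids: np.ndarray
    groups: np.ndarray
    true_labels: np.ndarray | None = None
    node_to_metacluster: np.ndarray | None = None
    excluded_metaclusters: set[int] = field(default_factory=set)
    subset_labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.codebook)

    @property
    def metacluster_assignments(self) -> np.ndarray:
        if self.node_to_metacluster is None:
            raise RuntimeError("metacluster() has not been run")
        return self.node_to_metacluster[self.node_assignments]

    @property
    def retained_metaclusters(self) -> list[int]:
        all_mc = sorted(set(self.node_to_metacluster.tolist()))
        return [m for m in all_mc if m not in self.excluded_metaclusters]

    def label_for(self, mc: int) -> str:
        return self.subset_labels.get(mc, f"MC{mc:02d}")


class SOMCluster:
    """Model object: SOM + metaclustering over a pooled event table.

    Parameters
    ----------
    pooled : DataFrame
        Output of :func:`immunet.preprocess.concatenate` /
        ``preprocess_cohort`` — marker columns plus ``subject_id`` and
        ``group`` — on the asinh5 scale.
    config : ClusteringConfig
    """

    def __init__(self, pooled: pd.DataFrame, config: ClusteringConfig | None = None):
        self.config = config or ClusteringConfig()
        if pooled.attrs.get("scale", "asinh5") != "asinh5":
            raise ValueError("pooled matrix must be asinh5-transformed")
        self.markers = [c for c in pooled.columns if c not in _META_COLUMNS]
        self._values = pooled[self.markers].to_numpy(dtype=float)
        self._subjects = pooled["subject_id"].to_numpy()
        self._groups = pooled["group"].to_numpy()
        self._true = (
            pooled[_LABEL_COLUMN].to_numpy() if _LABEL_COLUMN in pooled else None
        )

    def fit(self, rng=None) -> ClusterModel:
        """Train the SOM, assign events, metacluster, and flag mixed clusters."""
        model = self.fit_som(rng)
        metacluster(model, self.config)
        heat = expression_heatmap(model, values=self._values)
        model.excluded_metaclusters = flag_mixed(model, heatmap=heat)
        model.subset_labels = _phenotype_labels(heat)
        return model

    def fit_som(self, rng=None) -> ClusterModel:
        cfg = self.config
        rng = as_rng(cfg.seed if rng is None else rng)
        sigma0, sigma1 = cfg.som_neighborhood
        som = SelfOrganizingMap(
            cfg.grid_rows, cfg.grid_cols, cfg.som_epochs, sigma0, sigma1
        ).fit(self._values, rng)
        return ClusterModel(
            codebook=som.codebook,
            config=cfg,
            markers=self.markers,
            node_assignments=som.predict(self._values),
            subject_ids=self._subjects,
            groups=self._groups,
            true_labels=self._true,
        )


def fit_som(pooled: pd.DataFrame, config: ClusteringConfig | None = None, rng=None) -> ClusterModel:
    """Functional entry point: train the SOM and assign every event."""
    return SOMCluster(pooled, config).fit_som(rng)


def metacluster(
    model: ClusterModel,
    config: ClusteringConfig | None = None,
    min_node_fraction: float = 1e-3,
) -> ClusterModel:
    """Merge SOM nodes into metaclusters by hierarchical clustering of the
    codebook vectors (cut at ``n_metaclusters`` groups).

    Low-occupancy nodes (fewer than ``min_node_fraction`` of all events;
    SOM grid interpolators sitting between populations) are absorbed into
    the metacluster of their nearest well-occupied node rather than merged
    on their own, so they cannot surface as singleton junk metaclusters.
    Metacluster ids are renumbered by first-node order for determinism.
    """
    config = config or model.config
    k = config.n_metaclusters
    if k > model.n_nodes:
        raise ValueError(f"n_metaclusters {k} exceeds node count {model.n_nodes}")
    if k == model.n_nodes:
        model.node_to_metacluster = np.arange(model.n_nodes)
        return model
    counts = np.bincount(model.node_assignments, minlength=model.n_nodes)
    threshold = max(2, int(min_node_fraction * counts.sum()))
    solid = np.where(counts >= threshold)[0]
    if len(solid) < k:  # cannot merge below k solid nodes; use all
        solid = np.arange(model.n_nodes)
    z = linkage(model.codebook[solid], method=config.linkage)
    raw = fcluster(z, t=k, criterion="maxclust")
    node_to_mc_raw = np.empty(model.n_nodes, dtype=int)
    node_to_mc_raw[solid] = raw
    tiny = np.setdiff1d(np.arange(model.n_nodes), solid)
    if len(tiny):
        d2 = (
            (model.codebook[tiny][:, None, :] - model.codebook[solid][None, :, :]) ** 2
        ).sum(axis=-1)
        node_to_mc_raw[tiny] = raw[np.argmin(d2, axis=1)]
    remap, node_to_mc = {}, np.empty(model.n_nodes, dtype=int)
    for node, cl in enumerate(node_to_mc_raw):
        if cl not in remap:
            remap[cl] = len(remap)
        node_to_mc[node] = remap[cl]
    model.node_to_metacluster = node_to_mc
    return model


def expression_heatmap(
    model: ClusterModel, pooled: pd.DataFrame | None = None, values: np.ndarray | None = None
) -> pd.DataFrame:
    """Metaclusters x markers matrix of min-max scaled median asinh5
    expression (scaled within each marker across metaclusters).

    Row/column dendrogram leaf orders are exported in ``DataFrame.attrs``.
    """
    if values is None:
        if pooled is None:
            raise ValueError("provide the pooled matrix or its value array")
        values = pooled[model.markers].to_numpy(dtype=float)
    mc = model.metacluster_assignments
    ids = sorted(set(mc.tolist()))
    med = np.empty((len(ids), len(model.markers)))
    for row, m in enumerate(ids):
        mask = mc == m
        if not mask.any():
            raise ValueError(f"metacluster {m} has no events; median undefined")
        med[row] = np.median(values[mask], axis=0)
    lo, hi = med.min(axis=0), med.max(axis=0)
    span = hi - lo
    flat = span <= 1e-12
    if flat.any():
        warnings.warn(
            f"constant markers {[model.markers[i] for i in np.where(flat)[0]]}: "
            "scaled expression undefined, set to 0"
        )
    span[flat] = 1.0
    scaled = (med - lo) / span
    scaled[:, flat] = 0.0
    heat = pd.DataFrame(scaled, index=ids, columns=model.markers)
    if len(ids) > 2:
        heat.attrs["row_order"] = [ids[i] for i in leaves_list(linkage(scaled, "average"))]
        heat.attrs["col_order"] = [
            model.markers[i] for i in leaves_list(linkage(scaled.T, "average"))
        ]
    return heat


def flag_mixed(
    model: ClusterModel,
    heatmap: pd.DataFrame | None = None,
    pooled: pd.DataFrame | None = None,
    pairs=DEFAULT_EXCLUSIVE_PAIRS,
    tau: float = 0.5,
) -> set[int]:
    """Flag metaclusters whose scaled median expression exceeds ``tau`` on
    both markers of any mutually exclusive lineage pair (doublet-like
    mixed populations)."""
    if heatmap is None:
        heatmap = expression_heatmap(model, pooled)
    flagged = set()
    for a, b in pairs:
        if a not in heatmap.columns or b not in heatmap.columns:
            continue
        hit = (heatmap[a] > tau) & (heatmap[b] > tau)
        flagged.update(heatmap.index[hit].tolist())
    return flagged


def _phenotype_labels(heatmap: pd.DataFrame, tau: float = 0.5) -> dict[int, str]:
    """Generate phenotype strings: markers scaled above tau appended '+'."""
    labels = {}
    for mc, row in heatmap.iterrows():
        pos = [m for m in heatmap.columns if row[m] > tau and m != "CD45"]
        labels[mc] = ("".join(f"{m}+" for m in pos) or "Lin-") + f" (MC{mc:02d})"
    return labels


def compute_frequencies(model: ClusterModel) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject subset frequencies (% of all that subject's events).

    Excluded metaclusters are dropped from the columns but their events
    stay in the denominator (frequencies are % of CD45+ PBMC, not % of
    retained events).  Returns (frequency table, group labels).
    """
    mc = model.metacluster_assignments
    subjects = model.subject_ids
    uniq_subjects = list(dict.fromkeys(subjects.tolist()))
    retained = model.retained_metaclusters
    table = np.zeros((len(uniq_subjects), len(retained)))
    groups = {}
    for i, sid in enumerate(uniq_subjects):
        mask = subjects == sid
        total = mask.sum()
        if total == 0:
            raise ValueError(f"subject {sid} has zero events")
        counts = np.bincount(
            mc[mask], minlength=int(model.node_to_metacluster.max()) + 1
        )
        table[i] = 100.0 * counts[retained] / total
        groups[sid] = model.groups[mask][0]
    freq = pd.DataFrame(
        table, index=uniq_subjects, columns=[model.label_for(m) for m in retained]
    )
    return freq, pd.Series(groups, name="group")


def node_purity(model: ClusterModel) -> float:
    """Mean (event-weighted) modal true-label fraction per node; requires
    synthetic truth labels."""
    if model.true_labels is None:
        raise ValueError("no true labels available")
    pure, total = 0, 0
    for node in range(model.n_nodes):
        mask = model.node_assignments == node
        if not mask.any():
            continue
        counts = np.bincount(model.true_labels[mask])
        pure += counts.max()
        total += mask.sum()
    return pure / total


def cluster_stability(pooled: pd.DataFrame, config: ClusteringConfig, rng=None) -> float:
    """Mean pairwise adjusted Rand index of event assignments across
    ``config.repeats`` reseeded SOM+metacluster fits on the same data."""
    from sklearn.metrics import adjusted_rand_score

    rng = as_rng(config.seed if rng is None else rng)
    runs = []
    for _ in range(config.repeats):
        model = SOMCluster(pooled, config).fit_som(rng)
        metacluster(model, config)
        runs.append(model.metacluster_assignments)
    if len(runs) < 2:
        return 1.0
    scores = [
        adjusted_rand_score(runs[i], runs[j])
        for i in range(len(runs))
        for j in range(i + 1, len(runs))
    ]
    return float(np.mean(scores))
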