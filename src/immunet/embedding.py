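"""Subject-level PCA (with loadings) and event-level 2-D embedding.

Subject PCA treats subjects as observations and the 46 subset frequencies
as variables (standardized by default); any component pair can be
extracted — group separation in the source study shows up on PC1 vs PC3.
The event embedding is a seeded t-SNE preceded by PCA reduction; it is a
black-box visual-structure check assessed only through label statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._utils import as_rng

_VARIANCE_FLOOR = 1e-12


@dataclass
class PCAResult:
    scores: pd.DataFrame          # subjects x components
    loadings: pd.DataFrame        # subsets x components
    variance_explained: np.ndarray
    mean_: np.ndarray
    scale_: np.ndarray
    component_pair_used: tuple[int, int] = (0, 2)

    def pair(self, i: int, j: int) -> pd.DataFrame:
        """Scores for the component pair (i, j), zero-based."""
        out = self.scores.iloc[:, [i, j]].copy()
        self.component_pair_used = (i, j)
        return out


class SubjectPCA:
    """PCA model over a subject x subset frequency table."""

    def __init__(self, freq_table: pd.DataFrame, standardize: bool = True):
        if len(freq_table) < 3:
            raise ValueError("subject PCA needs at least 3 subjects")
        self.freq = freq_table
        self.standardize = standardize

    def fit(self, n_components: int | None = None) -> PCAResult:
        x = self.freq.to_numpy(dtype=float)
        mean = x.mean(axis=0)
        if self.standardize:
            scale = x.std(axis=0, ddof=1)
            flat = scale < _VARIANCE_FLOOR
            if flat.any():
                warnings.warn(
                    f"constant subset columns {list(self.freq.columns[flat])}; "
                    "left unscaled"
                )
                scale = np.where(flat, 1.0, scale)
        else:
            scale = np.ones_like(mean)
        z = (x - mean) / scale
        k = n_components or min(z.shape[0] - 1, z.shape[1])
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(z)
        comps = [f"PC{i + 1}" for i in range(k)]
        return PCAResult(
            scores=pd.DataFrame(scores, index=self.freq.index, columns=comps),
            loadings=pd.DataFrame(
                pca.components_.T, index=self.freq.columns, columns=comps
            ),
            variance_explained=pca.explained_variance_ratio_,
            mean_=mean,
            scale_=scale,
        )


def subject_pca(
    freq_table: pd.DataFrame, standardize: bool = True, n_components: int | None = None
) -> PCAResult:
    return SubjectPCA(freq_table, standardize=standardize).fit(n_components)


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # events x 2
    seed: int
    perplexity: float
    init: str


def event_embedding(
    values: np.ndarray | pd.DataFrame,
    seed: int = 0,
    perplexity: float = 30.0,
    n_pca: int = 10,
    init: str = "pca",
) -> EmbeddingResult:
    """Seeded 2-D t-SNE of (a PCA reduction of) pooled asinh5 events."""
    from sklearn.manifold import TSNE

    if isinstance(values, pd.DataFrame):
        values = values.select_dtypes(include=[np.number]).to_numpy(dtype=float)
    n = len(values)
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n events {n}")
    if n_pca and values.shape[1] > n_pca:
        values = PCA(n_components=n_pca, svd_solver="full").fit_transform(
            values - values.mean(axis=0)
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init=init,
        random_state=seed,
        max_iter=500,
    )
    coords = tsne.fit_transform(values)
    return EmbeddingResult(coordinates=coords, seed=seed, perplexity=perplexity, init=init)


def group_density(coords: np.ndarray, groups: np.ndarray, gridsize: int = 60):
    """Per-group 2-D histogram densities over a common grid (for density
    plots); returns {group: density array}, x edges, y edges."""
    xed = np.linspace(coords[:, 0].min(), coords[:, 0].max(), gridsize + 1)
    yed = np.linspace(coords[:, 1].min(), coords[:, 1].max(), gridsize + 1)
    out = {}
    for g in np.unique(groups):
        mask = groups == g
        h, _, _ = np.histogram2d(coords[mask, 0], coords[mask, 1], bins=[xed, yed])
        out[g] = h / max(h.sum(), 1)
    return out, xed, yed
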