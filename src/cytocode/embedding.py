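"""2-D embedding of events and density-contour population gating.

Cells are embedded with t-SNE on the transformed analyte channels; cell
populations are then read off the embedding by kernel density: the least
dense 10% of events are excluded, and the remaining events are partitioned
into connected components of the density-thresholded plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator
from sklearn.manifold import TSNE

from .events import EventMatrix


@dataclass
class Embedding:
    coords: np.ndarray               # events x 2
    params: dict = field(default_factory=dict)
    source_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be events x 2")


def embed2d(events: EventMatrix, channels: list[str] | None = None,
            perplexity: float = 30.0, n_iter: int = 1000,
            seed: int = 0) -> Embedding:
    """t-SNE embedding of the analyte channels (all of them by default).

    Deterministic for a fixed seed (PCA initialization, fixed random state).
    Requires at least 50 events and more than 3x the perplexity.
    """
    if events.n_events < 50:
        raise ValueError("embedding requires at least 50 events")
    if events.n_events <= 3 * perplexity:
        raise ValueError("need more than 3x perplexity events")
    channels = channels or events.analyte_names
    X = np.column_stack([events.column(c) for c in channels])
    ts = TSNE(n_components=2, perplexity=perplexity, max_iter=n_iter,
              init="pca", random_state=seed)
    coords = ts.fit_transform(X)
    return Embedding(np.asarray(coords, dtype=float),
                     {"perplexity": perplexity, "iterations": n_iter,
                      "seed": seed},
                     list(channels))


def silverman_kde(coords: np.ndarray) -> gaussian_kde:
    """Gaussian KDE with Silverman's bandwidth on the 2-D coordinates."""
    return gaussian_kde(coords.T, bw_method="silverman")


class ContourGater(BaseEstimator):
    """Density-contour population gating on embedded coordinates.

    fit() estimates a per-event Gaussian kernel density (Silverman
    bandwidth), flags the ``exclusion`` fraction of least dense events, and
    partitions retained events into connected components of the
    density-thresholded plane evaluated on a ``grid_size``² raster over the
    coordinate bounding box.

    Fitted attributes: ``density_`` (per-event KDE value), ``excluded_``
    (boolean), ``labels_`` (component id per event, -1 for excluded),
    ``n_populations_``.
    """

    def __init__(self, exclusion: float = 0.10, bandwidth: float | None = None,
                 grid_size: int = 256):
        self.exclusion = exclusion
        self.bandwidth = bandwidth
        self.grid_size = grid_size

    def fit(self, coords: np.ndarray | Embedding, y=None):
        if isinstance(coords, Embedding):
            coords = coords.coords
        coords = np.asarray(coords, dtype=float)
        if not 0.0 <= self.exclusion < 1.0:
            raise ValueError("exclusion must be in [0, 1)")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        n = len(coords)
        kde = gaussian_kde(coords.T, bw_method=self.bandwidth or "silverman")
        dens = kde(coords.T)

        n_excl = int(round(self.exclusion * n))
        order = np.argsort(dens, kind="mergesort")
        excluded = np.zeros(n, dtype=bool)
        excluded[order[:n_excl]] = True
        # with no exclusion there is no density contour to draw: the whole
        # plane is retained and forms a single region
        if n_excl == 0:
            cutoff = 0.0
        elif n_excl < n:
            cutoff = dens[order[n_excl]]
        else:
            cutoff = np.inf

        # raster the density, threshold at the exclusion cutoff, and label
        # 8-connected components
        g = self.grid_size
        xmin, ymin = coords.min(axis=0)
        xmax, ymax = coords.max(axis=0)
        pad_x = 0.01 * (xmax - xmin or 1.0)
        pad_y = 0.01 * (ymax - ymin or 1.0)
        gx = np.linspace(xmin - pad_x, xmax + pad_x, g)
        gy = np.linspace(ymin - pad_y, ymax + pad_y, g)
        XX, YY = np.meshgrid(gx, gy, indexing="ij")
        gd = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(g, g)
        above = gd >= cutoff
        comp, n_comp = ndimage.label(above, structure=np.ones((3, 3), dtype=int))

        # map each retained event to its grid cell's component; events whose
        # cell fell just under the raster threshold inherit the nearest
        # labeled cell
        ix = np.clip(np.searchsorted(gx, coords[:, 0]) - 1, 0, g - 1)
        iy = np.clip(np.searchsorted(gy, coords[:, 1]) - 1, 0, g - 1)
        lab = comp[ix, iy]
        if n_comp > 0 and np.any((lab == 0) & ~excluded):
            _, (ni, nj) = ndimage.distance_transform_edt(
                comp == 0, return_indices=True)
            fallback = comp[ni, nj]
            need = (lab == 0) & ~excluded
            lab[need] = fallback[ix[need], iy[need]]

        labels = np.where(excluded, -1, lab - 1)
        # compact population ids to contiguous 0..K-1 over retained events
        kept = np.unique(labels[labels >= 0])
        remap = {old: new for new, old in enumerate(kept)}
        labels = np.array([remap.get(l, -1) for l in labels])

        self.density_ = dens
        self.excluded_ = excluded
        self.labels_ = labels
        self.n_populations_ = len(kept)
        self.density_cutoff_ = float(cutoff) if np.isfinite(cutoff) else cutoff
        return self

    def fit_predict(self, coords, y=None) -> np.ndarray:
        return self.fit(coords).labels_


@dataclass
class ContourPopulations:
    density: np.ndarray
    excluded: np.ndarray
    population_id: np.ndarray
    n_populations: int


def contour_gate(embedding: Embedding | np.ndarray, exclusion: float = 0.10,
                 bandwidth: float | None = None,
                 grid_size: int = 256) -> ContourPopulations:
    """Functional wrapper over :class:`ContourGater`."""
    g = ContourGater(exclusion=exclusion, bandwidth=bandwidth,
                     grid_size=grid_size).fit(embedding)
    return ContourPopulations(g.density_, g.excluded_, g.labels_,
                              g.n_populations_)


def knn_label_agreement(X: np.ndarray, coords: np.ndarray,
                        labels: np.ndarray, k: int = 10) -> float:
    """Mean fraction of an event's k nearest embedding neighbors sharing its
    label — the neighborhood-preservation figure used to sanity-check an
    embedding against ground truth."""
    from sklearn.neighbors import NearestNeighbors
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = labels[idx[:, 1:]]
    return float((neigh == labels[:, None]).mean())
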