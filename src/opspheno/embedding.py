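"""Gene-level dimensionality reduction: variance-targeted PCA and a
diffusion-potential embedding.

The embedding follows the PHATE family of diffusion-geometry methods: an
adaptive-bandwidth alpha-decay kernel on k-nearest-neighbor distances is
row-normalized into a diffusion operator, powered to a scale chosen by the
knee of the von Neumann entropy of the spectrum, mapped through a
potential transform (log for ``gamma=1``, square-root for ``gamma=0``),
and the pairwise potential distances are embedded in 2-D by metric MDS
initialized from classical MDS.  Everything is deterministic given the
inputs and ``random_state``.

This is an O(n^2)-O(n^3) dense implementation intended for gene-level
matrices (hundreds to a few thousand rows), not for millions of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import smacof

__all__ = ["VariancePCA", "reduce_pca", "PhateEmbedding", "embed_phate", "Embedding"]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


class VariancePCA(BaseEstimator, TransformerMixin):
    """PCA keeping the smallest component count reaching a variance target.

    Components follow a deterministic sign convention (the largest-
    magnitude loading of each component is positive) so repeated fits are
    identical.
    """

    def __init__(self, variance_fraction: float = 0.95):
        self.variance_fraction = variance_fraction

    def fit(self, X, y=None) -> "VariancePCA":
        if not (0.0 < self.variance_fraction <= 1.0):
            raise ValueError("variance_fraction must lie in (0, 1]")
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2
        total = var.sum()
        ratio = var / total if total > 0 else np.zeros_like(var)
        max_k = min(X.shape[0] - 1, X.shape[1])
        if self.variance_fraction == 1.0:
            k = max_k
        else:
            k = int(np.searchsorted(np.cumsum(ratio), self.variance_fraction) + 1)
            k = min(k, max_k)
        self.components_ = _fix_signs(vt[:k])
        self.explained_variance_ratio_ = ratio[:k]
        self.n_components_ = k
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


def reduce_pca(profiles: pd.DataFrame, variance_fraction: float = 0.95):
    """Project a gene-profile matrix onto the PCs holding the target
    variance fraction.  Returns (reduced DataFrame, n_components)."""
    pca = VariancePCA(variance_fraction).fit(profiles.to_numpy(float))
    reduced = pd.DataFrame(
        pca.transform(profiles.to_numpy(float)),
        index=profiles.index,
        columns=[f"PC{i + 1}" for i in range(pca.n_components_)],
    )
    return reduced, pca.n_components_


@dataclass
class Embedding:
    """Low-dimensional coordinates with the full parameter record."""

    coordinates: pd.DataFrame  # rows = genes, columns = dims
    params: dict

    @property
    def row_ids(self) -> list:
        return list(self.coordinates.index)

    def to_numpy(self) -> np.ndarray:
        return self.coordinates.to_numpy(float)


class PhateEmbedding(BaseEstimator, TransformerMixin):
    """Diffusion-potential embedding of a gene-profile (or PC) matrix.

    Parameters
    ----------
    knn : adaptive-bandwidth neighbor count; the kernel bandwidth of each
        point is its distance to the ``knn``-th neighbor.
    decay : alpha-decay exponent of the kernel.
    gamma : potential transform; 1 gives the log potential, 0 the
        square-root potential.
    t : diffusion time, or ``"auto"`` to pick the knee of the von Neumann
        entropy of the operator spectrum.
    mds_dist : metric on potential rows (``euclidean`` or ``cosine``).
    """

    def __init__(
        self,
        n_components: int = 2,
        knn: int = 2,
        decay: float = 40.0,
        gamma: float = 1.0,
        t: int | str = "auto",
        t_max: int = 100,
        mds_dist: str = "euclidean",
        random_state: int = 7,
    ):
        self.n_components = n_components
        self.knn = knn
        self.decay = decay
        self.gamma = gamma
        self.t = t
        self.t_max = t_max
        self.mds_dist = mds_dist
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _kernel(self, D: np.ndarray) -> np.ndarray:
        n = D.shape[0]
        order = np.sort(D, axis=1)
        eps = order[:, min(self.knn, n - 1)]  # distance to knn-th neighbor (col 0 is self)
        positive = eps[eps > 0]
        floor = positive.min() if positive.size else 1.0
        eps = np.where(eps > 0, eps, floor)
        with np.errstate(over="ignore"):
            K = np.exp(-((D / eps[:, None]) ** self.decay))
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
        return K

    def _choose_t(self, K: np.ndarray, d: np.ndarray) -> int:
        # von Neumann entropy knee of the symmetric conjugate's spectrum
        A = K / np.sqrt(np.outer(d, d))
        lam = np.abs(np.linalg.eigvalsh(A))
        lam = lam[lam > 1e-12]
        ts = np.arange(1, self.t_max + 1)
        H = np.empty(len(ts), dtype=float)
        for i, t in enumerate(ts):
            w = lam**t
            p = w / w.sum()
            H[i] = float(-(p * np.log(p + 1e-300)).sum())
        # farthest point from the chord between the entropy endpoints
        x0, y0, x1, y1 = ts[0], H[0], ts[-1], H[-1]
        num = np.abs((y1 - y0) * ts - (x1 - x0) * H + x1 * y0 - y1 * x0)
        return int(ts[int(np.argmax(num))])

    def _potential(self, Pt: np.ndarray) -> np.ndarray:
        if self.gamma == 1.0:
            return -np.log(Pt + 1e-7)
        return (2.0 / (1.0 - self.gamma)) * Pt ** ((1.0 - self.gamma) / 2.0)

    @staticmethod
    def _classical_mds(D: np.ndarray, d: int) -> np.ndarray:
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        vals, vecs = np.linalg.eigh(B)
        idx = np.argsort(vals)[::-1][:d]
        coords = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))
        return _fix_signs(coords.T).T

    # -- API ---------------------------------------------------------------

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 3:
            raise ValueError("need at least 3 rows to embed")
        if n < self.knn + 1:
            raise ValueError("fewer rows than knn + 1")
        D = squareform(pdist(X, metric="euclidean"))
        K = self._kernel(D)
        d = K.sum(axis=1)
        P = K / d[:, None]
        t = self._choose_t(K, d) if self.t == "auto" else int(self.t)
        Pt = np.linalg.matrix_power(P, t)
        U = self._potential(Pt)
        Dpot = squareform(pdist(U, metric=self.mds_dist))
        init = self._classical_mds(Dpot, self.n_components)
        coords, _ = smacof(
            Dpot,
            metric=True,
            n_components=self.n_components,
            init=init,
            n_init=1,
            random_state=self.random_state,
            normalized_stress=False,
        )
        self.t_ = t
        self.embedding_ = coords
        return coords

    def fit(self, X, y=None) -> "PhateEmbedding":
        self.fit_transform(X)
        return self


def embed_phate(
    reduced: pd.DataFrame,
    n_components: int = 2,
    knn: int = 2,
    decay: float = 40.0,
    gamma: float = 1.0,
    t: int | str = "auto",
    mds_dist: str = "euclidean",
    random_state: int = 7,
) -> Embedding:
    """Embed a (genes x PCs/features) matrix; returns an :class:`Embedding`
    whose parameter record captures every knob."""
    est = PhateEmbedding(
        n_components=n_components,
        knn=knn,
        decay=decay,
        gamma=gamma,
        t=t,
        mds_dist=mds_dist,
        random_state=random_state,
    )
    coords = est.fit_transform(reduced.to_numpy(float))
    df = pd.DataFrame(
        coords, index=reduced.index, columns=[f"PHATE{i + 1}" for i in range(n_components)]
    )
    params = {
        "knn": knn,
        "decay": decay,
        "gamma": gamma,
        "t": est.t_,
        "mds_dist": mds_dist,
        "random_state": random_state,
        "n_input_columns": reduced.shape[1],
    }
    return Embedding(df, params)
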