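"""Cell/gene inclusion filters, robust per-FOV normalization, gene profiles.

The imaging tile (field of view, FOV) is the batch unit: illumination and
staining drift tile-to-tile, so every feature is standardized against the
cells sharing its tile using median / scaled MAD, which is exact against
affine per-tile corruption and insensitive to the (rare) perturbed cells
within a tile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import NTC_GENE

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # makes the MAD a consistent estimator of the normal SD

__all__ = [
    "MAD_SCALE",
    "filter_cells",
    "filter_genes",
    "FieldOfViewNormalizer",
    "normalize_per_fov",
    "aggregate_gene_profiles",
]


def _feature_cols(cells: pd.DataFrame) -> list[str]:
    return [c for c in cells.columns if c.startswith("feature_")]


def filter_cells(cells: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    """Keep cells with >= 1 barcode read mapping to a library guide."""
    valid = set(library["guide_id"])
    keep = (cells["n_barcode_reads"] >= 1) & cells["guide_id"].isin(valid)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_cells removed %d of %d cells", removed, len(cells))
    out = cells.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_cells: no cells retained")
    return out


def filter_genes(
    cells: pd.DataFrame,
    min_guides: int = 2,
    min_cells_per_guide: int = 50,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep genes with >= ``min_guides`` guides at >= ``min_cells_per_guide``.

    Non-targeting guides are always retained: they form the null reference
    population and are not subject to the per-gene coverage requirement.
    Returns the reduced table and the sorted list of retained (targeting)
    genes.
    """
    counts = (
        cells.groupby(["gene", "guide_id"], observed=True, sort=False)
        .size()
        .reset_index(name="n")
    )
    good_guides = counts[counts["n"] >= min_cells_per_guide]
    per_gene = good_guides.groupby("gene", observed=True).size()
    retained = sorted(g for g, k in per_gene.items() if k >= min_guides and g != NTC_GENE)
    keep = cells["gene"].isin(retained) | (cells["gene"] == NTC_GENE)
    out = cells.loc[keep].reset_index(drop=True)
    return out, retained


class FieldOfViewNormalizer(BaseEstimator, TransformerMixin):
    """Robust per-(FOV, feature) standardization.

    For each feature f within each field of view v,

        x' = (x - median_v(f)) / (1.4826 * MAD_v(f)),

    where MAD is the median absolute deviation from the median.  A feature
    that is constant within a tile (MAD = 0) is set to 0 there and the
    event logged.  ``fit`` learns the per-tile statistics, ``transform``
    applies them; the usual call is ``fit_transform`` on one table.

    Parameters
    ----------
    fov_column : column naming the imaging tile each cell belongs to.
    """

    def __init__(self, fov_column: str = "fov_id"):
        self.fov_column = fov_column

    def fit(self, X: pd.DataFrame, y=None) -> "FieldOfViewNormalizer":
        feats = _feature_cols(X)
        if not feats:
            raise ValueError("no feature_* columns to normalize")
        grouped = X.groupby(self.fov_column, observed=True)[feats]
        med = grouped.median()
        mad = X[feats].sub(med.loc[X[self.fov_column]].to_numpy()).abs()
        mad[self.fov_column] = X[self.fov_column].to_numpy()
        mad = mad.groupby(self.fov_column, observed=True)[feats].median()
        sizes = grouped.size()
        small = sizes[sizes < 2]
        if len(small):
            logger.warning("FOVs with fewer than 2 cells: %s", list(small.index))
        n_degenerate = int((mad.to_numpy() == 0).sum())
        if n_degenerate:
            logger.info("%d (FOV, feature) pairs have zero MAD; set to 0", n_degenerate)
        self.feature_names_ = feats
        self.median_ = med
        self.scale_ = MAD_SCALE * mad
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        feats = self.feature_names_
        med = self.median_.loc[X[self.fov_column]].to_numpy()
        scale = self.scale_.loc[X[self.fov_column]].to_numpy()
        vals = X[feats].to_numpy(dtype=float) - med
        out = np.divide(vals, scale, out=np.zeros_like(vals), where=scale != 0)
        res = X.copy()
        res[feats] = out
        return res


def normalize_per_fov(cells: pd.DataFrame, fov_column: str = "fov_id") -> pd.DataFrame:
    """Functional wrapper over :class:`FieldOfViewNormalizer`."""
    return FieldOfViewNormalizer(fov_column=fov_column).fit_transform(cells)


def aggregate_gene_profiles(
    cells: pd.DataFrame,
    keep_individual_ntc: bool = True,
) -> pd.DataFrame:
    """Mean normalized feature vector per gene (the gene profile matrix).

    Each non-targeting guide optionally becomes its own pseudo-gene row
    (named by its guide id) so controls can serve as reference points in
    embeddings.  Row order is deterministic (sorted).
    """
    feats = _feature_cols(cells)
    if keep_individual_ntc:
        key = np.where(cells["gene"] == NTC_GENE, cells["guide_id"], cells["gene"])
    else:
        key = cells["gene"].to_numpy()
    prof = (
        cells[feats]
        .assign(_key=key)
        .groupby("_key", observed=True)[feats]
        .mean()
        .sort_index()
    )
    prof.index.name = "gene"
    return prof
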