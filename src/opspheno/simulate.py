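"""Synthetic optical-pooled-screen data with known ground truth.

Every input the analysis pipeline consumes can be generated here: a CRISPR
guide library (a few guides per gene plus non-targeting controls), per-cell
feature tables with planted perturbation effects and field-of-view batch
structure, collections of gene lists for meta-analysis, and two-channel
Golgi images with known object geometry.

The per-cell feature model is a multivariate normal within correlated
feature blocks.  Control (non-targeting) cells are emitted under three
conditions — unstimulated, 4 h agonist, and 5 h agonist — whose mean
vectors ("archetypes") sit at a configurable separation along orthogonal
directions in feature space; targeting cells are emitted under the 4 h
condition only, as in a screen stimulated at a single time point.  Planted
hit genes shift their cells toward the unstimulated archetype, toward the
5 h archetype, or along a novel direction, scaled by a per-guide efficacy.
Field-of-view batch effects are affine per (FOV, feature): x -> scale*x +
shift, exactly the corruption the downstream robust normalization is built
to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("unstim_ctrl", "stim_4h", "stim_5h_ctrl")
NTC_GENE = "non-targeting"

__all__ = [
    "CONDITIONS",
    "NTC_GENE",
    "GeneEffect",
    "EffectSpec",
    "SimulatedScreen",
    "GeneListSource",
    "GeneListCollection",
    "make_guide_library",
    "simulate_screen",
    "simulate_gene_lists",
    "make_synthetic_golgi_image",
]


def make_guide_library(n_genes: int, guides_per_gene: int, n_ntc: int) -> pd.DataFrame:
    """Build a guide library table.

    Parameters
    ----------
    n_genes : number of targeted genes.
    guides_per_gene : guides designed against each gene (4 in a typical
        genome-wide library).
    n_ntc : number of non-targeting control guides.

    Returns
    -------
    DataFrame with columns ``guide_id``, ``gene``, ``is_ntc``.  Naming is
    deterministic (``GENE0001_g1`` ... , ``NTC_0001`` ...).
    """
    for name, val in (("n_genes", n_genes), ("guides_per_gene", guides_per_gene), ("n_ntc", n_ntc)):
        if int(val) != val or val < 1:
            raise ValueError(f"{name} must be a positive integer, got {val!r}")
    width = max(4, len(str(n_genes)))
    rows = []
    for i in range(1, n_genes + 1):
        gene = f"GENE{i:0{width}d}"
        for g in range(1, guides_per_gene + 1):
            rows.append((f"{gene}_g{g}", gene, False))
    ntc_width = max(4, len(str(n_ntc)))
    for j in range(1, n_ntc + 1):
        rows.append((f"NTC_{j:0{ntc_width}d}", NTC_GENE, True))
    return pd.DataFrame(rows, columns=["guide_id", "gene", "is_ntc"])


@dataclass(frozen=True)
class GeneEffect:
    """Planted effect for one gene.

    effect_class : one of ``toward_unstim``, ``toward_5h``, ``novel``,
        ``null``.  ``novel`` directions are drawn from the unit sphere,
        fixed by the simulation seed; genes sharing a ``direction_tag``
        share one direction (so they form a recoverable phenotype group),
        genes without a tag each get their own.
    effect_size : shift magnitude in units of the per-feature noise SD.
    efficacies : per-guide multipliers in [0, 1]; cycled if shorter than
        the gene's guide count.
    """

    effect_class: str = "null"
    effect_size: float = 0.0
    efficacies: Sequence[float] = (1.0,)
    direction_tag: str | None = None

    def __post_init__(self) -> None:
        if self.effect_class not in ("toward_unstim", "toward_5h", "novel", "null"):
            raise ValueError(f"unknown effect_class {self.effect_class!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if any(not (0.0 <= e <= 1.0) for e in self.efficacies):
            raise ValueError("efficacies must lie in [0, 1]")


@dataclass
class EffectSpec:
    """Ground-truth configuration of a simulated screen.

    The defaults describe a modest screen: 20 features in correlated
    blocks of 4 (within-block correlation 0.3), condition archetypes
    separated by 3 noise-SD, mild affine field-of-view batch effects,
    50 cells per guide, and 5 % of cells left without a mapped barcode.
    """

    n_features: int = 20
    block_sizes: Sequence[int] | None = None
    block_rho: float = 0.3
    condition_separation: float = 3.0
    fov_shift_sd: float = 0.3
    fov_scale_sd: float = 0.1
    cells_per_guide: int = 50
    cells_per_guide_dispersion: float | None = None
    unmapped_fraction: float = 0.05
    hit_genes: Mapping[str, GeneEffect] = field(default_factory=dict)

    def blocks(self) -> list[list[int]]:
        """Partition of feature indices into correlated blocks."""
        if self.block_sizes is None:
            size = 4 if self.n_features % 4 == 0 else 1
            sizes = [size] * (self.n_features // size)
        else:
            sizes = list(self.block_sizes)
            if sum(sizes) != self.n_features:
                raise ValueError("block_sizes must partition the feature set")
        out, start = [], 0
        for s in sizes:
            out.append(list(range(start, start + s)))
            start += s
        return out

    def feature_names(self) -> list[str]:
        return [f"feature_{i:03d}" for i in range(self.n_features)]


def _archetype_means(spec: EffectSpec) -> dict[str, np.ndarray]:
    """Condition means: 4 h stimulated is the origin; the unstimulated and
    5 h archetypes sit at ``condition_separation`` along orthogonal unit
    directions (first and second half of the feature vector)."""
    m = spec.n_features
    u_unstim = np.zeros(m)
    u_unstim[: m // 2] = 1.0
    u_unstim /= np.linalg.norm(u_unstim)
    u_5h = np.zeros(m)
    u_5h[m // 2:] = 1.0
    u_5h /= np.linalg.norm(u_5h)
    s = spec.condition_separation
    return {
        "unstim_ctrl": s * u_unstim,
        "stim_4h": np.zeros(m),
        "stim_5h_ctrl": s * u_5h,
        "_dir_unstim": u_unstim,
        "_dir_5h": u_5h,
    }


@dataclass
class SimulatedScreen:
    """A simulated screen: the cell table plus every piece of ground truth."""

    cells: pd.DataFrame
    library: pd.DataFrame
    gene_truth: pd.DataFrame        # gene, effect_class, effect_size, direction_tag
    effect_directions: pd.DataFrame  # gene x feature unit direction for non-null genes
    fov_truth: pd.DataFrame         # fov_id x feature shift and scale
    params: dict

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.cells.columns if c.startswith("feature_")]


def _block_noise(rng: np.random.Generator, n: int, spec: EffectSpec) -> np.ndarray:
    """Unit-variance noise with within-block correlation ``block_rho``."""
    x = rng.standard_normal((n, spec.n_features))
    rho = spec.block_rho
    if rho > 0:
        for block in spec.blocks():
            if len(block) < 2:
                continue
            shared = rng.standard_normal(n)
            x[:, block] = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * x[:, block]
    return x


def simulate_screen(
    library: pd.DataFrame,
    spec: EffectSpec,
    n_fov: int,
    seed: int,
) -> SimulatedScreen:
    """Simulate the per-cell feature table of an optical pooled screen.

    Non-targeting cells are produced under all three conditions; targeting
    cells only under the 4 h stimulated condition.  Cell features are
    archetype mean + block-correlated noise + planted effect (for hit
    genes) followed by the per-FOV affine batch corruption.  Everything is
    reproducible from ``seed``; passing ``seed=None`` is an error.
    """
    if seed is None:
        raise ValueError("seed is required; simulations must be reproducible")
    known = set(library["gene"])
    unknown = set(spec.hit_genes) - known
    if unknown:
        raise ValueError(f"hit_genes not in library: {sorted(unknown)[:5]}")
    # Independent streams: effect directions never perturb the cell-noise
    # stream, so a zero-effect hit gene yields a byte-identical table.
    rng = np.random.default_rng([int(seed), 0])
    rng_dir = np.random.default_rng([int(seed), 1])
    arch = _archetype_means(spec)
    m = spec.n_features

    # Fixed effect directions, drawn in sorted order for determinism.
    directions: dict[str, np.ndarray] = {}
    tag_dirs: dict[str, np.ndarray] = {}
    for gene in sorted(spec.hit_genes):
        eff = spec.hit_genes[gene]
        if eff.effect_class == "toward_unstim":
            directions[gene] = arch["_dir_unstim"]
        elif eff.effect_class == "toward_5h":
            directions[gene] = arch["_dir_5h"]
        elif eff.effect_class == "novel":
            if eff.direction_tag is not None:
                if eff.direction_tag not in tag_dirs:
                    v = rng_dir.standard_normal(m)
                    tag_dirs[eff.direction_tag] = v / np.linalg.norm(v)
                directions[gene] = tag_dirs[eff.direction_tag]
            else:
                v = rng_dir.standard_normal(m)
                directions[gene] = v / np.linalg.norm(v)

    # FOV affine corruption, per (FOV, feature).
    fov_shift = rng.normal(0.0, spec.fov_shift_sd, size=(n_fov, m))
    fov_scale = np.exp(rng.normal(0.0, spec.fov_scale_sd, size=(n_fov, m)))

    def n_cells() -> int:
        if spec.cells_per_guide_dispersion is None:
            return spec.cells_per_guide
        r = spec.cells_per_guide_dispersion
        p = r / (r + spec.cells_per_guide)
        return int(rng.negative_binomial(r, p))

    blocks_rows: list[pd.DataFrame] = []
    feats: list[np.ndarray] = []
    guide_counts: dict[str, int] = {}
    for row in library.itertuples(index=False):
        conds = CONDITIONS if row.is_ntc else ("stim_4h",)
        eff = spec.hit_genes.get(row.gene)
        for cond in conds:
            n = n_cells()
            if n == 0:
                continue
            x = arch[cond] + _block_noise(rng, n, spec)
            if eff is not None and eff.effect_class != "null" and cond == "stim_4h":
                k = guide_counts.get(row.gene, 0)
                guide_counts[row.gene] = k + 1
                efficacy = eff.efficacies[k % len(eff.efficacies)]
                x = x + eff.effect_size * efficacy * directions[row.gene]
            fov = rng.integers(0, n_fov, size=n)
            x = fov_scale[fov] * x + fov_shift[fov]
            reads = rng.poisson(3.0, size=n) + 1
            reads[rng.random(n) < spec.unmapped_fraction] = 0
            blocks_rows.append(
                pd.DataFrame(
                    {
                        "fov_id": fov,
                        "condition": cond,
                        "guide_id": row.guide_id,
                        "gene": row.gene,
                        "n_barcode_reads": reads,
                    }
                )
            )
            feats.append(x)

    cells = pd.concat(blocks_rows, ignore_index=True)
    cells.insert(0, "cell_id", [f"cell_{i:08d}" for i in range(len(cells))])
    fmat = np.vstack(feats)
    for j, name in enumerate(spec.feature_names()):
        cells[name] = fmat[:, j]

    gene_truth = pd.DataFrame(
        [
            (g, e.effect_class, e.effect_size, e.direction_tag)
            for g, e in sorted(spec.hit_genes.items())
        ],
        columns=["gene", "effect_class", "effect_size", "direction_tag"],
    )
    effect_directions = pd.DataFrame(
        {g: directions[g] for g in sorted(directions)}, index=spec.feature_names()
    ).T
    fov_truth = pd.concat(
        {
            "shift": pd.DataFrame(fov_shift, columns=spec.feature_names()),
            "scale": pd.DataFrame(fov_scale, columns=spec.feature_names()),
        },
        axis=1,
    )
    fov_truth.index.name = "fov_id"
    params = {
        "seed": int(seed),
        "n_fov": int(n_fov),
        "n_features": spec.n_features,
        "block_rho": spec.block_rho,
        "condition_separation": spec.condition_separation,
        "fov_shift_sd": spec.fov_shift_sd,
        "fov_scale_sd": spec.fov_scale_sd,
        "cells_per_guide": spec.cells_per_guide,
        "cells_per_guide_dispersion": spec.cells_per_guide_dispersion,
        "unmapped_fraction": spec.unmapped_fraction,
    }
    return SimulatedScreen(cells, library, gene_truth, effect_directions, fov_truth, params)


# ---------------------------------------------------------------------------
# Gene-list collections for meta-analysis


@dataclass
class GeneListSource:
    category: str
    ranked: bool
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.category:
            raise ValueError("category must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes within a source")


@dataclass
class GeneListCollection:
    """Named screen-derived gene lists, each with a category label."""

    sources: dict[str, GeneListSource]

    def __len__(self) -> int:
        return len(self.sources)

    def all_genes(self) -> list[str]:
        out: set[str] = set()
        for s in self.sources.values():
            out.update(s.genes)
        return sorted(out)


def simulate_gene_lists(
    n_sources: int,
    n_genes: int,
    overlap_spec: Mapping[tuple[int, int], int] | None,
    seed: int,
) -> GeneListCollection:
    """Generate gene lists with requested pairwise overlaps.

    ``overlap_spec`` maps source index pairs (i, j), 0-based, i < j, to the
    number of genes the two lists share.  Genes outside the specified
    overlaps are unique to their source.  Each source gets its own
    category (one category per screen technology).
    """
    if seed is None:
        raise ValueError("seed is required")
    if n_sources < 1 or n_genes < 1:
        raise ValueError("n_sources and n_genes must be >= 1")
    overlap_spec = dict(overlap_spec or {})
    per_source_shared = np.zeros(n_sources, dtype=int)
    for (i, j), k in overlap_spec.items():
        if not (0 <= i < j < n_sources):
            raise ValueError(f"bad source pair {(i, j)}")
        if k < 0:
            raise ValueError("overlap counts must be >= 0")
        per_source_shared[i] += k
        per_source_shared[j] += k
    if (per_source_shared > n_genes).any():
        raise ValueError("requested overlaps exceed list length")

    rng = np.random.default_rng(int(seed))
    total = n_sources * n_genes  # generous universe; uniqueness by construction
    universe = [f"GENE{i:05d}" for i in range(total + sum(overlap_spec.values()))]
    perm = rng.permutation(len(universe))
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = [universe[p] for p in perm[cursor: cursor + k]]
        cursor += k
        return out

    lists: list[list[str]] = [[] for _ in range(n_sources)]
    for (i, j), k in sorted(overlap_spec.items()):
        shared = take(k)
        lists[i].extend(shared)
        lists[j].extend(shared)
    for i in range(n_sources):
        lists[i].extend(take(n_genes - len(lists[i])))

    sources = {
        f"screen_{i + 1}": GeneListSource(category=f"category_{i + 1}", ranked=True, genes=lists[i])
        for i in range(n_sources)
    }
    return GeneListCollection(sources)


# ---------------------------------------------------------------------------
# Synthetic Golgi images


def make_synthetic_golgi_image(
    blobs: Sequence[tuple[tuple[float, float], float, float, float]],
    shape: tuple[int, int],
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render two-channel images of disk-shaped Golgi objects.

    Each blob is ``((row, col), radius, gm130_value, sting_value)``: a disk
    at ``gm130_value`` over ``background`` in the marker channel, and at
    ``sting_value`` inside the same disk in the measured channel.  Returns
    (gm130, sting, truth); the truth table records rasterized area, the
    noise-free mean STING value, and whether the disk overlaps another.
    """
    nrow, ncol = shape
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    gm = np.full(shape, float(background))
    st = np.full(shape, float(background))
    cover = np.zeros(shape, dtype=int)
    masks = []
    for (r0, c0), radius, _, _ in blobs:
        if r0 - radius < 0 or c0 - radius < 0 or r0 + radius >= nrow or c0 + radius >= ncol:
            raise ValueError("blob does not fit inside the image")
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        masks.append(mask)
        cover += mask
    rows = []
    for i, ((center, radius, gv, sv), mask) in enumerate(zip(blobs, masks)):
        gm[mask] = gv
        st[mask] = sv
        rows.append(
            {
                "blob": i,
                "row": center[0],
                "col": center[1],
                "radius": radius,
                "area": int(mask.sum()),
                "gm130_value": gv,
                "mean_sting": sv,
                "overlapping": bool((cover[mask] > 1).any()),
            }
        )
    if noise_sd > 0:
        rng = np.random.default_rng(int(seed))
        gm = np.clip(gm + rng.normal(0.0, noise_sd, shape), 0.0, None)
        st = np.clip(st + rng.normal(0.0, noise_sd, shape), 0.0, None)
    return gm, st, pd.DataFrame(rows)
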