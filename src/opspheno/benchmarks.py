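"""Reference synthetic benchmarks exercising the full pipeline.

Each function generates a screen (or image, or gene-list collection) at a
fixed study condition, runs the relevant slice of the pipeline, and
returns summary metrics with the ground truth alongside.  They serve as
integration-level checks of the statistical behavior the pipeline is
supposed to have: calibrated nulls, planted-hit recovery at realistic
effect sizes, recoverable phenotype clusters, sensible meta-analysis
weights, and accurate image quantification.

Problem sizes are desk-scale — a few hundred genes, tens of cells per
guide, a few thousand bootstrap draws — chosen so a full run completes in
minutes on one CPU while keeping every statistical mechanism intact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import simulate as sim
from .classify import MODELS, score_screen
from .clustering import feature_modules, select_resolution
from .embedding import embed_phate, reduce_pca
from .golgi import quantify_golgi
from .maic import prepare_gene_lists, run_maic
from .preprocess import aggregate_gene_profiles, filter_cells, normalize_per_fov
from .simulate import GeneListCollection, GeneListSource

__all__ = [
    "simulate_and_score",
    "null_calibration",
    "null_fdr_repeats",
    "planted_recovery",
    "clustering_recovery",
    "module_recovery",
    "maic_toy",
    "golgi_benchmark",
    "run_mini_pipeline",
]


def _build_screen(
    seed: int,
    n_genes: int,
    n_ntc: int,
    cells_per_guide: int,
    n_fov: int,
    hit_genes: dict | None = None,
    guides_per_gene: int = 4,
):
    lib = sim.make_guide_library(n_genes, guides_per_gene, n_ntc)
    spec = sim.EffectSpec(
        hit_genes=hit_genes or {},
        cells_per_guide=cells_per_guide,
        unmapped_fraction=0.0,  # constant guide sizes -> one shared null size
    )
    screen = sim.simulate_screen(lib, spec, n_fov=n_fov, seed=seed)
    cells = normalize_per_fov(filter_cells(screen.cells, lib))
    return screen, cells


def simulate_and_score(
    seed: int,
    n_genes: int,
    hit_genes: dict | None = None,
    n_ntc: int = 50,
    cells_per_guide: int = 50,
    n_fov: int = 40,
    n_boot: int = 2000,
    models=MODELS,
):
    """Simulate a screen and run the classifier -> bootstrap -> Stouffer/BH
    pipeline; returns (screen, guide_scores, hit_table)."""
    screen, cells = _build_screen(seed, n_genes, n_ntc, cells_per_guide, n_fov, hit_genes)
    guide_scores, hits = score_screen(
        cells, models=models, n_boot=n_boot, seed=seed, exact_nulls=True
    )
    return screen, guide_scores, hits


def null_calibration(seed: int, n_genes: int = 125, n_boot: int = 2000, models=MODELS):
    """No planted effects: per-model KS uniformity of guide p-values and
    the number of genes reaching q <= 0.001.

    The NTC pool is kept large relative to the guide group size (600 NTC
    guides vs 25-cell groups), mirroring the proportions of a real screen
    (~450 NTC guides vs ~10x larger gene space): the bootstrap null
    centers on the NTC pool mean, so a pool that is too small relative to
    the group size shifts every guide p-value together.
    """
    _, guide_scores, hits = simulate_and_score(
        seed, n_genes, n_boot=n_boot, models=models, n_ntc=600, cells_per_guide=25
    )
    ks = {}
    for model, df in guide_scores.groupby("model", observed=True):
        p = df["empirical_p"].dropna().to_numpy()
        ks[model] = stats.kstest(p, "uniform")
    q_cols = [c for c in hits.columns if c.startswith("q_")]
    n_fdr_hits = int((hits[q_cols] <= 0.001).any(axis=1).sum())
    return {"guide_scores": guide_scores, "hit_table": hits, "ks": ks, "n_fdr_hits": n_fdr_hits}


def null_fdr_repeats(
    seed: int,
    n_repeats: int = 20,
    n_genes: int = 100,
    n_boot: int = 2000,
    models=("unstimulated", "increased_stim"),
):
    """Repeat the null pipeline over seeds; returns per-repeat counts of
    genes at q <= 0.001 (should almost always be zero)."""
    counts = []
    for r in range(n_repeats):
        _, _, hits = simulate_and_score(
            seed + 10_000 + r, n_genes, n_boot=n_boot, models=models, n_fov=20,
            n_ntc=600, cells_per_guide=25,
        )
        q_cols = [c for c in hits.columns if c.startswith("q_")]
        counts.append(int((hits[q_cols] <= 0.001).any(axis=1).sum()))
    return counts


def planted_recovery(
    seed: int,
    n_genes: int = 200,
    n_hits: int = 20,
    effect_size: float = 4.0,
    efficacies=(1.0, 1.0, 0.5, 0.0),
    n_boot: int = 2000,
):
    """Plant strong hits with per-guide efficacy variation and measure
    recall / false positives of the union hit call at q <= 0.001."""
    lib = sim.make_guide_library(n_genes, 4, 50)
    genes = sorted(set(lib.loc[~lib["is_ntc"], "gene"]))
    classes = ["toward_unstim", "toward_5h", "novel"]
    hit_genes = {
        g: sim.GeneEffect(classes[i % 3], effect_size, tuple(efficacies))
        for i, g in enumerate(genes[:n_hits])
    }
    screen, guide_scores, hits = simulate_and_score(
        seed, n_genes, hit_genes=hit_genes, n_boot=n_boot, n_ntc=300
    )
    called = set(hits.index[hits["hit_any"]])
    planted = set(hit_genes)
    recall = len(called & planted) / len(planted)
    false_pos = len(called - planted)
    return {
        "hit_table": hits,
        "guide_scores": guide_scores,
        "planted": planted,
        "called": called,
        "recall": recall,
        "false_positives": false_pos,
    }


def clustering_recovery(
    seed: int,
    n_genes: int = 200,
    cells_per_guide: int = 30,
    resolutions=(0.1, 0.3, 1.0, 3.0),
):
    """Four planted archetype groups; PCA -> embedding -> stability-
    selected Leiden; returns ARI vs truth and both same-seed runs."""
    lib = sim.make_guide_library(n_genes, 4, 40)
    genes = sorted(set(lib.loc[~lib["is_ntc"], "gene"]))
    classes = [("toward_unstim", None), ("toward_5h", None), ("novel", "grpA"), ("novel", "grpB")]
    hit_genes, truth = {}, {}
    for i, g in enumerate(genes):
        cls, tag = classes[i % 4]
        hit_genes[g] = sim.GeneEffect(cls, 4.0, (1.0,), direction_tag=tag)
        truth[g] = i % 4
    spec = sim.EffectSpec(hit_genes=hit_genes, cells_per_guide=cells_per_guide, unmapped_fraction=0.0)
    screen = sim.simulate_screen(lib, spec, n_fov=30, seed=seed)
    cells = normalize_per_fov(filter_cells(screen.cells, lib))
    profiles = aggregate_gene_profiles(cells, keep_individual_ntc=False).loc[genes]
    reduced, n_pcs = reduce_pca(profiles, 0.95)
    emb = embed_phate(reduced, knn=2, gamma=1.0, random_state=7)
    run1 = select_resolution(emb, list(resolutions), seed=seed)
    run2 = select_resolution(emb, list(resolutions), seed=seed)
    ari = adjusted_rand_score([truth[g] for g in genes], run1.labels.loc[genes].to_numpy())
    return {
        "ari": float(ari),
        "result": run1,
        "repeat": run2,
        "n_pcs": n_pcs,
        "stability_identical": bool(run1.stability_curve.equals(run2.stability_curve)),
    }


def module_recovery(seed: int, n_pairs: int = 20, n_genes: int = 100):
    """Feature columns built as near-duplicate pairs must be re-paired
    exactly by the module clustering (ARI = 1)."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, (n_genes, n_pairs))
    X = np.empty((n_genes, 2 * n_pairs))
    X[:, ::2] = base
    X[:, 1::2] = base + rng.normal(0, 1e-3, base.shape)
    df = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(2 * n_pairs)])
    mapping, scores = feature_modules(df, n_modules=n_pairs)
    truth = np.repeat(np.arange(n_pairs), 2)
    return {"ari": float(adjusted_rand_score(truth, mapping.to_numpy())), "scores": scores}


def maic_toy(seed: int, n_truth: int = 50, list_len: int = 40):
    """Two near-duplicate informative sources plus one random source."""
    rng = np.random.default_rng(seed)
    truth = [f"G{i:03d}" for i in range(n_truth)]
    rand = [f"R{i:03d}" for i in rng.choice(10_000, size=list_len, replace=False)]
    coll = GeneListCollection(
        {
            "informative_1": GeneListSource("category_1", True, truth[:list_len]),
            "informative_2": GeneListSource("category_2", True, truth[n_truth - list_len:]),
            "random": GeneListSource("category_3", True, rand),
        }
    )
    res = run_maic(coll)
    shared = sorted(set(truth[:list_len]) & set(truth[n_truth - list_len:]))
    only_one = sorted(set(truth[:list_len]) - set(truth[n_truth - list_len:]))
    step_delta = float((res.one_step() - res.list_weights).abs().max())
    return {
        "result": res,
        "weights": res.list_weights,
        "score_two_category": float(res.gene_scores[shared[0]]),
        "score_one_category": float(res.gene_scores[only_one[0]]),
        "fixed_point_delta": step_delta,
    }


GOLGI_BLOBS = [
    ((100, 100), 20, 200.0, 120.0),
    ((100, 300), 25, 200.0, 90.0),
    ((300, 100), 22, 200.0, 150.0),
    ((330, 330), 30, 200.0, 60.0),
    ((430, 200), 18, 200.0, 100.0),  # close pair: 9 px edge gap
    ((430, 245), 18, 200.0, 100.0),
    ((250, 430), 12, 200.0, 80.0),   # ~440 px decoy, below the area filter
]
GOLGI_DIM = [((60, 430), 35, 50.0, 20.0), ((460, 60), 40, 50.0, 20.0), ((200, 250), 30, 50.0, 20.0)]


def golgi_benchmark(seed: int, noise_sd: float = 2.0):
    """Five expected objects (one from the merged pair), decoy filtered;
    mean STING error measured against the planted truth."""
    gm, st, truth = sim.make_synthetic_golgi_image(
        GOLGI_BLOBS + GOLGI_DIM, (512, 512), background=0.0, noise_sd=noise_sd, seed=seed
    )
    labels, meas = quantify_golgi(gm, st, merge_distance=30, min_area=600)
    bright = truth[truth["gm130_value"] == 200.0]
    errors, tolerances = [], []
    for _, obj in meas.iterrows():
        d = np.hypot(bright["row"] - obj["centroid_row"], bright["col"] - obj["centroid_col"])
        planted = bright.loc[d.idxmin()]
        errors.append(abs(obj["mean_sting"] - planted["mean_sting"]))
        tolerances.append(3 * noise_sd / np.sqrt(obj["area"]))
    return {
        "n_objects": int(labels.max()),
        "measurements": meas,
        "truth": truth,
        "mean_sting_errors": errors,
        "tolerances": tolerances,
    }


def run_mini_pipeline(seed: int, outdir) -> dict:
    """Small end-to-end run (simulate -> normalize -> classify -> cluster
    -> meta-analysis) writing every output table to ``outdir``; used to
    verify byte-level determinism of the whole path."""
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lib = sim.make_guide_library(30, 4, 20)
    genes = sorted(set(lib.loc[~lib["is_ntc"], "gene"]))
    classes = ["toward_unstim", "toward_5h", "novel"]
    hit_genes = {
        g: sim.GeneEffect(classes[i % 3], 4.0, (1.0, 1.0, 0.5, 0.0)) for i, g in enumerate(genes[:6])
    }
    spec = sim.EffectSpec(hit_genes=hit_genes, cells_per_guide=40, unmapped_fraction=0.05)
    screen = sim.simulate_screen(lib, spec, n_fov=15, seed=seed)
    cells = normalize_per_fov(filter_cells(screen.cells, lib))
    guide_scores, hits = score_screen(cells, n_boot=500, seed=seed, exact_nulls=False)
    profiles = aggregate_gene_profiles(cells, keep_individual_ntc=False).loc[genes]
    reduced, _ = reduce_pca(profiles, 0.95)
    emb = embed_phate(reduced, knn=2, gamma=1.0, random_state=7)
    clus = select_resolution(emb, [0.1, 0.5, 2.0], seed=seed)
    tables = {}
    for model in MODELS:
        tables[model] = (
            pd.DataFrame({"gene": hits.index.to_numpy(), "p": hits[f"p_{model}"].to_numpy()})
            .dropna()
        )
    coll = prepare_gene_lists(tables, top_n=10, p_cut=0.5)
    maic_res = run_maic(coll)

    io.write_tsv(guide_scores.round(12), outdir / "guide_scores.tsv", index=False)
    io.write_tsv(hits.round(12), outdir / "hit_table.tsv")
    emb_table = emb.coordinates.round(12).copy()
    emb_table["cluster"] = clus.labels
    io.write_tsv(emb_table, outdir / "embedding.tsv")
    clus.stability_curve.round(12).to_csv(outdir / "stability_curve.csv", index=False)
    io.write_tsv(maic_res.gene_scores.round(12).rename_axis("gene").to_frame(), outdir / "maic_scores.tsv")
    io.write_tsv(maic_res.list_weights.round(12).rename_axis("source").to_frame(), outdir / "maic_weights.tsv")
    return {
        "hit_table": hits,
        "cluster": clus,
        "maic": maic_res,
        "files": sorted(p.name for p in outdir.iterdir()),
    }
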