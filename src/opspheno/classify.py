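"""SVM phenotype classifiers, bootstrap nulls, and gene-level hit calling.

Three linear support-vector classifiers score each guide's cells:

* ``perturbed`` — one model per guide, trained to separate that guide's
  cells from non-targeting control (NTC) cells with an 80/20 train/test
  split; the guide score is the mean held-out decision value.
* ``unstimulated`` — pre-trained on NTC cells, unstimulated vs 4 h
  stimulated; higher score = cell looks unstimulated.
* ``increased_stim`` — pre-trained on NTC cells, 5 h vs 4 h stimulated;
  higher score = cell looks further along the stimulation time course.

Significance comes from an empirical null: pseudo-guides of NTC cells,
resampled with replacement at the guide's group size, pushed through the
same scorer.  Guide p-values are combined per gene with Stouffer's method
and corrected across genes with Benjamini-Hochberg; a gene is a hit in a
model at q <= 0.001 (default) and a hit overall if it is a hit in any
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .simulate import NTC_GENE

logger = logging.getLogger(__name__)

MODELS = ("perturbed", "unstimulated", "increased_stim")

__all__ = [
    "MODELS",
    "ClassifierParams",
    "ConditionClassifier",
    "train_condition_classifier",
    "score_guide_condition",
    "score_guide_perturbed",
    "NullDistribution",
    "bootstrap_null",
    "NullBank",
    "empirical_pvalue",
    "stouffer_combine",
    "bh_correct",
    "call_hits",
    "score_screen",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Linear-SVC hyperparameters used for all three classifier schemes.

    The defaults are deliberately heavily regularized (C = 1e-5) with a
    large iteration budget and balanced class weights, appropriate for
    separating broad, overlapping single-cell populations rather than
    fitting individual cells.
    """

    C: float = 1e-5
    max_iter: int = 100_000
    tol: float = 5e-5
    class_weighting: str = "balanced"
    seed: int = 7

    def __post_init__(self) -> None:
        if self.C <= 0 or self.tol <= 0:
            raise ValueError("C and tolerance must be positive")
        if self.class_weighting not in ("balanced", "none"):
            raise ValueError("class_weighting must be 'balanced' or 'none'")

    def make_svc(self) -> LinearSVC:
        return LinearSVC(
            C=self.C,
            max_iter=self.max_iter,
            tol=self.tol,
            class_weight=None if self.class_weighting == "none" else "balanced",
            random_state=self.seed,
        )


def _feature_cols(cells: pd.DataFrame) -> list[str]:
    return [c for c in cells.columns if c.startswith("feature_")]


class ConditionClassifier(BaseEstimator):
    """Linear SVM between two cell populations, oriented toward a target.

    ``fit(X, y)`` expects binary labels with 1 marking the target
    population; ``decision_function`` returns w.x + b oriented so larger
    values mean "more like the target".  The fitted attributes are
    ``coef_``, ``intercept_`` and ``feature_names_``.
    """

    def __init__(self, params: ClassifierParams = ClassifierParams()):
        self.params = params

    def fit(self, X, y, feature_names: Sequence[str] | None = None) -> "ConditionClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("both populations must be present to train")
        svc = self.params.make_svc().fit(X, y)
        # LinearSVC orients its decision toward the larger class label, so
        # labels {0, 1} with 1 = target already give the wanted sign.
        sign = 1.0 if list(svc.classes_)[-1] == 1 else -1.0
        self.coef_ = sign * svc.coef_.ravel()
        self.intercept_ = sign * float(svc.intercept_[0])
        self.feature_names_ = list(feature_names) if feature_names is not None else [
            f"x{i}" for i in range(X.shape[1])
        ]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.coef_):
            raise ValueError("feature count does not match the trained model")
        return X @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names_,
            "weights": list(map(float, self.coef_)),
            "intercept": self.intercept_,
            "params": {
                "C": self.params.C,
                "max_iter": self.params.max_iter,
                "tol": self.params.tol,
                "class_weighting": self.params.class_weighting,
                "seed": self.params.seed,
            },
        }


def train_condition_classifier(
    target_cells: pd.DataFrame,
    reference_cells: pd.DataFrame,
    params: ClassifierParams = ClassifierParams(),
    feature_subset: Sequence[str] | None = None,
) -> ConditionClassifier:
    """Train an SVM separating two NTC condition populations.

    The decision value is oriented so that larger means "more like
    ``target_cells``'s condition".
    """
    if target_cells.empty or reference_cells.empty:
        raise ValueError("both condition tables must be non-empty")
    feats = list(feature_subset) if feature_subset is not None else _feature_cols(target_cells)
    X = np.vstack([target_cells[feats].to_numpy(float), reference_cells[feats].to_numpy(float)])
    y = np.r_[np.ones(len(target_cells)), np.zeros(len(reference_cells))]
    return ConditionClassifier(params).fit(X, y, feature_names=feats)


def score_guide_condition(model: ConditionClassifier, guide_cells: pd.DataFrame) -> float:
    """Mean decision value of a guide's cells under a condition classifier."""
    if guide_cells.empty:
        raise ValueError("guide_cells must be non-empty")
    return float(model.decision_function(guide_cells[model.feature_names_].to_numpy(float)).mean())


def score_guide_perturbed(
    guide_X: np.ndarray,
    ntc_X: np.ndarray,
    params: ClassifierParams = ClassifierParams(),
    train_fraction: float = 0.8,
    rng: np.random.Generator | None = None,
) -> float:
    """Perturbed-vs-unperturbed score for one guide.

    Trains a linear SVM to separate the guide's cells (label 1) from NTC
    cells (label 0) on a ``train_fraction`` split and returns the mean
    decision value of the guide's held-out cells, oriented toward
    "perturbed".  Returns NaN (unscorable) when the guide has fewer than
    5 cells.
    """
    guide_X = np.asarray(guide_X, dtype=float)
    ntc_X = np.asarray(ntc_X, dtype=float)
    if len(guide_X) < 5:
        return float("nan")
    rng = rng or np.random.default_rng(params.seed)
    n_tr = max(1, int(round(train_fraction * len(guide_X))))
    n_tr = min(n_tr, len(guide_X) - 1)  # keep at least one held-out cell
    perm = rng.permutation(len(guide_X))
    tr, te = perm[:n_tr], perm[n_tr:]
    ntc_perm = rng.permutation(len(ntc_X))
    ntc_tr = ntc_perm[: max(1, int(round(train_fraction * len(ntc_X))))]
    X = np.vstack([guide_X[tr], ntc_X[ntc_tr]])
    y = np.r_[np.ones(len(tr)), np.zeros(len(ntc_tr))]
    model = ConditionClassifier(params).fit(X, y)
    return float(model.decision_function(guide_X[te]).mean())


# ---------------------------------------------------------------------------
# Bootstrap nulls and p-values


@dataclass
class NullDistribution:
    """Sorted bootstrap scores of NTC pseudo-guides at one group size."""

    model_id: str
    group_size: int
    scores: np.ndarray  # sorted ascending

    @property
    def n_boot(self) -> int:
        return len(self.scores)


class MeanDecisionScorer:
    """Scorer whose guide score is the mean of per-cell decision values.

    Declares ``is_mean`` so bootstrap resampling can be fully vectorized
    over precomputed per-cell values.
    """

    is_mean = True

    def __init__(self, model: ConditionClassifier):
        self.model = model

    def per_cell(self, X: np.ndarray) -> np.ndarray:
        return self.model.decision_function(X)

    def __call__(self, X: np.ndarray) -> float:
        return float(self.per_cell(X).mean())


class PerturbedNullScorer:
    """Scores an NTC pseudo-guide exactly like a real guide under the
    perturbed scheme: a fresh classifier is trained pseudo-guide vs the
    NTC reference, so the null includes training variance."""

    is_mean = False

    def __init__(
        self,
        ntc_reference: np.ndarray,
        params: ClassifierParams,
        train_fraction: float = 0.8,
        rng: np.random.Generator | None = None,
    ):
        self.ntc_reference = np.asarray(ntc_reference, dtype=float)
        self.params = params
        self.train_fraction = train_fraction
        self.rng = rng or np.random.default_rng(params.seed)

    def __call__(self, X: np.ndarray) -> float:
        return score_guide_perturbed(
            X, self.ntc_reference, self.params, self.train_fraction, rng=self.rng
        )


def bootstrap_null(
    ntc_X: np.ndarray,
    group_size: int,
    n_boot: int,
    scorer: Callable[[np.ndarray], float],
    seed: int,
    model_id: str = "null",
) -> NullDistribution:
    """Null distribution of guide scores from resampled NTC pseudo-guides.

    Each of ``n_boot`` pseudo-guides is ``group_size`` NTC cells sampled
    with replacement and pushed through ``scorer``.  Requires
    ``n_boot >= 100`` (smaller nulls have unusable tails).
    """
    ntc_X = np.asarray(ntc_X, dtype=float)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if group_size > len(ntc_X):
        raise ValueError("group_size exceeds the NTC population")
    rng = np.random.default_rng(int(seed))
    if getattr(scorer, "is_mean", False):
        values = scorer.per_cell(ntc_X)
        idx = rng.integers(0, len(values), size=(n_boot, group_size))
        scores = values[idx].mean(axis=1)
    else:
        scores = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, len(ntc_X), size=group_size)
            scores[b] = scorer(ntc_X[idx])
    return NullDistribution(model_id, int(group_size), np.sort(scores))


def empirical_pvalue(score: float, null: NullDistribution, side: str = "greater") -> float:
    """Add-one empirical p-value of a score against a bootstrap null.

    ``greater``: p = (1 + #{null >= score}) / (B + 1).  ``two_sided``
    doubles the smaller tail, capped at 1.  The add-one estimator keeps
    p in (0, 1], never exactly 0.
    """
    s = null.scores
    if len(s) == 0:
        raise ValueError("empty null distribution")
    b = len(s)
    n_ge = b - np.searchsorted(s, score, side="left")
    p_greater = (1.0 + n_ge) / (b + 1.0)
    if side == "greater":
        return float(p_greater)
    if side == "two_sided":
        n_le = np.searchsorted(s, score, side="right")
        p_less = (1.0 + n_le) / (b + 1.0)
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"unknown side {side!r}")


_P_FLOOR = 1e-300


def stouffer_combine(p_values: Iterable[float]) -> float:
    """Combine one-sided p-values with Stouffer's method.

    z_i = Phi^-1(1 - p_i); z = sum(z_i) / sqrt(k); p = 1 - Phi(z).
    p-values at exactly 0 or 1 are clipped to machine-safe bounds.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    clipped = np.clip(p, _P_FLOOR, 1 - 1e-16)
    if (clipped != p).any():
        logger.info("stouffer_combine clipped %d boundary p-values", int((clipped != p).sum()))
    z = stats.norm.isf(clipped)
    return float(stats.norm.sf(z.sum() / np.sqrt(len(z))))


def bh_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


class NullBank:
    """Lazily-built nulls bucketed by group size.

    Building a 100,000-draw null per guide is wasteful when guides have
    similar cell counts, so group sizes are bucketed on a sqrt(2)-spaced
    grid and a guide's p-value is interpolated (linearly in log2 group
    size) between the two bracketing buckets.  ``exact=True`` disables
    bucketing and builds a null at each requested size.
    """

    def __init__(
        self,
        ntc_X: np.ndarray,
        scorer: Callable[[np.ndarray], float],
        n_boot: int,
        seed: int,
        model_id: str = "model",
        exact: bool = False,
    ):
        self.ntc_X = np.asarray(ntc_X, dtype=float)
        self.scorer = scorer
        self.n_boot = int(n_boot)
        self.seed = int(seed)
        self.model_id = model_id
        self.exact = exact
        self._nulls: dict[int, NullDistribution] = {}

    def _null_at(self, size: int) -> NullDistribution:
        size = int(min(size, len(self.ntc_X)))
        if size not in self._nulls:
            self._nulls[size] = bootstrap_null(
                self.ntc_X,
                size,
                self.n_boot,
                self.scorer,
                seed=self.seed + size,  # distinct stream per bucket
                model_id=self.model_id,
            )
        return self._nulls[size]

    def _bracket(self, group_size: int) -> tuple[int, int]:
        k_lo = int(np.floor(2 * np.log2(group_size)))
        lo = int(round(2 ** (k_lo / 2)))
        hi = int(round(2 ** ((k_lo + 1) / 2)))
        lo = max(2, min(lo, group_size))
        hi = max(hi, group_size)
        return lo, hi

    def pvalue(self, score: float, group_size: int, side: str = "greater") -> float:
        if self.exact:
            return empirical_pvalue(score, self._null_at(group_size), side)
        lo, hi = self._bracket(group_size)
        p_lo = empirical_pvalue(score, self._null_at(lo), side)
        if hi == lo or min(hi, len(self.ntc_X)) <= lo:
            return p_lo
        p_hi = empirical_pvalue(score, self._null_at(hi), side)
        w = (np.log2(group_size) - np.log2(lo)) / (np.log2(hi) - np.log2(lo))
        return float((1 - w) * p_lo + w * p_hi)


# ---------------------------------------------------------------------------
# Gene-level aggregation


def call_hits(guide_scores: pd.DataFrame, q_threshold: float = 0.001) -> pd.DataFrame:
    """Aggregate guide scores and p-values into the gene-level hit table.

    ``guide_scores`` needs columns ``model``, ``gene``, ``guide_id``,
    ``n_cells``, ``mean_score``, ``empirical_p`` (one row per scorable
    guide and model).  Per model: gene score = mean of guide mean scores,
    gene p = Stouffer over guide p-values, q = BH across genes, hit iff
    q <= ``q_threshold``.  ``hit_any`` is the union over models.
    """
    scored = guide_scores.dropna(subset=["mean_score"])
    pieces = []
    for model, df in scored.groupby("model", observed=True, sort=False):
        gene_stats = (
            df.groupby("gene", observed=True)
            .agg(score=("mean_score", "mean"), n_guides=("guide_id", "nunique"))
            .sort_index()
        )
        gene_stats["p"] = [
            stouffer_combine(df.loc[df["gene"] == g, "empirical_p"]) for g in gene_stats.index
        ]
        gene_stats["q"] = bh_correct(gene_stats["p"].to_numpy())
        gene_stats["hit"] = gene_stats["q"] <= q_threshold
        gene_stats["model"] = model
        pieces.append(gene_stats.reset_index())
    long = pd.concat(pieces, ignore_index=True)
    wide = long.pivot(index="gene", columns="model")
    wide.columns = [f"{col}_{model}" for col, model in wide.columns]
    hit_cols = [c for c in wide.columns if c.startswith("hit_")]
    wide[hit_cols] = wide[hit_cols].fillna(False)
    wide["hit_any"] = wide[hit_cols].any(axis=1)
    return wide.sort_index()


# ---------------------------------------------------------------------------
# Full screen pipeline


def score_screen(
    cells: pd.DataFrame,
    params: ClassifierParams = ClassifierParams(),
    models: Sequence[str] = MODELS,
    n_boot: int = 10_000,
    seed: int = 0,
    q_threshold: float = 0.001,
    ntc_reference_size: int = 500,
    feature_subset: Sequence[str] | None = None,
    exact_nulls: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the classifier -> bootstrap -> Stouffer/BH pipeline on a screen.

    ``cells`` must already be read-filtered and normalized.  Returns the
    per-(guide, model) score table and the gene-level hit table.

    The 4 h NTC population is split in half: one half trains the
    classifiers (and provides the perturbed model's reference
    population), the other builds the bootstrap nulls, so null scores are
    never computed on cells a model was trained on.
    """
    unknown = set(models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    feats = list(feature_subset) if feature_subset is not None else _feature_cols(cells)
    is_ntc = cells["gene"] == NTC_GENE
    ntc_4h = cells[is_ntc & (cells["condition"] == "stim_4h")]
    targeting = cells[~is_ntc & (cells["condition"] == "stim_4h")]
    if ntc_4h.empty or targeting.empty:
        raise ValueError("need NTC and targeting cells in the stim_4h condition")
    rng = np.random.default_rng(int(seed))
    all_ntc_X = ntc_4h[feats].to_numpy(float)
    half = rng.permutation(len(all_ntc_X))
    train_X = all_ntc_X[half[: len(half) // 2]]
    null_X = all_ntc_X[half[len(half) // 2:]]

    guide_groups = [
        (gene, guide_id, df[feats].to_numpy(float))
        for (gene, guide_id), df in sorted(
            targeting.groupby(["gene", "guide_id"], observed=True), key=lambda kv: kv[0]
        )
    ]

    rows = []
    for model_name in models:
        if model_name in ("unstimulated", "increased_stim"):
            target_cond = "unstim_ctrl" if model_name == "unstimulated" else "stim_5h_ctrl"
            target = cells[is_ntc & (cells["condition"] == target_cond)]
            if target.empty:
                raise ValueError(f"no NTC cells in condition {target_cond!r}")
            X_tr = np.vstack([target[feats].to_numpy(float), train_X])
            y_tr = np.r_[np.ones(len(target)), np.zeros(len(train_X))]
            clf = ConditionClassifier(params).fit(X_tr, y_tr, feature_names=feats)
            scorer = MeanDecisionScorer(clf)
            side = "greater"

            def guide_score(X, scorer=scorer):
                return scorer(X)

        else:  # perturbed
            ref_idx = rng.choice(
                len(train_X), size=min(ntc_reference_size, len(train_X)), replace=False
            )
            ntc_ref = train_X[ref_idx]
            split_rng = np.random.default_rng(int(seed) + 1)
            scorer = PerturbedNullScorer(ntc_ref, params, rng=np.random.default_rng(int(seed) + 2))
            side = "two_sided"

            def guide_score(X, ref=ntc_ref, rng=split_rng):
                return score_guide_perturbed(X, ref, params, rng=rng)

        bank = NullBank(
            null_X, scorer, n_boot=n_boot, seed=int(seed) + 1000, model_id=model_name,
            exact=exact_nulls,
        )
        for gene, guide_id, X in guide_groups:
            s = guide_score(X)
            p = np.nan if np.isnan(s) else bank.pvalue(s, len(X), side=side)
            rows.append((model_name, gene, guide_id, len(X), s, p))

    guide_scores = pd.DataFrame(
        rows, columns=["model", "gene", "guide_id", "n_cells", "mean_score", "empirical_p"]
    )
    hit_table = call_hits(guide_scores, q_threshold=q_threshold)
    return guide_scores, hit_table
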