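"""Concept activation vectors and TCAV scoring with significance testing.

For a concept C, a layer l and a class k, a CAV is the unit normal of a
linear max-margin classifier (hinge loss, L2 penalty) separating the
concept patches' activations from random counterexamples, oriented so
the concept side scores positive.  The sensitivity of an input x is the
dot product of the class-k log-odds gradient at layer l with the CAV
(in a two-class softmax the log-odds is what the prediction of class k
actually increases with), and
the TCAV score is the fraction of class-k inputs with strictly positive
sensitivity:

    TCAVQ = |{x in X_k : S(x) > 0}| / |X_k|          (in [0, 1])

Scores are recomputed over repeated runs with fresh random
counterexamples; per run a null score from a random-vs-random CAV is
also recorded, and a two-sided Welch t-test of concept scores against
null scores decides significance at level alpha (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from . import cnn
from .ace import Concept, ConceptPatch

__all__ = [
    "CAV", "TCAVResult", "sample_random_counterexamples", "train_cav",
    "sensitivity", "tcav_score", "run_tcav", "plot_scores",
]


@dataclass
class CAV:
    v: np.ndarray               # unit normal, concept side positive
    layer: str
    train_accuracy: float
    run_index: int = 0


@dataclass
class TCAVResult:
    concept_id: int
    class_k: int
    scores: np.ndarray          # per-run TCAVQ
    mean: float
    std: float                  # sample std (ddof=1)
    p_value: float
    significant: bool
    null_scores: np.ndarray = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {"concept_id": int(self.concept_id), "class_k": int(self.class_k),
                "mean": self.mean, "std": self.std, "p_value": self.p_value,
                "significant": bool(self.significant),
                "runs": int(len(self.scores))}


def sample_random_counterexamples(pool: list[ConceptPatch], n: int,
                                  rng: np.random.Generator | int
                                  ) -> list[int]:
    """Indices of n segments drawn uniformly without replacement from the
    pooled SLIC segments; the patches were prepared identically to
    concept patches (grey-127 canvases)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if len(pool) < n:
        raise ValueError(f"pool has {len(pool)} segments, need {n}")
    return list(rng.choice(len(pool), size=n, replace=False))


def train_cav(concept_embeddings: np.ndarray, random_embeddings: np.ndarray,
              seed: int = 0, layer: str = "fc16", C: float = 0.1,
              run_index: int = 0) -> CAV:
    """Linear SVM separating concept from random activations; the CAV is
    the normalized weight vector pointing to the concept side."""
    if len(concept_embeddings) == 0 or len(random_embeddings) == 0:
        raise ValueError("both activation sets must be non-empty")
    x = np.concatenate([concept_embeddings, random_embeddings])
    y = np.r_[np.ones(len(concept_embeddings), dtype=int),
              np.zeros(len(random_embeddings), dtype=int)]
    clf = LinearSVC(C=C, random_state=seed, max_iter=5000)
    clf.fit(x, y)
    w = clf.coef_[0].astype(np.float64)
    norm = np.linalg.norm(w)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("degenerate CAV: identical activation sets")
    return CAV(w / norm, layer, float(clf.score(x, y)), run_index)


def sensitivity(gradient_row: np.ndarray, cav: CAV) -> float:
    """Directional derivative S = <grad h_{l,k}(x), v>."""
    g = np.asarray(gradient_row).ravel()
    if g.shape != cav.v.shape:
        raise ValueError("dimension mismatch between gradient and CAV")
    return float(g @ cav.v)


def tcav_score(sensitivities) -> float:
    """Fraction of inputs with strictly positive sensitivity."""
    s = np.asarray(list(sensitivities), dtype=float)
    if s.size == 0:
        raise ValueError("empty sensitivity list")
    return float(np.mean(s > 0))


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value; degenerate zero-variance ties
    count as no evidence (p = 1)."""
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    with np.errstate(all="ignore"):
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if not np.isfinite(p) else float(p)


def run_tcav(model: cnn.TileCNN, concepts: list[Concept],
             pool_embeddings: np.ndarray, eval_inputs: dict[int, np.ndarray],
             runs: int = 100, alpha: float = 0.01, seed: int = 0,
             n_counterexamples: int = 40, layer: str = "fc16"
             ) -> list[TCAVResult]:
    """TCAV over repeated runs for every (concept, class) combination.

    ``eval_inputs`` maps class index -> [0,1]-scaled class-k tiles.
    Each run draws fresh random counterexamples from the pooled segment
    embeddings for the concept CAVs and an independent pair of random
    draws for the null (random-vs-random) CAV.
    """
    if runs < 2:
        raise ValueError("need at least 2 runs for a p-value")
    if not concepts:
        raise ValueError("no concepts to score")
    rng = np.random.default_rng(seed)
    # the log-odds gradient is what increases the class-k prediction in a
    # 2-class softmax; it is fixed per CAV run, so compute it once per class
    grads = {k: cnn.class_gradient(model, layer, k, x, target="logodds")
             for k, x in eval_inputs.items()}

    n_pool = len(pool_embeddings)
    n_cex = min(n_counterexamples, max(2, n_pool // 2))
    scores = {(c.id, k): np.empty(runs) for c in concepts for k in eval_inputs}
    nulls = {k: np.empty(runs) for k in eval_inputs}
    concept_emb = {c.id: pool_embeddings[c.patch_indices] for c in concepts}

    for r in range(runs):
        cex = rng.choice(n_pool, size=n_cex, replace=False)
        for c in concepts:
            cav = train_cav(concept_emb[c.id], pool_embeddings[cex],
                            seed=r, layer=layer, run_index=r)
            for k in eval_inputs:
                scores[(c.id, k)][r] = tcav_score(grads[k] @ cav.v)
        ra = rng.choice(n_pool, size=n_cex, replace=False)
        rb = rng.choice(n_pool, size=n_cex, replace=False)
        try:
            null_cav = train_cav(pool_embeddings[ra], pool_embeddings[rb],
                                 seed=r, layer=layer, run_index=r)
            for k in eval_inputs:
                nulls[k][r] = tcav_score(grads[k] @ null_cav.v)
        except ValueError:
            for k in eval_inputs:
                nulls[k][r] = 0.5

    results = []
    for c in concepts:
        for k in eval_inputs:
            s = scores[(c.id, k)]
            p = _welch_p(s, nulls[k])
            results.append(TCAVResult(
                c.id, k, s, float(s.mean()), float(s.std(ddof=1)),
                p, bool(p < alpha), nulls[k].copy()))
    return results


def plot_scores(results: list[TCAVResult], path: str,
                class_names: dict[int, str] | None = None) -> None:
    """Grouped bar chart of mean TCAVQ with std whiskers; an asterisk
    marks statistically significant concepts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("no results to plot")
    class_names = class_names or {0: "negative", 1: "positive"}
    concept_ids = sorted({r.concept_id for r in results})
    classes = sorted({r.class_k for r in results})
    width = 0.8 / len(classes)
    fig, ax = plt.subplots(figsize=(1.6 * len(concept_ids) + 2, 4))
    xs = np.arange(len(concept_ids))
    for ci, k in enumerate(classes):
        rs = {r.concept_id: r for r in results if r.class_k == k}
        pos = xs + (ci - (len(classes) - 1) / 2) * width
        means = [rs[c].mean for c in concept_ids]
        stds = [rs[c].std for c in concept_ids]
        bars = ax.bar(pos, means, width=width, yerr=stds, capsize=3,
                      ecolor="black", label=class_names.get(k, str(k)))
        for b, c in zip(bars, concept_ids):
            if rs[c].significant:
                ax.text(b.get_x() + b.get_width() / 2,
                        min(1.02, rs[c].mean + rs[c].std + 0.03), "*",
                        ha="center", fontsize=14)
    ax.set_ylim(0, 1.12)
    ax.set_xticks(xs)
    ax.set_xticklabels([f"concept {c}" for c in concept_ids])
    ax.set_ylabel("TCAVQ")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
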