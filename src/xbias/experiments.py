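"""Orchestration of the five study configurations and bias-recovery checks.

Each experiment builds a dataset with one planted bias (and, where a
comparison is defined, an unbiased twin), trains the residual classifier
under the stated protocol, evaluates it on the slide-disjoint test
split, runs concept extraction + TCAV and Grad-CAM saliency, and applies
operational bias flags:

``dominance_shift``
    the negative ("absence-defined") class holds the majority of the
    significant concepts — the signature of class-ratio and sampling
    biases;
``marker_concept``
    a significant positive-class concept whose patches overlap the
    planted corner marker in >= 90% of cases;
``source_purity``
    a significant concept drawing all of its patches from a single
    source regime — the signature of a measurement bias.

The class-sampling-ratio experiment follows its own protocol: a fixed
epoch budget with early stopping and class weights disabled, because
class weighting or long training would let the model absorb the
imbalance.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ace, cnn, saliency, synthgen, tcav
from .synthgen import BiasConfig, ConfigurationError, GenParams, MarkerSpec

EXPERIMENTS = ("feature_vis", "class_ratio", "measurement", "sampling",
               "class_correlated")


@dataclass(frozen=True)
class ScaleConfig:
    """Problem sizes for one run; the defaults are the desk scale."""
    tile_size: int = 96
    n_slides: int = 30
    tiles_per_slide: int = 40
    max_epochs: int = 40
    ratio_epochs: int = 30          # fixed budget for the class-ratio protocol
    tcav_runs: int = 20
    k: int = 5
    ace_tiles: int = 30             # test tiles pooled for concept proposal
    eval_cap: int = 100             # class-k tiles scored per TCAV run
    min_members: int = 20
    min_tiles: int = 5
    n_counterexamples: int = 40


DESK = ScaleConfig()
# reduced sizes for quick replications (property tests, seed sweeps)
MINI = ScaleConfig(tile_size=64, n_slides=12, tiles_per_slide=14,
                   max_epochs=40, ratio_epochs=40, tcav_runs=20,
                   ace_tiles=14, eval_cap=60, min_members=10, min_tiles=4,
                   n_counterexamples=30)
PAPER = ScaleConfig(tile_size=256, max_epochs=100, ratio_epochs=100,
                    tcav_runs=100)


@dataclass
class ExperimentReport:
    experiment: str
    seed: int
    metrics_biased: cnn.Metrics
    metrics_unbiased: cnn.Metrics | None
    tcav_results: list[tcav.TCAVResult]
    concept_dominance: dict
    bias_flags: dict
    marker_overlap: dict | None = None
    source_purity: dict | None = None
    history: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self) -> str:
        payload = {
            "experiment": self.experiment,
            "seed": self.seed,
            "metrics_biased": self.metrics_biased.as_dict(),
            "metrics_unbiased": (self.metrics_unbiased.as_dict()
                                 if self.metrics_unbiased else None),
            "tcav": [r.as_dict() for r in self.tcav_results],
            "concept_dominance": self.concept_dominance,
            "bias_flags": self.bias_flags,
            "marker_overlap": self.marker_overlap,
            "source_purity": self.source_purity,
        }
        return json.dumps(payload, indent=2)


def derive_seeds(master: int) -> dict[str, int]:
    """Fan one master seed out to the pipeline stages (all < 2^31)."""
    state = np.random.SeedSequence(master).generate_state(5) & 0x7FFFFFFF
    names = ("data", "train", "ace", "tcav", "unbiased")
    return {n: int(s) for n, s in zip(names, state)}


# ---------------------------------------------------------------------
# decision checks
# ---------------------------------------------------------------------

def concept_dominance(results: list[tcav.TCAVResult],
                      threshold: float = 0.5) -> dict:
    """Per class, the share of significant concepts whose mean TCAVQ for
    that class exceeds the threshold; flags a dominance shift when the
    negative class holds the majority of significant concepts."""
    sig_ids = {r.concept_id for r in results if r.significant}
    if not sig_ids:
        return {"fractions": {}, "undefined": True, "shift": False,
                "n_significant": 0}
    counts = {k: 0 for k in sorted({r.class_k for r in results})}
    for cid in sig_ids:
        # a concept counts for the class where its influence is larger;
        # exact ties (e.g. both at the threshold) count for neither
        cand = [r for r in results if r.concept_id == cid and r.significant
                and r.mean > threshold]
        if not cand:
            continue
        best = max(cand, key=lambda r: r.mean)
        if sum(1 for r in cand if r.mean == best.mean) == 1:
            counts[best.class_k] += 1
    total = len(sig_ids)
    fractions = {k: c / total for k, c in counts.items()}
    return {"fractions": fractions, "undefined": False,
            "shift": fractions.get(0, 0.0) > 0.5, "n_significant": total}


def marker_overlap_check(concepts: list[ace.Concept],
                         mmask: np.ndarray) -> dict[int, float]:
    """Fraction of each concept's patches whose mask intersects the
    marker region."""
    out = {}
    for c in concepts:
        hits = sum(1 for p in c.patches if bool((p.mask & mmask).any()))
        out[c.id] = hits / len(c.patches) if c.patches else 0.0
    return out


def stratum_overlap_check(concepts: list[ace.Concept],
                          stratum_masks: dict[int, np.ndarray]
                          ) -> dict[int, float]:
    """Fraction of each concept's patches whose mask intersects the
    given stratum (e.g. collagen) on their source tile, using the
    generator's ground-truth masks."""
    out = {}
    for c in concepts:
        hits = 0
        for p in c.patches:
            m = stratum_masks.get(p.source_tile)
            if m is not None and bool((p.mask & m).any()):
                hits += 1
        out[c.id] = hits / len(c.patches) if c.patches else 0.0
    return out


def source_purity_check(concepts: list[ace.Concept],
                        tile_source: dict[int, str]) -> dict[int, float]:
    """Max over sources of the fraction of a concept's patches from that
    source."""
    out = {}
    for c in concepts:
        srcs = [tile_source[p.source_tile] for p in c.patches]
        if not srcs:
            out[c.id] = 0.0
            continue
        vals, counts = np.unique(srcs, return_counts=True)
        out[c.id] = float(counts.max() / counts.sum())
    return out


def _significant_for_class(results: list[tcav.TCAVResult], k: int,
                           threshold: float = 0.5) -> set[int]:
    return {r.concept_id for r in results
            if r.class_k == k and r.significant and r.mean > threshold}


# ---------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------

def _bias_for(name: str, scale: ScaleConfig) -> BiasConfig:
    kind = "none" if name == "feature_vis" else name
    return BiasConfig(kind=kind,
                      marker=MarkerSpec.default(scale.tile_size))


def _train_on(ds: synthgen.DatasetSplit, scale: ScaleConfig, name: str,
              seed: int, hsv: bool = False) -> tuple[cnn.TileCNN, pd.DataFrame]:
    xtr, ytr = synthgen.tiles_to_arrays(ds.train)
    xv, yv = synthgen.tiles_to_arrays(ds.val)
    model = cnn.build_model(cnn.ModelSpec(scale.tile_size), seed=seed)
    aug = cnn.AugmentConfig(hsv_jitter=hsv)
    if name == "class_ratio":
        cfg = cnn.TrainConfig(max_epochs=scale.ratio_epochs, early_stop=False,
                              class_weighting=False, seed=seed, augment=aug)
    else:
        cfg = cnn.TrainConfig(max_epochs=scale.max_epochs, early_stop=True,
                              patience=50, class_weighting=True, seed=seed,
                              augment=aug, stop_val_loss=5e-3)
    history = cnn.train(model, xtr, ytr, xv, yv, cfg)
    return model, history


def _balanced_sample(tiles: list[synthgen.Tile], n: int,
                     rng: np.random.Generator) -> list[synthgen.Tile]:
    pos = [t for t in tiles if t.y == 1]
    neg = [t for t in tiles if t.y == 0]
    half = n // 2
    pick = []
    for group in (pos, neg):
        take = min(half, len(group))
        idx = rng.choice(len(group), size=take, replace=False)
        pick.extend(group[i] for i in idx)
    return pick


def explain(model: cnn.TileCNN, ds: synthgen.DatasetSplit,
            scale: ScaleConfig, seeds: dict[str, int]
            ) -> tuple[ace.ConceptExtraction, list[tcav.TCAVResult]]:
    """ACE + TCAV on the test split."""
    rng = np.random.default_rng(seeds["ace"])
    ace_cfg = ace.ACEConfig(k=scale.k, min_members=scale.min_members,
                            min_tiles=scale.min_tiles)
    sample = _balanced_sample(ds.test, scale.ace_tiles, rng)
    extraction = ace.extract_concepts(model, sample, ace_cfg, seeds["ace"])
    if not extraction.concepts:
        return extraction, []
    eval_inputs = {}
    for k in (0, 1):
        tiles = [t for t in ds.test if t.y == k][:scale.eval_cap]
        x, _ = synthgen.tiles_to_arrays(tiles)
        eval_inputs[k] = x.astype(np.float32) / 255.0
    results = tcav.run_tcav(model, extraction.concepts,
                            extraction.embeddings, eval_inputs,
                            runs=scale.tcav_runs, seed=seeds["tcav"],
                            n_counterexamples=scale.n_counterexamples)
    return extraction, results


def run_experiment(name: str, seed: int = 0, scale: ScaleConfig = DESK,
                   outdir: str | None = None, with_unbiased: bool | None = None,
                   with_explanations: bool = True) -> ExperimentReport:
    """End-to-end run of one study configuration."""
    if name == "dataset_bias":
        raise ConfigurationError(
            "the patch-center dataset-bias design is excluded: concept "
            "patches carry no location context, so the method cannot "
            "surface a bias defined purely by position")
    if name not in EXPERIMENTS:
        raise ConfigurationError(f"unknown experiment {name!r}")
    if with_unbiased is None:
        with_unbiased = name in ("class_ratio", "sampling")

    seeds = derive_seeds(seed)
    params = GenParams(tile_size=scale.tile_size)
    hsv = name == "feature_vis"

    ds = synthgen.build_dataset(_bias_for(name, scale), scale.n_slides,
                                scale.tiles_per_slide, seeds["data"], params)
    model, history = _train_on(ds, scale, name, seeds["train"], hsv)
    xte, yte = synthgen.tiles_to_arrays(ds.test)
    metrics_biased = cnn.evaluate(model, xte, yte)

    metrics_unbiased = None
    unbiased_results: list[tcav.TCAVResult] = []
    if with_unbiased and name != "feature_vis":
        # paired control: same tile plan (minus the bias), same weight
        # init and training randomness — only the bias varies
        ds_u = synthgen.build_dataset(BiasConfig("none"), scale.n_slides,
                                      scale.tiles_per_slide, seeds["data"],
                                      params)
        model_u, _ = _train_on(ds_u, scale, name, seeds["train"], hsv)
        xte_u, yte_u = synthgen.tiles_to_arrays(ds_u.test)
        metrics_unbiased = cnn.evaluate(model_u, xte_u, yte_u)

    extraction = None
    results: list[tcav.TCAVResult] = []
    marker_overlap = source_purity = None
    if with_explanations:
        extraction, results = explain(model, ds, scale, seeds)
        mmask = synthgen.marker_mask(scale.tile_size,
                                     MarkerSpec.default(scale.tile_size))
        marker_overlap = marker_overlap_check(extraction.concepts, mmask)
        tile_source = {t.tile_id: t.source for t in ds.test}
        source_purity = source_purity_check(extraction.concepts, tile_source)

    dominance = concept_dominance(results)
    sig_pos = _significant_for_class(results, 1)
    sig_any = {r.concept_id for r in results if r.significant}
    flags = {
        "dominance_shift": bool(dominance["shift"]),
        "marker_concept": any(
            (marker_overlap or {}).get(cid, 0.0) >= 0.9 for cid in sig_pos),
        "source_purity": any(
            (source_purity or {}).get(cid, 0.0) >= 1.0 for cid in sig_any),
    }

    report = ExperimentReport(name, seed, metrics_biased, metrics_unbiased,
                              results, dominance, flags, marker_overlap,
                              source_purity, history)
    if outdir:
        _write_artifacts(report, extraction, model, ds, scale, outdir)
    return report


def _write_artifacts(report: ExperimentReport,
                     extraction: ace.ConceptExtraction | None,
                     model: cnn.TileCNN, ds: synthgen.DatasetSplit,
                     scale: ScaleConfig, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        fh.write(report.to_json())
    if report.history is not None:
        report.history.to_csv(os.path.join(outdir, "history.csv"), index=False)
    if report.tcav_results:
        tcav.plot_scores(report.tcav_results,
                         os.path.join(outdir, "tcavq_bars.png"))
    if extraction is not None:
        for c in extraction.concepts:
            ace.concept_gallery(c, os.path.join(outdir, f"concept_{c.id}.png"))
    for i, tile in enumerate(ds.test[:3]):
        hm = saliency.compute_heatmap(model, tile.pixels, 1, tile.tile_id)
        saliency.render(tile.pixels, hm,
                        os.path.join(outdir, f"saliency_{i}"))


def summarize(reports: list[ExperimentReport]) -> pd.DataFrame:
    """One row per experiment: metrics, metric deltas, and which bias
    flags fired."""
    if not reports:
        raise ValueError("no reports to summarize")
    rows = []
    for r in reports:
        row = {
            "experiment": r.experiment,
            "bacc_biased": r.metrics_biased.balanced_accuracy,
            "auc_biased": r.metrics_biased.auc,
            "bacc_unbiased": (r.metrics_unbiased.balanced_accuracy
                              if r.metrics_unbiased else np.nan),
            "auc_unbiased": (r.metrics_unbiased.auc
                             if r.metrics_unbiased else np.nan),
            "n_significant_concepts": r.concept_dominance.get("n_significant", 0),
        }
        row.update({f"flag_{k}": v for k, v in r.bias_flags.items()})
        rows.append(row)
    return pd.DataFrame(rows)
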