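"""End-to-end orchestration on synthetic or user-supplied data.

Chains the stages — simulate / load, preprocess, encode, label, train with
cross-validation, score, cluster, evaluate — and collects every figure-level
number into one JSON-serializable report keyed by a run manifest (config +
seeds), so a run can be reproduced exactly from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import assemble_input, cross_validate_ppi
from .clustering import ComplexDetector, write_clusters_gmt, write_clusters_long
from .elution import pad_profiles, preprocess
from .fcgr import FCGREncoder
from .labels import make_folds
from .metrics import (
    bootstrap_null,
    colocalization_score,
    composite_score,
    gogo_cluster_score,
    representation_separation,
)
from .nn import ModelConfig
from .saliency import categorize, saliency_map
from .simulate import SimConfig, simulate_dataset

__all__ = ["default_model_config", "run_synthetic_pipeline", "random_cluster_null"]


def default_model_config(seed: int = 0) -> ModelConfig:
    """Compact training configuration used by the worked examples.

    Eight filters and a (64, 16, 1) head keep a full 5-fold run on the
    default synthetic study (200 proteins, 20 complexes) in the minutes
    range on one CPU while the planted signal is still recovered cleanly.
    """
    return ModelConfig(
        n_filters=8,
        fc_sizes=(64, 16, 1),
        epochs=60,
        batch_size=128,
        learning_rate=1e-3,
        seed=seed,
    )


def random_cluster_null(
    clusters,
    reference,
    universe: list[str],
    n_random: int = 1000,
    seed: int = 0,
) -> dict:
    """Empirical composite-score null from size-matched random clusterings.

    Each replicate redraws every cluster as a uniform sample (without
    replacement) of matched size from the clustered-protein universe and
    recomputes the composite score; the p-value is the fraction of
    replicates reaching the observed composite (add-one corrected).
    """
    rng = np.random.default_rng(seed)
    sizes = [len(c) for c in clusters]
    observed = composite_score(clusters, reference)["composite"]
    universe = list(universe)
    null = np.empty(n_random)
    for r in range(n_random):
        fake = [
            frozenset(rng.choice(universe, size=s, replace=False)) for s in sizes
        ]
        null[r] = composite_score(fake, reference)["composite"]
    p = (1 + int(np.sum(null >= observed))) / (n_random + 1)
    return {
        "observed_composite": float(observed),
        "null_mean": float(null.mean()),
        "null_max": float(null.max()),
        "empirical_p": float(p),
        "n_random": n_random,
    }


def run_synthetic_pipeline(
    sim_cfg: SimConfig | None = None,
    model_cfg: ModelConfig | None = None,
    k_folds: int = 5,
    deep_split: int = 2,
    n_random_clusterings: int = 1000,
    n_saliency_pairs: int = 100,
    bootstrap_reps: int = 100_000,
    outdir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Full worked example on one seeded synthetic dataset.

    Returns a nested report: per-fold and mean classification metrics,
    composite-score components against the planted catalog, the random-
    clustering null, mean GOGO (BP) and colocalization scores of the
    predicted clusters, a size-matched bootstrap test of the colocalization
    scores, representation separation, and saliency category counts.
    """
    sim_cfg = sim_cfg or SimConfig(seed=seed)
    model_cfg = model_cfg or default_model_config(seed=seed)

    ds = simulate_dataset(sim_cfg)
    E = preprocess(ds.elution)
    Ep = pad_profiles(E, target_len=200)
    encoder = FCGREncoder()
    seqs = {pid: ds.sequences[pid] for pid in Ep.protein_ids}
    fcgr = encoder.fit(seqs).transform(seqs)
    X = assemble_input(Ep, fcgr)

    labels = ds.truth_pairs()
    folds = make_folds(labels, k=k_folds, seed=seed)
    clf, fold_table = cross_validate_ppi(X, Ep.protein_ids, folds, model_cfg)

    # score every pair the labeler produced (train, test and experimental)
    index = {p: i for i, p in enumerate(Ep.protein_ids)}
    all_pairs = folds.pairs
    pair_idx = np.column_stack([
        all_pairs["protein_a"].map(index).to_numpy(),
        all_pairs["protein_b"].map(index).to_numpy(),
    ])
    scores = clf.decision_function(pair_idx)
    edges = pd.DataFrame({
        "protein_a": all_pairs["protein_a"],
        "protein_b": all_pairs["protein_b"],
        "label_origin": np.where(
            all_pairs["label"] == "experimental", "experimental",
            np.where(all_pairs["fold"].notna(), "train", "unused"),
        ),
        "score": scores,
    })

    detector = ComplexDetector(deep_split=deep_split).fit(edges)
    clusters = detector.clusters_
    reference = ds.catalog.restrict(Ep.protein_ids).filter_min_size(3)
    comp = composite_score(clusters.clusters, reference)
    null = random_cluster_null(
        clusters.clusters,
        reference,
        detector.adjacency_.node_ids,
        n_random=n_random_clusterings,
        seed=seed + 1,
    )

    gogo_scores = [
        s for s in (
            gogo_cluster_score(c, ds.godag, "BP") for c in clusters.clusters
        ) if s is not None
    ]
    coloc_scores, coloc_sizes = [], []
    for c in clusters.clusters:
        s = colocalization_score(c, ds.localizations)
        if s is not None:
            coloc_scores.append(s)
            coloc_sizes.append(len(c))

    # size-matched bootstrap null of colocalization, background = random sets
    rng = np.random.default_rng(seed + 2)
    pool_sizes = sorted(set(coloc_sizes))
    pool = {
        s: [
            colocalization_score(
                rng.choice(Ep.protein_ids, size=s, replace=False), ds.localizations
            )
            for _ in range(20)
        ]
        for s in pool_sizes
    }
    boot = bootstrap_null(
        coloc_scores, coloc_sizes, pool, n_boot=bootstrap_reps, seed=seed + 3
    )

    reps = clf.protein_representations()
    sep = representation_separation(reps, Ep.protein_ids, reference)

    test_like = all_pairs[all_pairs["label"].isin(["positive", "negative"])]
    take = min(n_saliency_pairs, len(test_like))
    sal_rng = np.random.default_rng(seed + 4)
    chosen = test_like.iloc[sal_rng.permutation(len(test_like))[:take]]
    categories: dict[str, int] = {}
    for a, b in zip(chosen["protein_a"], chosen["protein_b"]):
        profile = saliency_map(
            clf.network_, X, (index[a], index[b]),
            n_measured_fractions=E.original_fractions,
        )
        cat = categorize(profile)
        categories[cat] = categories.get(cat, 0) + 1

    report = {
        "manifest": {
            "sim_config": dataclasses.asdict(sim_cfg),
            "model_config": dataclasses.asdict(model_cfg),
            "k_folds": k_folds,
            "deep_split": deep_split,
            "seed": seed,
        },
        "classification": {
            "per_fold": fold_table.reset_index().to_dict(orient="records"),
            "mean": fold_table.mean(numeric_only=True).to_dict(),
        },
        "clustering": {
            "n_clusters": len(clusters),
            "cluster_sizes": clusters.sizes(),
            **comp,
            "random_null": null,
        },
        "gogo_bp_mean": float(np.mean(gogo_scores)) if gogo_scores else None,
        "colocalization_mean": (
            float(np.mean(coloc_scores)) if coloc_scores else None
        ),
        "colocalization_bootstrap": boot,
        "representation_separation_p": sep["test_p"],
        "saliency_categories": categories,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        write_clusters_gmt(clusters, outdir / "clusters.gmt")
        write_clusters_long(clusters, outdir / "clusters_long.tsv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
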