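"""Two-stage pipeline orchestration.

Stage 1 (clustering): read/preprocess views -> train the shared-representation
model -> Cox-screen the embedding -> k-means with model selection -> log-rank
report.  Stage 2 (classification): scale/bin one view, prune features by
RF-RFE, tune a boosted-tree classifier.  Validation: push an external view
through the stored scaler/bins/model and, if survival is available, test the
prognostic separation of the predicted subtypes.  One seed in the config
determines every stochastic component.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, clustering, preprocess, views
from . import gcca as gcca_mod

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    view_paths: dict = field(default_factory=dict)      # name -> TSV path
    survival_path: str = ""
    annotation_path: str | None = None                  # promoter TSV, optional
    methylation_view: str | None = None                 # view to collapse probes on
    zeros_as_missing: dict = field(default_factory=dict)  # per view, default False
    log_transform_views: list = field(default_factory=list)
    feature_frac: float = 0.2
    sample_frac: float = 0.2
    knn_k: int = 10
    gcca: gcca_mod.GccaConfig = field(default_factory=gcca_mod.GccaConfig)
    network: gcca_mod.ViewNetworkConfig = field(default_factory=gcca_mod.ViewNetworkConfig)
    alpha: float = 0.05
    k_range: list = field(default_factory=lambda: [2, 3, 4, 5, 6])
    n_init: int = 100
    max_iter: int = 2000
    classify_view: str = "expression"
    n_bins: int = 30
    folds: int = 10
    repeats: int = 10
    budget: int = 50
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("gcca", gcca_mod.GccaConfig), ("network", gcca_mod.ViewNetworkConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def load_dataset(config: PipelineConfig) -> views.MultiOmicsDataset:
    """Read, preprocess and assemble the views named in the config."""
    if not Path(config.survival_path).exists():
        raise FileNotFoundError(f"survival file not found: {config.survival_path}")
    for name, p in config.view_paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"view {name!r} file not found: {p}")
    survival = views.read_survival(config.survival_path)
    annot = (
        views.read_promoter_annotation(config.annotation_path)
        if config.annotation_path
        else None
    )
    processed = []
    for name, path in config.view_paths.items():
        view = views.read_omics_view(path, name)
        if annot is not None and name == config.methylation_view:
            view = preprocess.average_promoter_probes(view, annot)
        view = preprocess.filter_missingness(
            view,
            feature_frac=config.feature_frac,
            sample_frac=config.sample_frac,
            zeros_as_missing=config.zeros_as_missing.get(name, False),
        )
        if view.missing_mask.any():
            view = preprocess.knn_impute(view, k=config.knn_k)
        if name in config.log_transform_views:
            view = preprocess.log_transform(view)
        processed.append(view)
    return preprocess.assemble_dataset(processed, survival)


def run_cluster_stage(config: PipelineConfig, dataset=None) -> dict:
    """Preprocess -> DGCCA -> Cox filter -> select_k -> log-rank; persist all."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        dataset = load_dataset(config)
    log.info("cluster stage: %d samples, %d views, seed %d",
             dataset.n_samples, dataset.n_views, config.seed)
    cfg = dataclasses.replace(config.gcca, seed=config.seed)
    model = gcca_mod.train_dgcca(dataset, config.network, cfg)
    gcca_mod.save_model(model, out / "dgcca_model.zip")
    embedding = gcca_mod.embed_samples(model, dataset)
    emb_df = pd.DataFrame(
        embedding, index=dataset.sample_ids,
        columns=[f"dim_{j + 1}" for j in range(embedding.shape[1])],
    )
    emb_df.to_csv(out / "embedding.tsv", sep="\t", index_label="sample_id")

    filtered, cox_results = clustering.filter_embedding(
        embedding, dataset.survival, alpha=config.alpha
    )
    pd.DataFrame(
        [dataclasses.asdict(r) for r in cox_results]
    ).to_csv(out / "cox_filter.tsv", sep="\t", index=False)

    sel = clustering.select_k(
        filtered, k_range=config.k_range, n_init=config.n_init,
        max_iter=config.max_iter, seed=config.seed,
    )
    sel.diagnostics.to_csv(out / "cluster_diagnostics.tsv", sep="\t", index=False)
    best = sel.models[sel.k_best]
    assign = pd.DataFrame(
        {"sample_id": dataset.sample_ids, "subtype": best.labels}
    )
    assign.to_csv(out / "assignments.tsv", sep="\t", index=False)

    comparison = clustering.logrank_groups(best.labels, dataset.survival)
    for g, curve in comparison.km_curves.items():
        curve.to_csv(out / f"km_group_{g}.tsv", sep="\t", index=False)
    report = (
        f"k_best\t{sel.k_best}\n"
        f"coordinates_selected\t{filtered.shape[1]}\n"
        f"logrank_chi2\t{comparison.chi2:.6g}\n"
        f"logrank_df\t{comparison.df}\n"
        f"logrank_p\t{comparison.p_value:.6g}\n"
    )
    (out / "survival_report.txt").write_text(report)
    return {
        "dataset": dataset, "model": model, "embedding": embedding,
        "filtered": filtered, "cox_results": cox_results, "selection": sel,
        "assignments": assign, "survival_comparison": comparison,
    }


def run_classify_stage(config: PipelineConfig, dataset, assignments,
                       external_reference=None) -> classify.SubtypeClassifier:
    """Scale -> bin -> RF-RFE -> tuned XGBoost on one view; archive the model."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    view = dataset.view(config.classify_view)
    assign = assignments.set_index("sample_id")["subtype"]
    unknown = [s for s in assign.index if s not in set(dataset.sample_ids)]
    if unknown:
        raise ValueError(f"assignments contain unknown samples: {unknown[:10]}")
    present = dataset.presence[:, [v.name for v in dataset.views].index(view.name)]
    keep = [s for s, p in zip(dataset.sample_ids, present) if p and s in assign.index]
    view = view.subset(samples=keep)
    labels = assign.loc[keep].to_numpy()
    if external_reference is not None:
        common = classify.intersect_features(view, external_reference)
        view = view.subset(features=common)
        log.info("restricted to %d features shared with the external cohort",
                 len(common))

    scaler = classify.fit_scaler(view)
    z = scaler.transform(view.values)
    bins = classify.fit_bins(z, config.n_bins, feature_ids=view.feature_ids)
    binned = pd.DataFrame(
        classify.apply_bins(bins, z).T, index=view.sample_ids,
        columns=view.feature_ids,
    )
    selection = classify.rf_rfe_select(
        binned, labels, folds=config.folds, repeats=config.repeats, seed=config.seed
    )
    selection.cv_curve.to_csv(out / "rfe_curve.tsv", sep="\t", index=False)
    clf = classify.tune_train_classifier(
        binned[selection.selected], labels, folds=config.folds,
        budget=config.budget, seed=config.seed, scaler=scaler, binning=bins,
    )
    classify.save_classifier(clf, out / "classifier.pkl")
    (out / "cv_metrics.txt").write_text(
        f"accuracy\t{clf.cv_accuracy:.4f}\nauc\t{clf.cv_auc:.4f}\n"
        f"n_features\t{len(clf.selected_features)}\n"
    )
    return clf


def run_validate_stage(config: PipelineConfig, clf, external_view,
                       external_survival=None) -> dict:
    """Predict subtypes on an external cohort; log-rank if survival given."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    preds = classify.predict_subtypes(clf, external_view)
    preds.to_csv(out / "predictions.tsv", sep="\t", index=False)
    result = {"predictions": preds}
    if external_survival is not None:
        surv = external_survival.subset(list(preds["sample_id"]))
        comparison = clustering.logrank_groups(preds["subtype"].to_numpy(), surv)
        (out / "validation_survival_report.txt").write_text(
            f"logrank_chi2\t{comparison.chi2:.6g}\n"
            f"logrank_df\t{comparison.df}\n"
            f"logrank_p\t{comparison.p_value:.6g}\n"
        )
        result["survival_comparison"] = comparison
    return result
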