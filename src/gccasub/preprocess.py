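"""Preprocessing of raw per-view matrices.

The order used by the pipeline mirrors standard multi-omics practice:
methylation probes are collapsed to gene promoters (mean beta-value over
TSS200/TSS1500 probes), features and then samples with excessive missingness
are dropped, remaining gaps are imputed by k-nearest-neighbour features, and
count-like views are log2-transformed to make scales commensurate across
views.  Finally the views are assembled over the union of their sample sets;
samples missing an entire view are kept and flagged, not discarded.
"""

from __future__ import annotations

import logging

import numpy as np

from .views import MultiOmicsDataset, OmicsDataError, OmicsView, PromoterAnnotation, SurvivalTable

log = logging.getLogger(__name__)


def average_promoter_probes(view: OmicsView, annot: PromoterAnnotation) -> OmicsView:
    """Collapse probe-level beta-values to one mean value per gene promoter.

    Only probes annotated to a TSS200/TSS1500 promoter region are used; the
    gene value is the arithmetic mean of its probes' beta-values, ignoring
    missing entries.  Unannotated probes are dropped.
    """
    by_gene = annot.genes_for(view.feature_ids)
    if not by_gene:
        raise OmicsDataError(
            f"view {view.name!r}: no probe overlaps the promoter annotation"
        )
    fidx = {f: i for i, f in enumerate(view.feature_ids)}
    vals = view.values.copy()
    vals[view.missing_mask] = np.nan
    genes = sorted(by_gene)
    out = np.empty((len(genes), view.n_samples))
    for gi, gene in enumerate(genes):
        rows = [fidx[p] for p in by_gene[gene]]
        with np.errstate(invalid="ignore"):
            out[gi] = np.nanmean(vals[rows], axis=0)
    return OmicsView(
        name=view.name, feature_ids=genes, sample_ids=list(view.sample_ids), values=out
    )


def filter_missingness(
    view: OmicsView,
    feature_frac: float = 0.2,
    sample_frac: float = 0.2,
    zeros_as_missing: bool = False,
) -> OmicsView:
    """Drop features, then samples, with too high a missing(-or-zero) fraction.

    A feature is dropped when its fraction of missing (optionally: missing or
    exactly zero) entries exceeds ``feature_frac``; sample fractions are then
    recomputed over the surviving features and compared against
    ``sample_frac``.  The feature pass runs first, deterministically.
    """
    for frac, nm in ((feature_frac, "feature_frac"), (sample_frac, "sample_frac")):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{nm} must lie in [0, 1], got {frac}")
    bad = view.missing_mask.copy()
    if zeros_as_missing:
        bad |= view.values == 0
    keep_f = bad.mean(axis=1) <= feature_frac
    if not keep_f.any():
        raise OmicsDataError(
            f"view {view.name!r}: every feature exceeds the {feature_frac:.0%} "
            "missingness threshold; relax feature_frac"
        )
    keep_s = bad[keep_f].mean(axis=0) <= sample_frac
    if not keep_s.any():
        raise OmicsDataError(
            f"view {view.name!r}: every sample exceeds the {sample_frac:.0%} "
            "missingness threshold; relax sample_frac"
        )
    log.info(
        "filter_missingness(%s): dropped %d/%d features, %d/%d samples "
        "(feature_frac=%.2f, sample_frac=%.2f, zeros_as_missing=%s)",
        view.name, (~keep_f).sum(), view.n_features, (~keep_s).sum(), view.n_samples,
        feature_frac, sample_frac, zeros_as_missing,
    )
    return OmicsView(
        name=view.name,
        feature_ids=[f for f, k in zip(view.feature_ids, keep_f) if k],
        sample_ids=[s for s, k in zip(view.sample_ids, keep_s) if k],
        values=view.values[np.ix_(keep_f, keep_s)],
        missing_mask=view.missing_mask[np.ix_(keep_f, keep_s)],
    )


def knn_impute(view: OmicsView, k: int = 10) -> OmicsView:
    """Fill each missing cell from the sample-wise mean of the k nearest features.

    Neighbours are the fully-observed features; distance is plain Euclidean
    computed over the samples where the target feature is observed.  Observed
    cells are left bit-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = view.missing_mask
    if not mask.any():
        return view
    complete = ~mask.any(axis=1)
    if complete.sum() < k:
        raise OmicsDataError(
            f"view {view.name!r}: only {int(complete.sum())} fully-observed "
            f"features available as neighbours, need k={k}"
        )
    vals = view.values.copy()
    pool = vals[complete]  # (n_complete, n_samples)
    starved = []
    for f in np.where(mask.any(axis=1))[0]:
        obs = ~mask[f]
        if not obs.any():
            starved.append(view.feature_ids[f])
            continue
        diff = pool[:, obs] - vals[f, obs]
        dist = np.sqrt((diff * diff).sum(axis=1))
        nearest = np.argsort(dist, kind="stable")[:k]
        vals[f, mask[f]] = pool[nearest][:, mask[f]].mean(axis=0)
    if starved:
        raise OmicsDataError(
            f"view {view.name!r}: features with no observed samples to compute "
            f"distances from: {starved}"
        )
    return OmicsView(
        name=view.name,
        feature_ids=list(view.feature_ids),
        sample_ids=list(view.sample_ids),
        values=vals,
        missing_mask=np.zeros_like(mask),
    )


def log_transform(view: OmicsView, offset: float = 1.0) -> OmicsView:
    """Elementwise log2(value + offset); offset defaults to a pseudocount of 1."""
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    shifted = view.values + offset
    observed_bad = (shifted <= 0) & ~view.missing_mask
    if observed_bad.any():
        f, s = np.argwhere(observed_bad)[0]
        raise OmicsDataError(
            f"view {view.name!r}: value {view.values[f, s]} + offset {offset} is "
            f"nonpositive at feature {view.feature_ids[f]!r}, sample "
            f"{view.sample_ids[s]!r}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log2(shifted)
    return OmicsView(
        name=view.name,
        feature_ids=list(view.feature_ids),
        sample_ids=list(view.sample_ids),
        values=out,
        missing_mask=view.missing_mask.copy(),
    )


def assemble_dataset(views: list[OmicsView], survival: SurvivalTable) -> MultiOmicsDataset:
    """Align views over the union of their sample sets and attach survival.

    Samples absent from a view keep a NaN column there and are flagged absent
    in the presence mask; the union, not the intersection, is the cohort.
    """
    if not views:
        raise OmicsDataError("need at least one view")
    universe: list[str] = []
    seen: set[str] = set()
    for v in views:
        for s in v.sample_ids:
            if s not in seen:
                seen.add(s)
                universe.append(s)
    missing_surv = [s for s in universe if s not in set(survival.sample_ids)]
    if missing_surv:
        raise OmicsDataError(f"samples without survival record: {missing_surv}")
    presence = np.zeros((len(universe), len(views)), dtype=bool)
    aligned = []
    for j, v in enumerate(views):
        pos = {s: i for i, s in enumerate(v.sample_ids)}
        vals = np.full((v.n_features, len(universe)), np.nan)
        msk = np.ones((v.n_features, len(universe)), dtype=bool)
        for i, s in enumerate(universe):
            if s in pos:
                presence[i, j] = True
                vals[:, i] = v.values[:, pos[s]]
                msk[:, i] = v.missing_mask[:, pos[s]]
        aligned.append(
            OmicsView(v.name, list(v.feature_ids), list(universe), vals, msk)
        )
    return MultiOmicsDataset(
        views=aligned,
        presence=presence,
        survival=survival.subset(universe),
        sample_ids=universe,
    )
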