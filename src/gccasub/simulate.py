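"""Synthetic multi-omics cohorts with planted, survival-linked subtypes.

The generator emulates the statistical structure the pipeline assumes: K
latent subtypes whose means sit ``cluster_separation`` apart in a shared
latent space; each view observes a fixed random nonlinear mixing
``A_v softplus(B_v h)`` of the latent factors on a fraction of its features
(the rest are pure noise); survival is exponential with a hazard that
multiplies by ``hazard_ratio`` per subtype, under independent uniform
censoring calibrated to a target censoring fraction; and each sample may drop
entire views at random while always retaining at least one.  A companion
generator produces a platform-shifted external cohort: new samples from the
same process, a partial feature overlap, and a per-feature strictly monotone
warp (affine plus bounded tanh) with fresh noise — the microarray-vs-RNA-seq
situation the rank-based discretization is designed to survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .views import MultiOmicsDataset, OmicsView, SurvivalTable
from .preprocess import assemble_dataset

__all__ = [
    "SimulationConfig", "SyntheticCohort", "ExternalCohort",
    "simulate_cohort", "simulate_platform_shift", "null_cohort", "write_cohort",
]

VIEW_NAMES = ("expression", "methylation", "mirna")


@dataclass
class SimulationConfig:
    """Cohort-generating parameters; defaults are the study conditions used
    throughout the tests (n=300, K=2, separation 8, HR 3, 10% missing views,
    30% censoring)."""

    n_samples: int = 300
    n_clusters: int = 2
    view_dims: tuple = (2000, 1500, 200)
    latent_dim: int = 10
    cluster_separation: float = 8.0
    shared_signal_frac: float = 0.3
    noise_sd: float = 0.5
    missing_view_rate: float = 0.1
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("need K >= 1 clusters")
        if self.n_clusters > self.latent_dim:
            raise ValueError("latent_dim must be >= n_clusters to place the means")
        if any(d < 1 for d in self.view_dims):
            raise ValueError("view dims must be positive")
        if not 0 <= self.missing_view_rate < 1:
            raise ValueError("missing_view_rate must lie in [0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0 <= self.shared_signal_frac <= 1:
            raise ValueError("shared_signal_frac must lie in [0, 1]")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")


@dataclass
class SyntheticCohort:
    dataset: MultiOmicsDataset
    true_labels: np.ndarray          # 1..K per sample
    latent: np.ndarray               # n x latent_dim generating factors
    cfg: SimulationConfig
    mixing: dict = field(default_factory=dict)   # per view: (A, B, shared rows)


@dataclass
class ExternalCohort:
    view: OmicsView
    true_labels: np.ndarray
    survival: SurvivalTable
    warp: dict = field(default_factory=dict)     # per feature: (a, b, c)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _censoring_horizon(lams: np.ndarray, probs: np.ndarray, target: float) -> float:
    """Solve for u with censoring C ~ U(0, u): mix_k P(C < T_k) = target,
    where P(C < T) = (1 - exp(-lam u)) / (lam u) for T ~ Exp(lam)."""

    def frac(u):
        return float(np.dot(probs, (1.0 - np.exp(-lams * u)) / (lams * u)) - target)

    lo, hi = 1e-9, 1.0
    while frac(hi) > 0:
        hi *= 10.0
        if hi > 1e12:
            raise ValueError(f"censoring target {target} infeasible")
    return brentq(frac, lo, hi)


def _cluster_means(k: int, dim: int, sep: float) -> np.ndarray:
    """K means with all pairwise distances exactly ``sep`` (scaled simplex)."""
    mu = np.zeros((k, dim))
    for i in range(k):
        mu[i, i] = sep / np.sqrt(2.0)
    return mu - mu.mean(axis=0)


def _survival_from_labels(labels, cfg, rng) -> SurvivalTable:
    lams = cfg.baseline_hazard * cfg.hazard_ratio ** np.arange(cfg.n_clusters)
    lam = lams[labels - 1]
    t = rng.exponential(1.0 / lam)
    if cfg.censoring_rate > 0:
        probs = np.bincount(labels - 1, minlength=cfg.n_clusters) / len(labels)
        u = _censoring_horizon(lams, probs, cfg.censoring_rate)
        c = rng.uniform(0.0, u, size=len(labels))
        event = (t <= c).astype(int)
        time = np.minimum(t, c)
    else:
        event = np.ones(len(labels), dtype=int)
        time = t
    sample_ids = [f"S{i:04d}" for i in range(len(labels))]
    return SurvivalTable(sample_ids, np.maximum(time, 1e-9), event)


def _view_matrix(h, dim, shared_frac, noise_sd, rng):
    """One view: shared-signal rows A softplus(B h) + noise, noise-only rest."""
    n, latent_dim = h.shape
    n_shared = int(round(shared_frac * dim))
    b = rng.normal(0.0, 1.0 / np.sqrt(latent_dim), size=(latent_dim, latent_dim))
    a = rng.normal(0.0, 1.0 / np.sqrt(latent_dim), size=(n_shared, latent_dim))
    x = rng.normal(0.0, 1.0, size=(dim, n))
    signal = a @ _softplus(b @ h.T)
    x[:n_shared] = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return x, a, b, n_shared


def simulate_cohort(cfg: SimulationConfig | None = None, **overrides) -> SyntheticCohort:
    """Draw a complete cohort: views, presence mask, survival, true labels."""
    cfg = replace(cfg or SimulationConfig(), **overrides)
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_samples, cfg.n_clusters
    labels = rng.integers(1, k + 1, size=n)
    mu = _cluster_means(k, cfg.latent_dim, cfg.cluster_separation)
    h = mu[labels - 1] + rng.normal(size=(n, cfg.latent_dim))
    survival = _survival_from_labels(labels, cfg, rng)
    sample_ids = survival.sample_ids

    views, mixing = [], {}
    for v, dim in enumerate(cfg.view_dims):
        name = VIEW_NAMES[v] if v < len(VIEW_NAMES) else f"view{v}"
        x, a, b, n_shared = _view_matrix(
            h, dim, cfg.shared_signal_frac, cfg.noise_sd, rng
        )
        feature_ids = [f"{name}_g{i:05d}" for i in range(dim)]
        views.append(OmicsView(name, feature_ids, sample_ids, x))
        mixing[name] = {"A": a, "B": b, "n_shared": n_shared}

    # drop whole views per sample, guaranteeing >= 1 retained
    presence = rng.uniform(size=(n, len(views))) >= cfg.missing_view_rate
    for i in np.where(~presence.any(axis=1))[0]:
        presence[i, rng.integers(len(views))] = True
    kept_views = [
        view.subset(samples=[s for s, keep in zip(sample_ids, presence[:, j]) if keep])
        for j, view in enumerate(views)
    ]
    dataset = assemble_dataset(kept_views, survival)
    # assemble uses first-seen order; re-align truth to its universe
    order = [sample_ids.index(s) for s in dataset.sample_ids]
    return SyntheticCohort(
        dataset=dataset,
        true_labels=labels[order],
        latent=h[order],
        cfg=cfg,
        mixing=mixing,
    )


def null_cohort(cfg: SimulationConfig | None = None, **overrides) -> SyntheticCohort:
    """No structure: zero separation and hazard ratio 1 (type-I calibration)."""
    cfg = replace(cfg or SimulationConfig(), **overrides)
    return simulate_cohort(cfg, cluster_separation=0.0, hazard_ratio=1.0)


def simulate_platform_shift(
    cohort: SyntheticCohort,
    view_name: str | None = None,
    overlap_frac: float = 0.65,
    shift_scale: float = 1.0,
    warp_strength: float = 0.5,
    new_noise_sd: float = 0.5,
    n_samples: int | None = None,
    seed: int = 1,
) -> ExternalCohort:
    """External cohort on a 'different platform' for one view.

    New samples are drawn from the same generative process; a random
    ``overlap_frac`` of the view's features is retained; each kept feature is
    warped by x -> a x + b + c tanh(x) with |c| < a (strictly monotone) and
    fresh measurement noise is added.
    """
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must lie in (0, 1]")
    if not 0 <= warp_strength < 1:
        raise ValueError(
            f"warp_strength={warp_strength} would break monotonicity (need < 1)"
        )
    cfg = cohort.cfg
    view_name = view_name or cohort.dataset.views[0].name
    ref = cohort.dataset.view(view_name)
    mix = cohort.mixing[view_name]
    rng = np.random.default_rng(seed)
    n = n_samples or cfg.n_samples

    labels = rng.integers(1, cfg.n_clusters + 1, size=n)
    mu = _cluster_means(cfg.n_clusters, cfg.latent_dim, cfg.cluster_separation)
    h = mu[labels - 1] + rng.normal(size=(n, cfg.latent_dim))
    survival = _survival_from_labels(labels, cfg, rng)
    survival = SurvivalTable(
        [f"E{i:04d}" for i in range(n)], survival.time, survival.event
    )

    dim = ref.n_features
    x = rng.normal(0.0, 1.0, size=(dim, n))
    signal = mix["A"] @ _softplus(mix["B"] @ h.T)
    x[: mix["n_shared"]] = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)

    keep = np.sort(rng.choice(dim, size=int(round(overlap_frac * dim)), replace=False))
    warp = {}
    warped = np.empty((len(keep), n))
    for row, fi in enumerate(keep):
        a = float(np.exp(rng.normal(0.0, 0.3)))
        b = float(rng.normal(0.0, shift_scale))
        c = float(rng.uniform(-warp_strength, warp_strength) * a)
        warped[row] = a * x[fi] + b + c * np.tanh(x[fi])
        warp[ref.feature_ids[fi]] = (a, b, c)
    warped += rng.normal(0.0, new_noise_sd, size=warped.shape)

    view = OmicsView(
        name=f"{view_name}_external",
        feature_ids=[ref.feature_ids[i] for i in keep],
        sample_ids=list(survival.sample_ids),
        values=warped,
    )
    return ExternalCohort(view=view, true_labels=labels, survival=survival, warp=warp)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Persist a cohort in the TSV formats the readers consume; returns paths."""
    from pathlib import Path
    import pandas as pd
    from .views import write_omics_view, write_survival

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for j, view in enumerate(cohort.dataset.views):
        pres = cohort.dataset.presence[:, j]
        sub = view.subset(samples=[s for s, p in zip(view.sample_ids, pres) if p])
        p = out / f"{view.name}.tsv"
        write_omics_view(sub, p)
        paths[view.name] = p
    paths["survival"] = out / "survival.tsv"
    write_survival(cohort.dataset.survival, paths["survival"])
    paths["truth"] = out / "truth.tsv"
    pd.DataFrame(
        {"sample_id": cohort.dataset.sample_ids, "cluster": cohort.true_labels}
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
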