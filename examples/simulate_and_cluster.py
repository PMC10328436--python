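"""Discover survival-linked subtypes in a simulated multi-omics cohort.

Generates a cohort with two planted subtypes (different hazards), learns the
shared deep-GCCA representation across the three views, screens its
coordinates for survival association, clusters the survival-linked
coordinates, and reports how well the planted structure is recovered.
"""

from sklearn.metrics import adjusted_rand_score

from gccasub import (
    GccaConfig,
    embed_samples,
    filter_embedding,
    logrank_groups,
    select_k,
    simulate_cohort,
    train_dgcca,
)
from gccasub.simulate import SimulationConfig

# smaller views than the defaults so the example runs in a few seconds
cfg = SimulationConfig(n_samples=200, view_dims=(200, 150, 60), seed=0)
cohort = simulate_cohort(cfg)
ds = cohort.dataset
print(f"cohort: {ds.n_samples} samples, {ds.n_views} views, "
      f"{(~ds.presence).sum()} missing sample-view pairs")

model = train_dgcca(ds, None, GccaConfig(embedding_dim=50, view_rank=50, seed=0))
embedding = embed_samples(model, ds)

filtered, cox = filter_embedding(embedding, ds.survival, alpha=0.05)
print(f"Cox screen kept {filtered.shape[1]}/{embedding.shape[1]} coordinates")

selection = select_k(filtered, k_range=range(2, 7), seed=0)
print(selection.diagnostics.round(3).to_string(index=False))
labels = selection.models[selection.k_best].labels

comp = logrank_groups(labels, ds.survival)
ari = adjusted_rand_score(cohort.true_labels, labels)
print(f"chose k={selection.k_best}; ARI vs planted truth = {ari:.3f}; "
      f"log-rank chi2={comp.chi2:.1f} (p={comp.p_value:.2e})")
# k=2 with a high ARI and a tiny log-rank p means the pipeline found the two
# planted subtypes and they differ in survival, as constructed.
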