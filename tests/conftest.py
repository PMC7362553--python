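import numpy as np
import pytest

from boostgrn import (
    BoostConfig,
    ExpressionDataset,
    ExpressionSeries,
    LagConfig,
    PriorConfig,
    SyntheticNetworkSpec,
    compute_prior,
    evaluate,
    fuse_prior,
    generate,
    importance_for_all_targets,
    normalize_l2,
    rank_edges,
    variance_update,
)


def make_dataset(n_genes=4, n_timepoints=6, n_series=2, seed=0, regulator_ids=None):
    """Small random expression dataset for unit tests."""
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1}" for i in range(n_genes)]
    series = [
        ExpressionSeries(
            gene_ids=list(gene_ids),
            times=np.arange(n_timepoints, dtype=float),
            values=rng.uniform(0.0, 2.0, size=(n_timepoints, n_genes)),
        )
        for _ in range(n_series)
    ]
    ds = ExpressionDataset(series=series)
    if regulator_ids is not None:
        ds = ds.with_regulators(regulator_ids)
    return ds


@pytest.fixture(scope="session")
def recovery_study():
    """Inference results on 10 seeded benchmarks at the reduced study size.

    Runs the full pipeline (20 genes, 40 edges, 5 series x 21 points,
    noise sd 0.1; boosting reduced to 200 trees at eta 0.05) once per seed
    and returns per-seed metrics with and without knockout-prior fusion.
    Shared across the recovery and prior-benefit checks so the fits are
    done only once.
    """
    lag = LagConfig()
    out = []
    for seed in range(10):
        bench = generate(SyntheticNetworkSpec(seed=seed))
        boost = BoostConfig(n_trees=200, eta=0.05, seed=seed)
        raw = importance_for_all_targets(bench.data, lag, boost)
        plain = variance_update(normalize_l2(raw))
        aupr, auroc = evaluate(rank_edges(plain), bench.truth)
        fused = normalize_l2(raw)
        prior = compute_prior(
            bench.knockout, fused.regulator_ids, fused.target_ids,
            PriorConfig(fuse_knockout=True),
        )
        fused = variance_update(fuse_prior(fused, prior))
        aupr_prior, auroc_prior = evaluate(rank_edges(fused), bench.truth)
        prevalence = len(bench.truth.edges) / len(bench.truth.universe)
        out.append(
            dict(seed=seed, aupr=aupr, auroc=auroc, aupr_prior=aupr_prior,
                 auroc_prior=auroc_prior, prevalence=prevalence)
        )
    return out
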