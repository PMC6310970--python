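"""Reduced-scale validation experiments.

Desk-scale counterparts of the method's studies, run on synthetic data with
planted ground truth. Each experiment fixes its own problem size and search
budget (documented in the methods note) so the whole battery runs on one
CPU in minutes; the quantities they measure — filter counts, recovery of
planted features, optimizer correctness — are the package's checkable
claims.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .encoding import EncodingSpec
from .ga import GAConfig, evolve
from .importance import aggregate_runs
from .model import EMDAVSearch
from .nn import FitnessRecord, TrainConfig, init_model, train_rprop_plus
from .preprocess import low_information_filter, scale_dataset, validate_presence
from .synth import SynthSpec, generate, planted_filter_table

# Scaled-down search budget: population 10, up to 10 generations, at most
# 2 hidden layers of at most 32 nodes, 200 training epochs. Per-bit
# mutation, no dropout and 3 hold-out repetitions keep the fitness signal
# informative at this tiny budget.
RECOVERY_GA = GAConfig(population_size=10, max_generations=10,
                       stall_generations=10, n_holdout_repetitions=3,
                       k_folds=3, mutation_mode="per_bit")
RECOVERY_TRAIN = TrainConfig(max_epochs=200, dropout_rate=0.0, patience=20)
RECOVERY_ENCODING = EncodingSpec(n_feature_bits=20, layer_field_bits=1,
                                 node_field_bits=5)


def recovery_dataset(seed: int):
    """200 x 20 synthetic dataset, 4 informative features, no structural
    zeros (the filters are exercised elsewhere; here the search is)."""
    return generate(SynthSpec(n_samples=200, n_features=20, n_informative=4,
                              zero_inflation=0.0, all_zero_fraction=0.0,
                              noise_sd=0.05, seed=seed))


def planted_recovery_run(seed: int) -> dict:
    """One scaled-down evolutionary search on a planted dataset.

    Returns the number of planted features in the best genome's mask (of 4)
    plus the best fitness trace.
    """
    ds = recovery_dataset(100 + seed)
    scaled, _ = scale_dataset(ds)
    res = evolve(scaled, replace(RECOVERY_GA, seed=seed),
                 replace(RECOVERY_TRAIN, seed=seed), RECOVERY_ENCODING)
    truth = set(ds.meta["informative_indices"])
    selected = {i for i, b in enumerate(res.best_phenotype.feature_mask) if b}
    return {"recovered": len(truth & selected),
            "n_planted": len(truth),
            "n_selected": len(selected),
            "best_mse": res.best_record.mean_mse,
            "best_trace": res.best_fitness_trace,
            "termination": res.termination_reason}


def planted_recovery_experiment(n_runs: int = 10, seed: int = 0) -> dict:
    """Repeat :func:`planted_recovery_run` over ``n_runs`` seeds."""
    runs = [planted_recovery_run(seed * 101 + i) for i in range(n_runs)]
    return {"runs": runs,
            "n_success": sum(r["recovered"] >= 3 for r in runs),
            "n_runs": n_runs}


def surrogate_bitcount_experiment(n_runs: int = 10, seed: int = 0) -> dict:
    """GA correctness against exhaustive search on a 12-bit genome.

    Fitness = number of set bits (transparent surrogate); the exhaustive
    optimum is the all-zero genome with fitness 0.
    """
    spec = EncodingSpec(n_feature_bits=5, layer_field_bits=2, node_field_bits=1)
    assert spec.total_length == 12

    def surrogate(genome, eval_seed):
        return FitnessRecord("surrogate", "holdout",
                             [float(genome.bits.sum())], [0.0], 1)

    exhaustive_best = 0.0  # min over all 2^12 bit strings of popcount
    wins = 0
    for i in range(n_runs):
        cfg = GAConfig(seed=seed * 977 + i, cache_on_active_region=False)
        res = evolve(None, cfg, None, spec, fitness_fn=surrogate)
        wins += res.best_record.mean_mse == exhaustive_best
    return {"n_match": wins, "n_runs": n_runs}


def filter_counts_experiment(seed: int = 0) -> dict:
    """Low-information filter on the synthetic 1074 x 140 stand-in table."""
    table = planted_filter_table(seed=seed)
    _, presence = validate_presence(table)
    filtered, report = low_information_filter(table)
    return {"n_input": table.n_features,
            "n_kept": filtered.n_features,
            "n_removed": len(report.removed_ids),
            "n_presence_removed": len(presence.removed_ids),
            "n_nonzero_target": int(np.sum(table.target != 0)),
            "n_samples": table.n_samples}


def importance_recovery_experiment(n_models: int = 20, seed: int = 0) -> dict:
    """Olden importance on a linear planted target with one dominant
    positive-weight feature; reports whether it ranks first."""
    spec = SynthSpec(n_samples=300, n_features=8, n_informative=3,
                     zero_inflation=0.0, all_zero_fraction=0.0,
                     effect_weights=(2.0, -1.0, 0.5), noise_sd=0.02,
                     link="linear", seed=seed)
    ds = generate(spec)
    scaled, _ = scale_dataset(ds)
    rng = np.random.default_rng(seed)
    cfg = TrainConfig(optimizer="rprop_plus", dropout_rate=0.0,
                      max_epochs=300, patience=20)
    models = []
    n = scaled.n_samples
    for _ in range(n_models):
        perm = rng.permutation(n)
        va, tr = perm[:n // 4], perm[n // 4:]
        m = init_model([scaled.n_features, 8, 1],
                       seed=int(rng.integers(2 ** 31)))
        m, _ = train_rprop_plus(m, (scaled.values[tr], scaled.target[tr]),
                                (scaled.values[va], scaled.target[va]),
                                replace(cfg, seed=int(rng.integers(2 ** 31))))
        models.append(m)
    table = aggregate_runs(models, scaled.feature_ids)
    frame = table.to_frame()
    dominant = ds.meta["informative_ids"][0]      # weight +2.0
    negative = ds.meta["informative_ids"][1]      # weight -1.0
    top_feature = frame.iloc[0]["feature_id"]
    neg_mean = float(table.mean_signed[table.feature_ids.index(negative)])
    return {"dominant_id": dominant, "top_feature": top_feature,
            "dominant_is_top": top_feature == dominant,
            "negative_id": negative, "negative_mean_signed": neg_mean,
            "negative_sign_correct": neg_mean < 0,
            "positive_pct_sum": sum(table.positive_relative.values())}


def toy_pipeline(seed: int = 0) -> dict:
    """Miniature end-to-end run: synthesize, preprocess, search, final
    Rprop+ training, Olden importance. Returns a JSON-serializable record
    of everything downstream of the seed (used for determinism checks)."""
    ds = generate(SynthSpec(n_samples=150, n_features=15, n_informative=3,
                            zero_inflation=0.1, all_zero_fraction=0.1,
                            noise_sd=0.05, seed=seed))
    search = EMDAVSearch(
        ds,
        ga_config=replace(RECOVERY_GA, population_size=8, max_generations=5,
                          seed=seed),
        train_config=replace(RECOVERY_TRAIN, max_epochs=100, seed=seed),
        encoding=RECOVERY_ENCODING)
    res = search.fit(n_executions=2, seed=seed)
    models = res.train_final(n_runs=5, max_epochs=200, seed=seed)
    table = res.importance()
    mse, r2 = res.final_fit_quality()
    return {"kept_features": list(search.dataset.feature_ids),
            "best_genome": res.best_genome.to_string(),
            "best_mse": res.best_record.mean_mse,
            "final_mse": mse, "final_r2": r2,
            "weights_digest": [float(np.sum(np.abs(w)))
                               for m in models for w in m.weights],
            "importance": {k: round(v, 12)
                           for k, v in table.positive_relative.items()},
            "report_rows": res.report.to_dict("records")}
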