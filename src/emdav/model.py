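"""High-level modelling interface.

:class:`EMDAVSearch` wraps the full method behind a fit/results pair:
build the model object from an expression table (or DataFrame), call
``fit()`` to run the evolutionary search, and work with the returned
:class:`EMDAVResults` — best phenotype, consolidated run report,
``summary()`` table, Rprop+ final training and Olden importance.

Example
-------
>>> from emdav import synth, model
>>> ds = synth.generate(synth.SynthSpec(n_samples=200, n_features=20,
...                                     n_informative=4, seed=7))
>>> search = model.EMDAVSearch(ds)           # preprocesses automatically
>>> res = search.fit(n_executions=1)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import ga as _ga
from . import importance as _imp
from . import nn as _nn
from .dataset import ExpressionDataset
from .encoding import EncodingSpec, decode
from .preprocess import ScalingSpec, WaveletSpec, preprocess_pipeline


class EMDAVSearch:
    """Joint evolutionary selection of input features, MLP architecture and
    validation protocol for a single-target expression regression.

    Parameters
    ----------
    dataset : ExpressionDataset
        Raw or already-scaled expression data. Raw data are pushed through
        the standard preprocessing pipeline (presence filter, low-information
        filter, wavelet denoising, scaling) at construction.
    ga_config, train_config : optional
        Search and training hyperparameters; defaults follow the method's
        published protocol (population 50, crossover 0.8, mutation 0.1,
        elitism 10%, RMSprop batch 50 / lr 0.01, patience 10, dropout 0.5).
    encoding : optional EncodingSpec
        Genome layout; ``n_feature_bits`` is forced to the preprocessed
        feature count.
    """

    def __init__(self, dataset: ExpressionDataset,
                 ga_config: _ga.GAConfig | None = None,
                 train_config: _nn.TrainConfig | None = None,
                 encoding: EncodingSpec | None = None,
                 wavelet: WaveletSpec | None = None,
                 scaling: ScalingSpec = ScalingSpec(),
                 denoise: bool = True):
        self.reports = {}
        if dataset.stage != "scaled":
            dataset, self.reports = preprocess_pipeline(
                dataset, wavelet=wavelet, scaling=scaling, denoise=denoise)
        self.dataset = dataset
        self.ga_config = ga_config or _ga.GAConfig()
        self.train_config = train_config or _nn.TrainConfig()
        base = encoding or EncodingSpec()
        self.encoding = EncodingSpec(n_feature_bits=dataset.n_features,
                                     layer_field_bits=base.layer_field_bits,
                                     node_field_bits=base.node_field_bits)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target_id: str, **kwargs):
        return cls(ExpressionDataset.from_frame(df, target_id), **kwargs)

    def fit(self, n_executions: int = 1, seed: int | None = None,
            fitness_fn=None) -> "EMDAVResults":
        """Run ``n_executions`` independent evolutionary searches."""
        ga_cfg = self.ga_config if seed is None else replace(self.ga_config, seed=seed)
        runs, report = _ga.run_emdav(self.dataset, ga_cfg, self.train_config,
                                     self.encoding, n_executions=n_executions,
                                     fitness_fn=fitness_fn)
        return EMDAVResults(search=self, runs=runs, report=report)


@dataclass
class EMDAVResults:
    """Results of the evolutionary search.

    ``report`` is the consolidated top-phenotype table (generation,
    individual, feature count, validation, hidden layers, MSE, R^2) across
    executions, ascending by MSE.
    """

    search: EMDAVSearch
    runs: list
    report: pd.DataFrame

    def __post_init__(self):
        self._final_models: list[_nn.MLPModel] = []

    @property
    def best_run(self):
        return min(self.runs, key=lambda r: r.best_record.mean_mse)

    @property
    def best_genome(self):
        return self.best_run.best_genome

    @property
    def best_phenotype(self):
        return decode(self.best_genome)

    @property
    def best_record(self):
        return self.best_run.best_record

    def selected_feature_ids(self) -> list:
        mask = np.asarray(self.best_phenotype.feature_mask, bool)
        return [f for f, m in zip(self.search.dataset.feature_ids, mask) if m]

    # -- final predictive model ---------------------------------------------
    def train_final(self, n_runs: int = 20, max_epochs: int = 1000,
                    seed: int = 0) -> list:
        """Retrain the best phenotype ``n_runs`` times with full-batch Rprop+
        (dropout disabled, runs differ only by seed); keeps the models for
        importance analysis and prediction."""
        p = self.best_phenotype
        ds = self.search.dataset
        mask = np.asarray(p.feature_mask, bool)
        X, y = ds.values[:, mask], ds.target
        rng = np.random.default_rng(seed)
        cfg = replace(self.search.train_config, optimizer="rprop_plus",
                      dropout_rate=0.0, max_epochs=max_epochs)
        n = X.shape[0]
        models = []
        for _ in range(n_runs):
            perm = rng.permutation(n)
            n_va = max(1, int(round(0.25 * n)))
            va, tr = perm[:n_va], perm[n_va:]
            m = _nn.init_model([X.shape[1], *p.hidden_layers, 1],
                               seed=int(rng.integers(2 ** 31)))
            m, _ = _nn.train_rprop_plus(m, (X[tr], y[tr]), (X[va], y[va]),
                                        replace(cfg, seed=int(rng.integers(2 ** 31))))
            models.append(m)
        self._final_models = models
        return models

    def predict(self, X=None) -> np.ndarray:
        """Mean prediction of the final Rprop+ models on the (scaled)
        selected-feature matrix; defaults to the training data."""
        if not self._final_models:
            raise RuntimeError("call train_final() first")
        if X is None:
            mask = np.asarray(self.best_phenotype.feature_mask, bool)
            X = self.search.dataset.values[:, mask]
        preds = np.vstack([_nn.forward(m, X) for m in self._final_models])
        return preds.mean(axis=0)

    def final_fit_quality(self):
        """(MSE, R^2) of the averaged final model on the full dataset."""
        ds = self.search.dataset
        yhat = self.predict()
        resid = ds.target - yhat
        ss_tot = float(np.sum((ds.target - ds.target.mean()) ** 2))
        mse = float(np.mean(resid ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
        return mse, r2

    def importance(self) -> _imp.ImportanceTable:
        """Olden connection-weight importance aggregated over the final
        Rprop+ models (positive-direction percentages sum to 100%)."""
        if not self._final_models:
            raise RuntimeError("call train_final() first")
        return _imp.aggregate_runs(self._final_models,
                                   self.selected_feature_ids())

    # -- plotting ------------------------------------------------------------
    def plot_fitness(self, ax=None):
        """Best and mean MSE per generation, one line pair per execution."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for i, run in enumerate(self.runs):
            gens = [g["generation"] for g in run.generations]
            ax.plot(gens, [g["best_mse"] for g in run.generations],
                    label=f"run {i} best")
            ax.plot(gens, [g["mean_mse"] for g in run.generations],
                    linestyle="--", alpha=0.5, label=f"run {i} mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("MSE")
        ax.set_yscale("log")
        ax.legend(fontsize="small")
        return ax

    def plot_importance(self, ax=None, top: int = 25):
        """Horizontal bars of positive-direction relative importance."""
        import matplotlib.pyplot as plt
        table = self.importance().to_frame().dropna(subset=["positive_relative_pct"])
        table = table.head(top).iloc[::-1]
        if ax is None:
            _, ax = plt.subplots()
        ax.barh(table["feature_id"], table["positive_relative_pct"])
        ax.set_xlabel("relative importance (%)")
        return ax

    # -- reporting -----------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        """Text report: best phenotypes across executions, ascending MSE."""
        cols = ["execution", "generation", "individual", "n_features",
                "validation", "hidden_layers", "mse", "r2"]
        head = self.report[cols].head(top)
        lines = ["Evolutionary search for expression-regression networks",
                 "=" * 56,
                 f"executions: {len(self.runs)}    "
                 f"phenotype evaluations: {sum(r.n_evaluations for r in self.runs)}",
                 f"best architecture: {self.best_phenotype.architecture_label()}"
                 f"    validation: {self.best_phenotype.validation}"
                 f"    features: {self.best_phenotype.n_selected}",
                 f"best mean test MSE: {self.best_record.mean_mse:.6f}"
                 f"    mean R2: {self.best_record.mean_r2:.4f}",
                 "", head.to_string(index=False,
                                    float_format=lambda v: f"{v:.6f}")]
        return "\n".join(lines)
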