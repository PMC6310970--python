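"""Synthetic expression-matrix generator.

Emulates the statistical shape of a bulk miRNA expression table: nonnegative,
right-skewed (log-normal) magnitudes with structural zeros (zero inflation),
a handful of identically-zero features (so the presence filter has work to
do), and a target driven by a small planted subset of features through a
noisy, optionally sigmoidal response in which some effects are repressive
(negative weight). Only the statistical shape is emulated — no sequence or
target-site biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import ExpressionDataset


def _sigmoid(t):
    return 1.0 / (1.0 + np.exp(-t))


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic expression generator.

    Defaults emulate a reduced TCGA-like table: ~1000 samples, ~100
    features, a small informative subset, moderate zero inflation and
    strong right skew. ``effect_weights`` are signed (negative =
    repression); if ``None``, weights alternate +1/-1 scaled by 1/sqrt(k).
    ``all_zero_fraction`` of features are identically zero.
    """

    n_samples: int = 1000
    n_features: int = 100
    n_informative: int = 8
    #: mean structural-zero probability; per-feature rates are drawn
    #: Uniform(0, 2*zero_inflation) so some features stay nearly complete
    #: while others cross the low-information filter's zero-mode threshold
    zero_inflation: float = 0.2
    dispersion: float = 1.5
    effect_weights: tuple | None = None
    noise_sd: float = 0.05
    link: str = "sigmoid"
    all_zero_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "n_features", "n_informative"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_samples < 1 or self.n_features < 1:
            raise ValueError("n_samples and n_features must be >= 1")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.link not in ("linear", "sigmoid"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.effect_weights is not None:
            object.__setattr__(self, "effect_weights", tuple(float(w) for w in self.effect_weights))
            if len(self.effect_weights) != self.n_informative:
                raise ValueError("effect_weights length must equal n_informative")

    def resolved_weights(self) -> np.ndarray:
        if self.effect_weights is not None:
            return np.asarray(self.effect_weights, float)
        k = self.n_informative
        signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        return signs / np.sqrt(max(k, 1))


def generate(spec: SynthSpec) -> ExpressionDataset:
    """Generate a dataset; a pure function of ``spec`` (incl. its seed).

    The target is ``link(sum_i w_i * x_i_scaled) + N(0, noise_sd)`` where
    ``x_i_scaled`` is the informative feature min-max scaled to [-1, 1]
    (matching how the features are presented to the network downstream).
    Metadata records the informative feature ids and their weights.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features

    # log-normal magnitudes, right-skewed for dispersion (sdlog) > 0
    x = rng.lognormal(mean=0.0, sigma=spec.dispersion, size=(n, p))
    if spec.zero_inflation > 0:
        rates = np.clip(rng.uniform(0.0, 2.0 * spec.zero_inflation, size=p),
                        0.0, 0.95)
        mask = rng.random((n, p)) >= rates
        x = x * mask

    # choose informative features, then plant structural-zero columns among
    # the remaining ones so the presence filter has victims
    perm = rng.permutation(p)
    informative = np.sort(perm[:spec.n_informative])
    n_dead = int(round(spec.all_zero_fraction * p))
    dead = np.sort(perm[spec.n_informative:spec.n_informative + n_dead])
    x[:, dead] = 0.0

    # keep informative columns clear of structural zeros so their signal
    # survives zero inflation: regenerate without the Bernoulli mask
    x[:, informative] = rng.lognormal(0.0, spec.dispersion,
                                      size=(n, spec.n_informative))

    w = spec.resolved_weights()
    xi = x[:, informative]
    span = xi.max(axis=0) - xi.min(axis=0)
    span[span == 0] = 1.0
    xi_scaled = 2.0 * (xi - xi.min(axis=0)) / span - 1.0
    eta = xi_scaled @ w
    y = _sigmoid(eta) if spec.link == "sigmoid" else eta
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)

    ids = tuple(f"feat_{j:04d}" for j in range(p))
    meta = {"informative_ids": [ids[j] for j in informative],
            "informative_indices": informative.tolist(),
            "effect_weights": w.tolist(),
            "all_zero_ids": [ids[j] for j in dead],
            "link": spec.link, "seed": spec.seed, "synthetic": True}
    return ExpressionDataset(values=x, feature_ids=ids, target=y,
                             target_id="target", stage="raw", meta=meta)


def planted_filter_table(n_samples: int = 1074, n_keep: int = 99,
                         n_q3_low: int = 25, n_zero_mode: int = 16,
                         seed: int = 0) -> ExpressionDataset:
    """Synthetic stand-in for a presence-filtered bulk expression table.

    Builds an ``n_samples x (n_keep + n_q3_low + n_zero_mode)`` matrix in
    which exactly ``n_keep`` features are constructed to survive the
    low-information filter, ``n_q3_low`` to fail the third-quartile rule
    (Q3 < 2) and ``n_zero_mode`` to fail the zero-mode rule (mode 0 in
    more than 15% of samples with Q3 >= 2). Defaults reproduce the shape
    of a 140-feature table that reduces to 99. The target is strictly
    positive. Entirely synthetic; feature ids carry their planted role.
    """
    rng = np.random.default_rng(seed)
    n = n_samples
    cols, ids = [], []
    for i in range(n_keep):
        # expressed feature: no zeros, median well above the Q3 threshold
        col = rng.lognormal(mean=2.0, sigma=1.0, size=n) + 2.0
        cols.append(col)
        ids.append(f"keep_{i:03d}")
    for i in range(n_q3_low):
        # weakly expressed: Q3 below 2 by construction
        col = rng.uniform(0.0, 1.5, size=n)
        cols.append(col)
        ids.append(f"q3low_{i:03d}")
    for i in range(n_zero_mode):
        # expressed but dropout-ridden: >15% exact zeros, Q3 still >= 2
        col = rng.lognormal(mean=2.5, sigma=0.5, size=n) + 2.0
        zero_frac = rng.uniform(0.20, 0.60)
        col[rng.random(n) < zero_frac] = 0.0
        if np.quantile(col, 0.75) < 2.0:  # keep the failure mode unambiguous
            col[col > 0] += 2.0
        cols.append(col)
        ids.append(f"zmode_{i:03d}")
    x = np.column_stack(cols)
    target = rng.lognormal(mean=1.0, sigma=0.5, size=n) + 0.1
    meta = {"synthetic": True, "planted_keep": n_keep,
            "planted_q3_low": n_q3_low, "planted_zero_mode": n_zero_mode,
            "seed": seed}
    return ExpressionDataset(values=x, feature_ids=tuple(ids), target=target,
                             target_id="target", stage="raw", meta=meta)


def write_dataset(ds: ExpressionDataset, path) -> Path:
    """Write TSV (features + target column) plus a JSON truth sidecar."""
    path = Path(path)
    ds.to_tsv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(ds.meta, indent=2))
    return sidecar
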