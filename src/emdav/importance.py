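"""Connection-weight (Olden) relative importance for trained networks.

The importance of an input is the sum, over every input-to-output path,
of the product of the connection weights along that path — sign preserved,
biases excluded, activation nonlinearities ignored (the connection-weights
idea). For a multilayer net this equals the input's row of the chained
product of all weight matrices; the brute-force path enumeration is kept
as a test oracle. Originally defined for single-hidden-layer networks, the
chained product is the natural multi-layer generalization.

Across repeated trainings the signed importances are averaged per feature;
features with positive mean are renormalized to percentages summing to
100% ("positive-direction" relative importance).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd

from .nn import MLPModel


def olden_signed(m: MLPModel) -> np.ndarray:
    """Signed importance vector, one entry per input feature."""
    if m.n_hidden_layers < 1:
        raise ValueError("need at least one hidden layer")
    product = reduce(np.matmul, m.weights)
    return product[:, 0]


def olden_paths(m: MLPModel) -> np.ndarray:
    """Brute-force path enumeration (test oracle, exponential in depth)."""
    sizes = m.layer_sizes
    n_in = sizes[0]
    out = np.zeros(n_in)

    def walk(layer, node, prod):
        if layer == len(m.weights):
            return prod
        total = 0.0
        for nxt in range(sizes[layer + 1]):
            total += walk(layer + 1, nxt, prod * m.weights[layer][node, nxt])
        return total

    for i in range(n_in):
        out[i] = walk(0, i, 1.0)
    return out


@dataclass
class ImportanceTable:
    """Aggregated signed importances and positive-direction percentages."""

    feature_ids: tuple
    signed_runs: np.ndarray   # (n_runs, n_features)
    mean_signed: np.ndarray
    positive_relative: dict   # feature_id -> % among positive-mean features
    n_runs: int

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped report, descending by positive relative importance."""
        rows = []
        for fid, ms in zip(self.feature_ids, self.mean_signed):
            rows.append({"feature_id": fid, "mean_signed": float(ms),
                         "positive_relative_pct": self.positive_relative.get(fid)})
        df = pd.DataFrame(rows)
        df = df.sort_values("positive_relative_pct", ascending=False,
                            na_position="last", kind="stable").reset_index(drop=True)
        df["rank"] = np.where(df["positive_relative_pct"].notna(),
                              np.arange(1, len(df) + 1), np.nan)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def aggregate_runs(models, feature_ids) -> ImportanceTable:
    """Average signed importances over independently trained models, then
    renormalize the positive-mean features to percentages summing to 100%."""
    feature_ids = tuple(feature_ids)
    runs = []
    for m in models:
        if m.n_inputs != len(feature_ids):
            raise ValueError("model input width does not match feature list")
        runs.append(olden_signed(m))
    runs = np.vstack(runs)
    mean_signed = runs.mean(axis=0)
    pos = mean_signed > 0
    positive_relative = {}
    if pos.any():
        total = mean_signed[pos].sum()
        for fid, ms, is_pos in zip(feature_ids, mean_signed, pos):
            if is_pos:
                positive_relative[fid] = 100.0 * float(ms) / float(total)
    return ImportanceTable(feature_ids=feature_ids, signed_runs=runs,
                           mean_signed=mean_signed,
                           positive_relative=positive_relative,
                           n_runs=runs.shape[0])


def importance_sanity_on_synthetic(ds, table: ImportanceTable) -> dict:
    """Rank planted informative features inside an aggregated table.

    ``ds.meta`` must carry the generator's truth sidecar. Reports each
    planted feature's rank by positive relative importance (None if it did
    not land in the positive set), plus sign agreement with the planted
    effect direction.
    """
    truth_ids = ds.meta.get("informative_ids", [])
    weights = dict(zip(truth_ids, ds.meta.get("effect_weights", [])))
    frame = table.to_frame()
    ranks = {row.feature_id: row.rank for row in frame.itertuples()
             if not np.isnan(row.rank)}
    report = {"planted": {}, "n_positive": len(table.positive_relative)}
    for fid in truth_ids:
        if fid not in table.feature_ids:
            report["planted"][fid] = {"present": False}
            continue
        ms = float(table.mean_signed[table.feature_ids.index(fid)])
        report["planted"][fid] = {
            "present": True,
            "rank": int(ranks[fid]) if fid in ranks else None,
            "mean_signed": ms,
            "sign_agrees": (np.sign(ms) == np.sign(weights.get(fid, 0.0)))
                           if fid in weights else None}
    return report
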