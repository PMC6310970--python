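"""Expression dataset container.

An :class:`ExpressionDataset` holds a samples x features expression matrix,
the feature identifiers, a numeric target vector (one value per sample) and
a provenance ``stage`` flag that records how far through the preprocessing
pipeline the data have travelled (``raw -> filtered -> denoised -> scaled``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

STAGES = ("raw", "filtered", "denoised", "scaled")


class StageError(ValueError):
    """Raised when a pipeline stage transition would go backwards."""


@dataclass(frozen=True)
class ExpressionDataset:
    """Samples x features expression matrix with a designated target.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_features)
        Expression values; nonnegative unless ``stage == "scaled"``.
    feature_ids : tuple of str
        Unique feature (e.g. miRNA) identifiers, one per column.
    target : ndarray, shape (n_samples,)
        The dependent variable (e.g. an mRNA expression level).
    target_id : str
        Name of the target column.
    stage : str
        One of ``raw``, ``filtered``, ``denoised``, ``scaled``.
    meta : dict
        Free-form provenance (informative-feature lists, scaling params...).
    """

    values: np.ndarray
    feature_ids: tuple
    target: np.ndarray
    target_id: str = "target"
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        target = np.asarray(self.target, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "target", target)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if values.shape[0] == 0:
            raise ValueError("empty expression matrix")
        # zero feature columns are allowed: a filter may remove everything
        if len(self.feature_ids) != values.shape[1]:
            raise ValueError("feature_ids length must equal number of columns")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids")
        if target.shape != (values.shape[0],):
            raise ValueError("target length must equal number of rows")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)

    # -- transitions ---------------------------------------------------------
    def advance(self, new_stage: str, **changes) -> "ExpressionDataset":
        """Return a copy at ``new_stage``; stages may only move forward."""
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise StageError(f"cannot move from {self.stage} back to {new_stage}")
        return replace(self, stage=new_stage, **changes)

    def select_features(self, mask) -> "ExpressionDataset":
        """Column subset by boolean mask or index array (stage preserved)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        ids = tuple(self.feature_ids[i] for i in idx)
        return replace(self, values=self.values[:, idx], feature_ids=ids)

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_ids))
        df[self.target_id] = self.target
        return df

    def to_tsv(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, target_id: str, stage: str = "raw",
                   meta: dict | None = None) -> "ExpressionDataset":
        if target_id not in df.columns:
            raise ValueError(f"target column {target_id!r} not in table")
        if df.isna().any().any():
            raise ValueError("missing values are not supported; clean the table first")
        feats = [c for c in df.columns if c != target_id]
        return cls(values=df[feats].to_numpy(float),
                   feature_ids=tuple(feats),
                   target=df[target_id].to_numpy(float),
                   target_id=target_id, stage=stage, meta=meta or {})

    @classmethod
    def from_table(cls, path, target_id: str | None = None,
                   stage: str = "raw") -> "ExpressionDataset":
        """Read a TSV/CSV table (delimiter auto-detected); last column is the
        target unless ``target_id`` names another column."""
        path = Path(path)
        df = pd.read_csv(path, sep=None, engine="python")
        if target_id is None:
            target_id = df.columns[-1]
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls.from_frame(df, target_id, stage=stage, meta=meta)
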