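"""Shared containers for the clinical + multi-omics prognosis pipeline.

The pipeline moves three kinds of data between stages: per-layer omics
matrices (samples x features on the layer's native measurement scale),
right-censored follow-up, and a small categorical clinical table (AJCC
T/N/M stage and age at diagnosis).  Everything downstream assumes one
shared sample ordering; the containers here validate that contract once
so the numerical code does not have to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

LAYERS = ("expression", "methylation", "mirna", "cluster_binary")
SCALES = ("fpkm", "beta", "rpm", "binary")

#: closed category sets; Tis / N1c / Mx are excluded upstream of this package
T_LEVELS = ("T1", "T2", "T3", "T4a", "T4b")
N_LEVELS = ("N0", "N1a", "N1b", "N2a", "N2b")
M_LEVELS = ("M0", "M1")


@dataclass
class FeatureMatrix:
    """One omics layer: samples (rows) x features (columns), NA allowed.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with feature ids as columns.
    layer
        One of :data:`LAYERS`.
    scale
        Measurement scale, one of :data:`SCALES` (``fpkm`` gene
        expression, ``beta`` methylation fraction in [0, 1], ``rpm``
        miRNA reads-per-million, ``binary`` cluster indicators).
    """

    values: pd.DataFrame
    layer: str
    scale: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample_ids in FeatureMatrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature_ids in FeatureMatrix")
        if self.scale == "beta":
            vals = self.values.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError("beta-scale values must lie in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, keep: Sequence[str]) -> "FeatureMatrix":
        """Pure column selection; values and sample order untouched."""
        return FeatureMatrix(self.values.loc[:, list(keep)], self.layer, self.scale)


@dataclass
class SurvivalData:
    """Per-sample follow-up: time in days and event indicator (1 = death)."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: pd.Index | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("survival times must be finite and >= 0")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0/1")

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalData":
        ids = self.sample_ids[idx] if self.sample_ids is not None else None
        return SurvivalData(self.time[idx], self.event[idx], ids)


@dataclass
class ClinicalTable:
    """T/N/M stage and age at diagnosis, one row per sample.

    Categories are restricted to the closed AJCC sets used throughout
    (T1..T4b, N0..N2b, M0/M1); unassessable categories are assumed to
    have been excluded before construction.
    """

    table: pd.DataFrame  # columns: t_stage, n_stage, m_stage, age_years

    REQUIRED = ("t_stage", "n_stage", "m_stage", "age_years")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"clinical table missing columns {missing}")
        for col, levels in (("t_stage", T_LEVELS), ("n_stage", N_LEVELS), ("m_stage", M_LEVELS)):
            bad = set(self.table[col]) - set(levels)
            if bad:
                raise ValueError(f"{col} contains unknown categories {sorted(bad)}")
        age = self.table["age_years"].to_numpy(dtype=float)
        if np.any(~np.isfinite(age)) or np.any(age <= 0):
            raise ValueError("age_years must be positive and finite")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, idx) -> "ClinicalTable":
        return ClinicalTable(self.table.iloc[idx])


@dataclass
class ClusterLabels:
    """A patient partition from one clustering run, labels in 1..k."""

    labels: np.ndarray
    k: int
    params: tuple  # (metric, linkage, k)
    name: str = "clusters"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        occupied = np.unique(self.labels)
        if occupied.min() < 1 or occupied.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if len(occupied) != self.k:
            raise ValueError("every label in 1..k must be occupied")

    def __len__(self) -> int:
        return self.labels.shape[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]
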