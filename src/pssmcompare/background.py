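"""Randomisation-based null distribution of column-pair IWS scores.

All columns of the query PSSM set and of the comparison PSSM set are pooled
into two column sets; random pairs (one column from each pool, drawn
independently with replacement) are scored with IWS to build an empirical
null.  The probability of an observed IWS score is the add-one-smoothed
proportion of null samples greater than or equal to it, so no probability is
ever exactly zero and window products stay well defined.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .metrics import gini_rows, pearson_rows
from .pssm import PSSM, normalise

DEFAULT_SIZE = 100_000
DEFAULT_SEED = 42


def _set_id(pssms: Sequence[PSSM]) -> str:
    h = hashlib.sha256("\x00".join(p.name for p in pssms).encode())
    return h.hexdigest()[:12]


@dataclass
class BackgroundDistribution:
    """Sorted empirical sample of null IWS scores.

    Reproducible: the same input sets, size and seed give byte-identical
    samples.
    """

    samples: np.ndarray
    size: int
    seed: int
    query_set_id: str = ""
    comparison_set_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size != self.size:
            raise ConfigError("background size does not match sample count")
        if self.samples.size == 0:
            raise ConfigError("background distribution is empty")
        if np.any(np.diff(self.samples) < 0):
            raise ConfigError("background samples must be sorted ascending")

    def to_json(self) -> str:
        return json.dumps(
            {
                "samples": [float(x) for x in self.samples],
                "size": self.size,
                "seed": self.seed,
                "query_set_id": self.query_set_id,
                "comparison_set_id": self.comparison_set_id,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BackgroundDistribution":
        obj = json.loads(text)
        return cls(
            samples=np.array(obj["samples"], dtype=float),
            size=int(obj["size"]),
            seed=int(obj["seed"]),
            query_set_id=obj.get("query_set_id", ""),
            comparison_set_id=obj.get("comparison_set_id", ""),
        )

    def save(self, path: str | os.PathLike) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "BackgroundDistribution":
        return cls.from_json(Path(path).read_text())


def _pool_columns(pssms: Sequence[PSSM]) -> np.ndarray:
    """Stack all columns of a (normalised) PSSM set as rows of an (m, 20) array."""
    pssms = [p if p.normalised else normalise(p) for p in pssms]
    return np.concatenate([p.weights.T for p in pssms], axis=0)


def build_background(
    query_pssms: Sequence[PSSM] | PSSM,
    comparison_pssms: Sequence[PSSM] | PSSM,
    size: int = DEFAULT_SIZE,
    seed: int = DEFAULT_SEED,
) -> BackgroundDistribution:
    """Sample ``size`` random column pairs and return their sorted IWS scores.

    Inputs are min-max normalised first (idempotent), mirroring the pipeline
    order.  Columns are drawn uniformly with replacement, one from the pooled
    query columns and one from the pooled comparison columns per pair.
    """
    if isinstance(query_pssms, PSSM):
        query_pssms = [query_pssms]
    if isinstance(comparison_pssms, PSSM):
        comparison_pssms = [comparison_pssms]
    query_pssms = list(query_pssms)
    comparison_pssms = list(comparison_pssms)
    if not query_pssms or not comparison_pssms:
        raise ConfigError("background requires non-empty query and comparison sets")
    if size < 1:
        raise ConfigError("background size must be >= 1")

    q_pool = _pool_columns(query_pssms)
    c_pool = _pool_columns(comparison_pssms)
    q_gini = gini_rows(q_pool)
    c_gini = gini_rows(c_pool)

    rng = np.random.default_rng(seed)
    qi = rng.integers(0, q_pool.shape[0], size=size)
    ci = rng.integers(0, c_pool.shape[0], size=size)
    scores = pearson_rows(q_pool[qi], c_pool[ci]) * (q_gini[qi] * c_gini[ci])
    scores.sort()
    return BackgroundDistribution(
        samples=scores,
        size=size,
        seed=seed,
        query_set_id=_set_id(query_pssms),
        comparison_set_id=_set_id(comparison_pssms),
    )


def iws_p(iws_value, dist: BackgroundDistribution):
    """Empirical probability of seeing an IWS at least as large as observed.

    ``(count of samples >= value + 1) / (size + 1)``; ties count toward the
    proportion.  Accepts a scalar or an array of IWS values; monotone
    non-increasing in the value, bounded in ``[1/(size+1), 1]``.
    """
    values = np.asarray(iws_value, dtype=float)
    idx = np.searchsorted(dist.samples, values, side="left")
    p = (dist.size - idx + 1.0) / (dist.size + 1.0)
    if np.ndim(iws_value) == 0:
        return float(p)
    return p
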