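"""Synthetic motif classes and benchmark scenarios.

Real short linear motifs have a few high-importance "fixed" positions (one
residue or a small allowed set) among wildcard positions.  This module
generates such motif classes, samples peptides from them, contaminates
samples with uniform-random noise peptides, and provides the split-half
recovery and titration experiment designs used to exercise the whole
comparison pipeline without any external data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .background import build_background
from .compare import compare_pssm_set
from .errors import ConfigError
from .pssm import ALPHABET, PSSM, PeptideSet, build_pssm, normalise

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass
class MotifSpec:
    """Qualitative description of a motif class.

    ``positions`` holds one entry per motif position: a string of allowed
    residues (length 1 = fixed position) or ``None`` for a wildcard.
    ``strength`` in (0, 1] is the total probability mass concentrated on the
    allowed set; the remainder is spread uniformly over disallowed residues.
    """

    name: str
    positions: Sequence[str | None]
    strength: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.strength <= 1.0):
            raise ConfigError(f"strength must be in (0, 1], got {self.strength}")
        for pos in self.positions:
            if pos is not None:
                if len(pos) == 0:
                    raise ConfigError("allowed set may not be empty")
                bad = set(pos) - set(ALPHABET)
                if bad:
                    raise ConfigError(f"non-canonical residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.positions)


def spec_to_pssm(spec: MotifSpec) -> PSSM:
    """Turn a motif spec into a probability PSSM.

    Fixed/allowed positions put ``strength`` mass uniformly on the allowed
    set and the rest uniformly on the other residues; wildcards are flat
    1/20 columns.
    """
    weights = np.zeros((20, spec.length))
    for j, pos in enumerate(spec.positions):
        if pos is None:
            weights[:, j] = 1.0 / 20.0
            continue
        allowed = [_AA_INDEX[aa] for aa in pos]
        k = len(allowed)
        if k == 20:
            weights[:, j] = 1.0 / 20.0
            continue
        weights[:, j] = (1.0 - spec.strength) / (20 - k)
        weights[allowed, j] = spec.strength / k
    return PSSM(name=spec.name, weights=weights, scoring_method="external")


def sample_peptides(pssm: PSSM, n: int, seed=None) -> PeptideSet:
    """Draw ``n`` peptides position-independently from a PSSM's columns.

    Column weights are used as sampling probabilities after per-column
    renormalisation; reproducible for a given seed.
    """
    if n < 1:
        raise ConfigError(f"need n >= 1 peptides, got {n}")
    W = pssm.weights
    if (W < 0).any():
        raise ConfigError("column weights must be non-negative to sample from")
    rng = np.random.default_rng(seed)
    draws = np.empty((n, pssm.length), dtype=int)
    for j in range(pssm.length):
        col = W[:, j]
        total = col.sum()
        if total <= 0:
            raise ConfigError(f"column {j + 1} of '{pssm.name}' is all zero")
        draws[:, j] = rng.choice(20, size=n, p=col / total)
    peptides = ["".join(ALPHABET[k] for k in row) for row in draws]
    return PeptideSet(peptides=peptides, name=f"{pssm.name}_sample")


def inject_noise(peptides: PeptideSet, noise_fraction: float, seed=None) -> PeptideSet:
    """Append ``round(noise_fraction * N)`` uniform-random peptides.

    The original peptides are kept unchanged at the front of the set.
    """
    if noise_fraction < 0:
        raise ConfigError("noise fraction must be non-negative")
    n_noise = int(round(noise_fraction * len(peptides)))
    if n_noise == 0:
        return peptides
    rng = np.random.default_rng(seed)
    length = peptides.length
    noise = [
        "".join(ALPHABET[k] for k in rng.integers(0, 20, size=length))
        for _ in range(n_noise)
    ]
    return PeptideSet(
        peptides=list(peptides.peptides) + noise,
        name=f"{peptides.name}_noise{noise_fraction:g}",
    )


def split_set(peptides: PeptideSet, seed=None) -> tuple[PeptideSet, PeptideSet]:
    """Randomly partition a peptide set into two disjoint halves.

    Sizes are ceil(N/2) and floor(N/2); the union is exactly the input.
    """
    n = len(peptides)
    if n < 2:
        raise ConfigError("need at least 2 peptides to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    cut = math.ceil(n / 2)
    first = [peptides.peptides[i] for i in order[:cut]]
    second = [peptides.peptides[i] for i in order[cut:]]
    return (
        PeptideSet(first, name=f"{peptides.name}_A"),
        PeptideSet(second, name=f"{peptides.name}_B"),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve via the rank-sum identity, midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ConfigError("roc_auc needs both positive and negative labels")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def random_pssm(length: int, seed=None, name: str = "random") -> PSSM:
    """A PSSM of independent Uniform(0,1) column weights (decoy material)."""
    rng = np.random.default_rng(seed)
    return PSSM(name=name, weights=rng.random((20, length)))


# ---------------------------------------------------------------------------
# Scenario construction


def make_motif_specs(
    n_classes: int,
    motif_length: int = 8,
    n_fixed: int = 3,
    seed=None,
    strength: float = 1.0,
) -> list[MotifSpec]:
    """Generate motif classes with disjoint fixed residues where possible.

    Each class gets ``n_fixed`` fixed positions placed at random.  Per
    position a pool of unused residues is consumed so classes do not share a
    determinant at the same position; if a pool runs dry (> 20 classes using
    one position) it is refilled and the overlap is logged.
    """
    if n_fixed > motif_length:
        raise ConfigError("n_fixed cannot exceed motif_length")
    rng = np.random.default_rng(seed)
    pools = {p: list(ALPHABET) for p in range(motif_length)}
    specs = []
    for k in range(n_classes):
        fixed_pos = sorted(rng.choice(motif_length, size=n_fixed, replace=False))
        positions: list[str | None] = [None] * motif_length
        for p in fixed_pos:
            if not pools[p]:
                logger.warning(
                    "residue pool exhausted at position %d; decoy classes may "
                    "share determinants",
                    p,
                )
                pools[p] = list(ALPHABET)
            aa = pools[p].pop(int(rng.integers(len(pools[p]))))
            positions[p] = aa
        specs.append(
            MotifSpec(name=f"class_{k:02d}", positions=positions, strength=strength)
        )
    return specs


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic benchmark scenario."""

    n_classes: int = 20
    motif_length: int = 8
    n_fixed: int = 3
    peptides_per_class: int = 40
    noise_fraction: float = 0.0
    background_size: int = 100_000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.peptides_per_class < 1:
            raise ConfigError("scenario needs >= 1 class and >= 1 peptide")
        if self.background_size < 1:
            raise ConfigError("background_size must be >= 1")
        if self.noise_fraction < 0:
            raise ConfigError("noise fraction must be non-negative")


# ---------------------------------------------------------------------------
# Benchmark experiments


def split_recovery_experiment(config: ScenarioConfig = ScenarioConfig()) -> dict:
    """Split-half self-recovery: can each class find its other half?

    Peptides sampled per class are split into disjoint halves; frequency
    PSSMs built from the A halves are queried against the set of B-half
    PSSMs with a pooled background.  Returns matched ranks, scores
    (-log10 corrected p), matched labels and the resulting ROC AUC.
    """
    rng = np.random.default_rng(config.seed)
    specs = make_motif_specs(
        config.n_classes, config.motif_length, config.n_fixed, seed=rng
    )
    queries, references = [], []
    for spec in specs:
        peps = sample_peptides(spec_to_pssm(spec), config.peptides_per_class, seed=rng)
        if config.noise_fraction > 0:
            peps = inject_noise(peps, config.noise_fraction, seed=rng)
        half_a, half_b = split_set(peps, seed=rng)
        queries.append(
            normalise(build_pssm(half_a, "frequency", name=f"{spec.name}_A"))
        )
        references.append(
            normalise(build_pssm(half_b, "frequency", name=f"{spec.name}_B"))
        )
    dist = build_background(
        queries, references, size=config.background_size, seed=config.seed
    )
    matched_ranks, scores, labels = [], [], []
    for i, query in enumerate(queries):
        results = compare_pssm_set(query, references, dist)
        for res in results:
            matched = res.comparison_name == f"{specs[i].name}_B"
            scores.append(-math.log10(res.corrected_p))
            labels.append(matched)
            if matched:
                matched_ranks.append(res.rank)
    return {
        "matched_ranks": matched_ranks,
        "scores": scores,
        "labels": labels,
        "auc": roc_auc(scores, labels),
        "top1_fraction": sum(r == 1 for r in matched_ranks) / len(matched_ranks),
    }


def titration_experiment(
    peptides_per_class: int = 20,
    noise_fraction: float = 0.0,
    n_classes: int = 20,
    motif_length: int = 8,
    n_fixed: int = 3,
    background_size: int = 20_000,
    seed: int = 42,
) -> float:
    """AUC of matched-class recovery for one sample-size / noise condition.

    Queries are frequency PSSMs built from (optionally noisy) peptide
    samples; references are the ideal class PSSMs.  Emulates peptide-count
    and noise titration benchmarks; returns the ROC AUC of
    -log10(corrected p) for matched vs mismatched pairs.
    """
    rng = np.random.default_rng(seed)
    specs = make_motif_specs(n_classes, motif_length, n_fixed, seed=rng)
    references = [normalise(spec_to_pssm(spec)) for spec in specs]
    queries = []
    for spec in specs:
        peps = sample_peptides(spec_to_pssm(spec), peptides_per_class, seed=rng)
        if noise_fraction > 0:
            peps = inject_noise(peps, noise_fraction, seed=rng)
        queries.append(
            normalise(build_pssm(peps, "frequency", name=f"{spec.name}_obs"))
        )
    dist = build_background(queries, references, size=background_size, seed=seed)
    scores, labels = [], []
    for i, query in enumerate(queries):
        for res in compare_pssm_set(query, references, dist):
            scores.append(-math.log10(res.corrected_p))
            labels.append(res.comparison_name == specs[i].name)
    return roc_auc(scores, labels)
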