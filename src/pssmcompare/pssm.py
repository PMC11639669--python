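"""PSSM data model, file I/O, construction from aligned peptides and normalisation.

A PSSM is a 20 x L matrix of per-position amino-acid preference weights over
the canonical alphabet ``ACDEFGHIKLMNPQRSTVWY``.  Rows are always stored in
canonical order internally; input files may list them in any order.

Three construction methods from aligned peptide sets are supported:

``frequency``
    (count + pseudocount) / (N + 20 * pseudocount) per cell.
``binomial_log``
    -log10 of the upper-tail binomial probability of observing at least the
    observed count given N trials at a flat background rate (default 1/20).
``psiblast_ic``
    information-content-weighted log-odds with BLOSUM62-derived pseudocount
    frequencies, in the standard published form.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import PSSMFormatError

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

SCORING_METHODS = ("frequency", "binomial_log", "psiblast_ic", "external")

#: Robinson & Robinson amino-acid background frequencies, canonical order.
ROBINSON_FREQUENCIES = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
ROBINSON_FREQUENCIES = ROBINSON_FREQUENCIES / ROBINSON_FREQUENCIES.sum()


@dataclass
class PSSM:
    """A named position-specific scoring matrix.

    Parameters
    ----------
    name : str
        Identifier.
    weights : numpy.ndarray
        Shape ``(20, L)``; row ``i`` corresponds to ``ALPHABET[i]``.
    scoring_method : str
        One of ``frequency``, ``binomial_log``, ``psiblast_ic``, ``external``.
    normalised : bool
        True when every column has been min-max scaled to [0, 1].
    """

    name: str
    weights: np.ndarray
    scoring_method: str = "external"
    normalised: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 20:
            raise PSSMFormatError(
                f"PSSM '{self.name}': weights must be 20 x L, "
                f"got shape {self.weights.shape}"
            )
        if self.weights.shape[1] < 1:
            raise PSSMFormatError(f"PSSM '{self.name}': needs at least one column")
        if self.scoring_method not in SCORING_METHODS:
            raise PSSMFormatError(
                f"unknown scoring method '{self.scoring_method}'"
            )
        if self.normalised:
            w = self.weights
            if w.min() < -1e-12 or w.max() > 1 + 1e-12:
                raise PSSMFormatError(
                    f"PSSM '{self.name}' flagged normalised but has values "
                    "outside [0, 1]"
                )

    @property
    def length(self) -> int:
        """Number of motif positions L."""
        return self.weights.shape[1]

    @property
    def alphabet(self) -> str:
        return ALPHABET

    def column(self, i: int) -> np.ndarray:
        return self.weights[:, i]

    def __eq__(self, other: object) -> bool:
        # identity of the matrix itself; name and flags are metadata
        if not isinstance(other, PSSM):
            return NotImplemented
        return self.weights.shape == other.weights.shape and bool(
            np.array_equal(self.weights, other.weights)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass
class PeptideSet:
    """A non-empty set of equal-length peptides over the canonical alphabet."""

    peptides: list[str]
    name: str = "peptides"

    def __post_init__(self) -> None:
        if not self.peptides:
            raise PSSMFormatError(f"peptide set '{self.name}' is empty")
        length = len(self.peptides[0])
        for pep in self.peptides:
            if len(pep) != length:
                raise PSSMFormatError(
                    f"peptide set '{self.name}' is not aligned: '{pep}' has "
                    f"length {len(pep)}, expected {length}; align the peptides "
                    "to equal length before building a PSSM"
                )
            bad = set(pep) - set(ALPHABET)
            if bad:
                raise PSSMFormatError(
                    f"peptide '{pep}' contains non-canonical residue(s) "
                    f"{sorted(bad)}; only {ALPHABET} are allowed"
                )

    @property
    def length(self) -> int:
        return len(self.peptides[0])

    def __len__(self) -> int:
        return len(self.peptides)


# ---------------------------------------------------------------------------
# I/O


def _source_text(source: str | os.PathLike, *, default_name: str) -> tuple[str, str]:
    """Return (text, name) for a path-or-literal-text source."""
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        path = Path(source)
        return path.read_text(), path.stem
    return str(source), default_name


def read_pssm(source: str | os.PathLike, format: str = "auto") -> PSSM:
    """Read a single PSSM from a TSV or JSON file (or literal text).

    TSV dialect: header ``AA<TAB>P1..PL`` then 20 rows, first field the
    one-letter residue.  JSON dialect: object with ``name``, ``alphabet``
    (row order of ``weights``), ``weights`` and optional ``scoring_method``
    and ``normalised``.  Rows are re-mapped to canonical alphabet order.
    """
    text, name = _source_text(source, default_name="pssm")
    fmt = _detect_format(text) if format == "auto" else format
    if fmt == "json":
        obj = _load_json(text)
        if isinstance(obj, list):
            if len(obj) != 1:
                raise PSSMFormatError(
                    "expected a single PSSM but the JSON file holds "
                    f"{len(obj)}; use read_pssm_set"
                )
            obj = obj[0]
        return _pssm_from_json_obj(obj, fallback_name=name)
    if fmt == "tsv":
        return _pssm_from_tsv(text, name=name)
    raise PSSMFormatError(f"unknown PSSM format '{format}'")


def read_pssm_set(source: str | os.PathLike, format: str = "auto") -> list[PSSM]:
    """Read one or many PSSMs; a JSON list is a PSSM set."""
    text, name = _source_text(source, default_name="pssm")
    fmt = _detect_format(text) if format == "auto" else format
    if fmt == "json":
        obj = _load_json(text)
        if isinstance(obj, dict):
            obj = [obj]
        return [
            _pssm_from_json_obj(o, fallback_name=f"{name}_{i}")
            for i, o in enumerate(obj)
        ]
    return [read_pssm(source, format=fmt)]


def _detect_format(text: str) -> str:
    head = text.lstrip()[:1]
    return "json" if head in "{[" else "tsv"


def _load_json(text: str):
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise PSSMFormatError(f"invalid JSON PSSM: {exc}") from exc


def _remap_rows(alphabet: str, rows: np.ndarray, *, name: str) -> np.ndarray:
    """Re-order 20 rows given in `alphabet` order into canonical order."""
    seen: dict[str, int] = {}
    for i, aa in enumerate(alphabet):
        if aa not in _AA_INDEX:
            raise PSSMFormatError(
                f"PSSM '{name}': unknown amino-acid row '{aa}'"
            )
        if aa in seen:
            raise PSSMFormatError(
                f"PSSM '{name}': duplicated amino-acid row '{aa}'"
            )
        seen[aa] = i
    missing = [aa for aa in ALPHABET if aa not in seen]
    if missing:
        raise PSSMFormatError(
            f"PSSM '{name}': missing amino-acid row(s) {missing}"
        )
    out = np.empty_like(rows)
    for aa, i in seen.items():
        out[_AA_INDEX[aa]] = rows[i]
    return out


def _pssm_from_json_obj(obj: dict, *, fallback_name: str) -> PSSM:
    if not isinstance(obj, dict):
        raise PSSMFormatError("JSON PSSM must be an object")
    try:
        alphabet = str(obj["alphabet"])
        weights = obj["weights"]
    except KeyError as exc:
        raise PSSMFormatError(f"JSON PSSM missing key {exc}") from exc
    name = str(obj.get("name", fallback_name))
    rows = []
    length = None
    for i, row in enumerate(weights):
        row = list(row)
        if length is None:
            length = len(row)
        elif len(row) != length:
            raise PSSMFormatError(
                f"PSSM '{name}': row {i} has {len(row)} positions, "
                f"expected {length} (ragged columns)"
            )
        rows.append(row)
    if len(rows) != 20:
        raise PSSMFormatError(
            f"PSSM '{name}': expected 20 rows, got {len(rows)}"
        )
    arr = _remap_rows(alphabet, np.array(rows, dtype=float), name=name)
    return PSSM(
        name=name,
        weights=arr,
        scoring_method=str(obj.get("scoring_method", "external")),
        normalised=bool(obj.get("normalised", False)),
    )


def _pssm_from_tsv(text: str, *, name: str) -> PSSM:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PSSMFormatError("empty PSSM file")
    header = lines[0].split("\t")
    if header[0].strip().upper() != "AA":
        raise PSSMFormatError(
            f"PSSM '{name}': TSV header must start with 'AA', got "
            f"'{header[0]}'"
        )
    length = len(header) - 1
    if length < 1:
        raise PSSMFormatError(f"PSSM '{name}': header declares no positions")
    order = []
    rows = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        aa = fields[0].strip()
        if len(fields) - 1 != length:
            raise PSSMFormatError(
                f"PSSM '{name}': row '{aa}' has {len(fields) - 1} positions "
                f"but the header declares {length} (P1..P{length})"
            )
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise PSSMFormatError(
                f"PSSM '{name}': non-numeric value in row '{aa}': {exc}"
            ) from exc
        order.append(aa)
    if len(rows) != 20:
        missing = [aa for aa in ALPHABET if aa not in order]
        raise PSSMFormatError(
            f"PSSM '{name}': expected 20 rows, got {len(rows)}"
            + (f"; missing {missing}" if missing else "")
        )
    arr = _remap_rows("".join(order), np.array(rows, dtype=float), name=name)
    return PSSM(name=name, weights=arr)


def write_pssm(pssm: PSSM, format: str = "tsv") -> str:
    """Serialise a PSSM; ``read_pssm(write_pssm(p)) == p`` bit-faithfully."""
    if format == "tsv":
        buf = io.StringIO()
        buf.write("AA\t" + "\t".join(f"P{i+1}" for i in range(pssm.length)) + "\n")
        for i, aa in enumerate(ALPHABET):
            buf.write(
                aa + "\t" + "\t".join(repr(float(x)) for x in pssm.weights[i]) + "\n"
            )
        return buf.getvalue()
    if format == "json":
        obj = {
            "name": pssm.name,
            "alphabet": ALPHABET,
            "weights": [[float(x) for x in row] for row in pssm.weights],
            "scoring_method": pssm.scoring_method,
            "normalised": pssm.normalised,
        }
        return json.dumps(obj, indent=1)
    raise PSSMFormatError(f"unknown PSSM format '{format}'")


def read_peptides(source: str | os.PathLike, name: str | None = None) -> PeptideSet:
    """Read peptides from plain text (one per line) or FASTA."""
    text, src_name = _source_text(source, default_name="peptides")
    text = text.strip()
    if not text:
        raise PSSMFormatError("empty peptide input")
    if text.startswith(">"):
        from Bio import SeqIO

        peptides = [
            str(rec.seq).upper() for rec in SeqIO.parse(io.StringIO(text), "fasta")
        ]
    else:
        peptides = [ln.strip().upper() for ln in text.splitlines() if ln.strip()]
    return PeptideSet(peptides=peptides, name=name or src_name)


# ---------------------------------------------------------------------------
# Construction


def _counts(peptides: PeptideSet) -> np.ndarray:
    counts = np.zeros((20, peptides.length), dtype=float)
    for pep in peptides.peptides:
        for pos, aa in enumerate(pep):
            counts[_AA_INDEX[aa], pos] += 1
    return counts


def build_pssm(
    peptides: PeptideSet,
    method: str = "frequency",
    pseudocount: float = 0.0,
    background: float | Sequence[float] = 1.0 / 20.0,
    name: str | None = None,
) -> PSSM:
    """Build a PSSM from an aligned peptide set.

    ``background`` is the per-residue background rate used by
    ``binomial_log`` (a flat scalar by default).
    """
    if pseudocount < 0:
        raise PSSMFormatError("pseudocount must be non-negative")
    counts = _counts(peptides)
    n = len(peptides)
    if method == "frequency":
        weights = (counts + pseudocount) / (n + 20.0 * pseudocount)
    elif method == "binomial_log":
        bg = np.broadcast_to(np.asarray(background, dtype=float).reshape(-1, 1)
                             if np.ndim(background) else
                             np.full((20, 1), float(background)),
                             (20, peptides.length))
        # upper tail P(X >= count), X ~ Binomial(n, bg); sf(k-1) == P(X >= k)
        tail = stats.binom.sf(counts - 1, n, bg)
        weights = -np.log10(np.clip(tail, 1e-300, 1.0))
    elif method == "psiblast_ic":
        weights = _psiblast_ic(counts, n)
    else:
        raise PSSMFormatError(f"unknown scoring method '{method}'")
    return PSSM(
        name=name or peptides.name,
        weights=weights,
        scoring_method=method,
    )


def _blosum62_conditional() -> np.ndarray:
    """q(a|b) derived from the BLOSUM62 half-bit log-odds matrix."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    s = np.array(
        [[mat[a, b] for b in ALPHABET] for a in ALPHABET], dtype=float
    )
    p = ROBINSON_FREQUENCIES
    # target frequencies q_ab ~ p_a p_b 2^(s_ab / 2), renormalised
    q = np.outer(p, p) * np.exp2(s / 2.0)
    q /= q.sum()
    return q / q.sum(axis=0, keepdims=True)  # column b -> P(a | b)


def _psiblast_ic(counts: np.ndarray, n: int) -> np.ndarray:
    """Information-content-weighted log-odds with BLOSUM62 pseudocounts."""
    cond = _blosum62_conditional()
    p = ROBINSON_FREQUENCIES[:, None]
    f_obs = counts / n
    g = cond @ f_obs  # pseudocount frequencies from observed composition
    alpha, beta = max(n - 1, 0), 10.0
    f = (alpha * f_obs + beta * g) / (alpha + beta)
    logodds = np.log2(f / p)
    ic = np.clip((f * logodds).sum(axis=0, keepdims=True), 0.0, None)
    return logodds * ic


# ---------------------------------------------------------------------------
# Normalisation


def normalise(pssm: PSSM, mode: str = "column") -> PSSM:
    """Min-max scale a PSSM to [0, 1]; idempotent.

    ``column`` (default) scales each column by its own min/max; a constant
    column maps to all zeros so it carries no importance signal.  ``matrix``
    uses a single min/max over the whole matrix.
    """
    w = pssm.weights
    if mode == "column":
        lo = w.min(axis=0, keepdims=True)
        hi = w.max(axis=0, keepdims=True)
        span = hi - lo
        out = np.where(span > 0, (w - lo) / np.where(span > 0, span, 1.0), 0.0)
    elif mode == "matrix":
        lo, hi = w.min(), w.max()
        out = (w - lo) / (hi - lo) if hi > lo else np.zeros_like(w)
    else:
        raise PSSMFormatError(f"unknown normalisation mode '{mode}'")
    return PSSM(
        name=pssm.name,
        weights=out,
        scoring_method=pssm.scoring_method,
        normalised=True,
    )
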