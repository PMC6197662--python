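"""Amphiphilic pseudo amino acid composition (PseAAC) features.

A protein of length ``L`` is mapped to a fixed-length vector of
``20 + 2*lambda`` elements: the 20 relative residue frequencies plus
``lambda`` tiers of sequence-order correlation factors computed twice, once
through a standardized hydrophobicity index and once through a standardized
hydrophilicity index (hence "amphiphilic"). The k-th tier factor is the mean
product of index values over all residue pairs separated by k positions,

    tau_{2k-1} = (1/(L-k)) * sum_i h1(E_i) * h1(E_{i+k})    (hydrophobicity)
    tau_{2k}   = (1/(L-k)) * sum_i h2(E_i) * h2(E_{i+k})    (hydrophilicity)

and the final vector is normalized so that all elements sum to one:

    e_k = f_k / (sum_f + w * sum_tau)            for k = 1..20
    e_k = w * tau_{k-20} / (sum_f + w * sum_tau) for k = 21..20+2*lambda

with weight factor ``w`` balancing composition against order information.

The module exposes both plain functions (``pseaac_vector``,
``extract_features``) and an sklearn-style transformer
(:class:`PseAACEncoder`) so feature extraction composes with pipelines and
model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    AlphabetError,
    DegenerateIndexError,
    IncompleteTableError,
    NormalizationError,
    ParameterError,
    SequenceTooShortError,
)

#: The 20 canonical residues in alphabetical one-letter order. This fixed
#: order defines the layout of the first 20 vector elements.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Letters that occur in real protein records but are not canonical residues.
NONSTANDARD_RESIDUES = frozenset("BJOUXZ*")

_RESIDUE_INDEX = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}


@dataclass(frozen=True)
class EnzymeSequence:
    """An identified amino-acid chain.

    Residues are uppercased on construction. ``on_nonstandard`` controls the
    policy for letters outside the canonical alphabet: ``"error"`` (default)
    raises :class:`AlphabetError`, ``"drop"`` removes them (which shortens L
    and therefore every correlation denominator — use deliberately).
    """

    id: str
    residues: str

    def __init__(self, id: str, residues: str, on_nonstandard: str = "error"):
        residues = residues.upper().strip()
        if on_nonstandard not in ("error", "drop"):
            raise ParameterError(
                f"on_nonstandard must be 'error' or 'drop', got {on_nonstandard!r}"
            )
        bad = [c for c in residues if c not in _RESIDUE_INDEX]
        if bad:
            if on_nonstandard == "error":
                raise AlphabetError(
                    f"sequence {id!r} contains non-canonical residue(s) "
                    f"{sorted(set(bad))}"
                )
            residues = "".join(c for c in residues if c in _RESIDUE_INDEX)
        if len(residues) == 0:
            raise AlphabetError(f"sequence {id!r} has no canonical residues")
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class IndexTable:
    """A named amino-acid index: one raw real value per canonical residue."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self):
        missing = set(CANONICAL_RESIDUES) - set(self.values)
        if missing:
            raise IncompleteTableError(
                f"index table {self.name!r} is missing residues {sorted(missing)}"
            )

    def as_array(self) -> np.ndarray:
        """Values in canonical residue order."""
        return np.array([self.values[aa] for aa in CANONICAL_RESIDUES], float)


@dataclass(frozen=True)
class NormalizedIndexTable:
    """A standardized index: zero mean, unit population SD over the 20 residues."""

    name: str
    values: Mapping[str, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[aa] for aa in CANONICAL_RESIDUES], float)


def load_index_table(path_or_name) -> IndexTable:
    """Load an index table from a two-column CSV (``residue,value``).

    ``path_or_name`` may be a filesystem path or the stem of one of the
    packaged tables (``hydrophobicity_tanford``, ``hydrophilicity_hopp_woods``).
    """
    p = Path(str(path_or_name))
    if p.suffix == "" and not p.exists():
        ref = resources.files("xylact").joinpath(f"data/{path_or_name}.csv")
        with resources.as_file(ref) as f:
            df = pd.read_csv(f)
        name = str(path_or_name)
    else:
        df = pd.read_csv(p)
        name = p.stem
    values = dict(zip(df["residue"].astype(str), df["value"].astype(float)))
    return IndexTable(name=name, values=values)


def normalize_index(raw: IndexTable) -> NormalizedIndexTable:
    """Standardize a raw index to zero mean and unit population SD.

    The population SD (divide by 20) matches the conversion used by the
    original amphiphilic PseAAC formulation. A constant table has zero SD and
    raises :class:`DegenerateIndexError`.
    """
    arr = raw.as_array()
    mean = arr.mean()
    sd = math.sqrt(((arr - mean) ** 2).mean())
    if sd == 0.0:
        raise DegenerateIndexError(
            f"index table {raw.name!r} is constant and cannot be standardized"
        )
    std = (arr - mean) / sd
    return NormalizedIndexTable(
        name=raw.name, values=dict(zip(CANONICAL_RESIDUES, std.tolist()))
    )


def default_hydrophobicity() -> IndexTable:
    return load_index_table("hydrophobicity_tanford")


def default_hydrophilicity() -> IndexTable:
    return load_index_table("hydrophilicity_hopp_woods")


@dataclass(frozen=True)
class PseAACParams:
    """Parameters of the encoding.

    lambda_ : correlation tier depth (0 gives plain composition); must be < L
        for every encoded sequence.
    weight : the w factor of the normalization; 0 turns correlation terms off.
    """

    lambda_: int = 7
    weight: float = 0.05
    hydrophobicity: IndexTable = field(default_factory=default_hydrophobicity)
    hydrophilicity: IndexTable = field(default_factory=default_hydrophilicity)

    def __post_init__(self):
        if self.lambda_ < 0:
            raise ParameterError(f"lambda must be >= 0, got {self.lambda_}")
        if self.weight < 0:
            raise ParameterError(f"weight must be >= 0, got {self.weight}")

    @property
    def n_features(self) -> int:
        return 20 + 2 * self.lambda_


@dataclass(frozen=True)
class CorrelationFactors:
    """Ordered sequence-order correlation factors tau_1..tau_{2*lambda}.

    Odd positions (tau_1, tau_3, ...) carry the hydrophobicity tiers, even
    positions the hydrophilicity tiers.
    """

    tau: np.ndarray
    lambda_: int


def _encode(seq: EnzymeSequence) -> np.ndarray:
    return np.fromiter((_RESIDUE_INDEX[c] for c in seq.residues), dtype=np.intp)


def residue_frequencies(seq: EnzymeSequence) -> np.ndarray:
    """Relative frequencies f_k of the 20 canonical residues (sums to 1)."""
    counts = np.bincount(_encode(seq), minlength=20)
    return counts / len(seq)


def correlation_factors(seq: EnzymeSequence, params: PseAACParams) -> CorrelationFactors:
    """Compute tau_1..tau_{2*lambda} for one sequence.

    Requires ``lambda < L``; each tier-k factor averages L-k pair products,
    so the deepest tier still has at least one term.
    """
    L = len(seq)
    lam = params.lambda_
    if lam >= L:
        raise SequenceTooShortError(
            f"sequence {seq.id!r} has length {L}; correlation depth "
            f"lambda={lam} requires L > lambda"
        )
    idx = _encode(seq)
    h1 = normalize_index(params.hydrophobicity).as_array()[idx]
    h2 = normalize_index(params.hydrophilicity).as_array()[idx]
    tau = np.empty(2 * lam)
    for k in range(1, lam + 1):
        tau[2 * k - 2] = np.dot(h1[:-k], h1[k:]) / (L - k)
        tau[2 * k - 1] = np.dot(h2[:-k], h2[k:]) / (L - k)
    return CorrelationFactors(tau=tau, lambda_=lam)


def pseaac_vector(seq: EnzymeSequence, params: PseAACParams | None = None) -> np.ndarray:
    """The full (20 + 2*lambda)-element amphiphilic PseAAC vector.

    Elements sum to 1. Raises :class:`NormalizationError` if the denominator
    ``1 + w * sum(tau)`` is non-positive (possible for strongly anticorrelated
    sequences under a large weight).
    """
    params = params or PseAACParams()
    f = residue_frequencies(seq)
    if params.lambda_ > 0:
        tau = correlation_factors(seq, params).tau
    else:
        tau = np.empty(0)
    denom = f.sum() + params.weight * tau.sum()
    if denom <= 0:
        raise NormalizationError(
            f"sequence {seq.id!r}: pseudo-composition denominator "
            f"{denom:.6g} <= 0 (weight={params.weight}, sum tau={tau.sum():.6g})"
        )
    return np.concatenate([f, params.weight * tau]) / denom


def feature_names(lambda_: int = 7) -> list[str]:
    """Column labels ``e1..e{20+2*lambda}``."""
    return [f"e{i}" for i in range(1, 21 + 2 * lambda_)]


def extract_features(
    sequences: Iterable[EnzymeSequence], params: PseAACParams | None = None
) -> pd.DataFrame:
    """Encode a batch of sequences into a feature matrix.

    Rows preserve input order and are indexed by sequence id; columns are
    ``e1..e{20+2*lambda}``. Per-sequence failures are re-raised with the
    offending id attached.
    """
    params = params or PseAACParams()
    rows, ids = [], []
    for seq in sequences:
        rows.append(pseaac_vector(seq, params))
        ids.append(seq.id)
    data = np.vstack(rows) if rows else np.empty((0, params.n_features))
    return pd.DataFrame(data, index=pd.Index(ids, name="id"),
                        columns=feature_names(params.lambda_))


@dataclass(frozen=True)
class MatrixComparison:
    """Per-column maximum absolute deviation between two feature matrices."""

    max_abs_deviation: pd.Series
    tol: float

    @property
    def passed(self) -> bool:
        return bool((self.max_abs_deviation <= self.tol).all())

    @property
    def failing_columns(self) -> list[str]:
        return list(self.max_abs_deviation.index[self.max_abs_deviation > self.tol])


def compare_feature_matrices(
    computed: pd.DataFrame, reference: pd.DataFrame, tol: float = 1e-3
) -> MatrixComparison:
    """Column-wise deviation report between a computed and a reference matrix.

    Used to calibrate index tables and the weight factor against an external
    reference extraction. Shapes and row order must match.
    """
    if computed.shape != reference.shape:
        raise ParameterError(
            f"shape mismatch: computed {computed.shape} vs reference {reference.shape}"
        )
    dev = np.abs(np.asarray(computed, float) - np.asarray(reference, float))
    series = pd.Series(dev.max(axis=0), index=computed.columns)
    return MatrixComparison(max_abs_deviation=series, tol=tol)


class PseAACEncoder(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from protein sequences to PseAAC vectors.

    Accepts an iterable of :class:`EnzymeSequence` or plain strings (strings
    are wrapped with positional ids). Stateless apart from parameter
    validation; ``fit`` exists for pipeline compatibility.

    Parameters
    ----------
    lambda_ : int, default 7
        Correlation tier depth; output dimension is ``20 + 2*lambda_``.
    weight : float, default 0.05
        Weight factor w of the pseudo-composition normalization.
    hydrophobicity, hydrophilicity : IndexTable or None
        Raw index tables; packaged defaults when None.
    on_nonstandard : {"error", "drop"}
        Policy for non-canonical residues when encoding plain strings.
    """

    def __init__(self, lambda_: int = 7, weight: float = 0.05,
                 hydrophobicity: IndexTable | None = None,
                 hydrophilicity: IndexTable | None = None,
                 on_nonstandard: str = "error"):
        self.lambda_ = lambda_
        self.weight = weight
        self.hydrophobicity = hydrophobicity
        self.hydrophilicity = hydrophilicity
        self.on_nonstandard = on_nonstandard

    def _params(self) -> PseAACParams:
        return PseAACParams(
            lambda_=self.lambda_,
            weight=self.weight,
            hydrophobicity=self.hydrophobicity or default_hydrophobicity(),
            hydrophilicity=self.hydrophilicity or default_hydrophilicity(),
        )

    def _as_sequences(self, X) -> list[EnzymeSequence]:
        out = []
        for i, item in enumerate(X):
            if isinstance(item, EnzymeSequence):
                out.append(item)
            else:
                out.append(EnzymeSequence(f"seq{i}", str(item),
                                          on_nonstandard=self.on_nonstandard))
        return out

    def fit(self, X, y=None):
        params = self._params()
        self.params_ = params
        self.n_features_out_ = params.n_features
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            self.fit(X)
        seqs = self._as_sequences(X)
        return np.asarray(extract_features(seqs, self.params_))

    def get_feature_names_out(self, input_features=None):
        return np.array(feature_names(self.lambda_), dtype=object)
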