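"""Hexapeptide window scorers.

Two generic scorer families cover the component predictors feeding the
meta-model: residue propensity scales aggregated over the window
(FoldAmyloid- or AGGRESCAN-style) and 6x20 position-specific matrices
(Waltz-style). Predictors whose published algorithm is not expressible as
either family (trained SVMs, multi-window contiguity scores) enter as
precomputed per-hexapeptide score tables.

Scorers are stateless scikit-learn transformers: ``transform`` maps a list
of hexapeptides to a score column, ``fit`` is a no-op.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AMINO_ACIDS, WINDOW, ProteinSequence


@dataclass(frozen=True)
class ResidueScale:
    """A named map from each of the 20 standard residues to a finite value."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(AMINO_ACIDS):
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard residues; "
                f"missing {sorted(set(AMINO_ACIDS) - keys)}, extra {sorted(keys - set(AMINO_ACIDS))}"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} contains non-finite values")


@dataclass(frozen=True)
class PositionSpecificMatrix:
    """A named 6 positions x 20 residues matrix of finite reals.

    ``values[p][a]`` is the contribution of residue ``a`` at window position
    ``p`` (0-based internally; files use 1-based position labels).
    """

    name: str
    values: tuple  # tuple of 6 per-position residue->value mappings

    def __post_init__(self) -> None:
        if len(self.values) != WINDOW:
            raise ValueError(f"pssm {self.name!r} must have exactly {WINDOW} positions")
        for p, row in enumerate(self.values):
            if set(row) != set(AMINO_ACIDS):
                raise ValueError(f"pssm {self.name!r}, position {p + 1}: wrong residue set")
            if not all(math.isfinite(v) for v in row.values()):
                raise ValueError(f"pssm {self.name!r}, position {p + 1}: non-finite value")

    @classmethod
    def from_array(cls, name: str, arr: np.ndarray) -> "PositionSpecificMatrix":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (WINDOW, 20):
            raise ValueError(f"pssm array must be {WINDOW}x20, got {arr.shape}")
        rows = tuple(dict(zip(AMINO_ACIDS, row)) for row in arr)
        return cls(name=name, values=rows)


class HexapeptideScorer(TransformerMixin, BaseEstimator):
    """Base class: maps hexapeptides to real-valued scores.

    Subclasses implement :meth:`score_window`. Windows containing residues the
    scorer cannot handle score ``nan`` via :meth:`score_sequence` (the
    "skip-window" policy) but raise from :meth:`score_window`.
    """

    name: str = "scorer"
    kind: str = "abstract"

    def fit(self, X=None, y=None):  # stateless; present for pipeline compatibility
        return self

    def score_window(self, hexapeptide: str) -> float:
        raise NotImplementedError

    def _safe_score(self, hexapeptide: str) -> float:
        try:
            return self.score_window(hexapeptide)
        except KeyError:
            return float("nan")

    def transform(self, X: Iterable[str]) -> np.ndarray:
        """Score a sequence of hexapeptides; returns an ``(n, 1)`` column."""
        scores = np.array([self._score_checked(h) for h in X], dtype=float)
        return scores.reshape(-1, 1)

    def _score_checked(self, hexapeptide: str) -> float:
        if len(hexapeptide) != WINDOW:
            raise ValueError(f"{hexapeptide!r} is not a hexapeptide")
        return self.score_window(hexapeptide)

    def score_sequence(self, seq: ProteinSequence) -> np.ndarray:
        """Scores for every sliding window of ``seq`` (length L-5).

        Unscoreable windows (nonstandard residues under the skip-window
        policy, or hexapeptides missing from an external table) are ``nan``.
        """
        if len(seq) < WINDOW:
            raise ValueError(
                f"sequence {seq.id!r} has length {len(seq)} < {WINDOW}; no windows"
            )
        return np.array([self._safe_score(w) for w in seq.windows()], dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray([self.name], dtype=object)


class ScaleScorer(HexapeptideScorer):
    """Residue-scale scorer: mean (default) or sum of per-residue values.

    Mean aggregation keeps scores on the scale's own units regardless of
    window length and is the default; sum equals 6x the mean on hexapeptides.
    """

    kind = "scale"

    def __init__(self, scale: ResidueScale, aggregation: str = "mean"):
        if aggregation not in ("mean", "sum"):
            raise ValueError(f"aggregation must be 'mean' or 'sum', got {aggregation!r}")
        self.scale = scale
        self.aggregation = aggregation

    @property
    def name(self) -> str:
        return self.scale.name

    def score_window(self, hexapeptide: str) -> float:
        vals = [self.scale.values[c] for c in hexapeptide]  # KeyError on unknown residue
        total = float(sum(vals))
        return total / WINDOW if self.aggregation == "mean" else total


class PSSMScorer(HexapeptideScorer):
    """Position-specific matrix scorer: sum of ``pssm[p][residue]`` over positions."""

    kind = "pssm"

    def __init__(self, pssm: PositionSpecificMatrix):
        self.pssm = pssm

    @property
    def name(self) -> str:
        return self.pssm.name

    def score_window(self, hexapeptide: str) -> float:
        return float(sum(self.pssm.values[p][c] for p, c in enumerate(hexapeptide)))


class TableScorer(HexapeptideScorer):
    """External scorer backed by a precomputed hexapeptide -> score table."""

    kind = "external"

    def __init__(self, name: str, table: Mapping[str, float]):
        self._name = name
        self.table = dict(table)

    @property
    def name(self) -> str:
        return self._name

    def score_window(self, hexapeptide: str) -> float:
        try:
            return float(self.table[hexapeptide])
        except KeyError:
            raise KeyError(
                f"scorer {self._name!r}: no precomputed score for {hexapeptide!r}"
            ) from None


class CachedScorer(HexapeptideScorer):
    """Memoising wrapper around another scorer.

    Emulates a precomputed score store: each distinct hexapeptide is scored
    once and the value is reused bit-identically thereafter. Optionally
    persists the cache as a two-column TSV.
    """

    kind = "cached"

    def __init__(self, scorer: HexapeptideScorer, cache_path: str | Path | None = None):
        self.scorer = scorer
        self.cache_path = cache_path
        self._cache: dict[str, float] = {}
        if cache_path is not None and Path(cache_path).exists():
            df = pd.read_csv(cache_path, sep="\t")
            self._cache = dict(zip(df["peptide"], df["score"].astype(float)))

    @property
    def name(self) -> str:
        return self.scorer.name

    def score_window(self, hexapeptide: str) -> float:
        if hexapeptide not in self._cache:
            self._cache[hexapeptide] = self.scorer.score_window(hexapeptide)
        return self._cache[hexapeptide]

    def save_cache(self) -> None:
        if self.cache_path is None:
            raise ValueError("no cache_path configured")
        pd.DataFrame(
            sorted(self._cache.items()), columns=["peptide", "score"]
        ).to_csv(self.cache_path, sep="\t", index=False)


def score_all_windows(seq: ProteinSequence, scorer: HexapeptideScorer) -> np.ndarray:
    """Per-window scores for ``seq``; value ``w`` (0-based) is the score of the
    window starting at 1-based residue ``w+1``."""
    return scorer.score_sequence(seq)


def hexapeptide_space_size(alphabet: Sequence[str] | str = AMINO_ACIDS, k: int = WINDOW) -> int:
    """Number of distinct k-mers over an alphabet (20^6 = 64,000,000 hexapeptides)."""
    n = len(set(alphabet))
    if n == 0:
        raise ValueError("alphabet is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    return n**k


def features_for_peptides(
    peptides: Sequence[str], scorers: Sequence[HexapeptideScorer]
) -> pd.DataFrame:
    """Feature matrix: one row per peptide, one named column per scorer."""
    names = [s.name for s in scorers]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate scorer names: {names}")
    cols = {s.name: s.transform(peptides).ravel() for s in scorers}
    return pd.DataFrame(cols, columns=names)


class FeatureStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise standardisation to sample mean 0 and sample (ddof=1) sd 1.

    The fitted location and scale are recorded so held-out peptides are
    transformed consistently with the training data.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("standardisation needs at least 2 rows")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.mean_ = X.mean(axis=0).to_numpy(dtype=float)
        self.scale_ = X.std(axis=0, ddof=1).to_numpy(dtype=float)
        zero = [str(c) for c, s in zip(X.columns, self.scale_) if not s > 0]
        if zero:
            raise ValueError(f"zero-variance scorer column(s): {zero}")
        return self

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if list(X.columns) != list(self.feature_names_in_):
            X = X[list(self.feature_names_in_)]
        return (X - self.mean_) / self.scale_

    def to_dict(self) -> dict:
        return {
            "columns": [str(c) for c in self.feature_names_in_],
            "mean": [float(m) for m in self.mean_],
            "scale": [float(s) for s in self.scale_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureStandardizer":
        obj = cls()
        obj.feature_names_in_ = np.asarray(d["columns"], dtype=object)
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.scale_ = np.asarray(d["scale"], dtype=float)
        return obj


# ---------------------------------------------------------------------------
# Parameter files

def read_scale_tsv(path: str | Path, name: str | None = None) -> ResidueScale:
    """Read a residue scale from a two-column TSV (residue, value)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if not {"residue", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'residue' and 'value'")
    values = {str(r.residue): float(r.value) for r in df.itertuples(index=False)}
    return ResidueScale(name=name or path.stem, values=values)


def write_scale_tsv(scale: ResidueScale, path: str | Path) -> None:
    pd.DataFrame(
        [(a, scale.values[a]) for a in AMINO_ACIDS], columns=["residue", "value"]
    ).to_csv(Path(path), sep="\t", index=False)


def read_pssm_tsv(path: str | Path, name: str | None = None) -> PositionSpecificMatrix:
    """Read a 6x20 matrix from a TSV with a ``position`` column plus 20 residue columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "position" not in df.columns:
        raise ValueError(f"{path}: expected a 'position' column")
    df = df.sort_values("position").set_index("position")
    if len(df) != WINDOW:
        raise ValueError(f"{path}: expected {WINDOW} positions, got {len(df)}")
    arr = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
    return PositionSpecificMatrix.from_array(name or path.stem, arr)


def write_pssm_tsv(pssm: PositionSpecificMatrix, path: str | Path) -> None:
    rows = [
        {"position": p + 1, **{a: pssm.values[p][a] for a in AMINO_ACIDS}}
        for p in range(WINDOW)
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_score_table_tsv(path: str | Path, name: str | None = None) -> TableScorer:
    """Read an external scorer's precomputed table (columns: peptide, score)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
    if not {"peptide", "score"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'peptide' and 'score'")
    return TableScorer(name or path.stem, dict(zip(df["peptide"], df["score"].astype(float))))
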