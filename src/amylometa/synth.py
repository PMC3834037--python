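"""Synthetic data generators for the whole pipeline.

Everything needed to exercise training, selection, evaluation and profiling
is generated in-process and reproducibly from a seed: a suite of synthetic
window scorers (stand-ins for published residue scales and position-specific
matrices, with randomly drawn parameters), labelled hexapeptide datasets
with tunable class separation, feature matrices sampled from a known
logistic model, and proteins with planted high-propensity segments.

Default class sizes (116 positive / 162 negative hexapeptides, 278 in all)
match the size of the experimentally characterised hexapeptide collections
that this kind of meta-predictor is trained on. The default separation of
2.0 gives individual synthetic scorers an AUC above 0.8, i.e. informative
but imperfect components, which is the regime where stacking them pays off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, WINDOW, LabelledHexDataset, ProteinSequence, RegionAnnotation
from .scorers import (
    HexapeptideScorer,
    PositionSpecificMatrix,
    PSSMScorer,
    ResidueScale,
    ScaleScorer,
)

__all__ = [
    "SyntheticConfig",
    "synthetic_scorer_suite",
    "residue_propensity",
    "gen_labelled_hexapeptides",
    "gen_features_from_logistic",
    "gen_stepwise_benchmark",
    "gen_annotated_protein",
    "scramble",
]

#: Default planted coefficients (intercept first) for logistic simulations.
DEFAULT_BETA = (-1.0, 0.8, -0.5, 0.6, 0.9)


@dataclass(frozen=True)
class SyntheticConfig:
    """Reproducible generator settings: identical config => identical output.

    separation is the effect size of the positive-class enrichment in
    high-propensity residues (0 = classes indistinguishable); planted_beta
    is (intercept, slopes...) for logistic feature simulation; rho is the
    equicorrelation of simulated feature columns.
    """

    seed: int = 0
    n_pos: int = 116
    n_neg: int = 162
    separation: float = 2.0
    planted_beta: tuple[float, ...] = DEFAULT_BETA
    rho: float = 0.0

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def synthetic_scorer_suite(
    seed: int = 0, n_scales: int = 3, n_pssm: int = 1
) -> list[HexapeptideScorer]:
    """A deterministic suite of synthetic component scorers.

    Parameters are standard-normal draws, not any published predictor's
    values: the suite emulates the *shape* of a residue-scale / matrix scorer
    panel (shared preference for the same residues, independent noise), not
    real amyloid propensities.

    All scorers share a common latent residue propensity (see
    :func:`residue_propensity`) perturbed per scorer, so the suite behaves
    like a panel of correlated but complementary predictors.
    """
    rng = np.random.default_rng((seed, 101))
    latent = rng.standard_normal(20)
    scorers: list[HexapeptideScorer] = []
    for i in range(n_scales):
        vals = 0.75 * latent + 0.66 * rng.standard_normal(20)
        scale = ResidueScale(
            name=f"synth-scale-{chr(ord('A') + i)}",
            values=dict(zip(AMINO_ACIDS, vals.round(4))),
        )
        scorers.append(ScaleScorer(scale))
    for i in range(n_pssm):
        rows = 0.75 * latent[None, :] + 0.66 * rng.standard_normal((WINDOW, 20))
        pssm = PositionSpecificMatrix.from_array(
            f"synth-pssm-{chr(ord('A') + i)}", rows.round(4)
        )
        scorers.append(PSSMScorer(pssm))
    return scorers


def residue_propensity(scorers: Sequence[HexapeptideScorer]) -> np.ndarray:
    """Consensus per-residue propensity of a scorer suite (z-scored, length 20).

    Scales contribute their values; matrices contribute their position-mean
    column. Used to bias the residue composition of synthetic positives.
    """
    cols = []
    for s in scorers:
        if isinstance(s, ScaleScorer):
            v = np.array([s.scale.values[a] for a in AMINO_ACIDS])
        elif isinstance(s, PSSMScorer):
            v = np.array(
                [np.mean([s.pssm.values[p][a] for p in range(WINDOW)]) for a in AMINO_ACIDS]
            )
        else:
            continue
        cols.append((v - v.mean()) / v.std())
    if not cols:
        raise ValueError("suite contains no scale or matrix scorers")
    consensus = np.mean(cols, axis=0)
    return (consensus - consensus.mean()) / consensus.std()


def _sample_peptides(
    rng: np.random.Generator, n: int, weights: np.ndarray, taken: set
) -> list[str]:
    aas = np.array(list(AMINO_ACIDS))
    out: list[str] = []
    while len(out) < n:
        draws = rng.choice(aas, size=(n - len(out), WINDOW), p=weights)
        for row in draws:
            pep = "".join(row)
            if pep not in taken:
                taken.add(pep)
                out.append(pep)
            if len(out) == n:
                break
    return out


def gen_labelled_hexapeptides(
    cfg: SyntheticConfig, scorers: Sequence[HexapeptideScorer] | None = None
) -> LabelledHexDataset:
    """Labelled hexapeptides with tunable class separation.

    Positive peptides draw residues with probability proportional to
    exp(separation * propensity(residue) / 2); negatives draw uniformly
    (the background). Exact class counts are honoured and duplicate
    peptides within a class are resampled.
    """
    if cfg.n_pos < 1 or cfg.n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    if scorers is None:
        scorers = synthetic_scorer_suite(cfg.seed)
    prop = residue_propensity(scorers)
    rng = cfg.rng(salt=1)
    w_pos = np.exp(cfg.separation * prop / 2.0)
    w_pos /= w_pos.sum()
    w_neg = np.full(20, 1.0 / 20.0)
    taken_pos: set = set()
    taken_neg: set = set()
    pos = _sample_peptides(rng, cfg.n_pos, w_pos, taken_pos)
    neg = _sample_peptides(rng, cfg.n_neg, w_neg, taken_neg)
    records = [(p, 1) for p in pos] + [(p, 0) for p in neg]
    return LabelledHexDataset(records=records, provenance=f"synthetic(seed={cfg.seed})")


def gen_features_from_logistic(
    cfg: SyntheticConfig, n: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix and labels drawn from a known logistic model.

    Columns are standard normal with pairwise correlation ``cfg.rho``
    (single-factor construction); labels are Bernoulli with probability
    logistic(b0 + X @ b) where ``cfg.planted_beta = (b0, b...)``.
    """
    beta = np.asarray(cfg.planted_beta, dtype=float)
    if beta.size < 1:
        raise ValueError("planted_beta must contain at least the intercept")
    k = beta.size - 1
    rng = cfg.rng(salt=2)
    if not 0.0 <= cfg.rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    z = rng.standard_normal((n, k))
    if cfg.rho > 0:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(cfg.rho) * shared + np.sqrt(1.0 - cfg.rho) * z
    eta = beta[0] + z @ beta[1:]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    X = pd.DataFrame(z, columns=[f"s{j + 1}" for j in range(k)])
    return X, y


def gen_stepwise_benchmark(
    cfg: SyntheticConfig,
    n: int,
    n_signal: int = 4,
    n_redundant: int = 7,
    copy_corr: float = 0.9,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Candidate pool for selection-consistency experiments.

    ``n_signal`` independent causal columns drive the labels through
    ``cfg.planted_beta`` (which must supply one slope per signal column);
    ``n_redundant`` extra columns are noisy copies of the causal ones with
    correlation ``copy_corr``, mimicking a predictor panel in which several
    scores are near-duplicates of others. The default correlation of 0.9
    keeps copies strongly redundant while leaving the originals identifiably
    more informative; at correlations much closer to 1 an original and its
    copy become statistically exchangeable and any selector picks between
    them at random. Returns (X, y, signal_names).
    """
    beta = np.asarray(cfg.planted_beta, dtype=float)
    if beta.size != n_signal + 1:
        raise ValueError(
            f"planted_beta must have intercept + {n_signal} slopes, got {beta.size}"
        )
    rng = cfg.rng(salt=3)
    sig = rng.standard_normal((n, n_signal))
    eta = beta[0] + sig @ beta[1:]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    dup_src = [j % n_signal for j in range(n_redundant)]
    noise = rng.standard_normal((n, n_redundant))
    dup = copy_corr * sig[:, dup_src] + np.sqrt(1.0 - copy_corr**2) * noise
    signal_names = [f"sig{j + 1}" for j in range(n_signal)]
    dup_names = [f"dup{j + 1}" for j in range(n_redundant)]
    X = pd.DataFrame(
        np.column_stack([sig, dup]), columns=signal_names + dup_names
    )
    return X, y, signal_names


def gen_annotated_protein(
    cfg: SyntheticConfig,
    length: int,
    n_hotspots: int,
    segment_len: tuple[int, int] = (WINDOW, 12),
    min_gap: int = WINDOW,
    scorers: Sequence[HexapeptideScorer] | None = None,
) -> tuple[ProteinSequence, list[RegionAnnotation]]:
    """A background sequence with planted high-propensity segments.

    Background residues are drawn depleted in high-propensity residues
    (weights proportional to exp(-separation * propensity / 2)); each planted
    segment (length uniform in ``segment_len``) is drawn with weights
    proportional to exp(separation * propensity), i.e. from the strong upper
    end of the positive-class composition -- planted segments emulate
    experimentally *validated* hot spots, which are unambiguous aggregators
    rather than borderline positives. Segments are
    separated from each other and the termini by at least ``min_gap``
    residues and their coordinates are returned as annotations.
    """
    if scorers is None:
        scorers = synthetic_scorer_suite(cfg.seed)
    prop = residue_propensity(scorers)
    rng = cfg.rng(salt=4)
    lo, hi = segment_len
    if lo < WINDOW:
        raise ValueError(f"segments must be at least {WINDOW} residues")
    lens = rng.integers(lo, hi + 1, size=n_hotspots).tolist() if n_hotspots else []
    needed = sum(lens) + (n_hotspots + 1) * min_gap
    if length < max(needed, WINDOW):
        raise ValueError(
            f"cannot pack {n_hotspots} segment(s) of {lo}-{hi} residues plus "
            f"{min_gap}-residue gaps into length {length}"
        )
    slack = length - needed
    # distribute the slack over the n+1 gaps uniformly at random
    cuts = np.sort(rng.integers(0, slack + 1, size=n_hotspots)) if n_hotspots else []
    extras = np.diff(np.concatenate([[0], cuts, [slack]])) if n_hotspots else [slack]

    aas = np.array(list(AMINO_ACIDS))
    w_hot = np.exp(cfg.separation * prop)
    w_hot /= w_hot.sum()
    w_bg = np.exp(-cfg.separation * prop / 2.0)
    w_bg /= w_bg.sum()

    parts: list[str] = []
    regions: list[RegionAnnotation] = []
    pos = 0
    seq_id = f"synthprot-{cfg.seed}"
    for i in range(n_hotspots):
        gap = min_gap + int(extras[i])
        parts.append("".join(rng.choice(aas, size=gap, p=w_bg)))
        pos += gap
        seg = "".join(rng.choice(aas, size=int(lens[i]), p=w_hot))
        regions.append(RegionAnnotation(seq_id, pos + 1, pos + len(seg)))
        parts.append(seg)
        pos += len(seg)
    tail = min_gap + int(extras[-1]) if n_hotspots else length
    parts.append("".join(rng.choice(aas, size=tail, p=w_bg)))
    residues = "".join(parts)
    assert len(residues) == length
    return ProteinSequence(id=seq_id, residues=residues), regions


def scramble(seq: ProteinSequence, seed: int = 0) -> ProteinSequence:
    """Uniform random permutation of a sequence's residues (an anagram),
    mirroring scrambled-peptide aggregation experiments."""
    rng = np.random.default_rng((seed, 5))
    perm = rng.permutation(len(seq.residues))
    return ProteinSequence(
        id=f"{seq.id}-scramble{seed}",
        residues="".join(seq.residues[i] for i in perm),
    )
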