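"""Per-residue amyloidogenicity profiles, hot-spot calling and variant scoring.

A profile is built with a sliding hexapeptide window: window ``w`` (1-based
start) covers residues ``w..w+5``, its meta-probability is assigned to the
window's third residue (``w+2``), and a hot spot is a maximal run of
consecutive windows at or above the decision threshold. Two AGGRESCAN-style
summaries quantify aggregation propensity: the Total Area (TA, the sum of
all window scores of the sequence) and the per-hot-spot Normalized Hot Spot
Area (NHSA, the area between profile and threshold divided by the number of
residues the hot spot covers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import WINDOW, ProteinSequence
from .model import LogisticMetaClassifier
from .scorers import HexapeptideScorer

__all__ = [
    "ScoreProfile",
    "HotSpot",
    "MutationEffect",
    "compute_profile",
    "call_hotspots",
    "total_area",
    "nhsa",
    "region_total_area",
    "mutation_effect",
    "write_profile_tsv",
    "write_hotspots_tsv",
]


@dataclass(frozen=True)
class ScoreProfile:
    """Window meta-scores for one sequence.

    ``window_scores[w-1]`` is the meta-probability of the window starting at
    1-based residue ``w`` (``nan`` where the window is unscoreable under the
    skip-window residue policy). Terminal residues 1-2 and L-2..L carry no
    assigned score.
    """

    sequence_id: str
    residues: str
    window_scores: np.ndarray

    def __post_init__(self) -> None:
        expected = len(self.residues) - WINDOW + 1
        if expected < 1:
            raise ValueError(f"sequence {self.sequence_id!r} shorter than one window")
        if len(self.window_scores) != expected:
            raise ValueError(
                f"expected {expected} window scores, got {len(self.window_scores)}"
            )

    @property
    def n_windows(self) -> int:
        return len(self.window_scores)

    @property
    def residue_assignment(self) -> dict[int, float]:
        """Window score placed on its third residue: residue w+2 <- window w."""
        return {
            w + 2: float(s)
            for w, s in zip(range(1, self.n_windows + 1), self.window_scores)
            if not np.isnan(s)
        }


@dataclass(frozen=True)
class HotSpot:
    """A maximal run of consecutive windows scoring >= the threshold.

    The residue span is the union of the run's windows, so it always holds
    that residue_end - residue_start + 1 = (last_window - first_window) + 6.
    """

    first_window: int
    last_window: int
    residue_start: int
    residue_end: int
    peak_score: float
    nhsa: float

    @property
    def n_residues(self) -> int:
        return self.residue_end - self.residue_start + 1


def compute_profile(
    seq: ProteinSequence,
    model: LogisticMetaClassifier,
    scorers: Sequence[HexapeptideScorer],
) -> ScoreProfile:
    """Score every window of ``seq`` with the component scorers, then map the
    component scores through the fitted meta-model."""
    if len(seq) < WINDOW:
        raise ValueError(f"sequence {seq.id!r} shorter than {WINDOW} residues")
    by_name = {s.name: s for s in scorers}
    needed = [str(n) for n in model.feature_names_in_]
    missing = set(needed) - set(by_name)
    if missing:
        raise ValueError(f"no scorer supplied for model component(s): {sorted(missing)}")
    cols = {name: by_name[name].score_sequence(seq) for name in needed}
    feats = pd.DataFrame(cols, columns=needed)
    scores = np.full(len(feats), np.nan)
    ok = ~feats.isna().any(axis=1).to_numpy()
    if ok.any():
        scores[ok] = model.predict_proba(feats.loc[ok])[:, 1]
    return ScoreProfile(sequence_id=seq.id, residues=seq.residues, window_scores=scores)


def call_hotspots(profile: ScoreProfile, threshold: float) -> list[HotSpot]:
    """Maximal runs of consecutive windows with score >= threshold, in order.

    Unscoreable (nan) windows terminate a run. Residue spans of distinct hot
    spots may not overlap each other's window runs but can share flanking
    residues only when runs are separated; by construction runs separated by
    at least one below-threshold window yield ordered, disjoint window ranges.
    """
    s = profile.window_scores
    above = np.zeros(len(s), dtype=bool)
    with np.errstate(invalid="ignore"):
        above[~np.isnan(s)] = s[~np.isnan(s)] >= threshold
    spots: list[HotSpot] = []
    w = 0
    while w < len(s):
        if not above[w]:
            w += 1
            continue
        start = w
        while w + 1 < len(s) and above[w + 1]:
            w += 1
        first, last = start + 1, w + 1  # 1-based window indices
        run = s[start : w + 1]
        spots.append(
            HotSpot(
                first_window=first,
                last_window=last,
                residue_start=first,
                residue_end=last + WINDOW - 1,
                peak_score=float(np.max(run)),
                nhsa=float(np.sum(run - threshold) / (last - first + WINDOW)),
            )
        )
        w += 1
    return spots


def total_area(profile: ScoreProfile) -> float:
    """TA: sum of all (scoreable) window scores along the sequence; independent
    of any threshold."""
    return float(np.nansum(profile.window_scores))


def nhsa(profile: ScoreProfile, hotspot: HotSpot, threshold: float) -> float:
    """NHSA: sum over the hot spot's windows of (score - threshold), divided by
    the number of residues the hot spot covers."""
    s = profile.window_scores[hotspot.first_window - 1 : hotspot.last_window]
    if np.any(np.isnan(s)) or np.any(s < threshold):
        raise ValueError("hot spot does not match the profile at this threshold")
    return float(np.sum(s - threshold) / hotspot.n_residues)


def region_total_area(profile: ScoreProfile, start: int, end: int) -> float:
    """TA restricted to windows whose start residue lies in [start, end]."""
    if not 1 <= start <= end:
        raise ValueError(f"invalid region {start}-{end}")
    lo = max(1, start)
    hi = min(profile.n_windows, end)
    if hi < lo:
        return 0.0
    return float(np.nansum(profile.window_scores[lo - 1 : hi]))


def _region_nhsa(profile: ScoreProfile, threshold: float, start: int, end: int) -> float:
    """Sum of per-hot-spot NHSA contributions from windows starting in the region."""
    out = 0.0
    for spot in call_hotspots(profile, threshold):
        lo = max(spot.first_window, start)
        hi = min(spot.last_window, end)
        if hi < lo:
            continue
        s = profile.window_scores[lo - 1 : hi]
        out += float(np.sum(s - threshold) / spot.n_residues)
    return out


@dataclass(frozen=True)
class MutationEffect:
    """Mutant-minus-wild-type change in aggregation propensity over a region."""

    wt_id: str
    mut_id: str
    region: tuple[int, int]
    delta_nhsa: float
    delta_ta: float
    mutation_kind: str  # "missense" or "frameshift"
    n_substitutions: int


def mutation_effect(
    wt: ProteinSequence,
    mut: ProteinSequence,
    region: tuple[int, int],
    model: LogisticMetaClassifier,
    scorers: Sequence[HexapeptideScorer],
    threshold: float,
) -> MutationEffect:
    """Score a sequence variant against its wild type over a residue region.

    delta_ta is the change in region-restricted TA (windows attributed to the
    region by their start residue); delta_nhsa sums, over called hot spots,
    the (score - threshold)/length contributions of windows starting in the
    region. Equal-length sequences are classified missense (with a warning if
    more than one position differs); length changes are frameshifts and the
    region is clipped to each sequence's own window range.
    """
    start, end = int(region[0]), int(region[1])
    if not 1 <= start <= end:
        raise ValueError(f"invalid region {start}-{end}")
    if len(wt) < WINDOW or len(mut) < WINDOW:
        raise ValueError("both sequences must be at least 6 residues long")
    if len(wt) == len(mut):
        n_sub = sum(a != b for a, b in zip(wt.residues, mut.residues))
        kind = "missense"
        if n_sub > 1:
            warnings.warn(
                f"{mut.id}: {n_sub} substitutions differ from {wt.id}; "
                "treating as a multi-substitution missense variant",
                stacklevel=2,
            )
    else:
        n_sub = -1
        kind = "frameshift"

    prof_wt = compute_profile(wt, model, scorers)
    prof_mut = compute_profile(mut, model, scorers)
    ta_wt = region_total_area(prof_wt, start, min(end, len(wt)))
    ta_mut = region_total_area(prof_mut, start, min(end, len(mut)))
    nhsa_wt = _region_nhsa(prof_wt, threshold, start, min(end, len(wt)))
    nhsa_mut = _region_nhsa(prof_mut, threshold, start, min(end, len(mut)))
    return MutationEffect(
        wt_id=wt.id,
        mut_id=mut.id,
        region=(start, end),
        delta_nhsa=nhsa_mut - nhsa_wt,
        delta_ta=ta_mut - ta_wt,
        mutation_kind=kind,
        n_substitutions=n_sub,
    )


# ---------------------------------------------------------------------------
# Reports


def write_profile_tsv(profile: ScoreProfile, path: str | Path) -> None:
    """Per-residue report: id, position, residue, assigned score ('NA' at the
    unassigned terminal residues and unscoreable windows)."""
    assign = profile.residue_assignment
    rows = [
        {
            "sequence_id": profile.sequence_id,
            "position": i,
            "residue": r,
            "score": assign.get(i, float("nan")),
        }
        for i, r in enumerate(profile.residues, start=1)
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False, na_rep="NA")


def write_hotspots_tsv(
    profile: ScoreProfile, spots: Sequence[HotSpot], path: str | Path
) -> None:
    rows = [
        {
            "sequence_id": profile.sequence_id,
            "residue_start": h.residue_start,
            "residue_end": h.residue_end,
            "peak_score": h.peak_score,
            "nhsa": h.nhsa,
            "ta": total_area(profile),
        }
        for h in spots
    ]
    pd.DataFrame(
        rows,
        columns=["sequence_id", "residue_start", "residue_end", "peak_score", "nhsa", "ta"],
    ).to_csv(Path(path), sep="\t", index=False)
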