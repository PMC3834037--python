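"""Reading, validation and writing of sequences, peptide datasets and region tables.

All residue and region coordinates in the public API are 1-based and
inclusive, matching the convention of protein mutation nomenclature
(e.g. "region 500-580 of the mature protein").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity codes mapped to a standard stand-in (B=Asx->N, Z=Glx->Q, J->L, U=Sec->C, O=Pyl->K).
AMBIGUITY_MAP = {"B": "N", "Z": "Q", "J": "L", "U": "C", "O": "K"}
#: Letters tolerated under the "skip-window" policy; windows containing them are unscoreable.
NONSTANDARD = set(AMBIGUITY_MAP) | {"X"}

WINDOW = 6  # hexapeptide window length; fixed throughout the package

VALIDATION_POLICIES = ("reject", "map-to-nearest", "skip-window")


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the accepted alphabet."""


class FastaParseError(ValueError):
    """A FASTA file could not be parsed."""


class DatasetFormatError(ValueError):
    """A tabular dataset violates the expected layout."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated amino-acid sequence.

    ``residues`` contains only the 20 standard one-letter codes, except under
    the ``skip-window`` validation policy where nonstandard letters survive
    and mark their windows unscoreable.
    """

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_windows(self) -> int:
        """Number of hexapeptide windows (L - 5; 0 for sequences shorter than 6)."""
        return max(0, len(self.residues) - WINDOW + 1)

    def window(self, start: int) -> str:
        """Hexapeptide starting at 1-based residue ``start``."""
        if not 1 <= start <= self.n_windows:
            raise IndexError(
                f"window start {start} out of range 1..{self.n_windows} for {self.id!r}"
            )
        return self.residues[start - 1 : start - 1 + WINDOW]

    def windows(self) -> list[str]:
        return [self.window(w) for w in range(1, self.n_windows + 1)]


@dataclass
class LabelledHexDataset:
    """Hexapeptides with binary amyloid labels (1 = amyloid-forming)."""

    records: list[tuple[str, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for i, (pep, lab) in enumerate(self.records):
            if len(pep) != WINDOW:
                raise DatasetFormatError(
                    f"record {i + 1}: peptide {pep!r} is not a hexapeptide"
                )
            bad = [c for c in pep if c not in AMINO_ACIDS]
            if bad:
                raise DatasetFormatError(
                    f"record {i + 1}: {bad[0]!r} is not a standard amino acid"
                )
            if lab not in (0, 1):
                raise DatasetFormatError(f"record {i + 1}: label {lab!r} not in {{0,1}}")
            if (pep, lab) in seen:
                raise DatasetFormatError(f"record {i + 1}: duplicate record ({pep}, {lab})")
            seen.add((pep, lab))

    @property
    def peptides(self) -> list[str]:
        return [p for p, _ in self.records]

    @property
    def labels(self) -> list[int]:
        return [l for _, l in self.records]

    @property
    def n_pos(self) -> int:
        return sum(self.labels)

    @property
    def n_neg(self) -> int:
        return len(self.records) - self.n_pos

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["peptide", "label"])


@dataclass(frozen=True)
class RegionAnnotation:
    """A 1-based inclusive residue interval on a named sequence."""

    sequence_id: str
    start: int
    end: int
    status: str = "amyloid"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid region {self.start}-{self.end} on {self.sequence_id!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def validate_sequence(
    raw: str, id: str = "seq", policy: str = "reject"
) -> ProteinSequence:
    """Validate and normalise a raw amino-acid string.

    Policies for nonstandard letters (B, J, O, U, X, Z):

    - ``reject`` (default): raise :class:`SequenceValidationError` at the first
      offending position.
    - ``map-to-nearest``: replace ambiguity codes with a standard stand-in
      (see :data:`AMBIGUITY_MAP`); ``X`` has no stand-in and is rejected.
    - ``skip-window``: keep the letter; downstream scorers mark every window
      containing it as unscoreable.

    Characters outside A-Z (after upper-casing and stripping whitespace and a
    trailing ``*``) are always rejected.
    """
    if policy not in VALIDATION_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {VALIDATION_POLICIES}")
    cleaned = "".join(raw.split()).upper().rstrip("*")
    if not cleaned:
        raise SequenceValidationError(f"sequence {id!r} is empty")
    out = []
    for pos, ch in enumerate(cleaned, start=1):
        if ch in AMINO_ACIDS:
            out.append(ch)
            continue
        if ch in NONSTANDARD:
            if policy == "reject":
                raise SequenceValidationError(
                    f"sequence {id!r}: nonstandard residue {ch!r} at position {pos}"
                )
            if policy == "map-to-nearest":
                if ch not in AMBIGUITY_MAP:
                    raise SequenceValidationError(
                        f"sequence {id!r}: residue {ch!r} at position {pos} "
                        "has no standard stand-in"
                    )
                out.append(AMBIGUITY_MAP[ch])
            else:  # skip-window
                out.append(ch)
            continue
        raise SequenceValidationError(
            f"sequence {id!r}: illegal character {ch!r} at position {pos}"
        )
    return ProteinSequence(id=id, residues="".join(out))


def _offending_line(path: Path) -> str:
    """Locate the first line that breaks FASTA syntax, for error messages."""
    for no, line in enumerate(path.read_text().splitlines(), start=1):
        if line.strip() and not line.startswith(">"):
            return f"line {no}: "
        if line.startswith(">"):
            break
    return ""


def read_fasta(path: str | Path, policy: str = "reject") -> list[ProteinSequence]:
    """Read a FASTA file into validated :class:`ProteinSequence` records.

    The header token before the first whitespace becomes the id. An empty file
    yields an empty list with a warning.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals malformed FASTA this way
        raise FastaParseError(f"{path}: {_offending_line(path)}{exc}") from exc
    if not records:
        # distinguish truly empty files from files with junk content
        text = path.read_text().strip()
        if text:
            first = text.splitlines()[0]
            raise FastaParseError(f"{path}: line 1 is not a FASTA header: {first!r}")
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
        return []
    return [validate_sequence(str(r.seq), id=r.id, policy=policy) for r in records]


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_hex_dataset(path: str | Path, provenance: str | None = None) -> LabelledHexDataset:
    """Read a tab-separated ``peptide<TAB>label`` file (header row required)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
    missing = {"peptide", "label"} - set(df.columns)
    if missing:
        raise DatasetFormatError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        pep = str(row.peptide)
        try:
            lab = int(row.label)
        except (TypeError, ValueError) as exc:
            raise DatasetFormatError(f"{path}: row {i}: label {row.label!r} not an integer") from exc
        if len(pep) != WINDOW:
            raise DatasetFormatError(f"{path}: row {i}: peptide {pep!r} is not a hexapeptide")
        if lab not in (0, 1):
            raise DatasetFormatError(f"{path}: row {i}: label {lab} not in {{0,1}}")
        bad = [c for c in pep if c not in AMINO_ACIDS]
        if bad:
            raise DatasetFormatError(
                f"{path}: row {i}: {bad[0]!r} is not a standard amino acid"
            )
        records.append((pep, lab))
    return LabelledHexDataset(records=records, provenance=provenance or str(path))


def write_hex_dataset(dataset: LabelledHexDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(Path(path), sep="\t", index=False)


def read_regions(path: str | Path, status: str = "amyloid") -> list[RegionAnnotation]:
    """Read a TSV of regions with columns ``sequence_id``, ``start``, ``end``."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = {"sequence_id", "start", "end"} - set(df.columns)
    if missing:
        raise DatasetFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        RegionAnnotation(str(r.sequence_id), int(r.start), int(r.end), status=status)
        for r in df.itertuples(index=False)
    ]


def write_regions(regions: Sequence[RegionAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(r.sequence_id, r.start, r.end, r.status) for r in regions],
        columns=["sequence_id", "start", "end", "status"],
    ).to_csv(Path(path), sep="\t", index=False)
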