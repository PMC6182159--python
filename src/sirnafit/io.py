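"""Screen-table and sequence I/O, the core data model, and model (de)serialization.

Screens are tab- or comma-separated tables with one row per siRNA oligo:
an oligo identifier, the guide-strand sequence (5'->3'), the intended
target gene (empty for non-targeting controls), library/screen labels,
and the cell-count phenotype expressed as a z-score against the screening
background (more negative = fewer cells).

Sequences are stored in the DNA alphabet (U -> T) so that 7-mer seeds hash
to a single canonical form regardless of how a vendor reports the strand.
Positions are 1-based from the 5' end of the guide strand; the seed region
is positions 2-8 inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

VALID_NT = frozenset("ACGT")
SEED_START = 2  # 1-based, inclusive
SEED_END = 8  # 1-based, inclusive
MODEL_FORMAT_VERSION = 1

#: canonical column names expected in screen tables
SCREEN_COLUMNS = ("oligo_id", "guide_seq", "target_gene", "library", "screen", "phenotype")
REQUIRED_COLUMNS = ("oligo_id", "guide_seq", "phenotype")


class SirnafitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SirnafitError):
    """A required column, option or argument is missing or inconsistent."""


class ValidationError(SirnafitError):
    """Input data violates an invariant (bad alphabet, bad length, ...)."""


class ModelFormatError(SirnafitError):
    """A serialized model file is malformed or has an unsupported version."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide sequence and convert RNA U to DNA T.

    Raises :class:`ValidationError` on characters outside A/C/G/T/U.
    """
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - VALID_NT
    if bad:
        raise ValidationError(
            f"sequence {seq!r} contains invalid characters: {sorted(bad)}"
        )
    return s


def seed_of(seq: str, start: int = SEED_START, end: int = SEED_END) -> str:
    """Return the seed region (guide positions ``start``..``end``, 1-based inclusive)."""
    if len(seq) < end:
        raise ValidationError(f"sequence of length {len(seq)} has no positions {start}-{end}")
    return seq[start - 1 : end]


@dataclass
class SiRNARecord:
    """One siRNA oligo with its phenotype readout.

    ``target_gene`` empty means a non-targeting control. ``phenotype`` is the
    cell-count z-score relative to the screening background.
    """

    oligo_id: str
    guide_seq: str
    phenotype: float
    target_gene: str = ""
    library: str = ""
    screen: str = ""

    @property
    def seed(self) -> str:
        return seed_of(self.guide_seq)

    def validate(self, length_range: tuple[int, int] | None = (19, 21)) -> None:
        """Check alphabet, finiteness and (optionally) length bounds."""
        bad = set(self.guide_seq) - VALID_NT
        if bad:
            raise ValidationError(
                f"oligo {self.oligo_id!r}: invalid characters {sorted(bad)}"
            )
        if length_range is not None:
            lo, hi = length_range
            if not lo <= len(self.guide_seq) <= hi:
                raise ValidationError(
                    f"oligo {self.oligo_id!r}: length {len(self.guide_seq)} "
                    f"outside [{lo}, {hi}]"
                )
        if not pd.notna(self.phenotype) or self.phenotype in (float("inf"), float("-inf")):
            raise ValidationError(f"oligo {self.oligo_id!r}: non-finite phenotype")


class ScreenDataset:
    """Ordered collection of :class:`SiRNARecord` plus free-form metadata.

    Oligo IDs must be unique within each screen label.
    """

    def __init__(
        self,
        records: Iterable[SiRNARecord],
        metadata: Mapping[str, str] | None = None,
    ):
        self.records: list[SiRNARecord] = list(records)
        self.metadata: dict[str, str] = dict(metadata or {})
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.screen, r.oligo_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate oligo_id {r.oligo_id!r} within screen {r.screen!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SiRNARecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SiRNARecord:
        return self.records[i]

    def sequences(self) -> list[str]:
        return [r.guide_seq for r in self.records]

    def phenotypes(self) -> "pd.Series":
        return pd.Series([r.phenotype for r in self.records], name="phenotype")

    def subset(self, indices: Sequence[int]) -> "ScreenDataset":
        return ScreenDataset([self.records[i] for i in indices], self.metadata)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "oligo_id": [r.oligo_id for r in self.records],
                "guide_seq": [r.guide_seq for r in self.records],
                "target_gene": [r.target_gene for r in self.records],
                "library": [r.library for r in self.records],
                "screen": [r.screen for r in self.records],
                "phenotype": [r.phenotype for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: Mapping[str, str] | None = None) -> "ScreenDataset":
        recs = [
            SiRNARecord(
                oligo_id=str(row.oligo_id),
                guide_seq=str(row.guide_seq),
                phenotype=float(row.phenotype),
                target_gene=str(getattr(row, "target_gene", "") or ""),
                library=str(getattr(row, "library", "") or ""),
                screen=str(getattr(row, "screen", "") or ""),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(recs, metadata)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def parse_screen_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    length_range: tuple[int, int] | None = (19, 21),
    on_invalid: str = "raise",
) -> ScreenDataset:
    """Read a delimited screen table into a :class:`ScreenDataset`.

    Parameters
    ----------
    path
        TSV (default) or CSV (by ``.csv`` extension) file with a header row.
    column_map
        Maps canonical names (``oligo_id``, ``guide_seq``, ``phenotype``, and
        optionally ``target_gene``, ``library``, ``screen``) to the file's
        column names. Defaults to the identity mapping.
    length_range
        Inclusive sequence-length bounds enforced per row (``None`` disables).
    on_invalid
        ``"raise"`` (default) raises a :class:`ValidationError` listing the
        offending row numbers; ``"skip"`` drops those rows instead.

    Sequences are uppercased and U->T normalized on ingestion.
    """
    path = Path(path)
    cmap = dict(column_map or {})
    for name in SCREEN_COLUMNS:
        cmap.setdefault(name, name)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for canonical in REQUIRED_COLUMNS:
        if cmap[canonical] not in df.columns:
            raise ConfigurationError(
                f"missing required column {cmap[canonical]!r} in {path} "
                f"(have: {list(df.columns)})"
            )

    records: list[SiRNARecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        rowd = dict(zip(df.columns, row))

        def get(canonical: str, default: str = "") -> str:
            col = cmap[canonical]
            val = rowd.get(col, default)
            return "" if pd.isna(val) else str(val)

        try:
            seq = normalize_sequence(get("guide_seq"))
            rec = SiRNARecord(
                oligo_id=get("oligo_id"),
                guide_seq=seq,
                phenotype=float(get("phenotype", "nan")),
                target_gene=get("target_gene"),
                library=get("library"),
                screen=get("screen"),
            )
            rec.validate(length_range=length_range)
        except (ValidationError, ValueError) as exc:
            bad_rows.append((i, str(exc)))
            continue
        records.append(rec)

    if bad_rows:
        msg = "; ".join(f"row {i}: {m}" for i, m in bad_rows[:10])
        if len(bad_rows) > 10:
            msg += f"; ... ({len(bad_rows)} invalid rows total)"
        if on_invalid == "raise":
            raise ValidationError(f"invalid rows in {path}: {msg}")
        if on_invalid != "skip":
            raise ConfigurationError(f"unknown on_invalid mode {on_invalid!r}")
    return ScreenDataset(records, metadata={"source": str(path)})


def write_screen_table(dataset: ScreenDataset, path: str | Path) -> None:
    path = Path(path)
    dataset.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def read_fasta_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read (oligo_id, normalized sequence) pairs from a FASTA file."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, normalize_sequence(str(rec.seq))))
    return out


def write_fasta_sequences(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in pairs:
            fh.write(f">{name}\n{seq}\n")


# --- model serialization -----------------------------------------------------
#
# Models are stored as JSON with a format-version tag. Python's json module
# round-trips float64 exactly (shortest-repr), so save/load reproduces all
# weights bit-identically.


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted model (positional linear, seed, or combined) to JSON."""
    payload = model.to_dict()
    payload["format_version"] = MODEL_FORMAT_VERSION
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`; dispatches on its ``kind`` tag."""
    # local import to avoid a cycle (predictor imports io for errors)
    from . import predictor

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"malformed model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "kind" not in payload:
        raise ModelFormatError(f"model file {path} lacks a 'kind' tag")
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model file {path} has format version {version!r}; "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    kind = payload["kind"]
    dispatch = {
        "positional_linear": predictor.PositionalLinearModel,
        "seed": predictor.SeedModel,
        "combined": predictor.CombinedModel,
    }
    if kind not in dispatch:
        raise ModelFormatError(f"unknown model kind {kind!r} in {path}")
    try:
        return dispatch[kind].from_dict(payload)
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"model file {path} is missing fields: {exc}") from exc
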