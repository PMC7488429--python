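"""Profile-HMM hit tables.

A :class:`ProfileHit` records one match of a profile HMM against one protein
of one genome, scored in bits.  Hit tables are the raw evidence for every
downstream computation: bit-score threshold calibration, marker copy counts,
and query-genome scoring.

Two on-disk dialects are supported:

``tsv4``
    A four-column TSV (``genome_id``, ``protein_id``, ``profile_id``,
    ``bit_score``) with a header line; ``#`` comment lines are skipped.
    Write/read round-trips are lossless.

``hmmer-tblout``
    The per-target tabular output of ``hmmsearch --tblout`` /
    ``hmmscan --tblout``: whitespace-separated columns where column 1 is the
    target (protein), column 3 the query (profile) and column 6 the
    full-sequence bit score.  tblout files carry no genome column, so the
    caller supplies the ``genome_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError

TSV4_COLUMNS = ("genome_id", "protein_id", "profile_id", "bit_score")


@dataclass(frozen=True)
class ProfileHit:
    """One profile-vs-protein match with its full-sequence bit score."""

    genome_id: str
    protein_id: str
    profile_id: str
    bit_score: float

    def __post_init__(self) -> None:
        if not (self.genome_id and self.protein_id and self.profile_id):
            raise InputError("hit identifiers must be non-empty")
        if not math.isfinite(self.bit_score):
            raise InputError(
                f"non-finite bit score for {self.protein_id}/{self.profile_id}"
            )


def hits_to_frame(hits: Iterable[ProfileHit]) -> pd.DataFrame:
    """Tabulate hits as a DataFrame with the tsv4 columns."""
    return pd.DataFrame(
        [(h.genome_id, h.protein_id, h.profile_id, h.bit_score) for h in hits],
        columns=list(TSV4_COLUMNS),
    )


def frame_to_hits(frame: pd.DataFrame) -> list[ProfileHit]:
    return [
        ProfileHit(str(r.genome_id), str(r.protein_id), str(r.profile_id), float(r.bit_score))
        for r in frame.itertuples(index=False)
    ]


def read_hit_table(
    path: str | Path,
    dialect: str = "tsv4",
    genome_id: str | None = None,
) -> list[ProfileHit]:
    """Read a hit table.

    Parameters
    ----------
    dialect:
        ``"tsv4"`` or ``"hmmer-tblout"``.
    genome_id:
        Required for the tblout dialect, which has no genome column.
    """
    path = Path(path)
    if dialect == "tsv4":
        return _read_tsv4(path)
    if dialect == "hmmer-tblout":
        if genome_id is None:
            raise InputError("hmmer-tblout dialect requires a genome_id")
        return _read_tblout(path, genome_id)
    raise InputError(f"unknown hit-table dialect: {dialect!r}")


def _read_tsv4(path: Path) -> list[ProfileHit]:
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype={"genome_id": str, "protein_id": str, "profile_id": str},
        )
    except pd.errors.EmptyDataError:
        return []
    missing = set(TSV4_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"{path}: missing tsv4 columns: {sorted(missing)}")
    scores = pd.to_numeric(frame["bit_score"], errors="coerce")
    bad = scores.isna() & frame["bit_score"].notna()
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise InputError(f"{path}:{line}: non-numeric bit score {frame['bit_score'][bad.idxmax()]!r}")
    frame = frame.assign(bit_score=scores).dropna(subset=["bit_score"])
    return frame_to_hits(frame[list(TSV4_COLUMNS)])


def _read_tblout(path: Path, genome_id: str) -> list[ProfileHit]:
    hits: list[ProfileHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise InputError(f"{path}:{lineno}: short tblout line ({len(fields)} fields)")
            try:
                score = float(fields[5])
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: non-numeric bit score {fields[5]!r}"
                ) from None
            hits.append(ProfileHit(genome_id, fields[0], fields[2], score))
    return hits


def write_hit_table(hits: Sequence[ProfileHit], path: str | Path) -> None:
    """Write hits in the tsv4 dialect (lossless round-trip)."""
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
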