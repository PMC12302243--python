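"""Reading and writing AIRR Rearrangement TSV files.

Follows the AIRR Community v1 Rearrangement schema column names.  Each row is
one sequenced receptor chain (a :class:`Rearrangement`); a file holds one
sample (donor x timepoint x locus), optionally mixed loci which can be
filtered or partitioned at read time.  Unknown columns are carried through
untouched so files annotated by upstream tools survive a round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import EmptySampleError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

LOCI = ("IGH", "TRB", "TRD")

#: columns that must be present in any readable rearrangement table
REQUIRED_COLUMNS = ("sequence_id", "locus", "v_call", "j_call", "junction", "productive")

#: canonical write order for known columns (AIRR names)
_KNOWN_COLUMNS = (
    "sequence_id",
    "locus",
    "v_call",
    "j_call",
    "junction",
    "junction_length",
    "sequence",
    "sequence_alignment",
    "germline_alignment",
    "duplicate_count",
    "productive",
    "clone_id",
)

_NT = set("ACGTN")
_GAPS = set(".-")


@dataclass
class Rearrangement:
    """One germline-annotated receptor chain record."""

    sequence_id: str
    locus: str
    v_call: str
    j_call: str
    junction: str
    duplicate_count: int = 1
    productive: Optional[bool] = True
    junction_length: Optional[int] = None
    sequence: Optional[str] = None
    sequence_alignment: Optional[str] = None
    germline_alignment: Optional[str] = None
    clone_id: Optional[str] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.junction_length is None:
            self.junction_length = len(self.junction)

    def validate(self) -> None:
        """Check the record-level invariants; raise ValidationError on failure."""
        if self.junction_length != len(self.junction):
            raise ValidationError(
                f"{self.sequence_id}: junction_length {self.junction_length} "
                f"!= len(junction) {len(self.junction)}"
            )
        if self.duplicate_count < 1:
            raise ValidationError(f"{self.sequence_id}: duplicate_count < 1")
        if self.sequence_alignment is not None and self.germline_alignment is not None:
            if len(self.sequence_alignment) != len(self.germline_alignment):
                raise ValidationError(
                    f"{self.sequence_id}: alignment lengths differ"
                )
        for name in ("junction", "sequence"):
            value = getattr(self, name)
            if value is not None and not set(value) <= _NT:
                raise ValidationError(f"{self.sequence_id}: bad character in {name}")
        for name in ("sequence_alignment", "germline_alignment"):
            value = getattr(self, name)
            if value is not None and not set(value) <= (_NT | _GAPS):
                raise ValidationError(f"{self.sequence_id}: bad character in {name}")


@dataclass
class RepertoireSample:
    """A collection of rearrangements for one donor/timepoint/locus."""

    records: list[Rearrangement]
    locus: Optional[str] = None
    donor_id: str = ""
    timepoint: Optional[str] = None
    cohort: Optional[str] = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_molecules(self) -> int:
        """Total unique molecules (sum of duplicate_count over records)."""
        return sum(r.duplicate_count for r in self.records)

    def with_records(self, records: Iterable[Rearrangement]) -> "RepertoireSample":
        """Copy of this sample carrying ``records`` instead."""
        return RepertoireSample(
            records=list(records),
            locus=self.locus,
            donor_id=self.donor_id,
            timepoint=self.timepoint,
            cohort=self.cohort,
        )


def _parse_bool(value: str, where: str) -> Optional[bool]:
    if value == "":
        return None
    if value in ("T", "TRUE", "True", "true", "1"):
        return True
    if value in ("F", "FALSE", "False", "false", "0"):
        return False
    raise ValidationError(f"{where}: unparsable boolean {value!r}")


def read_rearrangements(
    path,
    locus_filter: Optional[str] = None,
    **sample_meta,
) -> RepertoireSample:
    """Read an AIRR Rearrangement TSV into a :class:`RepertoireSample`.

    Records are returned in file order; rows whose ``locus`` differs from
    ``locus_filter`` (if given) are dropped.  Missing optional columns yield
    absent fields; a missing ``duplicate_count`` column defaults every record
    to one molecule (logged once per file).

    Raises
    ------
    SchemaError
        if a required column is absent.
    EmptySampleError
        if the file has no data rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    if len(df) == 0:
        raise EmptySampleError(f"{path}: no rearrangement records")
    if "duplicate_count" not in df.columns:
        logger.info("%s: no duplicate_count column; assuming 1 molecule per record", path)

    known = set(_KNOWN_COLUMNS)
    extra_cols = [c for c in df.columns if c not in known]

    records: list[Rearrangement] = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        if locus_filter is not None and row["locus"] != locus_filter:
            continue
        sid = row["sequence_id"]

        def opt(col: str) -> Optional[str]:
            v = row.get(col, "")
            return v if v != "" else None

        dup = opt("duplicate_count")
        jl = opt("junction_length")
        rec = Rearrangement(
            sequence_id=sid,
            locus=row["locus"],
            v_call=row["v_call"],
            j_call=row["j_call"],
            junction=row["junction"],
            duplicate_count=int(dup) if dup is not None else 1,
            productive=_parse_bool(row.get("productive", ""), sid),
            junction_length=int(jl) if jl is not None else None,
            sequence=opt("sequence"),
            sequence_alignment=opt("sequence_alignment"),
            germline_alignment=opt("germline_alignment"),
            clone_id=opt("clone_id"),
            extras={c: row[c] for c in extra_cols},
        )
        records.append(rec)

    loci = sorted({r.locus for r in records})
    locus = locus_filter if locus_filter is not None else (loci[0] if len(loci) == 1 else None)
    return RepertoireSample(records=records, locus=locus, **sample_meta)


def write_rearrangements(sample: RepertoireSample, path) -> None:
    """Write a sample as an AIRR TSV with deterministic column order.

    Booleans are serialized as ``T``/``F`` per AIRR convention; columns absent
    on every record are omitted; pass-through extras follow the known columns
    in sorted order.  An empty sample yields a header-only file.
    """
    rows = []
    extra_cols: set[str] = set()
    for r in sample.records:
        extra_cols.update(r.extras)
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "locus": r.locus,
                "v_call": r.v_call,
                "j_call": r.j_call,
                "junction": r.junction,
                "junction_length": r.junction_length,
                "sequence": r.sequence,
                "sequence_alignment": r.sequence_alignment,
                "germline_alignment": r.germline_alignment,
                "duplicate_count": r.duplicate_count,
                "productive": {True: "T", False: "F", None: None}[r.productive],
                "clone_id": r.clone_id,
                **r.extras,
            }
        )
    columns = list(_KNOWN_COLUMNS) + sorted(extra_cols)
    df = pd.DataFrame(rows, columns=columns)
    # drop all-empty optional columns, keep required ones even if empty
    keep = [
        c
        for c in columns
        if c in REQUIRED_COLUMNS or c in ("duplicate_count",) or df[c].notna().any()
    ]
    if len(df) == 0:
        keep = list(REQUIRED_COLUMNS) + ["duplicate_count"]
        df = pd.DataFrame(columns=keep)
    df[keep].to_csv(path, sep="\t", index=False, na_rep="")


def filter_productive(sample: RepertoireSample) -> RepertoireSample:
    """Retain only records flagged productive, preserving order.

    Raises ValidationError if any record lacks the productivity flag.
    """
    for r in sample.records:
        if r.productive is None:
            raise ValidationError(f"{r.sequence_id}: missing productive flag")
    return sample.with_records(r for r in sample.records if r.productive)


def partition_by_locus(sample: RepertoireSample) -> dict[str, RepertoireSample]:
    """Split a mixed-locus sample into one sample per locus (disjoint cover)."""
    out: dict[str, list[Rearrangement]] = {}
    for r in sample.records:
        out.setdefault(r.locus, []).append(r)
    return {
        locus: RepertoireSample(
            records=recs,
            locus=locus,
            donor_id=sample.donor_id,
            timepoint=sample.timepoint,
            cohort=sample.cohort,
        )
        for locus, recs in out.items()
    }


def write_fasta(sequences: Mapping[str, str], path) -> None:
    """Write germline reference sequences as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    seqio_write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file of germline references into a name -> sequence map."""
    from Bio.SeqIO import parse as seqio_parse

    return {rec.id: str(rec.seq) for rec in seqio_parse(path, "fasta")}
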