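"""Amplicon quantification: library/sample-sheet/count-matrix types, demultiplexing
and hairpin counting.

Read layout (fixed by this artifact): bases 1-6 sample index, bases 7-27 the
21-nt hairpin sense sequence, any remaining bases a constant tail. Counting
matches the 21-nt window at that fixed offset against the library; a ``scan``
fallback searches all offsets.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

INDEX_LEN = 6
HAIRPIN_LEN = 21
HAIRPIN_OFFSET = 6  # 0-based start of the hairpin window within the read
CONSTANT_TAIL = "AGATCGGA"

_DNA21 = re.compile(r"^[ACGT]{21}$")
_DNA6 = re.compile(r"^[ACGT]{6}$")

VALID_CONDITIONS = ("reference", "DMSO", "treated")
VALID_TREATMENTS = ("none", "PLX", "SCH")
VALID_DAYS = (0, 4, 7)


class ValidationError(ValueError):
    """Raised when an input table violates its documented contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class HairpinLibrary:
    """Hairpin annotation: id, target gene, 21-nt target sequence, pool.

    ``hairpin_id`` is unique; each hairpin maps to exactly one gene. The pool
    field is carried for QC only — counting is pool-agnostic.
    """

    COLUMNS = ("hairpin_id", "gene", "target_sequence", "pool")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"library is missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["hairpin_id"] = df["hairpin_id"].astype(str)
        df["gene"] = df["gene"].astype(str)
        df["target_sequence"] = df["target_sequence"].astype(str)
        if df["hairpin_id"].duplicated().any():
            dups = df.loc[df["hairpin_id"].duplicated(), "hairpin_id"].tolist()
            raise ValidationError(f"duplicate hairpin ids: {dups}")
        bad = df.loc[~df["target_sequence"].str.match(_DNA21), "hairpin_id"]
        if len(bad):
            raise ValidationError(
                f"target_sequence must match [ACGT]{{21}}; offenders: {bad.tolist()}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def hairpin_ids(self) -> list[str]:
        return self.df["hairpin_id"].tolist()

    @property
    def gene_of(self) -> dict[str, str]:
        return dict(zip(self.df["hairpin_id"], self.df["gene"]))

    @property
    def sequence_of(self) -> dict[str, str]:
        return dict(zip(self.df["hairpin_id"], self.df["target_sequence"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HairpinLibrary":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


class SampleSheet:
    """Per-sample metadata: id, 6-bp index, condition/treatment/day/replicate."""

    COLUMNS = ("sample_id", "index", "condition", "treatment", "day", "replicate")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet is missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["index"] = df["index"].astype(str)
        df["day"] = df["day"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids")
        if df["index"].duplicated().any():
            dups = df.loc[df["index"].duplicated(), "index"].tolist()
            raise ValidationError(f"duplicate sample indices: {dups}")
        if not df["index"].str.match(_DNA6).all():
            raise ValidationError("sample indices must be 6-bp ACGT strings")
        bad_cond = set(df["condition"]) - set(VALID_CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown conditions: {sorted(bad_cond)}")
        bad_trt = set(df["treatment"]) - set(VALID_TREATMENTS)
        if bad_trt:
            raise ValidationError(f"unknown treatments: {sorted(bad_trt)}")
        bad_day = set(df["day"]) - set(VALID_DAYS)
        if bad_day:
            raise ValidationError(f"unknown days: {sorted(bad_day)}")
        ref = df[df["condition"] == "reference"]
        if (ref["day"] != 0).any():
            raise ValidationError("reference samples must be day 0")
        trt = df[df["condition"] == "treated"]
        if (trt["treatment"] == "none").any():
            raise ValidationError("treated samples need a treatment ∈ {PLX, SCH}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def index_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["index"]))

    def select(self, condition=None, treatment=None, day=None) -> list[str]:
        """Sample ids matching the given metadata values (None = any)."""
        m = pd.Series(True, index=self.df.index)
        if condition is not None:
            m &= self.df["condition"] == condition
        if treatment is not None:
            m &= self.df["treatment"] == treatment
        if day is not None:
            m &= self.df["day"] == int(day)
        return self.df.loc[m, "sample_id"].tolist()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "index": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


class CountMatrix:
    """Integer hairpin × sample count matrix with its sample sheet attached."""

    def __init__(self, counts: pd.DataFrame, samples: SampleSheet):
        if set(counts.columns) != set(samples.sample_ids):
            extra = set(counts.columns) - set(samples.sample_ids)
            miss = set(samples.sample_ids) - set(counts.columns)
            raise ValidationError(
                f"count columns do not match sample sheet (extra={sorted(extra)}, "
                f"missing={sorted(miss)})"
            )
        counts = counts.loc[:, samples.sample_ids].copy()
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integral")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        counts.index = counts.index.astype(str)
        counts.index.name = "hairpin_id"
        self.counts = counts
        self.samples = samples

    @property
    def hairpin_ids(self) -> list[str]:
        return self.counts.index.tolist()

    def validate_against(self, lib: HairpinLibrary) -> None:
        unknown = set(self.hairpin_ids) - set(lib.hairpin_ids)
        if unknown:
            raise ValidationError(f"hairpins not in library: {sorted(unknown)}")


def read_counts(
    path: str | Path,
    samples: SampleSheet,
    library: HairpinLibrary | None = None,
) -> CountMatrix:
    """Read a count TSV (first column hairpin_id, header = sample ids).

    Non-integer or negative cells raise a :class:`ValidationError` naming the
    offending row and column; with ``library`` given, unknown hairpins raise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals != vals.round()) | (vals < 0)]
        if len(bad):
            raise ValidationError(
                f"non-integer or negative count at row {bad[0]!r}, column {col!r}"
            )
    cm = CountMatrix(df.astype(np.int64), samples)
    if library is not None:
        cm.validate_against(library)
    return cm


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


def _mismatch_variants(seq: str) -> Iterator[str]:
    for i, base in enumerate(seq):
        for b in "ACGT":
            if b != base:
                yield seq[:i] + b + seq[i + 1 :]


def _build_lookup(
    seqs: Mapping[str, str], max_mismatch: int
) -> dict[str, set[str]]:
    """Map every sequence within ``max_mismatch`` of a target to the target ids
    it could belong to (>1 id ⇒ ambiguous)."""
    lut: dict[str, set[str]] = {}
    for key, seq in seqs.items():
        lut.setdefault(seq, set()).add(key)
    if max_mismatch >= 1:
        for key, seq in seqs.items():
            for var in _mismatch_variants(seq):
                lut.setdefault(var, set()).add(key)
    return lut


@dataclass
class DemuxResult:
    assigned: dict[str, list[str]]
    unassigned: list[str]
    n_total: int

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())


def _read_seq(read) -> str:
    return str(read.seq) if isinstance(read, SeqRecord) else str(read)


def demultiplex(
    reads: Iterable, sheet: SampleSheet, max_mismatch: int = 0
) -> DemuxResult:
    """Assign reads to samples by their leading 6-bp index.

    Default is exact matching; ``max_mismatch=1`` tolerates one substitution
    (reads whose index is then compatible with >1 sample go unassigned).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    index_of = sheet.index_of  # validated unique on construction
    lut = _build_lookup({s: ix for s, ix in index_of.items()}, max_mismatch)
    assigned: dict[str, list[str]] = {s: [] for s in sheet.sample_ids}
    unassigned: list[str] = []
    n = 0
    for read in reads:
        n += 1
        seq = _read_seq(read)
        hit = lut.get(seq[:INDEX_LEN])
        if hit is not None and len(hit) == 1:
            assigned[next(iter(hit))].append(seq)
        else:
            unassigned.append(seq)
    return DemuxResult(assigned=assigned, unassigned=unassigned, n_total=n)


# ---------------------------------------------------------------------------
# Hairpin counting
# ---------------------------------------------------------------------------


@dataclass
class CountTally:
    counted: int = 0
    no_match: int = 0
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.counted + self.no_match + self.ambiguous


def _library_collisions(seqs: Mapping[str, str], max_mismatch: int) -> list[tuple[str, str]]:
    pairs = []
    ids = list(seqs)
    by_seq: dict[str, list[str]] = {}
    for h in ids:
        by_seq.setdefault(seqs[h], []).append(h)
    if max_mismatch >= 1:
        lut = _build_lookup(seqs, 1)
        for h in ids:
            hits = lut.get(seqs[h], set())
            for other in hits:
                if other != h:
                    pairs.append(tuple(sorted((h, other))))
    else:
        for same in by_seq.values():
            for a in same:
                for b in same:
                    if a < b:
                        pairs.append((a, b))
    return sorted(set(pairs))


def count_hairpins(
    reads: Iterable,
    lib: HairpinLibrary,
    max_mismatch: int = 0,
    offset: int = HAIRPIN_OFFSET,
    scan: bool = False,
) -> tuple[pd.Series, CountTally]:
    """Count reads per hairpin by matching the 21-nt window at ``offset``.

    A read increments hairpin *h* iff its window is within ``max_mismatch``
    substitutions of *h*'s target sequence and *h* is the unique such hairpin;
    reads matching none or several are tallied as discarded. With ``scan``,
    every offset of the read is tried (unique overall match required).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    seqs = lib.sequence_of
    collisions = _library_collisions(seqs, max_mismatch)
    if collisions:
        warnings.warn(
            f"library hairpin pairs within {max_mismatch} mismatch "
            f"(their reads will be discarded as ambiguous): {collisions}",
            stacklevel=2,
        )
    lut = _build_lookup(seqs, max_mismatch)
    counts = pd.Series(0, index=pd.Index(lib.hairpin_ids, name="hairpin_id"), dtype=np.int64)
    tally = CountTally()
    for read in reads:
        seq = _read_seq(read)
        if scan:
            hits: set[str] = set()
            for off in range(0, max(1, len(seq) - HAIRPIN_LEN + 1)):
                got = lut.get(seq[off : off + HAIRPIN_LEN])
                if got:
                    hits |= got
        else:
            hits = lut.get(seq[offset : offset + HAIRPIN_LEN], set())
        if not hits:
            tally.no_match += 1
        elif len(hits) > 1:
            tally.ambiguous += 1
        else:
            counts[next(iter(hits))] += 1
            tally.counted += 1
    return counts, tally


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_fastq(path: str | Path) -> Iterator[SeqRecord]:
    with _open_maybe_gzip(path) as fh:
        yield from SeqIO.parse(fh, "fastq")


def quantify_fastq(
    fastq_path: str | Path,
    lib: HairpinLibrary,
    sheet: SampleSheet,
    index_mismatch: int = 0,
    hairpin_mismatch: int = 0,
    scan: bool = False,
) -> tuple[CountMatrix, dict]:
    """Demultiplex a FASTQ file and count hairpins per sample.

    Returns the count matrix plus a log dict of assignment/discard tallies.
    Conservation holds: assigned + unassigned = total; per sample
    counted + no_match + ambiguous = assigned.
    """
    demux = demultiplex(parse_fastq(fastq_path), sheet, max_mismatch=index_mismatch)
    cols = {}
    log: dict = {
        "n_reads": demux.n_total,
        "n_unassigned": len(demux.unassigned),
        "per_sample": {},
    }
    for sample in sheet.sample_ids:
        counts, tally = count_hairpins(
            demux.assigned[sample], lib, max_mismatch=hairpin_mismatch, scan=scan
        )
        cols[sample] = counts
        log["per_sample"][sample] = {
            "assigned": len(demux.assigned[sample]),
            "counted": tally.counted,
            "no_match": tally.no_match,
            "ambiguous": tally.ambiguous,
        }
    counts_df = pd.DataFrame(cols, index=pd.Index(lib.hairpin_ids, name="hairpin_id"))
    return CountMatrix(counts_df, sheet), log
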