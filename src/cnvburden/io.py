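"""Readers and writers for the file formats the pipeline touches.

Supported formats:

* PennCNV ``rawcnv`` text dialect — one call per line::

      chr22:18890000-20400000 numsnp=500 length=1,510,001 state2,cn=1 S01 startsnp=rsA endsnp=rsB

  The declared ``length=`` field is advisory (PennCNV's printed length can
  carry formatting artifacts); coordinates are authoritative.

* BED3+ (0-based half-open) for carrier export, with two extra columns
  (name = sample id, score = copy number) plus a num_snps column so the
  export round-trips losslessly through :func:`read_carriers_bed`.

* Delimited cohort tables (TSV/CSV, delimiter sniffed from the extension).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from .model import CnvCall, SampleRecord, normalize_chrom


class ParseError(ValueError):
    """Raised when an input file does not match its declared dialect."""


_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+?):(?P<start>\d+)-(?P<end>\d+)"
    r"\s+numsnp=(?P<numsnp>[\d,]+)"
    r"\s+length=(?P<length>[\d,]+)"
    r"\s+state(?P<state>\d+),cn=(?P<cn>\d+)"
    r"\s+(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?"
    r"(?:\s+endsnp=(?P<endsnp>\S+))?"
    r"(?:\s+\S+=\S+)*"  # tolerate trailing key=value fields (conf=, ...)
    r"\s*$"
)


def _int_nosep(token: str) -> int:
    return int(token.replace(",", ""))


def read_rawcnv(path: str | Path) -> list[CnvCall]:
    """Parse a PennCNV ``rawcnv`` file into :class:`CnvCall` records.

    Raises :class:`ParseError` naming the offending line number on any
    malformed line; invariant violations (``end < start``) surface the
    same way.
    """
    calls: list[CnvCall] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _RAWCNV_RE.match(line)
            if m is None:
                raise ParseError(f"{path}: line {lineno}: not a rawcnv record: {line.strip()!r}")
            try:
                calls.append(
                    CnvCall(
                        sample_id=m["sample"],
                        chrom=m["chrom"],
                        start=int(m["start"]),
                        end=int(m["end"]),
                        copy_number=int(m["cn"]),
                        num_snps=_int_nosep(m["numsnp"]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return calls


# PennCNV HMM state for each copy number (state3 = LOH, not emitted here)
_STATE_OF_CN = {0: 1, 1: 2, 2: 4, 3: 5, 4: 6}


def write_rawcnv(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Write calls in the rawcnv dialect (deterministic field order)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for c in calls:
            state = _STATE_OF_CN.get(c.copy_number, 6)
            fh.write(
                f"chr{c.chrom}:{c.start}-{c.end}"
                f"\tnumsnp={c.num_snps}"
                f"\tlength={c.length_bp:,}"
                f"\tstate{state},cn={c.copy_number}"
                f"\t{c.sample_id}\n"
            )


_COHORT_COLUMNS = ("sample_id", "study", "group", "onset_age", "lrr_sd", "baf_sd", "cnv_count")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cohort(path: str | Path) -> list[SampleRecord]:
    """Read a delimited cohort table into :class:`SampleRecord` records.

    The header must name sample_id, study, group, onset_age, lrr_sd,
    baf_sd and cnv_count.  ``group`` is parsed case-insensitively;
    empty ``onset_age`` means missing.  Duplicate sample ids are an
    error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str, "study": str})
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate sample_id(s): {', '.join(sorted(set(dup)))}")
    records = []
    for row in df.itertuples(index=False):
        onset = row.onset_age
        onset = None if pd.isna(onset) else float(onset)
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row.sample_id),
                    study=str(row.study),
                    group=str(row.group),
                    onset_age=onset,
                    lrr_sd=float(row.lrr_sd),
                    baf_sd=float(row.baf_sd),
                    cnv_count=int(row.cnv_count),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: sample {row.sample_id!r}: {exc}") from exc
    return records


def write_cohort(samples: Iterable[SampleRecord], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "study": s.study,
                "group": s.group,
                "onset_age": "" if s.onset_age is None else s.onset_age,
                "lrr_sd": s.lrr_sd,
                "baf_sd": s.baf_sd,
                "cnv_count": s.cnv_count,
            }
            for s in samples
        ],
        columns=list(_COHORT_COLUMNS),
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_carriers_bed(carriers: Iterable[CnvCall], path: str | Path) -> None:
    """Export calls as BED3+ (0-based half-open): chrom, start-1, end,
    sample_id, copy_number, strand '.', num_snps."""
    with open(path, "wt", encoding="utf-8") as fh:
        for c in carriers:
            fh.write(
                f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.sample_id}"
                f"\t{c.copy_number}\t.\t{c.num_snps}\n"
            )


def read_carriers_bed(path: str | Path) -> list[CnvCall]:
    """Read back a BED file written by :func:`write_carriers_bed`."""
    calls = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}: line {lineno}: expected >=7 BED columns")
            chrom, start0, end, name, score, _strand, num_snps = fields[:7]
            calls.append(
                CnvCall(
                    sample_id=name,
                    chrom=normalize_chrom(chrom),
                    start=int(start0) + 1,
                    end=int(end),
                    copy_number=int(score),
                    num_snps=int(num_snps),
                )
            )
    return calls
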