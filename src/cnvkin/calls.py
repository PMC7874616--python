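"""CNV call records and file I/O.

Supported dialects:

* PennCNV ``.rawcnv``-style text (caller A), one call per line::

      chr1:1000001-1800000  numsnp=35 length=800,000  state2,cn=1 SAMPLE startsnp=rs1 endsnp=rs9 conf=15.502

* generic tab-separated caller tables (caller B) with columns
  ``sample  chrom  start  end  type``;

* tab-separated consensus tables with columns
  ``sample  chrom  start  end  type  n_snps  confidence``;

* BED (0-based half-open), converted to 1-based inclusive on read.

All in-memory coordinates are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DELETION = "deletion"
DUPLICATION = "duplication"
CNV_TYPES = (DELETION, DUPLICATION)


@dataclass(frozen=True)
class CNVCall:
    """One caller-attributed or consensus copy-number segment."""

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    type: str  # "deletion" | "duplication"
    n_snps: int | None = None
    confidence: float | None = None
    caller: str = "A"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"start > end for {self.sample_id} {self.chrom}:{self.start}-{self.end}"
            )
        if self.type not in CNV_TYPES:
            raise ValueError(f"type must be one of {CNV_TYPES}, got {self.type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, str, int, int, str]:
        """Identity key ignoring provenance fields."""
        return (self.sample_id, self.chrom, self.start, self.end, self.type)

    def with_caller(self, caller: str) -> "CNVCall":
        return replace(self, caller=caller)


_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>[\d,]+)-(?P<end>[\d,]+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+length=(?P<length>[\d,]+)\s+"
    r"state\d+,cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
    r"(?:\s+startsnp=\S+)?(?:\s+endsnp=\S+)?"
    r"(?:\s+conf=(?P<conf>[-\d.eE+]+))?\s*$"
)


def _cn_to_type(cn: int) -> str:
    return DELETION if cn < 2 else DUPLICATION


def _type_to_cn(cnv_type: str) -> int:
    return 1 if cnv_type == DELETION else 3


def read_rawcnv(path: str | Path, caller: str = "A") -> list[CNVCall]:
    """Parse a PennCNV rawcnv-style file."""
    calls: list[CNVCall] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        m = _RAWCNV_RE.match(line.strip())
        if m is None:
            raise ValueError(f"{path}:{lineno}: unparseable rawcnv line: {line!r}")
        conf = m.group("conf")
        calls.append(
            CNVCall(
                sample_id=m.group("sample"),
                chrom=m.group("chrom"),
                start=int(m.group("start").replace(",", "")),
                end=int(m.group("end").replace(",", "")),
                type=_cn_to_type(int(m.group("cn"))),
                n_snps=int(m.group("numsnp")),
                confidence=float(conf) if conf is not None else None,
                caller=caller,
            )
        )
    return calls


def write_rawcnv(calls: Iterable[CNVCall], path: str | Path) -> None:
    lines = []
    for c in calls:
        cn = _type_to_cn(c.type)
        state = 2 if cn == 1 else 5
        numsnp = c.n_snps if c.n_snps is not None else 0
        line = (
            f"{c.chrom}:{c.start}-{c.end}\tnumsnp={numsnp}"
            f"\tlength={c.length:,}\tstate{state},cn={cn}\t{c.sample_id}"
        )
        if c.confidence is not None:
            line += f"\tconf={c.confidence:.3f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


_TABLE_COLUMNS = ["sample", "chrom", "start", "end", "type"]
_CONSENSUS_COLUMNS = _TABLE_COLUMNS + ["n_snps", "confidence"]


def read_call_table(path: str | Path, caller: str = "B") -> list[CNVCall]:
    """Read a tab-separated caller table (sample, chrom, start, end, type
    [, n_snps, confidence])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    calls = []
    for row in df.itertuples(index=False):
        n_snps = getattr(row, "n_snps", None)
        conf = getattr(row, "confidence", None)
        calls.append(
            CNVCall(
                sample_id=str(row.sample),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                type=str(row.type),
                n_snps=int(n_snps) if n_snps is not None and pd.notna(n_snps) else None,
                confidence=float(conf) if conf is not None and pd.notna(conf) else None,
                caller=caller,
            )
        )
    return calls


def calls_to_frame(calls: Iterable[CNVCall]) -> pd.DataFrame:
    rows = [
        {
            "sample": c.sample_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "type": c.type,
            "n_snps": c.n_snps,
            "confidence": c.confidence,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=_CONSENSUS_COLUMNS)


def write_call_table(calls: Iterable[CNVCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a BED file into a frame with 1-based inclusive start/end columns.

    Columns beyond chrom/start/end are kept (default name ``name``, then
    positional ``col4``...).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = df.shape[1]
    if names is None:
        names = ["chrom", "start", "end", "name"] + [f"col{i}" for i in range(5, ncol + 1)]
        names = names[:ncol]
    df.columns = list(names)
    df["start"] = df["start"].astype(int) + 1  # BED is 0-based half-open
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write a frame with 1-based inclusive start/end as BED."""
    out = df.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", index=False, header=False)


def calls_to_bed(calls: Iterable[CNVCall], path: str | Path) -> None:
    df = calls_to_frame(calls)
    bed = df[["chrom", "start", "end"]].copy()
    bed["name"] = df["sample"] + ":" + df["type"]
    write_bed(bed, path)
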