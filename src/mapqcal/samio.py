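"""Line-level SAM reading and writing.

Only the fields the recalibrator needs are interpreted (QNAME, FLAG,
RNAME, POS, MAPQ, CIGAR, SEQ, QUAL and the NM/MD tags); everything else is
carried verbatim so a recalibrated file differs from its input in the MAPQ
column only. Input may be headerless; parse failures report the 1-based
line number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100

MAPQ_UNAVAILABLE = 255

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

QUERY_CONSUMING = frozenset("MIS=X")
REFERENCE_CONSUMING = frozenset("MDN=X")


class SamParseError(ValueError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class MappingRecord:
    """One SAM alignment line."""

    read_id: str
    flag: int
    ref_name: str
    pos: int  # 1-based leftmost; 0 when unmapped
    mapq: int | None  # None when the SAM value is 255 ("unavailable")
    cigar: list[tuple[int, str]] = field(default_factory=list)
    sequence: str = ""
    base_qualities: list[int] = field(default_factory=list)
    nm: int | None = None
    md: str | None = None
    line_number: int | None = None

    @property
    def mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def strand(self) -> str:
        return "-" if self.flag & FLAG_REVERSE else "+"

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)


def parse_cigar(text: str) -> list[tuple[int, str]]:
    if text == "*":
        return []
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(text)]
    if "".join(f"{n}{op}" for n, op in ops) != text:
        raise ValueError(f"malformed CIGAR string {text!r}")
    return ops


def cigar_to_string(cigar: list[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in cigar) if cigar else "*"


def _parse_line(line: str, line_number: int) -> MappingRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise SamParseError(f"expected >= 11 tab-separated fields, got {len(fields)}", line_number)
    try:
        flag = int(fields[1])
        pos = int(fields[3])
        mapq_raw = int(fields[4])
    except ValueError as exc:
        raise SamParseError(f"non-numeric mandatory field ({exc})", line_number) from None
    try:
        cigar = parse_cigar(fields[5])
    except ValueError as exc:
        raise SamParseError(str(exc), line_number) from None
    if not flag & FLAG_UNMAPPED and pos < 1:
        raise SamParseError("mapped record with POS < 1", line_number)

    seq = "" if fields[9] == "*" else fields[9]
    qual = [] if fields[10] == "*" else [ord(c) - 33 for c in fields[10]]
    if seq and cigar:
        consumed = sum(n for n, op in cigar if op in QUERY_CONSUMING)
        if consumed != len(seq):
            raise SamParseError(
                f"CIGAR consumes {consumed} query bases but SEQ has {len(seq)}", line_number
            )

    nm = None
    md = None
    for tag in fields[11:]:
        if tag.startswith("NM:i:"):
            nm = int(tag[5:])
        elif tag.startswith("MD:Z:"):
            md = tag[5:]
    return MappingRecord(
        read_id=fields[0],
        flag=flag,
        ref_name=fields[2],
        pos=pos,
        mapq=None if mapq_raw == MAPQ_UNAVAILABLE else mapq_raw,
        cigar=cigar,
        sequence=seq,
        base_qualities=qual,
        nm=nm,
        md=md,
        line_number=line_number,
    )


def parse_sam(source: str | Path | Iterable[str]) -> Iterator[MappingRecord]:
    """Parse SAM text (path or line iterable) into MappingRecords.

    Header lines are skipped; a malformed alignment line raises
    :class:`SamParseError` naming the line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            yield from parse_sam(handle)
        return
    for line_number, line in enumerate(source, start=1):
        if not line.strip() or line.startswith("@"):
            continue
        yield _parse_line(line, line_number)


def record_to_line(record: MappingRecord) -> str:
    mapq = MAPQ_UNAVAILABLE if record.mapq is None else record.mapq
    fields = [
        record.read_id,
        str(record.flag),
        record.ref_name or "*",
        str(record.pos),
        str(mapq),
        cigar_to_string(record.cigar),
        "*",  # RNEXT
        "0",  # PNEXT
        "0",  # TLEN
        record.sequence or "*",
        "".join(chr(q + 33) for q in record.base_qualities) or "*",
    ]
    if record.nm is not None:
        fields.append(f"NM:i:{record.nm}")
    if record.md is not None:
        fields.append(f"MD:Z:{record.md}")
    return "\t".join(fields)


def write_sam(
    records: Iterable[MappingRecord],
    path: str | Path,
    references: Iterable[tuple[str, int]] = (),
    program: str = "mapqcal",
) -> None:
    """Write records with a minimal @HD/@SQ/@PG header."""
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references:
            handle.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        handle.write(f"@PG\tID:{program}\tPN:{program}\n")
        for record in records:
            handle.write(record_to_line(record) + "\n")
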