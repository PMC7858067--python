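"""Reader/writer for a minimal GenomeDiff (GD) dialect.

GenomeDiff is the tab-separated mutation-description format produced by the
Breseq variant caller.  Only the mutation record types SNP, INS, DEL, MOB and
AMP are interpreted; evidence and validation lines (RA, MC, JC, UN, ...)
found in real Breseq output are skipped with a logged warning.

Field order after the three bookkeeping columns (type, id, parent_ids):

    SNP  seq_id  position  new_seq
    INS  seq_id  position  new_seq
    DEL  seq_id  position  size
    MOB  seq_id  position  repeat_name  strand  duplication_size
    AMP  seq_id  position  size  new_copy_number

Trailing ``key=value`` pairs are preserved in ``RawEntry.extra``.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

logger = logging.getLogger(__name__)

HEADER = "#=GENOME_DIFF"

#: positional fields (after seq_id, position) per known mutation type
_TYPE_FIELDS = {
    "SNP": ("new_seq",),
    "INS": ("new_seq",),
    "DEL": ("size",),
    "MOB": ("repeat_name", "strand", "duplication_size"),
    "AMP": ("size", "new_copy_number"),
}
_INT_FIELDS = {"size", "duplication_size", "new_copy_number", "strand"}


class GenomeDiffFormatError(ValueError):
    """Missing or malformed #=GENOME_DIFF header."""


class GenomeDiffParseError(ValueError):
    """Malformed record line; the message names the line number."""


@dataclass
class RawEntry:
    """One mutation line from a GenomeDiff file, fields still unannotated."""
    type: str
    seq_id: str
    position: int
    fields: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)
    entry_id: str = "."
    parent_ids: str = "."
    line_number: int = 0

    def __eq__(self, other):
        if not isinstance(other, RawEntry):
            return NotImplemented
        return (self.type, self.seq_id, self.position, self.fields,
                self.extra) == (other.type, other.seq_id, other.position,
                                other.fields, other.extra)


def _open(source: Union[str, Path, TextIO]) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source)
    return source


def read_genomediff(source: Union[str, Path, TextIO]) -> list[RawEntry]:
    """Parse a GD stream into raw mutation entries.

    Raises :class:`GenomeDiffFormatError` when the ``#=GENOME_DIFF`` header
    is absent and :class:`GenomeDiffParseError` (naming the line) when a
    known record type has too few fields.  Unknown record types are skipped.
    """
    stream = _open(source)
    close = isinstance(source, (str, Path))
    try:
        first = stream.readline()
        if not first.startswith(HEADER):
            raise GenomeDiffFormatError(
                f"not a GenomeDiff stream: expected leading {HEADER!r}")
        entries: list[RawEntry] = []
        for lineno, line in enumerate(stream, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            rtype = cols[0]
            if rtype not in _TYPE_FIELDS:
                logger.warning("skipping unknown GD entry type %r at line %d",
                               rtype, lineno)
                continue
            names = _TYPE_FIELDS[rtype]
            needed = 5 + len(names)
            if len(cols) < needed:
                raise GenomeDiffParseError(
                    f"line {lineno}: {rtype} record needs {needed} fields, "
                    f"got {len(cols)}")
            try:
                position = int(cols[4])
                fields = {}
                for name, raw in zip(names, cols[5 : 5 + len(names)]):
                    fields[name] = int(raw) if name in _INT_FIELDS else raw
            except ValueError as exc:
                raise GenomeDiffParseError(f"line {lineno}: {exc}") from exc
            extra = dict(kv.split("=", 1)
                         for kv in cols[5 + len(names):] if "=" in kv)
            entries.append(RawEntry(type=rtype, seq_id=cols[3],
                                    position=position, fields=fields,
                                    extra=extra, entry_id=cols[1],
                                    parent_ids=cols[2], line_number=lineno))
        return entries
    finally:
        if close:
            stream.close()


def write_genomediff(entries: Iterable[RawEntry],
                     target: Union[str, Path, TextIO]) -> None:
    """Write entries in the same dialect ``read_genomediff`` accepts."""
    own = isinstance(target, (str, Path))
    stream = open(target, "w") if own else target
    try:
        stream.write(HEADER + "\n")
        for i, e in enumerate(entries, start=1):
            cols = [e.type, str(i), ".", e.seq_id, str(e.position)]
            cols += [str(e.fields[name]) for name in _TYPE_FIELDS[e.type]]
            cols += [f"{k}={v}" for k, v in sorted(e.extra.items())]
            stream.write("\t".join(cols) + "\n")
    finally:
        if own:
            stream.close()


def loads(text: str) -> list[RawEntry]:
    return read_genomediff(io.StringIO(text))


def dumps(entries: Iterable[RawEntry]) -> str:
    buf = io.StringIO()
    write_genomediff(entries, buf)
    return buf.getvalue()
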