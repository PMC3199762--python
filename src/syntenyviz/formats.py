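"""The two tab-delimited interchange formats and their in-memory model.

A *synteny file* lists conserved regions, one per row, as a pair of intervals —
one on each of two named sequences — plus any number of numeric attribute
columns (alignment score, E-value, percent identity, ...) declared in the
header.  An *annotation file* lists styled features (genes, repeats,
expression bars) assigned to named tracks alongside a sequence.

Both files are UTF-8, tab-delimited, with ``#`` comment lines, and may arrive
gzip- or zip-compressed; the first non-comment line is a required header.

Coordinates are 1-based and inclusive at both ends everywhere, matching GFF3.
Reverse orientation is encoded positionally: a row whose start exceeds its end
denotes a minus-orientation interval and is normalized on parse to a sorted
interval plus an orientation flag; the writer re-emits start > end so that
``parse(write(x)) == x`` exactly.

Synteny header:    ``org1 start1 end1 org2 start2 end2 [attr ...]``
Annotation header: ``org start end track shape color [strand] [label] [value]``

The trailing optional ``value`` column carries a per-feature number (used for
variable-height expression bars); ``strand`` defaults to ``.`` and ``label``
to the empty string when their columns are absent.
"""

from __future__ import annotations

import gzip
import io
import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

from .colors import resolve_color
from .errors import FormatError

FORWARD = "forward"
REVERSE = "reverse"

#: Closed vocabulary of annotation glyph shapes. ``line`` renders as a bar
#: (variable-height when the feature carries a value).
SHAPES = ("box", "arrow", "line")

STRANDS = ("+", "-", ".")

SYNTENY_REQUIRED = ("org1", "start1", "end1", "org2", "start2", "end2")
ANNOTATION_REQUIRED = ("org", "start", "end", "track", "shape", "color")
ANNOTATION_OPTIONAL = ("strand", "label", "value")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """A 1-based, inclusive genomic interval with an orientation flag.

    ``start <= end`` always holds; a single-base interval is always forward
    (positional encoding cannot distinguish its orientation).
    """

    start: int
    end: int
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise FormatError(f"interval bounds must be integers: {self.start!r}, {self.end!r}")
        if self.start < 1:
            raise FormatError(f"interval start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise FormatError(
                f"interval start {self.start} > end {self.end}; "
                "use Interval.from_raw for positional reverse encoding"
            )
        if self.orientation not in (FORWARD, REVERSE):
            raise FormatError(f"unknown orientation {self.orientation!r}")
        if self.start == self.end and self.orientation == REVERSE:
            object.__setattr__(self, "orientation", FORWARD)

    @classmethod
    def from_raw(cls, start: int, end: int) -> "Interval":
        """Build from raw file coordinates; start > end means reverse."""
        if start > end:
            return cls(end, start, REVERSE)
        return cls(start, end, FORWARD)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_reverse(self) -> bool:
        return self.orientation == REVERSE

    def raw(self) -> tuple[int, int]:
        """File-order coordinates (start > end when reverse)."""
        return (self.end, self.start) if self.is_reverse else (self.start, self.end)

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and self.end >= start


@dataclass
class SyntenyRecord:
    """One conserved region: an interval on each of two sequences, plus
    named numeric attributes (score, E-value, identity, ...)."""

    seq_a: str
    interval_a: Interval
    seq_b: str
    interval_b: Interval
    attributes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seq_a or not self.seq_b:
            raise FormatError("sequence names must be non-empty")
        if "length" in self.attributes:
            raise FormatError('"length" is an implicit attribute and cannot be stored')
        for name, value in self.attributes.items():
            if not name:
                raise FormatError("attribute names must be non-empty")
            if not math.isfinite(float(value)):
                raise FormatError(f"attribute {name!r} must be finite, got {value!r}")

    @property
    def is_inverted(self) -> bool:
        """True when the two sides have opposite orientation (an inversion)."""
        return self.interval_a.is_reverse != self.interval_b.is_reverse


@dataclass
class AnnotationFeature:
    """One styled feature on a named track of one sequence."""

    seq: str
    interval: Interval
    track: str
    shape: str
    color: str
    strand: str = "."
    label: str = ""
    value: float | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError("feature sequence name must be non-empty")
        if not self.track:
            raise FormatError("feature track name must be non-empty")
        if self.shape not in SHAPES:
            raise FormatError(
                f"unknown shape {self.shape!r}; expected one of {', '.join(SHAPES)}"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"unknown strand {self.strand!r}; expected +, - or .")
        resolve_color(self.color)  # raises FormatError when unresolvable
        if self.value is not None and not math.isfinite(float(self.value)):
            raise FormatError(f"feature value must be finite, got {self.value!r}")


@dataclass
class SequenceInfo:
    """A named sequence with a display length (>= every observed coordinate)."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("sequence name must be non-empty")
        if self.length < 1:
            raise FormatError(f"sequence length must be >= 1, got {self.length}")


@dataclass
class Dataset:
    """A full submission: synteny records, annotation features, the sequence
    table derived from them, and the ordered attribute column names."""

    records: list[SyntenyRecord]
    features: list[AnnotationFeature]
    sequences: dict[str, SequenceInfo]
    attribute_names: list[str]

    def validate(self) -> None:
        """Re-check every cross-object invariant; raise FormatError on failure."""
        for rec in self.records:
            if list(rec.attributes.keys()) != list(self.attribute_names):
                raise FormatError(
                    f"record attributes {list(rec.attributes)} differ from "
                    f"declared attribute_names {self.attribute_names}"
                )
            for name, iv in ((rec.seq_a, rec.interval_a), (rec.seq_b, rec.interval_b)):
                self._check_seq(name, iv.end)
        for feat in self.features:
            self._check_seq(feat.seq, feat.interval.end)

    def _check_seq(self, name: str, end: int) -> None:
        info = self.sequences.get(name)
        if info is None:
            raise FormatError(f"sequence {name!r} missing from sequence table")
        if end > info.length:
            raise FormatError(
                f"coordinate {end} on {name!r} exceeds declared length {info.length}"
            )


# ---------------------------------------------------------------------------
# I/O plumbing
# ---------------------------------------------------------------------------

def open_maybe_compressed(path: str | Path) -> TextIO:
    """Open a text file transparently, whether plain, gzipped, or zipped.

    The container is detected from magic bytes, not the file name.  A zip
    archive must contain exactly one member.  Content must decode as UTF-8.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] == b"\x1f\x8b":
        with gzip.open(path, "rb") as gz:
            data = gz.read()
    elif magic == b"PK\x03\x04":
        with zipfile.ZipFile(path) as zf:
            members = zf.namelist()
            if len(members) != 1:
                raise FormatError(
                    f"ambiguous archive: zip file {path} has {len(members)} members, expected 1"
                )
            data = zf.read(members[0])
    else:
        data = path.read_bytes()
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(f"encoding error: {path} is not valid UTF-8 ({exc})") from exc
    return io.StringIO(text)


def _data_lines(stream: TextIO | Iterable[str]) -> Iterator[tuple[int, list[str]]]:
    """Yield (line_number, columns) for non-blank, non-comment lines."""
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line.split("\t")


def _parse_int(cell: str, what: str, lineno: int) -> int:
    try:
        return int(cell)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer {what} {cell!r}") from exc


def _parse_finite(cell: str, what: str, lineno: int) -> float:
    try:
        value = float(cell)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric {what} value {cell!r}") from exc
    if not math.isfinite(value):
        raise FormatError(f"line {lineno}: {what} value {cell!r} is not finite")
    return value


def _interval_from_cells(s: str, e: str, side: str, lineno: int) -> Interval:
    start = _parse_int(s, f"start ({side})", lineno)
    end = _parse_int(e, f"end ({side})", lineno)
    if start < 1 or end < 1:
        raise FormatError(f"line {lineno}: coordinates must be >= 1, got {start}, {end}")
    return Interval.from_raw(start, end)


# ---------------------------------------------------------------------------
# Synteny format
# ---------------------------------------------------------------------------

def parse_synteny(stream: TextIO | Iterable[str]) -> tuple[list[SyntenyRecord], list[str]]:
    """Parse a synteny file into records plus the ordered attribute names."""
    lines = _data_lines(stream)
    try:
        header_lineno, header = next(lines)
    except StopIteration:
        raise FormatError("empty synteny file: header line required") from None
    for i, required in enumerate(SYNTENY_REQUIRED):
        if i >= len(header) or header[i] != required:
            raise FormatError(
                f"line {header_lineno}: synteny header must start with "
                f"{', '.join(SYNTENY_REQUIRED)}; missing or misplaced {required!r}"
            )
    attribute_names = header[len(SYNTENY_REQUIRED):]
    seen: set[str] = set()
    for name in attribute_names:
        if not name:
            raise FormatError(f"line {header_lineno}: empty attribute column name")
        if name == "length":
            raise FormatError(
                f'line {header_lineno}: "length" is reserved for the implicit '
                "length attribute and cannot be a column"
            )
        if name in seen:
            raise FormatError(f"line {header_lineno}: duplicate attribute column {name!r}")
        seen.add(name)

    n_cols = len(SYNTENY_REQUIRED) + len(attribute_names)
    records: list[SyntenyRecord] = []
    for lineno, cols in lines:
        if len(cols) != n_cols:
            raise FormatError(
                f"line {lineno}: expected {n_cols} columns, found {len(cols)}"
            )
        if not cols[0] or not cols[3]:
            raise FormatError(f"line {lineno}: empty sequence name")
        interval_a = _interval_from_cells(cols[1], cols[2], "org1", lineno)
        interval_b = _interval_from_cells(cols[4], cols[5], "org2", lineno)
        attributes = {
            name: _parse_finite(cell, f"attribute {name!r}", lineno)
            for name, cell in zip(attribute_names, cols[6:])
        }
        records.append(
            SyntenyRecord(cols[0], interval_a, cols[3], interval_b, attributes)
        )
    return records, attribute_names


def write_synteny(records: Sequence[SyntenyRecord], attribute_names: Sequence[str]) -> str:
    """Serialize records to canonical synteny-format text (LF line ends)."""
    out = ["\t".join(list(SYNTENY_REQUIRED) + list(attribute_names))]
    for rec in records:
        if list(rec.attributes.keys()) != list(attribute_names):
            raise FormatError(
                f"record attributes {list(rec.attributes)} do not match "
                f"declared columns {list(attribute_names)}"
            )
        sa, ea = rec.interval_a.raw()
        sb, eb = rec.interval_b.raw()
        cells = [rec.seq_a, str(sa), str(ea), rec.seq_b, str(sb), str(eb)]
        cells += [repr(float(rec.attributes[name])) for name in attribute_names]
        out.append("\t".join(cells))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Annotation format
# ---------------------------------------------------------------------------

def parse_annotation(stream: TextIO | Iterable[str]) -> list[AnnotationFeature]:
    """Parse an annotation file into a list of features."""
    lines = _data_lines(stream)
    try:
        header_lineno, header = next(lines)
    except StopIteration:
        raise FormatError("empty annotation file: header line required") from None
    for i, required in enumerate(ANNOTATION_REQUIRED):
        if i >= len(header) or header[i] != required:
            raise FormatError(
                f"line {header_lineno}: annotation header must start with "
                f"{', '.join(ANNOTATION_REQUIRED)}; missing or misplaced {required!r}"
            )
    tail = header[len(ANNOTATION_REQUIRED):]
    allowed_tail = list(ANNOTATION_OPTIONAL)
    # optional columns must appear in canonical order, each at most once
    pos = 0
    for name in tail:
        try:
            pos = allowed_tail.index(name, pos) + 1
        except ValueError:
            raise FormatError(
                f"line {header_lineno}: unexpected annotation column {name!r}; "
                f"optional columns are {', '.join(ANNOTATION_OPTIONAL)} in that order"
            ) from None
    columns = list(ANNOTATION_REQUIRED) + tail

    features: list[AnnotationFeature] = []
    for lineno, cols in lines:
        if len(cols) != len(columns):
            raise FormatError(
                f"line {lineno}: expected {len(columns)} columns, found {len(cols)}"
            )
        row = dict(zip(columns, cols))
        interval = _interval_from_cells(row["start"], row["end"], "feature", lineno)
        strand = row.get("strand", "") or "."
        value_cell = row.get("value", "")
        value = _parse_finite(value_cell, "feature", lineno) if value_cell else None
        try:
            features.append(
                AnnotationFeature(
                    seq=row["org"],
                    interval=interval,
                    track=row["track"],
                    shape=row["shape"],
                    color=row["color"],
                    strand=strand,
                    label=row.get("label", ""),
                    value=value,
                )
            )
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return features


def write_annotation(features: Sequence[AnnotationFeature]) -> str:
    """Serialize features with the full canonical header (LF line ends)."""
    out = ["\t".join(list(ANNOTATION_REQUIRED) + list(ANNOTATION_OPTIONAL))]
    for feat in features:
        s, e = feat.interval.raw()
        out.append(
            "\t".join(
                [
                    feat.seq,
                    str(s),
                    str(e),
                    feat.track,
                    feat.shape,
                    feat.color,
                    feat.strand,
                    feat.label,
                    "" if feat.value is None else repr(float(feat.value)),
                ]
            )
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(
    records: Sequence[SyntenyRecord],
    features: Sequence[AnnotationFeature] = (),
    attribute_names: Sequence[str] | None = None,
    lengths: Mapping[str, int] | None = None,
) -> Dataset:
    """Assemble and validate a :class:`Dataset`.

    Sequence display lengths default to the maximum end coordinate observed
    for each name; ``lengths`` may declare larger values (declaring a length
    smaller than an observed coordinate is an error).  A feature referencing
    a sequence never named by any record and not declared in ``lengths`` is
    an orphan and rejected.
    """
    records = list(records)
    features = list(features)
    lengths = dict(lengths or {})
    if attribute_names is None:
        attribute_names = list(records[0].attributes.keys()) if records else []
    attribute_names = list(attribute_names)

    record_seqs: set[str] = set()
    observed: dict[str, int] = {}
    order: list[str] = []

    def see(name: str, end: int) -> None:
        if name not in observed:
            order.append(name)
            observed[name] = end
        else:
            observed[name] = max(observed[name], end)

    for rec in records:
        see(rec.seq_a, rec.interval_a.end)
        see(rec.seq_b, rec.interval_b.end)
        record_seqs.update((rec.seq_a, rec.seq_b))
    orphans = sorted(
        {f.seq for f in features} - record_seqs - set(lengths)
    )
    if orphans:
        raise FormatError(
            "annotation features reference sequences with no synteny record and "
            f"no declared length: {', '.join(orphans)}"
        )
    for feat in features:
        see(feat.seq, feat.interval.end)
    for name in lengths:
        if name not in observed:
            order.append(name)
            observed[name] = 0

    sequences: dict[str, SequenceInfo] = {}
    for name in order:
        length = lengths.get(name, observed[name])
        if length < observed[name]:
            raise FormatError(
                f"declared length {length} for {name!r} is smaller than the "
                f"maximum observed coordinate {observed[name]}"
            )
        sequences[name] = SequenceInfo(name, length)

    ds = Dataset(records, features, sequences, attribute_names)
    ds.validate()
    return ds


def read_synteny(path: str | Path) -> tuple[list[SyntenyRecord], list[str]]:
    """Parse a (possibly compressed) synteny file from disk."""
    return parse_synteny(open_maybe_compressed(path))


def read_annotation(path: str | Path) -> list[AnnotationFeature]:
    """Parse a (possibly compressed) annotation file from disk."""
    return parse_annotation(open_maybe_compressed(path))


def load_dataset(
    synteny_path: str | Path,
    annotation_path: str | Path | None = None,
    lengths: Mapping[str, int] | None = None,
) -> Dataset:
    """Read synteny (+ optional annotation) files and assemble a Dataset."""
    records, attribute_names = read_synteny(synteny_path)
    features = read_annotation(annotation_path) if annotation_path else []
    return build_dataset(records, features, attribute_names, lengths)
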