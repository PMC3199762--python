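"""Converters from common alignment/annotation outputs to the interchange formats.

Three converters are provided, mirroring the helper scripts a comparative
genomics workflow typically needs:

* BLAST tabular (``-outfmt 6``, the fixed 12-column layout) -> synteny records;
* lastz/BLASTZ "general" tabular output -> synteny records, driven by an
  explicit ordered field specification because that format is user-configurable;
* GFF3 -> annotation features, with a style map deciding track/shape/color
  per feature type.

All outputs satisfy the formats-module invariants; no rows are dropped
silently (GFF3 drops happen only via an explicit ``types_keep`` set).
"""

from __future__ import annotations

import urllib.parse
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .errors import ConfigError, FormatError
from .formats import (
    AnnotationFeature,
    Interval,
    SyntenyRecord,
    _data_lines,
    _parse_finite,
    _parse_int,
)

#: Column order of BLAST ``-outfmt 6``.
BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: Attribute columns emitted for every BLAST-derived record, in order.
BLAST_ATTRIBUTES = ("identity", "aln_length", "evalue", "bitscore")

#: Default lastz/BLASTZ general-format field layout.
LASTZ_DEFAULT_FIELDS = ("name1", "start1", "end1", "name2", "start2", "end2", "score")

_LASTZ_REQUIRED = ("name1", "start1", "end1", "name2", "start2", "end2")
_LASTZ_ATTRS = ("score", "identity")


def blast_tab_to_synteny(
    stream: TextIO | Iterable[str],
    query_name_as: str = "org1",
) -> tuple[list[SyntenyRecord], list[str]]:
    """Convert BLAST tabular (outfmt 6) lines to synteny records.

    One record per HSP line.  The query maps to the org1 side and the subject
    to org2 (swapped when ``query_name_as == "org2"``).  A subject interval
    with sstart > send yields reverse orientation; outfmt 6 never reports a
    reversed query for nucleotide searches, so only the subject side can flip.
    Attributes carried over: identity (pident), aln_length, evalue, bitscore.
    """
    if query_name_as not in ("org1", "org2"):
        raise ConfigError(f"query_name_as must be 'org1' or 'org2', got {query_name_as!r}")
    records: list[SyntenyRecord] = []
    for lineno, cols in _data_lines(stream):
        if len(cols) != len(BLAST_COLUMNS):
            raise FormatError(
                f"line {lineno}: BLAST outfmt 6 requires {len(BLAST_COLUMNS)} "
                f"columns, found {len(cols)}"
            )
        row = dict(zip(BLAST_COLUMNS, cols))
        q_iv = Interval.from_raw(
            _parse_int(row["qstart"], "qstart", lineno),
            _parse_int(row["qend"], "qend", lineno),
        )
        s_iv = Interval.from_raw(
            _parse_int(row["sstart"], "sstart", lineno),
            _parse_int(row["send"], "send", lineno),
        )
        attributes = {
            "identity": _parse_finite(row["pident"], "pident", lineno),
            "aln_length": _parse_finite(row["length"], "length", lineno),
            "evalue": _parse_finite(row["evalue"], "evalue", lineno),
            "bitscore": _parse_finite(row["bitscore"], "bitscore", lineno),
        }
        if query_name_as == "org1":
            rec = SyntenyRecord(row["qseqid"], q_iv, row["sseqid"], s_iv, attributes)
        else:
            rec = SyntenyRecord(row["sseqid"], s_iv, row["qseqid"], q_iv, attributes)
        records.append(rec)
    return records, list(BLAST_ATTRIBUTES)


def lastz_to_synteny(
    stream: TextIO | Iterable[str],
    field_spec: Sequence[str] = LASTZ_DEFAULT_FIELDS,
) -> tuple[list[SyntenyRecord], list[str]]:
    """Convert lastz/BLASTZ "general" tabular output to synteny records.

    ``field_spec`` names the columns in file order and must include
    name1, start1, end1, name2, start2, end2; recognized optional fields are
    score and identity (kept as attributes) and strand2 ("-" flips the
    org2-side orientation).  Unrecognized field names are read and ignored.
    """
    field_spec = list(field_spec)
    missing = [f for f in _LASTZ_REQUIRED if f not in field_spec]
    if missing:
        raise ConfigError(f"field_spec missing required fields: {', '.join(missing)}")
    attribute_names = [f for f in _LASTZ_ATTRS if f in field_spec]

    records: list[SyntenyRecord] = []
    for lineno, cols in _data_lines(stream):
        if len(cols) != len(field_spec):
            raise FormatError(
                f"line {lineno}: expected {len(field_spec)} columns per "
                f"field_spec, found {len(cols)}"
            )
        row = dict(zip(field_spec, cols))
        iv_a = Interval.from_raw(
            _parse_int(row["start1"], "start1", lineno),
            _parse_int(row["end1"], "end1", lineno),
        )
        iv_b = Interval.from_raw(
            _parse_int(row["start2"], "start2", lineno),
            _parse_int(row["end2"], "end2", lineno),
        )
        if row.get("strand2") in ("-", "−"):
            iv_b = Interval(iv_b.start, iv_b.end, "reverse") if iv_b.start < iv_b.end else iv_b
        attributes = {
            name: _parse_finite(row[name], name, lineno) for name in attribute_names
        }
        records.append(SyntenyRecord(row["name1"], iv_a, row["name2"], iv_b, attributes))
    return records, attribute_names


@dataclass
class TrackStyleMap:
    """Maps a GFF3 feature type to (track name, shape, color) for display.

    Unmapped types fall back to ``default``: track named after the type,
    drawn per the default shape/color.  The stock map styles ``gene`` as
    blue arrows on a "gene" track.
    """

    styles: dict[str, tuple[str, str, str]] = field(
        default_factory=lambda: {"gene": ("gene", "arrow", "blue")}
    )
    default: tuple[str, str] = ("box", "gray")  # (shape, color) for unmapped types

    def style_for(self, feature_type: str) -> tuple[str, str, str]:
        if feature_type in self.styles:
            return self.styles[feature_type]
        shape, color = self.default
        return feature_type, shape, color


def _gff3_attributes(column: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if column in (".", ""):
        return attrs
    for pair in column.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        if "=" not in pair:
            raise FormatError(f"line {lineno}: malformed GFF3 attribute {pair!r}")
        key, _, value = pair.partition("=")
        attrs[key] = urllib.parse.unquote(value)
    return attrs


def gff3_to_annotation(
    stream: TextIO | Iterable[str],
    style: TrackStyleMap | None = None,
    types_keep: set[str] | None = None,
) -> list[AnnotationFeature]:
    """Convert GFF3 feature lines to annotation features.

    GFF3 is already 1-based inclusive, so start/end are adopted verbatim.
    ``types_keep`` restricts output to the named feature types (None keeps
    all).  Labels come from the Name attribute, falling back to ID; a
    malformed attribute column produces a warning and an unlabeled feature.
    Lines after a ``##FASTA`` directive are ignored.
    """
    style = style or TrackStyleMap()
    features: list[AnnotationFeature] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if line.startswith("##FASTA"):
            break
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"line {lineno}: GFF3 requires 9 columns, found {len(cols)}")
        seq, _source, ftype, start_s, end_s, _score, strand, _phase, attr_col = cols
        if types_keep is not None and ftype not in types_keep:
            continue
        start = _parse_int(start_s, "start", lineno)
        end = _parse_int(end_s, "end", lineno)
        if start > end:
            raise FormatError(f"line {lineno}: GFF3 start {start} > end {end}")
        try:
            attrs = _gff3_attributes(attr_col, lineno)
        except FormatError as exc:
            warnings.warn(f"{exc}; keeping feature with empty label", stacklevel=2)
            attrs = {}
        track, shape, color = style.style_for(ftype)
        features.append(
            AnnotationFeature(
                seq=seq,
                interval=Interval(start, end),
                track=track,
                shape=shape,
                color=color,
                strand=strand if strand in ("+", "-") else ".",
                label=attrs.get("Name", attrs.get("ID", "")),
            )
        )
    return features
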