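"""Seeded synthetic synteny/annotation generator.

Generates coordinate-level genome pairs — no nucleotide sequences — with a
controllable number of non-nested, non-overlapping conserved blocks per
sequence pair, a tunable inversion probability, attribute values drawn from
declared distributions, and styled annotation tracks.  Everything is
reproducible from the seed, and every generated dataset satisfies the
interchange-format invariants, so the generator doubles as the test-fixture
source for the whole package.

The demo dataset (:func:`figure1_fixture`) is a three-organism example with
all three pairs present and three annotation tracks: "gene" (blue arrows),
"expression" (green value-scaled bars), "transposon" (black boxes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .formats import (
    REVERSE,
    AnnotationFeature,
    Dataset,
    Interval,
    SyntenyRecord,
    build_dataset,
    write_annotation,
    write_synteny,
)
from .viewmodel import ViewState, initial_state

#: (name, distribution, lo, hi); distribution is "uniform" or "loguniform".
AttrSpec = tuple[str, str, float, float]

DEFAULT_ATTRIBUTES: tuple[AttrSpec, ...] = (
    ("score", "uniform", 200.0, 10_000.0),
    ("evalue", "loguniform", 1e-50, 1e-2),
    ("identity", "uniform", 80.0, 100.0),
)

DEFAULT_TRACKS: tuple[tuple[str, str, str], ...] = (
    ("gene", "arrow", "blue"),
    ("expression", "line", "green"),
    ("transposon", "box", "black"),
)


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated dataset.

    Defaults describe a small bacterial-scale comparison: two 1 Mb
    sequences sharing 20 conserved blocks of 5-50 kb, one block in five
    inverted, with BLAST-like score/E-value/identity attributes and three
    annotation tracks of 30 features each.
    """

    n_sequences: int = 2
    seq_length: int = 1_000_000
    n_blocks: int = 20
    block_length_range: tuple[int, int] = (5_000, 50_000)
    inversion_rate: float = 0.2
    attributes: tuple[AttrSpec, ...] = DEFAULT_ATTRIBUTES
    n_features_per_track: int = 30
    tracks: tuple[tuple[str, str, str], ...] = DEFAULT_TRACKS
    seq_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ConfigError("n_sequences must be >= 2")
        lo, hi = self.block_length_range
        if not (1 <= lo <= hi <= self.seq_length):
            raise ConfigError("block_length_range must fit in seq_length")
        if not (0.0 <= self.inversion_rate <= 1.0):
            raise ConfigError("inversion_rate must be in [0, 1]")
        for name, dist, a, b in self.attributes:
            if dist not in ("uniform", "loguniform"):
                raise ConfigError(f"unknown distribution {dist!r} for attribute {name!r}")
            if dist == "loguniform" and a <= 0:
                raise ConfigError(f"loguniform lower bound must be > 0 for {name!r}")

    def names(self) -> tuple[str, ...]:
        if self.seq_names is not None:
            if len(self.seq_names) != self.n_sequences:
                raise ConfigError("seq_names length must equal n_sequences")
            return self.seq_names
        return tuple(f"seq{i + 1}" for i in range(self.n_sequences))


def _place_blocks(rng: np.random.Generator, lengths: np.ndarray, seq_length: int) -> np.ndarray:
    """Non-overlapping 1-based start positions for blocks of given lengths.

    Blocks keep their input order along the sequence; free space is split
    among the gaps by sorting uniform offsets.
    """
    total = int(lengths.sum())
    free = seq_length - total
    if free < 0:
        raise ConfigError(
            f"cannot place {len(lengths)} blocks totalling {total} bp on a "
            f"{seq_length} bp sequence; reduce n_blocks or block lengths"
        )
    offsets = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    starts = offsets + np.concatenate(([0], np.cumsum(lengths[:-1]))) + 1
    return starts.astype(np.int64)


def _draw_attribute(rng: np.random.Generator, spec: AttrSpec) -> float:
    _, dist, lo, hi = spec
    if dist == "uniform":
        return float(rng.uniform(lo, hi))
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_dataset(spec: SimSpec) -> Dataset:
    """Generate a dataset per the spec; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    names = spec.names()
    lo, hi = spec.block_length_range

    records: list[SyntenyRecord] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            lengths = rng.integers(lo, hi + 1, size=spec.n_blocks)
            starts_a = _place_blocks(rng, lengths, spec.seq_length)
            # independent layout on the partner: same block lengths, permuted
            # order along the sequence, so rearrangements are common
            perm = rng.permutation(spec.n_blocks)
            starts_b_sorted = _place_blocks(rng, lengths[perm], spec.seq_length)
            starts_b = np.empty(spec.n_blocks, dtype=np.int64)
            starts_b[perm] = starts_b_sorted
            inverted = rng.random(spec.n_blocks) < spec.inversion_rate
            for k in range(spec.n_blocks):
                iv_a = Interval(int(starts_a[k]), int(starts_a[k] + lengths[k] - 1))
                iv_b = Interval(
                    int(starts_b[k]),
                    int(starts_b[k] + lengths[k] - 1),
                    REVERSE if inverted[k] else "forward",
                )
                attrs = {s[0]: _draw_attribute(rng, s) for s in spec.attributes}
                records.append(SyntenyRecord(names[i], iv_a, names[j], iv_b, attrs))

    features: list[AnnotationFeature] = []
    for name in names:
        for track, shape, color in spec.tracks:
            for _ in range(spec.n_features_per_track):
                length = int(rng.integers(500, 5_001))
                start = int(rng.integers(1, spec.seq_length - length + 1))
                strand = "." if shape == "line" else ("+", "-")[int(rng.integers(0, 2))]
                value = float(rng.uniform(0.0, 100.0)) if shape == "line" else None
                features.append(
                    AnnotationFeature(
                        seq=name,
                        interval=Interval(start, start + length - 1),
                        track=track,
                        shape=shape,
                        color=color,
                        strand=strand,
                        label=f"{track}_{name}_{len(features)}",
                        value=value,
                    )
                )

    attribute_names = [s[0] for s in spec.attributes]
    lengths_map = {name: spec.seq_length for name in names}
    return build_dataset(records, features, attribute_names, lengths_map)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write synteny.tsv and annotation.tsv for a dataset; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    syn = out_dir / "synteny.tsv"
    ann = out_dir / "annotation.tsv"
    syn.write_text(write_synteny(dataset.records, dataset.attribute_names))
    ann.write_text(write_annotation(dataset.features))
    return syn, ann


def generate_blast_tabular(
    n_hsps: int = 500,
    minus_fraction: float = 0.2,
    seed: int = 0,
    query: str = "query1",
    subject: str = "subject1",
    seq_length: int = 1_000_000,
) -> str:
    """BLAST outfmt-6 text with a controlled minus-strand subject fraction.

    The first ``round(n_hsps * minus_fraction)`` HSPs are minus-strand
    (sstart > send); the rest are plus-strand.  Used for converter tests.
    """
    rng = np.random.default_rng(seed)
    n_minus = round(n_hsps * minus_fraction)
    lines = []
    for i in range(n_hsps):
        aln_len = int(rng.integers(100, 5_000))
        qstart = int(rng.integers(1, seq_length - aln_len + 1))
        sstart = int(rng.integers(1, seq_length - aln_len + 1))
        qend = qstart + aln_len - 1
        send = sstart + aln_len - 1
        if i < n_minus:
            sstart, send = send, sstart
        pident = round(float(rng.uniform(80.0, 100.0)), 2)
        mismatch = int(round(aln_len * (100.0 - pident) / 100.0))
        evalue = float(np.exp(rng.uniform(np.log(1e-180), np.log(1e-3))))
        bitscore = round(float(rng.uniform(50.0, 5_000.0)), 1)
        lines.append(
            "\t".join(
                [
                    query, subject, f"{pident:.2f}", str(aln_len), str(mismatch), "0",
                    str(qstart), str(qend), str(sstart), str(send),
                    f"{evalue:.2e}", f"{bitscore:.1f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


FIGURE1_SEED = 8191  # fixed internal seed of the demo dataset


def figure1_fixture() -> Dataset:
    """The three-organism demo dataset: pairs A-B, A-C, B-C and three
    styled tracks (gene/blue arrows, expression/green bars, transposon/black
    boxes) on every organism.  Deterministic."""
    spec = SimSpec(
        n_sequences=3,
        seq_length=500_000,
        n_blocks=12,
        block_length_range=(5_000, 30_000),
        inversion_rate=0.25,
        n_features_per_track=20,
        seq_names=("OrganismA", "OrganismB", "OrganismC"),
        seed=FIGURE1_SEED,
    )
    return generate_dataset(spec)


def figure1_state(dataset: Dataset) -> ViewState:
    """The demo view: pair A-B, blocks mode, transposon hidden on panel B."""
    state = initial_state(dataset, ("OrganismA", "OrganismB"))
    state.tracks.hidden_b.add("transposon")
    return state
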