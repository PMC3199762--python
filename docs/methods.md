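# Methods

## The display model

`syntenyviz` draws the classic dual-genome integrated synteny view: two
horizontal rulers, one per selected sequence, with one glyph per conserved
region between them. In *blocks* mode the glyph is a filled quadrilateral
(ribbon) whose top edge spans the region's interval on panel A and whose
bottom edge spans its interval on panel B; in *lines* mode it is a segment
joining the two interval midpoints. A region whose two sides have opposite
orientation is an inversion, and its ribbon's bottom edge is traversed in
the opposite direction to the top edge, producing the self-crossing
("twisted") ribbon that is the standard visual signature of an inversion.
Annotation tracks stack outward from each ruler — panel A's above, panel
B's below — one lane per visible track, in the panel's track order.

## Coordinates and formats

All coordinates are 1-based and inclusive at both ends, in files and in
every public interface; this matches GFF3, so converted annotations are
adopted verbatim with no off-by-one shift. Reverse orientation is encoded
positionally (start > end on either side of a synteny row), as alignment
tools report minus-strand hits; the parser normalizes to a sorted interval
plus an orientation flag, and the writer re-emits start > end, so
write→parse is an exact identity. A single-base interval normalizes to
forward: positional encoding cannot express its orientation, and making it
canonical keeps the round trip exact for every representable value.

Attribute values must be finite reals with no missing cells; the filter
semantics (total inclusive-range tests) require totality. Floats are
serialized with `repr`, the shortest exactly-round-tripping form.

The annotation format adds one optional trailing `value` column beyond
strand and label; it carries a per-feature number used to scale expression
bar heights. Files may be plain, gzip, or single-member zip; the container
is detected from magic bytes, not the file name.

## Filtering and visibility

Every record exposes the implicit attribute `length`, defined as the
**maximum** of its two side lengths, so the default length filter is
symmetric under swapping the genomes (minimum, mean, or side-A length would
be defensible alternatives; max was chosen for that symmetry). Filters are
inclusive on both bounds and conjunctive across attributes, which makes
filtering anti-monotone in strictness and composable.

A record is drawn when it overlaps **either** panel's viewport. The
alternative (require both) was rejected because it hides exactly the
interesting cases — rearranged blocks whose partner lies outside the other
panel's window. Intervals are never clipped in the view model; clipping is
purely a rendering concern.

## Viewport algebra

Viewports are integer base-pair windows. Zoom computes a new span
`round(span / factor)` (half away from zero, floored at 1 bp, capped at the
sequence length), centers it on the old midpoint (or an explicit center),
and clamps to the sequence; pan shifts by `round(fraction × span)` with the
same clamping. Spans are counted inclusively (`end − start + 1`) everywhere.
Because both operations round to integers, zooming in by k and back out by
1/k restores the span only to within the scaled rounding error (≤ k/2 + ½
bp); it is exact to ±1 bp for k ≤ 2, the canonical zoom-button step, and the
tests assert exactly that.

## Rendering choices

* The bp→px map is linear over the viewport: `x = margin +
  (pos − start)/span × drawable_width`, i.e. the left edge of the base.
  Ribbon corner x values are this map applied to the record's interval
  endpoints, which is what the geometry tests check to 1e-6 px; track
  feature rectangles extend to the left edge of `end + 1` so a feature
  covers its full final base.
* Ruler tick steps come from the 1-2-5 ladder: the smallest step in
  {1,2,5}×10^k placing at most `max_ticks` tick multiples inside the
  viewport. Labels pick bp/kb/Mb so tick values divide evenly, with
  thousands separators.
* Ribbon fill opacity is fixed at 0.6 so overlapping blocks remain
  readable. Two color schemes exist: *categorical* (default) cycles a
  12-color colorblind-safe palette (Paul Tol's qualitative hues, listed in
  `syntenyviz/colors.py`) by record index; *attribute:NAME* min-max
  normalizes the named attribute over the drawn records and maps it through
  a documented light-yellow→deep-blue sequential ramp, with the midpoint
  color when all values are equal.
* Features in one track share a single lane and overdraw in file order;
  stacked sub-lanes were deliberately left out. Arrows point with strand;
  strand "." falls back to a box. Shape `line` renders as a bar whose
  height scales with the feature's `value`, min-max normalized within its
  track (a thin fixed bar when no value is present).
* SVG export writes elements in glyph order with all numbers formatted to
  exactly 2 decimals and no timestamps or generator metadata, so identical
  scenes give identical bytes across runs and processes. PNG export
  (Pillow) rasterizes the same scene at `dpi/96` scale; PNG bytes are not
  promised stable across rasterizer versions, so reproducibility pipelines
  should compare SVG.

## The simulator

The generator emulates the *coordinate structure* of a pairwise whole-genome
comparison, not its sequence content: for each sequence pair it places
`n_blocks` non-nested, non-overlapping blocks (lengths uniform in
`block_length_range`) on each side by splitting the free space uniformly,
permutes block order on the second sequence so rearrangements are common,
inverts each block with probability `inversion_rate`, and draws attribute
values from declared uniform or log-uniform distributions. Defaults model a
small bacterial-scale comparison: 1 Mb sequences, 20 blocks of 5–50 kb,
inversion rate 0.2, BLAST-like score (uniform 200–10 000), E-value
(log-uniform 1e-50–1e-2) and identity (uniform 80–100 %) attributes, and
three tracks of 30 features each. All draws come from one seeded NumPy
generator, so the same seed yields byte-identical files.

What the simulator does **not** model — overlapping or nested blocks,
many-to-many homology, length differences between a block's two sides,
coordinate errors — bounds what passing tests show: they verify the
formats, state machine, and geometry exactly, but say nothing about how a
figure looks under pathological real-data block structures beyond the
clipping and overdraw rules above.

The bundled demo dataset (`figure1_fixture`) is a fixed-seed three-organism
instance (500 kb sequences, 12 blocks per pair, all three pairs present)
with "gene" (blue arrows), "expression" (green value-scaled bars) and
"transposon" (black boxes) tracks; its companion view state hides the
transposon track on panel B only.

## Degenerate inputs and tie-breaks

* Empty record list: writers emit a header-only file; a dataset with no
  records cannot seed a view (there is no pair to select).
* (A,B) seen before (B,A): both rows belong to one pair, keyed and paneled
  by first-seen orientation.
* Declared sequence lengths must cover every observed coordinate; features
  on sequences never named by a record require a declared length.
* Zip archives must contain exactly one member; anything else is ambiguous
  and rejected rather than guessed.
* Color names resolve through the CSS named-color table to `#rrggbb`;
  unknown names are format errors at parse time, not draw time.

## Problem sizes in the test and acceptance runs

Randomized checks use many small instances rather than few large ones:
round trips over 1 000 (tests) / 200 (acceptance script) datasets of 3
blocks each, converter fidelity on 500 HSPs with a 20 % minus-strand
fraction, filter oracles on 200 random cases, tick-ladder oracles on 1 000
random spans, and a 10 000-block run for the inversion-rate statistic
(checked within 3 standard errors). The full suite runs in a few seconds.

## Known limitations

Only two genomes are displayed at a time (multi-genome layouts are out of
scope); annotation tracks are single-lane; BLAST ingestion is fixed to the
default 12-column tabular layout; GFF3 ingestion is flat (no parent/child
reconstruction); there is no interactive event loop — the CLI plus config
files replace it.
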