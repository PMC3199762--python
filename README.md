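# syntenyviz

Headless, scriptable visualization of pairwise genome synteny.

Comparative genomics routinely produces sets of *conserved regions* (synteny
blocks): pairs of intervals, one on each of two genomes, judged homologous by
an aligner such as BLAST or lastz. `syntenyviz` is for biologists and
bioinformaticians who have such blocks for **their own sequences** — drafts,
local assemblies, unpublished strains — and want a publication-quality
dual-genome figure without a web service or an interactive GUI: every figure
is produced by a function call or a shell command and is byte-reproducible
from a plain-text config.

The toolkit provides:

* **Interchange formats** — two simple tab-delimited files. The *synteny
  file* has one conserved region per row (`org1 start1 end1 org2 start2 end2`
  plus any number of named numeric attribute columns: score, E-value, percent
  identity, ...). The *annotation file* lists styled features per track
  (`org start end track shape color [strand] [label] [value]`). Coordinates
  are 1-based inclusive; a row with start > end denotes reverse orientation;
  files may be gzip- or zip-compressed.
* **Converters** — BLAST tabular (`-outfmt 6`), lastz/BLASTZ "general"
  tabular, and GFF3 into those formats.
* **A view model** — pair selection, per-panel viewports with zoom/pan/reset,
  inclusive-range filters over any attribute (plus the implicit block
  `length`), and per-panel track order/visibility/style overrides.
* **A renderer** — panel A's annotation tracks above its ruler, panel B's
  below, and one colored ribbon per conserved region between the rulers; an
  inverted block (opposite orientations on the two sides) draws a
  self-crossing "twisted" ribbon. Export to deterministic SVG or PNG.
* **A simulator** — seeded synthetic datasets (non-overlapping blocks,
  controllable inversion rate, attribute distributions, styled tracks) so the
  whole pipeline is testable without downloads.

## Worked example

```sh
# a three-organism demo dataset with gene/expression/transposon tracks
syntenyviz simulate --out-dir demo --figure1

syntenyviz pairs demo/synteny.tsv
# OrganismA    OrganismB
# OrganismA    OrganismC
# OrganismB    OrganismC

syntenyviz validate demo/synteny.tsv demo/annotation.tsv
# OK: 36 records, 180 features, 3 sequences, 3 pairs, attributes: score, evalue, identity

syntenyviz plot demo/synteny.tsv demo/annotation.tsv \
    --pair OrganismA,OrganismB \
    --filter evalue:max=1e-10 --filter length:min=8000 \
    --hide-track transposon:b \
    --out fig.svg --save-config view.cfg --verbose
# wrote fig.svg (155 glyphs)
```

The 36 records are 12 conserved blocks for each of the three genome pairs;
the figure draws only the A–B pair's blocks that pass both filters (E-value
at most 1e-10 **and** block length at least 8 kb), as ribbons between the two
rulers, with the transposon track hidden below panel B. Re-running

```sh
syntenyviz plot demo/synteny.tsv demo/annotation.tsv --config view.cfg --out fig2.svg
```

reproduces `fig.svg` byte-for-byte (`cmp fig.svg fig2.svg` is silent): the
saved config captures the complete view state.

The same pipeline from Python:

```python
from syntenyviz import (figure1_fixture, figure1_state, FilterSpec,
                        render_figure, export_svg)

ds = figure1_fixture()
state = figure1_state(ds)                    # pair A-B, transposon hidden on B
state.filters = [FilterSpec("evalue", max=1e-10)]
export_svg(render_figure(ds, state), "fig.svg")
```

Converting real aligner output:

```sh
blastn -query A.fa -subject B.fa -outfmt 6 > hits.tsv
syntenyviz convert blast --in hits.tsv --out synteny.tsv
syntenyviz convert gff3 --in B.gff3 --keep-types gene --out annotation.tsv
```

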