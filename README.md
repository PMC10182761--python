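# irdraw

Detection and visualization of chloroplast-genome junction sites.

Most plastomes are circular tetrad molecules: a large single-copy region
(LSC), a small single-copy region (SSC), and two inverted-repeat arms
(IRb, IRa) that are reverse complements of each other. The four region
boundaries — **JLB** (LSC/IRb), **JSB** (IRb/SSC), **JSA** (SSC/IRa) and
**JLA** (IRa/LSC) — move as the IR expands or contracts, shifting genes
like *rps19*, *ycf1*, *ndhF* and *trnH* between single-copy and duplicated
territory. Comparing the genes flanking each junction across species is a
standard readout of plastome structural evolution.

The catch: a deposited GenBank record linearizes the circle at an
arbitrary point — sometimes mid-LSC, mid-IR, or mid-SSC — so regions and
genes can wrap the origin and naive junction-finding breaks. `irdraw`
normalizes any rotation first:

1. count canonical k-mers (k-mer ≡ its reverse complement; default
   k = 55, step 1, windows wrap the circle) — IR sequence counts twice,
   single-copy sequence once;
2. rotate the sequence to the midpoint of the longest single-copy run, so
   neither IR arm can straddle the origin;
3. find the longest pair of reverse-complementary substrings by
   anti-diagonal seed-and-extend (chaining exact matches across ≤ 10 bp
   point divergences between arms);
4. map the arms back to deposited coordinates (wrap written as
   start > end), label the longer gap LSC and the shorter SSC, and filter
   genomes with arms < 100 bp or no gene annotation;
5. re-rotate so the LSC starts at base 1, compute the four junctions with
   their flanking/spanning genes and distances, and draw one row per
   genome (arrows give transcription direction; right = plus strand).

Output is SVG (canonical, byte-stable across runs) with best-effort PDF
and PNG conversions, plus TSV tables of region coordinates and junction
contexts.

## Worked example

The package ships a generator for ground-truth miniature plastomes (900 bp
LSC, 300 bp IRs, 200 bp SSC by default) covering all nine deposited
starting-point groups:

```sh
irdraw make-fixtures -o fixtures --seed 1
irdraw draw -i fixtures/group_a.gb -i fixtures/group_h.gb -o out --formats svg,png
```

`out/cpgenomes.regions.tsv` reports the detected tetrads in deposited
coordinates:

```text
accession     organism               region  start  end   length
SYN_000001.1  Synthetica plastoma-a  LSC     1      900   900
SYN_000001.1  Synthetica plastoma-a  IRb     901    1200  300
SYN_000001.1  Synthetica plastoma-a  SSC     1201   1400  200
SYN_000001.1  Synthetica plastoma-a  IRa     1401   1700  300
SYN_000008.1  Synthetica plastoma-h  LSC     151    1050  900
SYN_000008.1  Synthetica plastoma-h  IRb     1051   1350  300
SYN_000008.1  Synthetica plastoma-h  SSC     1351   1550  200
SYN_000008.1  Synthetica plastoma-h  IRa     1551   150   300
```

The second record was deposited starting inside IRa, so its IRa wraps the
origin — start 1551 greater than end 150 denotes the wrap. After
standardization both genomes have identical junction geometry, as
`out/cpgenomes.junctions.tsv` shows (positions are the last base of the
upstream region; `name:left|right` is a junction-spanning gene with its
base counts on each side):

```text
accession     junction  position  left_gene  left_distance  right_gene  right_distance  spanning
SYN_000001.1  JLB       900       rps19      0              rps19       0               rps19:60|60
SYN_000001.1  JSB       1200      ndhF       0              ndhF        0               ndhF:19|61
SYN_000001.1  JSA       1400      ycf1       0              ycf1        0               ycf1:44|46
SYN_000001.1  JLA       1700      ycf2       0              ycf2        0               ycf2:9|41
SYN_000008.1  JLB       900       rps19      0              rps19       0               rps19:60|60
...
```

Reading the first row: *rps19* crosses JLB with 60 bases in the LSC and 60
in the IRb — exactly as planted by the generator. `out/cpgenomes.junctions.svg`
stacks one annotated row per genome.

Library use mirrors the CLI:

```python
from irdraw import parse_genbank, detect_tetrad, standardize_start, compute_junctions

genome = parse_genbank("fixtures/group_h.gb")
result = detect_tetrad(genome)            # deposited coordinates, wrap-aware
std_genome, std_tetrad = standardize_start(genome, result.tetrad)
for site in compute_junctions(std_tetrad):
    print(site.name, site.position)       # JLB 900, JSB 1200, JSA 1400, JLA 1700
```

A two-column tab-separated configuration file (`path<TAB>LSC:s-e;IRb:s-e;SSC:s-e;IRa:s-e`)
can override detection with user-supplied junction coordinates
(`irdraw draw -c run.cfg ...`).

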