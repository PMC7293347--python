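# lampsmith

Design and evaluate **LAMP assays** (loop-mediated isothermal amplification)
for species detection — the kind of portable molecular test used in
biosecurity surveillance to identify, say, an invasive fruit fly larva in
intercepted produce within the hour, on a battery-powered real-time
fluorometer.

A LAMP assay uses four to six primers recognising six to eight closely
linked template regions, laid out 5'→3' on the plus strand as

```
F3  F2  [LF]  F1  ........  B1  [LB]  B2  B3
```

with the two inner primers being fusions:
**FIP** = revcomp(F1) + F2 and **BIP** = revcomp(B1) + B2.
`lampsmith` covers the full desk-side workflow around such an assay:

* **alignment profiling** — per-column base counts, minimal IUPAC degenerate
  consensus, and region-level exclusivity statistics (how different the
  *closest* non-target sequence is over a candidate footprint) for a
  "target" vs "non-target" pair of aligned FASTA sets sharing one
  coordinate frame;
* **primer modelling** — degenerate expansion and degeneracy counting,
  FIP/BIP assembly, nearest-neighbour melting temperature (SantaLucia 2004
  parameters, Owczarzy divalent salt correction, worst case over degenerate
  expansions), and run-length self-dimer/hairpin scoring with 3'-anchor
  flagging;
* **design search** — exhaustive, deterministic scanning of the joint
  alignment for eight-region layouts satisfying geometry, degeneracy-cap,
  indel and exclusivity criteria, ranked by a transparent weighted score
  (−log₂ degeneracy + capped non-target mismatch bonus − self-structure −
  Tm spread);
* **in-silico specificity screening** — minimum-mismatch placement of every
  region on a template, 3'-window mismatches weighted ×3, and a
  positive / late / negative class per template;
* **assay arithmetic** — primer master-mix recipes, in-reaction
  concentrations, serial dilutions and protocol timing, all in exact
  rationals;
* **run interpretation** — amplification-time calling from real-time
  fluorescence curves, anneal-derivative peak location from annealing
  sweeps, well classification, group summaries and sensitivity regressions;
* **synthetic data** — seeded generators for every input above, with known
  ground truth.

The bundled worked example is a published-style six-primer assay for the
Queensland fruit fly (*Bactrocera tryoni*) targeting the 5' COI barcode
region, including its degenerate BIP (degeneracy 8) and its
1:6:3 primer-ratio recipe.

## Worked example

Bench arithmetic for the 1:6:3 (outer : inner : loop) primer master mix —
100 µL at 10 µM outer and 100 µM inner/loop stocks, 10 µL of mix per 25 µL
reaction:

```
$ lampsmith mix
component  stock_uM  volume_uL
       F3      10.0       10.0
       B3      10.0       10.0
      FIP     100.0        6.0
      BIP     100.0        6.0
    Floop     100.0        3.0
    Bloop     100.0        3.0
    water       NaN       62.0
F3: 0.4 uM in reaction
...
FIP: 2.4 uM in reaction
...
Floop: 1.2 uM in reaction
```

Each ratio unit is 100 pmol of each primer in the slot; the mix tops up
with 62 µL of water and yields final reaction concentrations of 0.4, 2.4
and 1.2 µM for the outer, inner and loop primers.  A five-fold sensitivity
dilution series:

```
$ lampsmith dilute --start 10 --factor 5 --steps 4
     1:1  10.000 ng/uL
     1:5  2.000 ng/uL
    1:25  0.400 ng/uL
   1:125  0.080 ng/uL
   1:625  0.016 ng/uL
```

Screening the bundled primer set against synthetic templates at increasing
p-distance from the assay's consensus reproduces the expected specificity
gradient — clean targets amplify, ~2 % divergent near-neighbours still
screen positive, ~5 % divergent templates are late, distant templates are
negative:

```python
from lampsmith import datasets, synth
from lampsmith.screen import screen_panel

qff = datasets.qff_primer_set()
consensus = synth.amplicon_template(qff, seed=9)
panel = synth.make_panel(consensus, [0.0, 2.0, 5.0, 10.0], 2, seed=11)
print(screen_panel(qff, panel)[["template", "weighted_score", "class"]])
```

```
template  weighted_score    class
 div0_00             0.0 positive
 div2_00             7.0 positive
 div5_00            11.0     late
div10_00            26.0 negative
...
```

Simulated real-time runs round-trip through the caller: a noiseless well
with true amplification at 12.0 min and a true anneal peak at 82.5 °C is
called at 12.0 min / 82.5 °C and classified positive (`lampsmith simulate
run` + `lampsmith analyze-run`).

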