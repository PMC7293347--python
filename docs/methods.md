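# Methods

This note documents the models, algorithms, defaults and design choices
behind `lampsmith`, and what its synthetic-data tests do and do not show
about real data.

## Alignment profiling

Both the target set (the species complex the assay must detect) and the
non-target set (congeners it must not detect) are consumed as *pre-aligned*
FASTA in a single shared column frame; producing that joint alignment is
the user's job (any standard aligner).  Coordinates everywhere are 0-based,
half-open, in alignment-column space; `column_to_reference_map` converts to
ungapped coordinates of a designated reference record (e.g. mitogenome
positions) for reporting.

Per column we count A/C/G/T/gap (input ambiguity codes are tallied
separately and contribute their full expansion to the consensus) and emit
the *minimal* IUPAC code covering every observed canonical base; column
degeneracy is the size of that code.  All-gap columns are flagged and
conservatively profiled as `N`/4.

Region (footprint) statistics follow three conventions chosen for
primer-binding realism:

* a gap in any **target** sequence inside a span disqualifies the span from
  design — a primer cannot straddle an indel-variable site;
* a **non-target** base mismatches when it is *not contained* in the target
  consensus code at that column: degenerate positions bind all covered
  variants, so they never count as discriminating.  Non-target gaps count
  as mismatches;
* the 3'-terminal window (default 5 bases, the standard specificity
  heuristic) sits at the span end for plus-sense regions and the span start
  for minus-sense regions.  The window flag is evaluated on the non-target
  sequence achieving the minimum mismatch count (first such sequence on
  ties).

The non-target mismatch minimum is computed from a precomputed per-column
mismatch matrix with cumulative sums, so the design search pays O(n
sequences) per span; unit tests verify it against a naive double loop.

## Primer model

FIP/BIP are assembled as revcomp(anchor) + extension, with each elementary
region's sequence stored 5'→3' in its own annealing sense (F3/F2/F1/LB
plus; LF/B1/B2/B3 minus).  Degeneracy is the product of per-position IUPAC
code sizes; expansion refuses above a cap (default 4096) with guidance.
Degeneracy 1 renders as `"None"` in report tables, mirroring bench
convention, but is stored numerically.

**Melting temperature** uses the nearest-neighbour duplex model via
Biopython with the SantaLucia (2004) unified parameters and the Owczarzy
(2008) divalent-aware salt correction.  Default conditions are conventional
LAMP design conditions — 50 mM monovalent salt, 4 mM Mg²⁺, 1.4 mM dNTPs,
100 nM oligo — and both the parameter table and correction method are
fields of `TmConditions`, because published primer tables rarely state
their prediction software: reproducing someone else's printed Tm is a
calibration exercise, and this package only promises consistency within a
few degrees under standard conditions.  Degenerate primers report the
*minimum* Tm over expansions as the headline (worst-case binding governs
assay behaviour) plus the min–max range.

**Self-structure** scoring is deliberately run-length based, not a free
energy model: the longest antiparallel self-complementary run between two
copies (self-dimer), the longest intramolecular stem with loop ≥ 3
(hairpin), and a flag when a run ≥ 4 touches the 3'-terminal window.
Degenerate codes pair when *any* covered base can pair (worst case).  The
enumeration is exhaustive and deterministic, validated against independent
brute-force oracles.  A transparent integer score is easier to test and to
explain in a design report than ΔG, at the cost of ignoring stacking
energetics; users needing ΔG should re-check shortlisted candidates in a
thermodynamic folder.

## Design search

The scan mechanises the conventional manual procedure: enumerate
eight-region layouts left-to-right (F3, F2, F1, B1, B2, B3, with loop
primers fitted greedily between F2–F1 and B1–B2 when a window allows)
under geometry defaults taken from common LAMP design guidance — outer and
loop primers 18–26 nt, F2/B2 18–24, F1/B1 20–24, inter-region spacings
(0–20, 0–60, 0–100, 0–60, 0–20 columns) and an amplicon span of 120–320
columns.  All values live in `GeometryConstraints` and are
config-overridable; they are conventions, not measurements.

Spans containing target gaps or exceeding a per-primer degeneracy cap
(default 16) are pruned.  Enumeration stops deterministically at
`max_candidates` (default 500).  Candidates are then *degeneracy-applied*
(each region's sequence replaced by the degenerate consensus over its
span, strand-adjusted; over-cap candidates flagged, not dropped) and scored:

```
rank = 1.0 · (−log2 total degeneracy)
     + 1.0 · min-over-regions non-target mismatches   (capped at 4)
     − 0.5 · worst self-structure penalty             (doubled when 3'-anchored)
     − 0.2 · Tm spread across the assembled primers
```

The mismatch bonus saturates at 4 because "more than 3 bases different
from the closest non-target" is the conventional exclusivity preference —
a preference, hence a soft bonus rather than a hard filter.  Each
component is one-directional, so worsening any single criterion can never
raise the rank.  Ties break by loop-primer presence (loop primers speed
amplification, so six-primer sets are preferred at equal scores), then
leftmost F3, then smallest amplicon — the search is fully deterministic.

## Specificity screening

Each region footprint (mapped to plus-strand sense) is placed at its
minimum-mismatch ungapped offset on the template; the best F3 and B3
placements anchor a search window (±10 bases) for the interior regions.
Matching honours IUPAC containment: a degenerate primer code covering the
template base is a match, and a template `N` mismatches anything narrower
than `N`.  A region whose best placement still mismatches ≥ 50 % of its
length is "not found" and forces a negative class.

Classes are assigned from a weighted mismatch score (3'-window mismatches
weight 3, body mismatches 1, summed over all regions):

* **positive**: score ≤ T1 = 8 and no F2/B2 3'-window exceeds 2 mismatches;
* **late**: score ≤ T2 = 20 (or a low score failing only the 3' rule);
* **negative**: above T2, or any region not found.

T1/T2 were calibrated once, from expected-mismatch arithmetic over the
bundled assay's ~187 screened footprint bases (expected weighted score
≈ 5.3 / 13.4 / 26.7 at 2 / 5 / 10 % uniform divergence), so that
0–2 % divergent templates screen positive and ≥ 5 % screen late-or-negative
— the qualitative pattern real panels show, where a ~2 % divergent sister
species amplifies but a ~5 % divergent one amplifies only very late.  Real
panels do not disclose whether mismatch *count* or *position* dominates
that boundary; the 3×-weighting of 3' mismatches is a calibrated stand-in,
not an experimentally fitted kinetic model, and the classes are
categorical — no amplification *time* is predicted, since time depends on
chemistry not modelled here.

## Assay arithmetic

All volume/concentration arithmetic is exact (`fractions.Fraction`),
rendered to bench precision (1 decimal for µM, 3 for ng/µl) only on
output; a five-fold dilution of 10 ng/µl really ends at 10/625 = 0.016
exactly.  The primer-mix parameterisation fixes one ratio unit as the
amount of outer primer in `unit_volume` µL of outer stock (default: 10 µL
of 10 µM = 100 pmol), so the conventional 1:6:3 recipe at 10/100/100 µM
stocks reproduces the bench volumes (10/6/3 µL per primer, 62 µL water)
verbatim, and alternative ratios (1:8:4, 1:10:5, 1:12:6) follow from the
same operation.  Protocol duration sums holds plus |ΔT|/rate for ramps:
the crude-extraction program (65 °C 6 min, 98 °C 2 min) totals 8 min and
the amplification-plus-anneal program (65 °C 25 min, 98→73 °C at
0.05 °C/s) totals 33.3 min — instruments add overhead on top, which is
noted, not modelled.

## Run interpretation

Portable fluorometers report "time of amplification" and "anneal
derivative temperature" from unpublished algorithms, so this module defines
documented surrogates and validates them against synthetic ground truth:

* **Time calling** — Savitzky–Golay smoothing (window 9, order 2) and
  slope estimation; detection requires the smoothed plateau to exceed the
  baseline by max(100 a.u., 5 × baseline SD).  Take-off is located by
  walking back from the global slope maximum to the 20 %-of-max-slope
  crossing; the *reported* time is the quadratically refined slope-peak
  (inflection) time.  Reporting the crossing itself would be biased early
  by ≈ 2.9 × the sigmoid rise scale; the inflection is the generator's
  ground truth and is recovered to < 0.001 min on noiseless input.
* **Anneal peak** — on the temperature-ascending sweep, the maximum of
  −dS/dT after wider smoothing (window 15: derivative estimates at a
  0.2 °C grid need more support under noise), with sub-grid precision from
  a local quadratic fit.  Detection requires the annealing transition
  amplitude to clear max(100 a.u., 5 × robust residual SD); the residual
  estimate has many degrees of freedom, unlike a MAD of the heavily
  smoothed derivative, which proved unstable.
* **Classification** — negative when no call; anomalous when called but
  the anneal temperature is missing or outside the expected window
  (default 82.5 ± 1.2 °C, covering the observed positive range of the
  bundled assay and config-visible per assay); late when called at ≥ 24
  min with a good anneal; positive otherwise.  The rule is monotone in
  time.
* **Summaries and regressions** — group summaries use sample SD (n−1),
  render to one decimal and leave SD blank for single wells, matching how
  such tables are printed; regressions are ordinary least squares with
  R² = squared Pearson correlation.

Measured behaviour on the synthetic grid (times 8–29 min, peaks 78–86 °C):
noiseless calls are exact to < 0.001 min / < 0.001 °C; at Gaussian noise of
5 % of amplitude, every well in a 100-seed grid is still detected, with
worst-case errors ≈ 0.24 min and ≈ 0.6 °C.  Larger errors at the peak
location stem from derivative noise at the fine temperature grid.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`) and bit-reproducible.
Alignment defaults mirror a COI-barcoding study's scale: 658 columns, 82
target sequences, 2922 non-target sequences; tests use smaller explicit
sizes.  The substitution model is uniform-site/uniform-base with no
transition bias, rate heterogeneity, indels or phylogenetic structure —
sufficient for oracle equivalence and threshold calibration, but it means
passing tests demonstrate algorithmic correctness, *not* performance on
real sequence evolution (real near-neighbours share hotspots and codon
structure that uniform noise lacks).  Amplification curves are 4-parameter
logistics (closed-form ground truth at the inflection); melt curves are
logistic transitions in temperature; both take additive Gaussian noise.
The run generator does not model optical drift, bubbles or multi-product
melts.

The constrained design fixture carves an alignment into gap-bounded
islands sized exactly to the minimum region lengths, so exactly one layout
is feasible; two-fold polymorphic columns planted in the B1/B2 islands
make the unique candidate's BIP degenerate (R/R/Y → degeneracy 8).  This
exercises the full search path — enumeration, degeneracy application,
scoring — against a known answer.

## Known limitations

* No free-energy secondary-structure or heteroduplex model; no kinetic
  amplification model.
* Screening operates on the barcode region only; whole-genome off-target
  search is out of scope.
* The joint target/non-target alignment must be produced externally.
* Multiplex design and proprietary instrument file formats are not
  supported; runs are ingested from a documented CSV dialect
  (`well, sample, phase, x, y`).
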