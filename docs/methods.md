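# Methods

## Model and assumptions

Single-domain PL7 alginate lyases fold into a β-jelly roll with a deep
substrate-binding cleft. Substrate binding on the "+" side of the cleavage
site is conserved across the family (the interacting residues come from
three conserved sequence regions), while the "−" side is shaped by two
variable loops, loop1 and loop2. The number of sugar units the "−" section
accommodates before cleavage sets the product length, and across the
family this reduces to the length of loop1: 12 residues or more predicts
di-/trisaccharide-predominant products (`SMALL_OLIGO`), 11 or fewer
predicts Dp ≥ 4 products (`LARGE_OLIGO`). The package treats this rule as
given and concentrates on computing loop1/loop2 reliably from sequence.

Assumptions inherited by every prediction:

* the query is a **single-domain, endolytic** PL7 lyase — hence the
  pre-screens (length, AlyA5 similarity) rather than post-hoc checks;
* the secondary-structure string, when supplied, is accurate enough that
  strand runs flanking the loops are present (noisy single-residue strand
  calls are suppressed, see below);
* loop identity is purely topological: no structural superposition is
  attempted, and the di- vs trisaccharide split inside `SMALL_OLIGO` is
  deliberately not predicted (the underlying rule stops at the class
  level).

## Loop location

1. **Anchor.** The QI(V)H region (pattern `Q[IV]H`) is located by
   degenerate scanning. `X` in a query matches only wildcard pattern
   positions, never fixed letters, so unknown residues cannot create an
   anchor. With several QI(V)H matches, candidates are filtered by region
   order (a RxEL(V)R match must precede, a YFKxGxYxQ match follow, when
   those regions matched anywhere); remaining ties go to alignment — the
   anchor position of the best-aligned reference template is projected
   onto the query and the nearest candidate wins — or, with no templates,
   to the most N-terminal candidate. The ambiguity is flagged either way.
2. **Segmentation.** The SS string is cut into maximal runs; strand runs
   shorter than `min_strand_len` (default 2) are relabelled coil. Helix
   runs survive segmentation — they are only lumped with coil during loop
   extraction, so a helix inside a loop lengthens the loop (required for
   loops with small helical insertions, such as AlyV's 18- and 28-residue
   loops).
3. **Topology walk.** The center strand is the E segment containing the
   anchor's His (majority-overlap rule if the anchor straddles segments).
   loop1 = the contiguous non-strand run abutting the center strand's
   N-terminal end (truncation at position 1 is flagged, not rejected);
   loop2 = the third non-strand run after the C-terminal end, i.e. after
   skipping loop-strand-loop-strand. Fewer than two strands after the
   center strand is a hard failure.
4. **Fallback.** With no SS, or when SS and motif disagree (no center
   strand), the loop spans of the best-aligned template (by global
   percent identity) are projected through the alignment column map;
   endpoints on gap columns snap inward. Results carry a
   `projected-from:<id>` flag so downstream users can tell the two
   strategies apart. The fallback is a package addition for offline
   operation; the original procedure always had predicted SS available.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `length_threshold` | 400 residues | multi-domain screen; 400 itself passes (the stated threshold is read as inclusive) |
| `exolytic_identity_threshold` | 40 % | global identity to AlyA5 at or above which a sequence is flagged exolytic-like; unstated in the source procedure, so it is conservative, configurable and always reported |
| `min_strand_len` | 2 residues | strand runs shorter than this are relabelled coil before the topology walk |
| scoring | BLOSUM62, gap open −10 / extend −1 | conventional protein-alignment defaults; the first gap residue costs the open score, each further residue the extend score |
| `LOOP1_CLASS_BOUNDARY` | 12 | loop1 length at which the class switches to `SMALL_OLIGO` |

Percent identity = identical aligned pairs ÷ all alignment columns × 100
(global alignment, so single-gap columns count in the denominator). This
convention is stated because published identity figures are
method-dependent; none of them is treated as reproducible here.

## Reference data

The eight structure-solved reference enzymes ship with their loop
sequences; AlyV and PyAly additionally carry boundary coordinates
(loop1 117–134 / 183–210 and 108–117 / 159–170 respectively), which pin
their loop1/loop2 split exactly. For the other six entries only the
concatenated loop text was available during transcription; their split is
a plausible reading consistent with the observed product groups and is
flagged `split_verified = no` in the bundled TSV. A user-supplied
reference file can override the bundled one.

The full-length natural sequences of the reference enzymes (and of AlyA5,
needed by the exolytic screen) are not redistributed. The package instead
provides *stand-ins*: synthetic scaffolds that reproduce every published
residue-numbered fact the pipeline consumes — loop spans and sequences,
anchor positions (PyAly Gln123/His125, AlyV Gln139/His141), conserved
regions in order — with filler drawn from an alphabet that cannot complete
any conserved-region pattern. When AlyA5 is absent the exolytic screen is
skipped with a warning rather than failing the pipeline.

## Synthetic generator

`generate()` emits, N→C: flank — scaffold strands — a strand carrying
RxEL(V)R — loop1 of the requested length — a center strand containing
QI(V)H — loop, strand, loop, strand — loop2 of the requested length — a
strand carrying YFKxGxYxQ — flank, together with matching SS labels and
truth annotations. Filler residues come from `ACDEFGKLMNPSTW`
(no H/I/Q/R/V/Y), so decoy-free outputs contain exactly one QI(V)H match —
asserted at generation time. Optional decoy QIH copies are planted in the
N-terminal flank (before the RxEL(V)R region, so region-order filtering
must resolve them), and a total-length target pads the C-terminal flank to
exercise the length screen. Panels draw loop1 lengths uniformly from 4–15,
the range observed across the single-domain PL7 database.

What the generator does **not** emulate: real amino-acid composition,
homology between records, SS-prediction noise, and strand-count variation
of real jelly rolls. A green synthetic round trip therefore establishes
that the topology walk is implemented correctly, not that JPred-predicted
SS on natural sequences will always present the expected strand pattern;
flagged failures on real inputs fall back to projection or surface as
errors by design.

## Numerical and edge-case choices

* Residue coordinates are 1-based inclusive everywhere; conversion happens
  only at file and slicing boundaries.
* Main-product ties in a distribution break toward smaller Dp with an
  explicit `tied` flag (observed data never ties; the rule is for
  completeness).
* Disaccharide-predominant distributions group with
  trisaccharide-predominant ones (`TRI_DI_PREDOMINANT`), matching the
  unified long-loop1 prediction.
* Distribution percents must sum to 100 ± 0.5 (rounding slack for printed
  tables); normalization from raw areas is exact.
* Chimera construction replaces loop1 first, re-derives loop2 coordinates
  from the length shift, then replaces loop2 — a fixed order that avoids
  span-shift bugs. Swaps are positional; no register realignment.
* Batch runs never abort on a bad record: screening failures and
  annotation errors become row statuses.

## Known limitations

* The loop1/loop2 split of six reference entries is transcribed from
  flattened table text and marked unverified (see above).
* The anchor-disambiguation alignment partners are a reasoned choice (the
  bundled templates); the original procedure does not name its alignment
  set.
* Predictions are class-level only; absolute product percentages and
  polyM/polyG substrate preference are out of scope.
* Accession-level validation (recomputing loop1 lengths for the
  characterized GenBank accessions) needs the fetched records and a
  secondary-structure prediction; offline, the corresponding test states
  exactly what to provide and fails until it is provided.
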