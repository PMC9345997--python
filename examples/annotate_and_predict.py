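"""Annotate loop1/loop2 on a sequence and predict its product class.

Uses the bundled PyAly-like and AlyV-like stand-ins (synthetic sequences
carrying the published loop spans and catalytic anchors) with their
crystal-consistent secondary structure.  The printed spans are 1-based
inclusive residue coordinates; the class states whether the enzyme is
expected to release di/trisaccharides (SMALL_OLIGO, loop1 >= 12) or larger
oligomers (LARGE_OLIGO, loop1 <= 11).
"""

from pl7loop import alyv_standin, predict, pyaly_standin

for standin in (pyaly_standin(), alyv_standin()):
    pred = predict(standin.record, ss=standin.ss)
    ann = pred.annotation
    print(f"{standin.record.id} ({len(standin.record)} aa)")
    print(f"  loop1 {ann.loop1_span[0]}-{ann.loop1_span[1]}: {ann.loop1_seq}")
    print(f"  loop2 {ann.loop2_span[0]}-{ann.loop2_span[1]}: {ann.loop2_seq}")
    print(f"  {pred.rationale}")
    # A short loop1 cannot reach the -2 sugar-binding subsite, so cleavage
    # tends to leave longer products; a long loop1 closes the cleft earlier.
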