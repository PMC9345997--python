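"""Generate a ground-truth synthetic panel and verify the round trip.

Every generated record carries a full scaffold (three conserved regions in
order, strand/loop topology) plus matching secondary structure and truth
loop spans; annotating it back must recover the truth exactly.  This is
the self-check that makes every other pipeline stage testable offline.
"""

from pl7loop import annotate_loops, generate_panel, write_loop_table
from pl7loop.synthetic import truth_table_rows

panel = generate_panel(25, seed=42)
recovered = 0
for item in panel:
    ann = annotate_loops(item.record, ss=item.ss)
    ok = ann.loop1_span == item.loops.loop1_span and ann.loop2_span == item.loops.loop2_span
    recovered += ok

write_loop_table(truth_table_rows(panel), "truth_table.tsv")
print(f"panel of {len(panel)} records, loop1 lengths 4..15 (seed 42)")
print(f"annotation recovered truth spans in {recovered}/{len(panel)} records")
print("wrote truth_table.tsv (generator ground truth per record)")
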