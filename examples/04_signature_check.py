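"""Check the helix-27 diagnostic base pair across alignment rows.

Andalucina SSU rRNA carries a C:G pair in the basal stem of helix 27 where
other jakobids show A:T.  The two stem columns are configuration (taken
from a secondary-structure annotation of the alignment), and the check is
a strict paired-column read-out.
"""

from stygdiv import AlignedSeq, call_signature

# toy alignment: columns 3 and 8 form the diagnostic pair
rows = [
    AlignedSeq("andalucina_like_1", "GGCTTAAGCC"),
    AlignedSeq("andalucina_like_2", "TACTGTGGAA"),
    AlignedSeq("other_jakobid", "GGATTAATCC"),
    AlignedSeq("partial_clone", "GG-TTAAGCC"),
]

for row in rows:
    call = call_signature(row, (3, 8))
    print(f"{row.id:<20} columns {call.columns}: {call.call}")

# CG supports membership in Andalucina, AT is the state of the remaining
# jakobids, and 'other' (gap/ambiguity/any different pair, including the
# reversed orientation G:C) means the site is uninformative for that row.
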