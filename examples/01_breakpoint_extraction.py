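"""Extract CNA-associated breakpoints from a hand-built segmented profile.

A breakpoint is the start of a new copy-number segment; the first segment
of a chromosome and transitions between two neutral segments are excluded.
"""

import pandas as pd

from breakgene.breakpoints import derive_breakpoints
from breakgene.profiles_io import ProbeMap, Segment, SegmentedProfile

# 40 probes on one chromosome at 17 kb spacing
probe_map = ProbeMap(pd.DataFrame({
    "probe_id": [f"p{i}" for i in range(40)],
    "chromosome": ["1"] * 40,
    "position": [(i + 1) * 17_000 for i in range(40)],
}))

# neutral -> gain -> neutral -> neutral(re-segmented) profile
profile = SegmentedProfile("tumor_01", {"1": [
    Segment(0, 9, 0.01, 0),      # neutral
    Segment(10, 24, 0.58, 1),    # single-copy gain
    Segment(25, 31, -0.02, 0),   # back to neutral
    Segment(32, 39, 0.04, 0),    # neutral again: boundary 31|32 is NOT a breakpoint
]})

for b in derive_breakpoints(profile, probe_map):
    print(f"breakpoint between probes {b.left_probe}|{b.right_probe} "
          f"(calls {b.left_call}->{b.right_call}), "
          f"localized to ({b.interval[0]:,}, {b.interval[1]:,}] bp")

# Two breakpoints are reported (9|10 and 24|25): the gain's start and end.
# The neutral-neutral boundary at 31|32 is suppressed, and the chromosome
# start never counts. Each breakpoint is only localized to the ~17 kb gap
# between its flanking probes.
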