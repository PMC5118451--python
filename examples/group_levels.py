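"""Where in a group's hierarchy does outcome-relevant dynamics live?

Simulates a study of 25 three-member teams whose shared physiological
coupling varies between teams and drives a per-team outcome.  The
multi-level scheme analyses each team at the individual level (average
classical RQA over the three members), the dyad level (average over the
three pairs) and the full group level, then regresses the outcome on the
four measures at each level.
"""

import mdrqa as M
from mdrqa.simulators import gen_team_study

teams, outcome = gen_team_study(25, seed=1, design="group")
spec = M.EmbeddingSpec(m=2, tau=6, zscore=True)  # 3 channels embedded once: D = 6
table = M.level_sweep(teams, outcome, spec, T=0.12, mode="meanfrac")

print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\nThe outcome was constructed to depend on the team's shared coupling:\n"
    "the individual level (1) explains almost nothing, while multi-member\n"
    "levels recover the association (single seed; averages over seeds favour\n"
    "the full group level for outcomes driven by whole-group dynamics)."
)
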