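"""Recurrence analysis of the Lorenz system, channel by channel and jointly.

Integrates the chaotic Lorenz system, reconstructs its attractor from
each single channel by time-delay embedding (D=3, tau=4) and compares the
four recurrence measures with the multidimensional analysis that uses all
three measured channels directly as phase-space coordinates, plus the
joint plot that keeps only coincident recurrences of the three
single-channel plots.
"""

import mdrqa as M

ts = M.simulate_lorenz(M.LorenzParams(), zscore=True)
print(f"Lorenz trajectory: {ts.n_samples} samples x {ts.n_channels} channels\n")

print(f"{'analysis':<10}{'RR %':>8}{'DET %':>8}{'ADL':>8}{'LDL':>6}")
spaces = {}
for name in ts.channels:
    spaces[name] = M.delay_embed(ts.channel(name), D=3, tau=4, name=name)
    R = M.recurrence_plot(spaces[name], T=0.1, mode="absolute", theiler=1)
    r = M.rqa_measures(R)
    print(f"RQA({name})    {r.rr_pct:>8.2f}{r.det_pct:>8.1f}{r.adl:>8.2f}{r.ldl:>6d}")

md = M.mdrp(ts, M.EmbeddingSpec(m=1, zscore=False), T=0.08, mode="meanfrac", theiler=1)
r_md = M.rqa_measures(md)
print(f"{'MdRQA':<10}{r_md.rr_pct:>8.2f}{r_md.det_pct:>8.1f}{r_md.adl:>8.2f}{r_md.ldl:>6d}")

joint = M.joint_recurrence_plot(list(spaces.values()), T=0.1, mode="absolute", theiler=1)
r_j = M.rqa_measures(joint)
print(f"{'JRQA':<10}{r_j.rr_pct:>8.2f}{r_j.det_pct:>8.1f}{r_j.adl:>8.2f}{r_j.ldl:>6d}")

print(
    f"\nThe multidimensional plot sees the true attractor: its diagonal lines"
    f"\n(ADL {r_md.adl:.1f}) outlast every single-channel reconstruction, and its"
    f"\nrecurrence rate is ~{r_md.rr / r_j.rr:.1f}x the joint plot's, which keeps only cells"
    f"\nrecurrent in all three channel plots simultaneously."
)
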