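"""Does recurrence analysis see the coupling between two oscillators?

Two van der Pol relaxation oscillators (mu=100) are coupled
asymmetrically (eps2 = 5*eps1).  For a sweep of coupling strengths the
script compares how the recurrence rate of the cross-recurrence plot
(two separately embedded trajectories) and of the multidimensional plot
(both channels as one phase space) tracks the coupling.
"""

import numpy as np

import mdrqa as M

eps_grid = np.logspace(np.log10(0.005), np.log10(0.05), 6)
rr_md, rr_cr = [], []
print(f"{'eps1':>8}{'RR MdRQA %':>12}{'RR CRQA %':>12}")
for eps1 in eps_grid:
    ts = M.simulate_vdp_pair(M.VdpParams(eps1=float(eps1)), zscore=True)
    R = M.mdrp(ts, M.EmbeddingSpec(m=1, zscore=False), T=0.01, mode="meanfrac")
    Px = M.delay_embed(ts.channel("x"), 2, 1, "x")
    Py = M.delay_embed(ts.channel("y"), 2, 1, "y")
    C = M.cross_recurrence_plot(Px, Py, T=0.01, mode="meanfrac")
    rr_md.append(M.rqa_measures(R).rr_pct)
    rr_cr.append(M.rqa_measures(C).rr_pct)
    print(f"{eps1:>8.4f}{rr_md[-1]:>12.3f}{rr_cr[-1]:>12.3f}")

c_md = np.corrcoef(eps_grid, rr_md)[0, 1]
c_cr = np.corrcoef(eps_grid, rr_cr)[0, 1]
print(f"\ncorr(eps1, RR): MdRQA {c_md:+.2f} vs CRQA {c_cr:+.2f}")
print(
    "The multidimensional recurrence rate rises almost monotonically with\n"
    "coupling strength; the cross-recurrence rate barely moves because both\n"
    "oscillators are individually periodic whether or not they are coupled."
)
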