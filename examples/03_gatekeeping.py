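"""Walk the serial gatekeeping procedure on three primary p-values.

Each primary comparison (iron vs placebo, MNPs vs placebo) is tested at
2.5% two-sided; the head-to-head test runs only if a gate opens — at
2.5% after one rejection, 5% after two — and is otherwise reported as an
estimate with a 95% CI and no p-value.
"""
from triarm.multiplicity import gatekeeper_primary, hochberg_family

for ps in ((0.004, 0.018, 0.030), (0.004, 0.200, 0.030),
           (0.060, 0.200, 0.001)):
    out = gatekeeper_primary(*ps)
    print(f"p-values {ps}:")
    for label, d in out.decisions.items():
        alpha = "untested" if d.assigned_alpha is None \
            else f"alpha={d.assigned_alpha:g}"
        padj = "suppressed" if d.p_adjusted is None else f"{d.p_adjusted:.3f}"
        print(f"  {label:16s} {alpha:12s} rejected={d.rejected!s:5s} "
              f"adjusted p={padj}  CI level={d.ci_level:.1%}")
    print()

rej, adj = hochberg_family([0.030, 0.008, 0.041, 0.012], family_alpha=0.025)
print("Hochberg family at 2.5% (key secondary endpoints):")
print("  rejected:", rej)
print("  adjusted p:", [round(a, 3) for a in adj])
# With both primaries rejected the head-to-head alpha doubles to 5%;
# with none rejected its p-value is suppressed entirely.
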