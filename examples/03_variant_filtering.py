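"""Consensus filtering of two variant callers' exome calls.

Takes the records two callers agree on, then keeps variants with depth
> 20x, alt fraction > 0.25, a missense consequence and strand bias < 0.05 —
the set suitable for discriminating cell-line subclones.
"""

from clonelines import VariantRecord, apply_filters, intersect_callers


def rec(pos, caller, depth=120, af=0.48, csq="missense_variant", sbp=0.01):
    return VariantRecord("7", pos, "G", "A", depth=depth, alt_fraction=af,
                         consequence=csq, strand_bias_p=sbp, caller=caller)


caller_a = [rec(101, "gatk"), rec(205, "gatk", depth=18),
            rec(310, "gatk", csq="synonymous_variant"),
            rec(442, "gatk", af=0.08), rec(519, "gatk")]
caller_b = [rec(101, "varscan"), rec(205, "varscan"), rec(310, "varscan"),
            rec(442, "varscan"), rec(630, "varscan")]

consensus, diff = intersect_callers(caller_a, caller_b)
kept, attrition = apply_filters(consensus)

print(f"caller A / B calls : {len(caller_a)} / {len(caller_b)}")
print(f"consensus          : {len(consensus)} "
      f"(A-only {len(diff['only_a'])}, B-only {len(diff['only_b'])})")
for crit in ("depth", "alt_fraction", "consequence", "strand_bias"):
    print(f"  fail {crit:<12}: {attrition['fail_' + crit]}")
print(f"kept               : {attrition['kept']} -> "
      f"{[r.pos for r in kept]}")
# Only variants both callers report and that pass all four strict filters
# remain; the attrition counts show which criterion removed what.
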