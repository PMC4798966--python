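"""Price decomposition of a two-group cooperator/cheater community.

Two six-member groups, one seeded with 1 cooperator and one with 5,
reproduce under the rule "each cooperator sires one cooperator and helps
every other member sire one extra offspring; each cheater sires two".
The decomposition shows how a positive between-group covariance can
outweigh the within-group decline of cooperators.
"""

from mlsel import GroupComposition, GroupRecord, price_decompose, reproduce_group

offspring = {c: reproduce_group(GroupComposition(c, 6 - c)) for c in (1, 5)}
for c, off in offspring.items():
    print(f"group starting with {c}/6 cooperators -> size {off.size}, "
          f"{off.cooperators} cooperators (frequency {float(off.cooperator_freq):.4f})")

records = [GroupRecord(6, c, off.size, off.cooperators) for c, off in offspring.items()]
dec = price_decompose(records, exact=True)
print(f"\nmean final group size   pibar   = {float(dec.mean_final_size):g}")
print(f"community freq change   dPbar   = {float(dec.delta_p):.4f}")
print(f"between-group term      Cov     = {float(dec.covariance_term):.4f}")
print(f"within-group term       Ave     = {float(dec.expectation_term):.4f}")
print(f"identity residual               = {float(dec.residual()):g}")
print("\nCov + Ave = pibar * dPbar: cooperation spreads globally (dPbar > 0)")
print("even though cooperator frequency fell inside both groups, because the")
print("covariance between group productivity and cooperator frequency wins.")
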