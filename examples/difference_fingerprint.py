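"""Compute a reaction difference fingerprint for a hand-checkable reaction.

Urea-1-carboxylate + H2O <=> 2 CO2 + 2 NH3 (KEGG R00005) is small enough to
enumerate by hand: at path length 1 the difference fingerprint keeps only
the three bond types whose counts change, and every single-atom term cancels
because the equation is elementally balanced.
"""
from rxndiff import reaction_difference_fingerprint
from rxndiff.worked_examples import R00005, compound_graphs

compounds = compound_graphs()
rfp = reaction_difference_fingerprint(R00005, compounds, max_len=1)

print(f"reaction : {R00005.equation}")
print(f"max_len  : {rfp.max_len}")
for fragment in sorted(rfp.entries):
    print(f"  {fragment:6s} {rfp.entries[fragment]:+d}")
print(f"norm     : {rfp.norm():.4f}")
print()
print("Three C-N bonds and one C-O bond are consumed and two C=O bonds are")
print("formed per turnover; that signed bond-pattern change is what the")
print("classifier compares between reactions.")
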