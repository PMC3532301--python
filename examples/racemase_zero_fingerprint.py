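"""Why racemases must be excluded before nearest-neighbour assignment.

L-glutamate <=> D-glutamate (KEGG R00260) only inverts a stereocentre.
Linear fragments ignore stereochemistry, so the reactant and product
fingerprints are identical and the difference fingerprint is empty — the
reaction carries no signal the classifier could use.  The dataset filter
records this as exclusion category 6.
"""
from rxndiff import filter_dataset, reaction_difference_fingerprint
from rxndiff.worked_examples import R00260, compound_graphs

compounds = compound_graphs()
rfp = reaction_difference_fingerprint(R00260, compounds, max_len=3)

print(f"reaction    : {R00260.equation}")
print(f"entries     : {dict(rfp.entries)}")
print(f"norm        : {rfp.norm()}")

report = filter_dataset([R00260], compounds, max_len=3)
disposition = report.dispositions[0]
print(f"filter      : category {disposition.category} ({disposition.message})")
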