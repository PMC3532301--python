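"""Assign an EC number to an uncharacterised reaction.

The N-methylation of L-tryptophan by S-adenosyl-L-methionine (KEGG R00683,
annotated 'enzyme not yet characterized') is compared against labelled
training reactions.  Its closest neighbour is the serotonin N-methylation
R02910 (EC 2.1.1) at Euclidean distance 2 on the directed path-counting
scale, so the query inherits EC 2.1.1 — transferases, one-carbon groups,
methyltransferases.
"""
from rxndiff import assign_ec, prepare_training
from rxndiff.worked_examples import R00005, R00683, R02910, compound_graphs

compounds = compound_graphs()
training = prepare_training([R02910, R00005], compounds, max_len=3,
                            directed=True)

result = assign_ec(R00683, training, compounds=compounds, max_len=3,
                   directed=True)

print(f"query        : {R00683.equation}")
print(f"assigned EC  : {result.ec}")
print(f"min distance : {result.min_distance:g}")
print(f"supported by : {', '.join(result.supporting_ids)}")
print(f"tie broken   : {result.tie_broken}")
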