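"""Assign homology identities to one side's ocelli.

A buthid-style side: a row of three large, similar ocelli plus two
smaller dorsal satellites.  The labeler splits size tiers at the first
large diameter gap, reads the major row front to back, and places the
minors by 45-degree sector around the posterolateral major (PLMa).
"""

from sixocellus import OcellusObservation, SideRecord, label_side, pattern_of

side = SideRecord(
    side="sinistral",
    observations=[
        OcellusObservation(ap=0.20, dv=0.00, diameter=0.90),  # anterior major
        OcellusObservation(ap=0.38, dv=0.00, diameter=1.00),  # largest, mid row
        OcellusObservation(ap=0.56, dv=0.00, diameter=0.92),  # posterior major
        OcellusObservation(ap=0.48, dv=0.08, diameter=0.40),  # small, anterodorsal
        OcellusObservation(ap=0.64, dv=0.08, diameter=0.50),  # small, posterodorsal
    ],
)

labeled = label_side(side)
for k, obs in enumerate(labeled.observations):
    ident = labeled.identity_of(k)
    conf = labeled.confidence.get(k, "unassigned")
    print(f"obs {k}: ap={obs.ap:.2f} dv={obs.dv:+.2f} d={obs.diameter:.2f} -> {ident.value} ({conf})")

call = pattern_of(labeled.identity_set)
print(f"pattern: {call.name.value} with {call.count} ocelli")
# The five ocelli resolve to ALMa, MLMa, PLMa + ADMi, PDMi: the Type 5
# pattern (PLMi absent), the commonest buthid condition.
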