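"""Classify identity sets and walk the loss lattice.

Every subset of the ten identities maps to exactly one outcome: one of
the eleven defined patterns (six-ocellus root, nine named reductions,
eyeless) or ABNORMAL.  The lattice lists which single/multi-ocellus
losses derive each named pattern from another.
"""

from sixocellus import OcellusIdentity as I
from sixocellus import catalog_size, is_reduction, lattice, pattern_of
from sixocellus.patterns import PatternName

for identities in (
    {I.ALMA, I.MLMA, I.PLMA, I.ADMI, I.PDMI},
    {I.MLMA, I.PLMA, I.PDMI},
    {I.PLMA},
    set(),
    {I.MLMA, I.PLMA, I.PLMI},  # no named pattern has PLMi without PDMi
):
    call = pattern_of(identities)
    names = ", ".join(sorted(i.value for i in identities)) or "(none)"
    print(f"{{{names}}} -> {call.name.value}")

print(f"\n{catalog_size()} named general patterns; lattice edges:")
for edge in lattice():
    lost = ", ".join(sorted(i.value for i in edge.lost))
    print(f"  {edge.parent.value} -> {edge.child.value}  (loss of {lost})")

print("\nT1 is a reduction of T2B:", is_reduction(PatternName.T1, PatternName.T2B))
# Reduction = member-set inclusion, consistent with lattice reachability.
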