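"""Assign the ansamer descriptor to a bridged macrolactam and its mirror image.

Builds an amatoxin-like synthetic bicycle (8-residue macrolactam, CB-SG-CB
bridge between residues 4 and 8, bridge apex above the ring plane), assigns
P_ansa/M_ansa, and shows that reflecting the molecule flips the call.
"""

from ansamer.descriptor import assign_ansamer
from ansamer.synth_fixtures import make_amatoxin_like, mirror

system = make_amatoxin_like(bridge_height=3.0)
result = assign_ansamer(system)
print(f"descriptor          : {result.descriptor}")
print(f"bridgehead alpha    : atom {result.alpha} "
      f"({system.names[result.alpha]} of residue {system.resids[result.alpha]})")
print(f"leading atom L      : atom {result.leading} "
      f"({system.names[result.leading]} of residue {system.resids[result.leading]})")
print(f"side sign / proj (A): {result.side:+d} / {result.projection:.3f}")

reflected = assign_ansamer(mirror(system))
print(f"mirror image        : {reflected.descriptor}")

# The side sign says which face of the N->C-oriented ring plane carries the
# bridge; +1 (counter-clockwise seen from L) maps to M_ansa, -1 to P_ansa.
# Mirroring a molecule must always flip the descriptor - the enantiomer law.
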