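"""Hydrogen bonds, amide exposure, dihedrals and RMSF of a small ensemble.

Runs the combined conformational analyses on a 20-frame noisy ensemble of a
synthetic bicycle and prints the filtered H-bond populations, the per-residue
amide SASA classes, one residue's backbone dihedrals and the mean RMSF.
"""

import numpy as np

from ansamer.ensemble_analysis import (
    amide_sasa,
    backbone_dihedrals,
    hbond_populations,
    rmsf,
)
from ansamer.synth_fixtures import FixtureSpec, make_ensemble

ensemble = make_ensemble(
    FixtureSpec(n_residues=6, bridge_span=(2, 5)), n_frames=20, noise=0.08, seed=3
)

hbonds = hbond_populations(ensemble)  # strict >10% population filter
print(f"H-bonds with population > 10%: {len(hbonds)}")
for record in hbonds:
    print(f"  donor {record.donor} -> acceptor {record.acceptor}: "
          f"population {record.population:.2f}")

exposures = amide_sasa(ensemble, n_sphere_points=240)
for e in exposures[:3]:
    print(f"residue {e.residue}: amide SASA {e.mean_sasa_nm2:.3f} nm^2 "
          f"-> {e.exposure_class}")

dihedrals = backbone_dihedrals(ensemble.system, model=0)
d = dihedrals[0]
print(f"residue {d.residue}: phi={d.phi:7.1f} psi={d.psi:7.1f} "
      f"omega={d.omega:7.1f} ({d.omega_class})")

values = rmsf(ensemble)
print(f"mean RMSF over {ensemble.n_frames} frames: {np.mean(values):.3f} A")

# The fixtures carry no amide hydrogens or carbonyl contacts engineered for
# bonding, so the H-bond list is typically empty here; the bare ring
# nitrogens classify as exposed (>0.04 nm^2).  The RMSF reflects the 0.08 A
# Gaussian jitter (about 0.08*sqrt(3) ~ 0.14 A) after removing the random
# rigid motion of each frame by superposition.
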