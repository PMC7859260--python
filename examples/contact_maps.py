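"""Residue contact matrices of a planted dimer at paired cut-offs.

Builds a small synthetic bundle holding one C2 dimer, accumulates the
inter-helix BB-bead contact matrix at 0.5 and 0.8 nm, and normalises each
to its most frequent contact.  The 0.8 nm support always contains the
0.5 nm support: both cut-offs describe the same interface, the looser one
with more flanking residues.
"""

import numpy as np

from helixpack import contact_matrix, cutoff_sweep, normalize
from helixpack.synthetic import SyntheticSpec, generate_trajectory, plan_assemblies

assemblies = plan_assemblies(n_c2=1, n_helices=16, pair_distance=0.95)
traj, _ = generate_trajectory(
    SyntheticSpec(n_helices=16, n_residues=24, assemblies=assemblies,
                  jitter_sigma=0.02, n_frames=20, dt=100.0, seed=11)
)

for cutoff in (0.5, 0.8):
    m = normalize(contact_matrix(traj, cutoff))
    i, j = np.unravel_index(np.argmax(m.counts), m.counts.shape)
    print(f"cutoff {cutoff} nm: {m.n_nonzero_pairs} residue pairs in contact, "
          f"strongest at residues ({i + 1}, {j + 1}) "
          f"(normalised weight {m.counts[i, j]:.2f})")

print("\ncut-off sweep (totals must be monotone; 0.4 nm sees nothing at CG "
      "bead spacing):")
print(cutoff_sweep(traj, [0.4, 0.5, 0.8, 1.0]).to_string(index=False))
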