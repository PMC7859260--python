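"""Radial density map of neighbour helices in the body-fixed frame.

Generates a 36-helix patch with planted C2 dimers and a C3 trimer, then
accumulates every neighbour centroid in every reference helix's body frame
(origin = centroid of the reference residues, X = orientation bisector).
Planted partners pile up into first-orbit spots; the empty grid background
sits on the ~4.2 nm second orbit.
"""

import numpy as np

from helixpack import density_map, radial_cloud
from helixpack.synthetic import SyntheticSpec, generate_trajectory, plan_assemblies

assemblies = plan_assemblies(n_c2=2, n_c3=1, n_helices=36)
traj, _ = generate_trajectory(
    SyntheticSpec(n_helices=36, n_residues=30, assemblies=assemblies,
                  jitter_sigma=0.04, orientation_noise=8.0,
                  n_frames=30, dt=100.0, seed=4)
)

cloud = radial_cloud(traj, center_residue=15, stride_ns=100.0)
print(f"radial cloud: {len(cloud)} points "
      f"({cloud.n_skipped} skipped for degenerate orientation)")
first_orbit = cloud.radius < 1.5
print(f"first-orbit points (< 1.5 nm): {first_orbit.sum()} "
      f"— these are the planted dimer/trimer partners")

dmap = density_map(cloud, bandwidth=0.1, grid_step=0.05, extent=3.0)
px, py = dmap.peak_xy
print(f"density peak at ({px:.2f}, {py:.2f}) nm, "
      f"radius {np.hypot(px, py):.2f} nm "
      f"(the most persistent partner position)")
print(f"grid integrates to {dmap.total_mass:.0f} ~ point count within the "
      f"+/-3 nm window")
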