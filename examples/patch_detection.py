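"""Detect hydrophobic patches on a tiny synthetic structure.

Builds a five-residue pseudo-chain (pattern H P H P H, 3 A spacing), runs
the surface sampler and the patch finder, and prints each patch with its
area.  Because the hydrophobic residues are separated by hydrophilic ones
but the clouds still touch at this spacing or not depending on geometry,
the patch count shows how surface adjacency - not sequence adjacency -
defines a patch.
"""

from molpatch.fixtures import FixtureSpec, make_structure
from molpatch.measures import measures_from_structure
from molpatch.patch_finder import find_patches
from molpatch.surface import SurfaceParams, compute_point_cloud

params = SurfaceParams()  # probe 1.5 A, density 1.5 pts/A^2, cutoff 1.25 A
model = make_structure(
    FixtureSpec(kind="pseudo_chain", n_residues=5, hydrophobic_pattern="HPHPH", spacing=3.0)
)

cloud = compute_point_cloud(model, params)
patches = find_patches(cloud, params)
measures = measures_from_structure(model, params)

print(f"surface points: {cloud.n_points}, total area {cloud.total_area:.1f} A^2")
print(f"TASA {measures.tasa:.1f}  THSA {measures.thsa:.1f}  "
      f"RHSA {measures.rhsa_percent:.1f}%  LHP {measures.lhp:.1f} (A^2 / %)")
for p in patches.patches:
    print(f"  patch rank {p.rank}: {p.area:.1f} A^2 over residues {sorted(p.residues)}")
print("The rank-1 area is the LHP; patch areas always sum to the THSA.")
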