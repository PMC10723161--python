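"""Three-group voxelwise ANCOVA with GRF cluster correction.

Simulates a 15/15/15 AD/aMCI/NC cohort whose DMN target-region static
coupling differs by group, computes per-subject smoothed static z-maps,
runs the voxelwise group F test adjusting for age, sex, education and head
movement, applies Gaussian-random-field cluster correction (voxel p<0.001,
cluster p<0.05) and reports surviving clusters with Bonferroni post hoc
pairwise tests.
"""
import numpy as np

import seedfc as s
from seedfc.pipeline import RunConfig, compute_subject_maps, group_cluster_analysis
from seedfc.rft import extract_cluster_values, posthoc_pairwise

scene = s.default_scene(("DMN",), rng_seed=21)
config = RunConfig(scene=scene, out_dir="/tmp/unused", n_per_group=(15, 15, 15))
table = s.generate_participants((15, 15, 15), rng_seed=21)
subj = compute_subject_maps(table, scene, config, kinds=("static",))

clusters, res = group_cluster_analysis(
    subj.static["DMN"], subj.table, subj.masks["gm"], scene.affine, network="DMN"
)
print(f"ANCOVA: F({res.df1}, {res.df2}) per voxel over "
      f"{subj.masks['gm'].sum()} gray-matter voxels")
print(f"surviving clusters (voxel p<0.001, cluster p<0.05): {len(clusters)}")
for c in clusters:
    print(f"  cluster {c.cluster_id}: {c.n_voxels} voxels, "
          f"peak MNI {tuple(round(v) for v in c.peak_mni)}, "
          f"peak F {c.peak_stat:.2f}, corrected p {c.cluster_p:.4f}")

vals = extract_cluster_values(subj.static["DMN"], clusters[0])
groups = subj.table["group"].to_numpy()
print("\ncluster-mean static z by group:")
for g in s.GROUPS:
    print(f"  {g:5s} {vals[groups == g].mean():+.3f}")
print("\npost hoc Welch t-tests (Bonferroni x3):")
for cmp_ in posthoc_pairwise(vals, groups):
    print(f"  {cmp_.pair[0]:>5s} vs {cmp_.pair[1]:<5s} t={cmp_.t_stat:+6.2f} "
          f"adjusted p={cmp_.p_adjusted:.2e} {cmp_.significance}")
# The surviving cluster sits on the planted target region; the group means
# mirror the simulated coupling ladder (NC > aMCI > AD), the pattern the
# analysis is designed to detect in patient data.
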