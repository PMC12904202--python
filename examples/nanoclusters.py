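"""Active-zone nanocluster statistics on synthetic localization data.

Generates two-channel 3D localization clouds (release-site clusters
displaced 100-300 nm from scaffold clusters), runs DBSCAN, measures
radii of gyration and cross-channel distances, and computes the
pixel-based hotspot enrichment of a synthetic ROI.
"""

import numpy as np

from synprime import (dbscan, distance_to_cluster_centers, gen_az_clouds,
                      gen_hotspot_roi, hotspot_enrichment, nnd)

munc, bsn, truth = gen_az_clouds(n_az=6, seed=11)

counts, rgs, dists = [], [], []
for az in range(6):
    m_pts = munc.points[munc.az_id == az]
    b_pts = bsn.points[bsn.az_id == az]
    res = dbscan(m_pts, eps=50.0, min_pts=5)
    counts.append(res.n_clusters)
    rgs.extend(res.r_g.tolist())
    centers = dbscan(b_pts, eps=120.0, min_pts=5).centers
    if centers.size:
        dists.append(distance_to_cluster_centers(m_pts, centers).distances)

dists = np.concatenate(dists)
print(f"release-site clusters per AZ: median {np.median(counts):.1f} "
      f"(generated {truth['clusters_per_az']})")
print(f"cluster radius of gyration: median {np.median(rgs):.0f} nm "
      f"(generated {truth['effective_rg_munc13']:.0f} nm incl. "
      f"{truth['loc_error']:.0f} nm localization error)")
print(f"distance to nearest scaffold-cluster center: median "
      f"{np.median(dists):.0f} nm, "
      f"{100 * np.mean(dists < 250):.0f}% below 250 nm")

d = nnd(munc.points[munc.az_id == 0], bsn.points[bsn.az_id == 0])
print(f"point-to-point NND (AZ 0): median {np.median(d.distances):.0f} nm")

roi, bg, _ = gen_hotspot_roi(contrast=6.0, seed=2)
res = hotspot_enrichment(roi, bg)
print(f"hotspot enrichment z90/z50 = {res.enrichment:.2f}")

print()
print("Cluster sizes and per-AZ counts characterize release-site topology;")
print("the 100-300 nm offset to scaffold centers and the z90/z50 ratio")
print("quantify how release machinery concentrates within the terminal.")
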