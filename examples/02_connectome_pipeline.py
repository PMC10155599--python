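"""From resting-state timeseries to a vertex-to-ROI connectome.

Generates a small synthetic cohort, assigns vertices to ROIs by
winner-take-all over the parcellation z-maps, cuts each rest run into
contiguous halves (the augmentation scheme), and correlates every vertex's
timeseries with every ROI's mean timeseries.
"""

import numpy as np

from surftask import (
    CohortConfig,
    make_cohort,
    roi_mean_timeseries,
    split_segments,
    vertex_to_roi_fc,
    winner_take_all,
)

cfg = CohortConfig(level=2, n_subjects=2, n_rois=6, n_contrasts=3,
                   n_timepoints=120, n_runs=2, seed=42)
cohort, truth = make_cohort(cfg)

parc = winner_take_all(cohort.zmaps)
agreement = np.mean(parc.labels == truth.labels)
print(f"winner-take-all recovers the generating parcel labels at "
      f"{100 * agreement:.1f}% of vertices")

subject = cohort.subjects[0]
segments = split_segments(subject["runs"], scheme="halves")
print(f"{len(subject['runs'])} runs x 2 halves -> {len(segments)} connectome "
      f"samples per subject (each {segments[0].n_timepoints} timepoints)")

conn = vertex_to_roi_fc(segments[0], roi_mean_timeseries(segments[0], parc),
                        subject=subject["id"])
print(f"connectome shape: {conn.data.shape}  (vertices x ROIs), "
      f"values in [{conn.data.min():.2f}, {conn.data.max():.2f}]")
# A vertex correlates most with its own ROI's mean series:
own = np.mean([conn.data[v, parc.labels[v]] for v in range(conn.data.shape[0])])
other = conn.data.mean()
print(f"mean correlation with own ROI {own:.2f} vs overall mean {other:.2f}")
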