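"""Shared fixtures: small rendered scenes reused across test modules."""

import numpy as np
import pytest

from cytomorph import (
    FilterSpec,
    LabelVolume,
    RenderSpec,
    propagate_seeds,
    render_movie,
    wildtype_timecourse,
)

SMALL_SPACING = (0.5, 0.25, 0.25)


def seeds_from_truth(gt_frame, spacing, erosion=(2, 4, 4)):
    """Frame seeds derived from a ground-truth label frame (0 = background)."""
    lab = gt_frame.astype(np.int32).copy()
    lab[lab > 0] += 1
    lab[gt_frame == 0] = 1
    return propagate_seeds(LabelVolume(lab, spacing, background_label=1),
                           erosion)


def small_wildtype_timecourse(n_frames=16, radius=4.0):
    """Fast division timecourse: onset at frame 3, pinch complete by 12."""
    return wildtype_timecourse(n_frames=n_frames, radius=radius,
                               onset_frame=3, cytokinesis_lag_frames=3,
                               elongation_frames=6, ingression_frames=6)


@pytest.fixture(scope="session")
def small_movie():
    """Rendered 16-frame wild-type division at 0.5/0.25 µm spacing."""
    tc = small_wildtype_timecourse()
    spec = RenderSpec(voxel_spacing=SMALL_SPACING, noise_sd=5.0, rng_seed=2)
    movie, gt_labels, truth, origin = render_movie(tc, spec)
    return {"tc": tc, "spec": spec, "movie": movie, "gt": gt_labels,
            "truth": truth, "origin": origin}


@pytest.fixture(scope="session")
def small_segmentation(small_movie):
    """Watershed of the small movie from ground-truth frame-0 seeds."""
    from cytomorph import segment_movie

    sp = small_movie["spec"].voxel_spacing
    seeds = seeds_from_truth(small_movie["gt"][0], sp)
    labels, diag = segment_movie(small_movie["movie"], seeds, sp,
                                 FilterSpec(), erosion_radius=(2, 4, 4))
    return {"labels": labels, "diag": diag, **small_movie}
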