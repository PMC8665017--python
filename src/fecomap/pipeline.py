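"""End-to-end orchestration: simulate → ΔF/F → kinetics → connectivity.

Convenience layer used by the command-line demo and by validation runs
that recover a planted connectivity matrix from synthetic movies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import preprocessing as pre
from . import response_metrics as rm
from . import synthetic_data as syn

__all__ = [
    "default_roi_layout",
    "simulate_connectivity_trials",
    "recover_matrix",
    "gain_estimates",
]

#: Erosion (pixels) applied to analysis ROI masks so the 5×5 spatial
#: filter cannot mix background into the ROI mean. Equals the filter
#: radius of the default kernel.
ANALYSIS_SHRINK = 2.0


def default_roi_layout(
    post_labels: tuple[str, ...],
    frame_shape: tuple[int, int],
    radius: float = 6.0,
) -> list[syn.DiskRoi]:
    """Disjoint disk ROIs on a grid, one per post class."""
    h, w = frame_shape
    n = len(post_labels)
    n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    rois = []
    for k, post in enumerate(post_labels):
        r = (k // n_cols + 0.5) * h / n_rows
        c = (k % n_cols + 0.5) * w / n_cols
        rois.append(syn.DiskRoi(label=post, center=(r, c), radius=radius, post_label=post))
    return rois


def simulate_connectivity_trials(
    planted: syn.PlantedConnectivity,
    n_flies: int,
    scene: syn.SceneParams,
    model: syn.GcampModel,
    protocol: syn.StimulusProtocol,
    seed: int,
    roi_radius: float = 6.0,
    threshold: float | str = "otsu",
) -> pd.DataFrame:
    """Simulate one movie per (fly, pre source) and measure peak responses.

    Each movie carries one disk ROI per post class; traces are extracted
    through the full preprocessing chain (smooth, threshold, ROI mean on
    eroded masks, lowest-window ΔF/F), and the peak ΔF/F during the
    plateau-intensity pulse becomes one trial row. Per-movie seeds are
    derived deterministically from ``seed``.
    """
    plateau = conn.select_plateau_intensity(protocol.intensities.tolist())
    pulse = next(p for p in protocol.pulses if p.intensity == plateau)
    shape = (scene.image_height, scene.image_width)
    layout = default_roi_layout(planted.post_labels, shape, radius=roi_radius)
    masks = [roi.roi_mask(shape, shrink=ANALYSIS_SHRINK) for roi in layout]

    ss = np.random.SeedSequence(seed)
    movie_seeds = ss.generate_state(n_flies * len(planted.pre_labels))

    rows = []
    k = 0
    for fly in range(n_flies):
        for pre_label in planted.pre_labels:
            movie_scene = replace(scene, seed=int(movie_seeds[k] % 2**31))
            k += 1
            movie, _ = syn.gen_roi_movie(
                movie_scene, model, planted, protocol, layout, pre_label=pre_label
            )
            traces = pre.movie_to_dff(movie, masks, threshold=threshold)
            for trace in traces:
                kin = rm.peak_response(trace, pulse.onset, pulse.duration)
                rows.append(
                    {
                        "fly_id": f"fly{fly}",
                        "pre_label": pre_label,
                        "post_label": trace.label,
                        "intensity": pulse.intensity,
                        "f_peak": kin.f_peak,
                    }
                )
    return pd.DataFrame(rows)


def recover_matrix(trials: pd.DataFrame) -> conn.ConnectivityMatrix:
    """Connectivity matrix from simulated trials (all at one intensity)."""
    return conn.build_matrix(trials)


def gain_estimates(
    matrix: conn.ConnectivityMatrix,
    model: syn.GcampModel,
    protocol: syn.StimulusProtocol,
    frame_times: np.ndarray,
) -> pd.DataFrame:
    """Convert measured peak ΔF/F back to planted-gain estimates.

    Divides each cell by the unit-gain model peak on the same frame
    grid, restricted to the plateau pulse's stimulation window.
    """
    plateau = conn.select_plateau_intensity(protocol.intensities.tolist())
    pulse = next(p for p in protocol.pulses if p.intensity == plateau)
    t = np.asarray(frame_times, dtype=float)
    in_win = (t >= pulse.onset) & (t <= pulse.offset)
    unit_peak = float(model.response(t[in_win], protocol).max())
    return matrix.values / unit_peak
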