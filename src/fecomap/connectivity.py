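"""Connectivity aggregation.

Turns per-trial peak responses into the group-level products of a
functional connectivity screen: intensity–response curves, selection of
the plateau stimulation intensity used for group analyses, the
pre-subtype × post-class connectivity matrix, and the 6-leg ×
6-neuromere segment map.

All group summaries use two-stage averaging — trials are averaged
within each fly before averaging across flies — so flies with unequal
trial counts contribute equally. Untested (pre, post) pairs are
reported as missing (NaN), never imputed as zero: "no response" and
"not measured" are different facts. Values stay in the ΔF/F units of
the inputs; no row or column normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidParameterError

__all__ = [
    "NEUROMERES",
    "TRIAL_COLUMNS",
    "IntensityResponseCurve",
    "ConnectivityMatrix",
    "intensity_response_curve",
    "select_plateau_intensity",
    "build_matrix",
    "build_segment_map",
    "read_trials",
    "plot_heatmap",
]

#: The six leg-associated ventral-nerve-cord subdivisions, fixed order.
NEUROMERES: tuple[str, ...] = ("T1L", "T1R", "T2L", "T2R", "T3L", "T3R")

TRIAL_COLUMNS = ("fly_id", "pre_label", "post_label", "intensity", "f_peak")


def _check_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise InvalidParameterError(f"trial table lacks columns {sorted(missing)}")
    if len(trials) == 0:
        raise DataError("trial table is empty")
    if not np.all(trials["intensity"] > 0):
        raise DataError("trial intensities must be > 0")
    if not np.all(np.isfinite(trials["f_peak"])):
        raise DataError("trial f_peak values must be finite")
    return trials


@dataclass(frozen=True)
class IntensityResponseCurve:
    """Mean peak response per stimulation intensity for one pre/post pair."""

    intensities: np.ndarray  # ascending, mW/mm^2
    mean_f_peak: np.ndarray  # across-fly means of within-fly means
    per_fly: pd.DataFrame  # index = fly_id, columns = intensity

    def to_frame(self) -> pd.DataFrame:
        out = self.per_fly.T.copy()
        out.insert(0, "mean_f_peak", self.mean_f_peak)
        out.index.name = "intensity"
        return out


def intensity_response_curve(trials: pd.DataFrame) -> IntensityResponseCurve:
    """Two-stage intensity–response curve from trials of one pre/post pair."""
    _check_trials(trials)
    pairs = trials[["pre_label", "post_label"]].drop_duplicates()
    if len(pairs) > 1:
        raise DataError(
            "intensity_response_curve expects trials from a single pre/post pair; "
            f"got {len(pairs)}"
        )
    per_fly = (
        trials.groupby(["fly_id", "intensity"])["f_peak"].mean().unstack().sort_index(axis=1)
    )
    mean = per_fly.mean(axis=0).to_numpy()
    return IntensityResponseCurve(
        intensities=per_fly.columns.to_numpy(dtype=float),
        mean_f_peak=mean,
        per_fly=per_fly,
    )


def select_plateau_intensity(
    curve: IntensityResponseCurve | Sequence[float], target: float = 0.3
) -> float:
    """Protocol intensity closest to the plateau target.

    Responses to escalating optogenetic pulses typically plateau near
    0.3 mW/mm²; group analyses use the protocol intensity closest to
    that value (0.28 mW/mm² for the standard six-step protocol). Ties
    go to the lower intensity.
    """
    if isinstance(curve, IntensityResponseCurve):
        intensities = np.asarray(curve.intensities, dtype=float)
    else:
        intensities = np.asarray(list(curve), dtype=float)
    if intensities.size == 0:
        raise DataError("cannot select an intensity from an empty curve")
    intensities = np.sort(intensities)
    return float(intensities[np.argmin(np.abs(intensities - target))])


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Pre × post grid of two-stage-averaged peak ΔF/F responses."""

    values: pd.DataFrame  # rows = pre labels, cols = post labels; NaN = untested
    n_flies: pd.DataFrame  # same shape; fly count behind each cell
    intensity_used: float | None = None

    def to_csv(self, path: str | Path, float_format: str = "%.6g") -> None:
        self.values.to_csv(path, float_format=float_format)

    def cell(self, pre: str, post: str) -> float:
        return float(self.values.loc[pre, post])


def _two_stage(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    per_fly = trials.groupby(["pre_label", "post_label", "fly_id"])["f_peak"].mean()
    values = per_fly.groupby(["pre_label", "post_label"]).mean().unstack()
    counts = per_fly.groupby(["pre_label", "post_label"]).size().unstack()
    return values, counts


def build_matrix(trials: pd.DataFrame, intensity: float | None = None) -> ConnectivityMatrix:
    """Connectivity matrix from trials recorded at a single intensity.

    Cell (pre, post) is the across-fly mean of within-fly mean peak
    ΔF/F; pairs without trials are NaN. All trials must share one
    intensity (pass ``intensity`` to assert which); the result is
    invariant to fly relabeling and trial order.
    """
    _check_trials(trials)
    present = np.unique(trials["intensity"].to_numpy(dtype=float))
    if len(present) > 1:
        raise DataError(
            f"trials mix intensities {present.tolist()}; filter to one before building"
        )
    if intensity is not None and not np.isclose(present[0], intensity):
        raise DataError(
            f"trials are at {present[0]} mW/mm^2, not the stated {intensity}"
        )
    values, counts = _two_stage(trials)
    return ConnectivityMatrix(
        values=values, n_flies=counts, intensity_used=float(present[0])
    )


def build_segment_map(trials: pd.DataFrame, intensity: float | None = None) -> ConnectivityMatrix:
    """6×6 map: stimulated leg (rows) × recorded neuromere (columns).

    Labels must come from the T1L…T3R vocabulary; the fixed neuromere
    order is used for both axes and untested cells are NaN.
    """
    _check_trials(trials)
    bad = set(trials["pre_label"]) - set(NEUROMERES)
    bad |= set(trials["post_label"]) - set(NEUROMERES)
    if bad:
        raise DataError(
            f"unknown segment labels {sorted(bad)}; expected one of {list(NEUROMERES)}"
        )
    base = build_matrix(trials, intensity=intensity)
    values = base.values.reindex(index=list(NEUROMERES), columns=list(NEUROMERES))
    counts = base.n_flies.reindex(index=list(NEUROMERES), columns=list(NEUROMERES))
    return ConnectivityMatrix(
        values=values, n_flies=counts, intensity_used=base.intensity_used
    )


def read_trials(path: str | Path) -> pd.DataFrame:
    """Load a trial table (fly_id, pre_label, post_label, intensity, f_peak)."""
    trials = pd.read_csv(path)
    return _check_trials(trials)


def plot_heatmap(matrix: ConnectivityMatrix, path: str | Path, title: str = "") -> None:
    """Render the matrix as a PNG heatmap (NaN cells drawn light gray)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * matrix.values.shape[1],
                                    1.0 + 0.5 * matrix.values.shape[0]))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(matrix.values.to_numpy(dtype=float), cmap=cmap, aspect="auto")
    ax.set_xticks(range(matrix.values.shape[1]), matrix.values.columns, rotation=45)
    ax.set_yticks(range(matrix.values.shape[0]), matrix.values.index)
    fig.colorbar(im, ax=ax, label="peak ΔF/F")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
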