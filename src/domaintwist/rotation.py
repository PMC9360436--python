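"""Inter-domain rotation angle of a two-domain protein against crystal references.

The measurement follows the standard domain-rotation recipe for arrestin-like
proteins: fix an inactive and an active reference structure, superpose the
active onto the inactive using the N-domain selection to define the
inactive-to-active C-domain rotation (its axis u and magnitude theta_ref),
then, frame by frame, superpose the trajectory frame onto the inactive
reference on the N-domain and report the signed twist about u of the
rotation carrying the inactive C-domain onto the frame's C-domain.  By
construction the inactive reference scores 0 degrees and the active
reference scores theta_ref (about 20 degrees for beta-arrestin-1).

Alignment is anchored to the inactive structure only; the active structure
enters solely through the reference axis and angle, which keeps the scalar
well defined and signed (negative values mean rotation past the inactive
pose, away from the active one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    RigidTransform,
    kabsch_superpose,
    rotation_to_axis_angle,
    twist_about_axis,
)
from .structure import AtomSelection, Ensemble, Structure, match_selections

__all__ = [
    "RotationReference",
    "AngleSeries",
    "DegenerateReferenceError",
    "build_reference",
    "trajectory_angles",
    "rolling_average",
]

#: References closer than this are rejected: the rotation axis is numerically
#: undefined as theta -> 0.
MIN_REFERENCE_ANGLE_DEG = 0.5


class DegenerateReferenceError(ValueError):
    """Inactive/active pair differs by less than the minimum reference angle."""


def _rotation_only_kabsch(source: np.ndarray, dest: np.ndarray) -> np.ndarray:
    """Best proper rotation mapping centroid-removed ``source`` onto ``dest``."""
    transform, _ = kabsch_superpose(source - source.mean(axis=0), dest - dest.mean(axis=0))
    return transform.rotation


@dataclass
class RotationReference:
    """Inactive/active crystal pair with the derived rotation axis.

    ``axis`` and ``theta_ref_deg`` are the axis-angle of the rotation that
    maps the inactive C-domain onto the N-domain-aligned active C-domain;
    the twist of that rotation about ``axis`` equals ``theta_ref_deg``.
    """

    inactive: Structure
    active: Structure
    n_selection: AtomSelection
    c_selection: AtomSelection
    axis: np.ndarray
    theta_ref_deg: float
    inactive_c_centroid: np.ndarray
    # resolved index caches against the inactive structure
    _n_idx_inactive: np.ndarray = field(repr=False, default=None)
    _c_idx_inactive: np.ndarray = field(repr=False, default=None)


def build_reference(
    inactive: Structure,
    active: Structure,
    n_selection: AtomSelection,
    c_selection: AtomSelection,
) -> RotationReference:
    """Derive the rotation axis and reference angle from a crystal pair.

    The active structure is first superposed onto the inactive one using the
    N-domain selection (typically the Calpha atoms of the N-domain beta
    strands); the rotation-only Kabsch solution mapping the inactive
    C-domain onto the aligned active C-domain then yields the axis and
    reference angle.  Selections are matched atom-by-atom between the two
    structures (chain, residue number, atom name); mismatches raise with the
    unmatched residues listed.
    """
    n_idx_in, n_idx_ac = match_selections(inactive.atoms, active.atoms, n_selection)
    c_idx_in, c_idx_ac = match_selections(inactive.atoms, active.atoms, c_selection)

    align, _ = kabsch_superpose(active.coordinates[n_idx_ac], inactive.coordinates[n_idx_in])
    active_c_aligned = align.apply(active.coordinates[c_idx_ac])
    inactive_c = inactive.coordinates[c_idx_in]

    rotation = _rotation_only_kabsch(inactive_c, active_c_aligned)
    axis_angle = rotation_to_axis_angle(rotation)
    if axis_angle.angle_deg < MIN_REFERENCE_ANGLE_DEG:
        raise DegenerateReferenceError(
            f"inactive/active C-domain rotation is {axis_angle.angle_deg:.3f} deg, below the "
            f"{MIN_REFERENCE_ANGLE_DEG} deg guard: rotation axis undefined"
        )
    return RotationReference(
        inactive=inactive,
        active=active,
        n_selection=n_selection,
        c_selection=c_selection,
        axis=axis_angle.axis,
        theta_ref_deg=axis_angle.angle_deg,
        inactive_c_centroid=inactive_c.mean(axis=0),
        _n_idx_inactive=n_idx_in,
        _c_idx_inactive=c_idx_in,
    )


@dataclass
class AngleSeries:
    """Per-frame signed twist angles (degrees) for one run."""

    run_id: str
    angle_deg: np.ndarray
    alignment_rmsd_A: np.ndarray
    frame_index: np.ndarray = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.alignment_rmsd_A = np.asarray(self.alignment_rmsd_A, dtype=float)
        if self.frame_index is None:
            self.frame_index = np.arange(len(self.angle_deg))
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if not (len(self.angle_deg) == len(self.alignment_rmsd_A) == len(self.frame_index)):
            raise ValueError("angle, rmsd and frame index lengths differ")
        if np.any(self.alignment_rmsd_A < 0) or not np.all(np.isfinite(self.alignment_rmsd_A)):
            raise ValueError("alignment RMSD must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.angle_deg)

    def to_frame(self, rolling_window: int | None = None) -> pd.DataFrame:
        """Tabulate as the CSV layout ``run_id,frame,angle_deg,rmsd_A``."""
        df = pd.DataFrame(
            {
                "run_id": self.run_id,
                "frame": self.frame_index,
                "angle_deg": self.angle_deg,
                "rmsd_A": self.alignment_rmsd_A,
            }
        )
        if rolling_window is not None:
            df["angle_deg_rolling"] = rolling_average(self.angle_deg, rolling_window)
        return df


def trajectory_angles(ensemble: Ensemble, reference: RotationReference) -> AngleSeries:
    """Per-frame inter-domain twist angle of a trajectory.

    For every frame: (i) superpose the frame onto the inactive reference via
    the N-domain selection, recording the alignment RMSD; (ii) take the
    rotation-only Kabsch solution from the inactive C-domain onto the
    aligned frame C-domain; (iii) report its signed twist about the
    reference axis.  Frames with non-finite coordinates are skipped with a
    warning and counted in ``n_skipped``.
    """
    n_idx_ref, n_idx_frame = match_selections(
        reference.inactive.atoms, ensemble.topology, reference.n_selection
    )
    c_idx_ref, c_idx_frame = match_selections(
        reference.inactive.atoms, ensemble.topology, reference.c_selection
    )
    inactive_n = reference.inactive.coordinates[n_idx_ref]
    inactive_c = reference.inactive.coordinates[c_idx_ref]
    inactive_c0 = inactive_c - inactive_c.mean(axis=0)

    angles, rmsds, kept = [], [], []
    skipped = 0
    for fi, frame in enumerate(ensemble.frames):
        if not np.all(np.isfinite(frame)):
            skipped += 1
            continue
        align, rmsd = kabsch_superpose(frame[n_idx_frame], inactive_n)
        frame_c = align.apply(frame[c_idx_frame])
        rotation = _rotation_only_kabsch(inactive_c, frame_c)
        angles.append(twist_about_axis(rotation, reference.axis))
        rmsds.append(rmsd)
        kept.append(fi)
    if skipped:
        warnings.warn(
            f"run {ensemble.run_id!r}: skipped {skipped} frame(s) with non-finite coordinates",
            stacklevel=2,
        )
    return AngleSeries(
        run_id=ensemble.run_id,
        angle_deg=np.array(angles),
        alignment_rmsd_A=np.array(rmsds),
        frame_index=np.array(kept, dtype=int),
        n_skipped=skipped,
    )


def rolling_average(values: np.ndarray | AngleSeries, window: int) -> np.ndarray:
    """Centered moving mean with symmetric edge shrinkage.

    ``window`` must be an odd positive integer no longer than the series.
    At position i the half-width shrinks to ``min(window//2, i, n-1-i)`` so
    the window stays centered; output length equals input length.
    """
    if isinstance(values, AngleSeries):
        values = values.angle_deg
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window <= 0 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    k = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - k
    hi = idx + k + 1
    return (csum[hi] - csum[lo]) / (hi - lo)
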