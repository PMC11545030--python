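"""Rigid-body superposition and per-residue fluctuation (RMSF) analysis.

A trajectory is an ordered stack of per-residue coordinate frames (one
representative point per residue, the C-alpha convention) for one
thermodynamic condition (e.g. a simulation temperature).  The root mean
square fluctuation of residue *i* over ``T`` superposed frames is

    RMSF_i = sqrt( (1/T) * sum_t || r_i(t) - <r_i> ||^2 )

where ``<r_i>`` is the time-average position of residue *i* after every
frame has been least-squares superposed onto a common reference.  Residues
whose RMSF falls strictly below the protein-average RMSF are later called
"stable" by the screening stage.

Coordinates are in nanometres by convention (documented, not enforced).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "RmsfProfile",
    "kabsch_superpose",
    "apply_transform",
    "compute_rmsf",
]


@dataclass(frozen=True)
class Trajectory:
    """Multi-frame, per-residue coordinate set for one condition.

    Parameters
    ----------
    condition_label:
        Free-text tag for the thermodynamic condition (e.g. ``"298.15K_1bar"``).
    coords:
        Array of shape ``(n_frames, n_residues, 3)``, nanometres.
    residue_ids:
        1-based residue sequence numbers, strictly increasing.
    residue_codes:
        One-letter amino-acid codes, same length as ``residue_ids``.
    """

    condition_label: str
    coords: np.ndarray
    residue_ids: np.ndarray
    residue_codes: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        ids = np.asarray(self.residue_ids, dtype=int)
        codes = np.asarray(self.residue_codes, dtype="U1")
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise InputError(
                f"coords must have shape (n_frames, n_residues, 3), got {coords.shape}"
            )
        if coords.shape[0] < 1:
            raise InputError("a trajectory needs at least one frame")
        if coords.shape[1] != ids.shape[0] or codes.shape[0] != ids.shape[0]:
            raise InputError("residue_ids/residue_codes length must match coords")
        if not np.all(np.isfinite(coords)):
            raise InputError("trajectory coordinates must be finite")
        if ids.size > 1 and not np.all(np.diff(ids) > 0):
            raise InputError("residue_ids must be strictly increasing")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_ids", ids)
        object.__setattr__(self, "residue_codes", codes)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class RmsfProfile:
    """Per-residue fluctuation values (nm) for one condition."""

    condition_label: str
    residue_ids: np.ndarray
    values: np.ndarray
    residue_codes: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        ids = np.asarray(self.residue_ids, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if ids.shape != values.shape:
            raise InputError("residue_ids and values must have the same length")
        if values.size == 0:
            raise InputError("empty RMSF profile")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise InputError("RMSF values must be finite and non-negative")
        object.__setattr__(self, "residue_ids", ids)
        object.__setattr__(self, "values", values)
        if self.residue_codes is not None:
            codes = np.asarray(self.residue_codes, dtype="U1")
            if codes.shape != ids.shape:
                raise InputError("residue_codes length must match residue_ids")
            object.__setattr__(self, "residue_codes", codes)

    @property
    def mean_rmsf(self) -> float:
        """Protein-average RMSF; the stability threshold downstream."""
        return float(np.mean(self.values))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_after)`` such that
    ``mobile @ rotation.T + translation`` minimizes the (weighted) RMSD to
    ``reference``.  The rotation is proper (determinant +1, no reflection).

    Raises
    ------
    InputError
        On point-count mismatch, fewer than 3 points, or all-zero weights.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise InputError(
            f"point sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError("point sets must have shape (n_points, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise InputError("at least 3 points are required for a unique rotation")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise InputError("weights length must match the point count")
        if np.any(w < 0):
            raise InputError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise InputError("weights must not all be zero")
        w = w / total

    mu_mobile = w @ mobile
    mu_reference = w @ reference
    mob_c = mobile - mu_mobile
    ref_c = reference - mu_reference
    with warnings.catch_warnings():
        # align_vectors warns for near-degenerate geometries; the returned
        # rotation is still the least-squares optimum.
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    rotation = rot.as_matrix()
    translation = mu_reference - rotation @ mu_mobile
    moved = mobile @ rotation.T + translation
    rmsd_after = float(np.sqrt(np.sum(w * np.sum((moved - reference) ** 2, axis=1))))
    return rotation, translation, rmsd_after


def apply_transform(
    coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray
) -> np.ndarray:
    """Apply a rigid-body transform to an ``(n, 3)`` coordinate array."""
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def _superpose_stack(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    fitted = np.empty_like(frames)
    for t in range(frames.shape[0]):
        if np.array_equal(frames[t], reference):
            # already aligned; keeps static trajectories exactly static
            fitted[t] = frames[t]
            continue
        rotation, translation, _ = kabsch_superpose(frames[t], reference)
        fitted[t] = frames[t] @ rotation.T + translation
    return fitted


def compute_rmsf(
    traj: Trajectory,
    superpose: bool = True,
    reference_policy: str = "first_frame",
    center: str = "time_average",
    discard_frames: int = 0,
) -> RmsfProfile:
    """Per-residue RMSF of a trajectory after rigid-body superposition.

    Parameters
    ----------
    superpose:
        Remove global rotation/translation by least-squares fitting every
        frame onto a reference before measuring fluctuations (default on;
        all residues, unweighted).
    reference_policy:
        ``"first_frame"`` fits onto frame 0; ``"mean_structure"`` fits onto
        the mean of first-frame-fitted coordinates (one refinement pass).
    center:
        Deviations are measured about the per-residue ``"time_average"``
        position (the standard RMSF definition) or about the superposition
        ``"reference"`` coordinates.
    discard_frames:
        Leading frames to drop (equilibration discard; default 0).
    """
    if reference_policy not in ("first_frame", "mean_structure"):
        raise InputError(f"unknown reference_policy: {reference_policy!r}")
    if center not in ("time_average", "reference"):
        raise InputError(f"unknown center: {center!r}")
    if discard_frames < 0 or discard_frames >= traj.n_frames:
        raise InputError(
            f"discard_frames={discard_frames} leaves no frames of {traj.n_frames}"
        )
    frames = traj.coords[discard_frames:]
    n_frames = frames.shape[0]

    if n_frames == 1:
        if superpose:
            warnings.warn(
                "single-frame trajectory: RMSF is identically zero",
                stacklevel=2,
            )
        values = np.zeros(traj.n_residues)
        return RmsfProfile(
            traj.condition_label, traj.residue_ids, values, traj.residue_codes
        )

    if superpose:
        reference = frames[0]
        fitted = _superpose_stack(frames, reference)
        if reference_policy == "mean_structure":
            reference = fitted.mean(axis=0)
            fitted = _superpose_stack(frames, reference)
    else:
        reference = frames[0]
        fitted = frames

    if center == "time_average":
        center_coords = fitted.mean(axis=0)
    else:
        center_coords = reference
    deviations = fitted - center_coords
    values = np.sqrt(np.mean(np.sum(deviations**2, axis=2), axis=0))
    # zero-iff-static: a residue occupying one point in every superposed
    # frame gets an exact 0, not summation round-off
    static = np.all(fitted == fitted[:1], axis=(0, 2))
    values[static] = 0.0
    logger.info(
        "RMSF: condition=%s frames=%d residues=%d superpose=%s policy=%s "
        "center=%s mean_rmsf=%.4f",
        traj.condition_label,
        n_frames,
        traj.n_residues,
        superpose,
        reference_policy,
        center,
        float(values.mean()),
    )
    return RmsfProfile(
        traj.condition_label, traj.residue_ids, values, traj.residue_codes
    )
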