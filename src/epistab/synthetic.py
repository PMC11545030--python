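"""Seeded generators for toy trajectories and 4PL plate reads, plus fixtures.

The generators make every downstream stage testable without any external
data:

* ``generate_reference`` builds a toy C-alpha backbone as a self-avoiding-ish
  random walk with a fixed 0.38 nm step (no physics; downstream math only
  consumes coordinates).
* ``generate_trajectory`` adds per-residue isotropic Gaussian fluctuation
  about the reference, so the true per-residue RMSF is known in closed form
  (sigma * sqrt(3) per-axis sigma), optionally contaminated with global
  rigid-body motion to exercise superposition invariance.
* ``generate_plate`` draws OD450 reads from a known 4PL curve with
  multiplicative Gaussian noise (constant CV, matching how immunoassay
  precision is reported as percent CVs).

Fixture data: the six literature-curated candidate epitopes of bovine
β-lactoglobulin (collected from the IEDB and prior linear-epitope mapping
studies) with their reported stable/total residue counts, and a
deterministic full-chain stability mask consistent with those counts.
All randomness is driven by explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .dynamics import Trajectory
from .errors import InputError
from .screen import Epitope, StabilityMask

__all__ = [
    "AMINO_ACID_LETTERS",
    "ReferenceStructure",
    "FluctuationSpec",
    "PlateSpec",
    "generate_reference",
    "generate_trajectory",
    "generate_plate",
    "bundled_epitope_fixture",
    "REPORTED_STABLE_COUNTS",
    "BLG_N_RESIDUES",
    "reported_counts_mask",
    "sigma_from_mask",
]

AMINO_ACID_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

CA_STEP_NM = 0.38  # consecutive C-alpha spacing
MIN_SELF_DISTANCE_NM = 0.30  # soft self-avoidance radius for the toy walk

#: Chain length of mature bovine β-lactoglobulin.
BLG_N_RESIDUES = 162

#: Stable/total residue counts reported for the six candidate epitopes.
REPORTED_STABLE_COUNTS: dict[str, tuple[int, int]] = {
    "E1": (8, 15),
    "E2": (10, 14),
    "E3": (13, 20),
    "E4": (9, 15),
    "E5": (5, 18),
    "E6": (9, 15),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceStructure:
    """Static per-residue coordinates standing in for a crystal structure."""

    residue_ids: np.ndarray
    residue_codes: np.ndarray
    coords: np.ndarray  # (n_residues, 3), nm

    def __post_init__(self) -> None:
        ids = np.asarray(self.residue_ids, dtype=int)
        codes = np.asarray(self.residue_codes, dtype="U1")
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError("coords must have shape (n_residues, 3)")
        if not (ids.shape[0] == codes.shape[0] == coords.shape[0]):
            raise InputError("residue_ids/codes/coords lengths differ")
        if ids.size > 1 and not np.all(np.diff(ids) > 0):
            raise InputError("residue_ids must be strictly increasing")
        if not np.all(np.isfinite(coords)):
            raise InputError("coordinates must be finite")
        object.__setattr__(self, "residue_ids", ids)
        object.__setattr__(self, "residue_codes", codes)
        object.__setattr__(self, "coords", coords)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class FluctuationSpec:
    """Controls for Gaussian per-residue fluctuation about a reference.

    ``per_residue_sigma`` is the per-axis standard deviation (nm) of each
    residue; the induced true RMSF is ``sigma * sqrt(3)``.  With
    ``global_motion`` on, each frame additionally receives a random rigid
    rotation+translation, which superposition must remove.
    """

    per_residue_sigma: np.ndarray
    n_frames: int
    seed: int
    condition_label: str = "synthetic"
    global_motion: bool = False

    def __post_init__(self) -> None:
        sigma = np.asarray(self.per_residue_sigma, dtype=float)
        if sigma.ndim != 1:
            raise InputError("per_residue_sigma must be 1-D")
        if np.any(sigma < 0):
            raise InputError("sigma must be non-negative elementwise")
        if self.n_frames < 1:
            raise InputError("n_frames must be >= 1")
        object.__setattr__(self, "per_residue_sigma", sigma)


@dataclass(frozen=True)
class PlateSpec:
    """Controls for synthetic OD450 plate reads drawn from a known 4PL curve.

    Defaults mirror a competitive β-lactoglobulin calibration: the positive
    standard series 0.1-500 µg/mL in triplicate, ten buffer blanks, and 5%
    multiplicative read noise.
    """

    true_params: tuple[float, float, float, float] = (1.8, 1.2, 5.0, 0.06)
    standard_concentrations: tuple[float, ...] = (0.1, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0)
    n_replicates: int = 3
    noise_cv: float = 0.05
    n_blanks: int = 10
    seed: int = 0
    sample_true_concentrations: dict[str, float] = field(default_factory=dict)
    n_negative_controls: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.standard_concentrations, dtype=float)
        if conc.size == 0:
            raise InputError("empty standard series")
        if np.any(conc <= 0):
            raise InputError(
                "standard concentrations must be strictly positive "
                "(zero-analyte wells are blanks)"
            )
        if np.unique(conc).size != conc.size:
            raise InputError("standard concentrations must be distinct")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise InputError("noise_cv must be >= 0")
        if self.n_blanks < 0 or self.n_negative_controls < 0:
            raise InputError("well counts must be non-negative")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_reference(n_residues: int, seed: int) -> ReferenceStructure:
    """Toy C-alpha backbone: fixed-step random walk with soft self-avoidance."""
    if n_residues < 1:
        raise InputError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_residues, 3))
    for i in range(1, n_residues):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= CA_STEP_NM / np.linalg.norm(step)
            candidate = coords[i - 1] + step
            dists = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
            if dists.size == 0 or dists.min() >= MIN_SELF_DISTANCE_NM:
                break
        coords[i] = candidate
    codes = rng.choice(list(AMINO_ACID_LETTERS), size=n_residues)
    return ReferenceStructure(
        residue_ids=np.arange(1, n_residues + 1),
        residue_codes=codes,
        coords=coords,
    )


def generate_trajectory(ref: ReferenceStructure, spec: FluctuationSpec) -> Trajectory:
    """Frames = reference + isotropic Gaussian(0, sigma_i per axis) noise.

    With ``spec.global_motion`` each frame is additionally rotated by a
    uniform random rotation and translated by a Normal(0, 1 nm) offset.
    """
    sigma = spec.per_residue_sigma
    if sigma.shape[0] != ref.n_residues:
        raise InputError(
            f"sigma length {sigma.shape[0]} != residue count {ref.n_residues}"
        )
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(size=(spec.n_frames, ref.n_residues, 3)) * sigma[None, :, None]
    coords = ref.coords[None, :, :] + noise
    if spec.global_motion:
        rotations = Rotation.random(spec.n_frames, rng=rng)
        translations = rng.normal(scale=1.0, size=(spec.n_frames, 3))
        for t in range(spec.n_frames):
            coords[t] = coords[t] @ rotations[t].as_matrix().T + translations[t]
    return Trajectory(
        condition_label=spec.condition_label,
        coords=coords,
        residue_ids=ref.residue_ids,
        residue_codes=ref.residue_codes,
    )


def _four_pl(x: float, params: tuple[float, float, float, float]) -> float:
    a, b, c, d = params
    if x == 0:
        return a
    return d + (a - d) / (1.0 + (x / c) ** b)


def generate_plate(spec: PlateSpec) -> pd.DataFrame:
    """Synthetic plate table with the schema of the plate CSV.

    Columns: well_id, role, concentration, replicate, od450.  Standard and
    blank ODs are ``4PL(x) * (1 + eps)`` with ``eps ~ Normal(0, noise_cv)``
    (blanks at x = 0); samples carry no concentration in the table (the
    caller holds the truth in ``spec.sample_true_concentrations``);
    negative-control wells read at the assay floor ``d`` times noise.
    """
    rng = np.random.default_rng(spec.seed)

    def noisy(true_od: float) -> float:
        od = true_od * (1.0 + rng.normal(scale=spec.noise_cv)) if spec.noise_cv > 0 else true_od
        return max(od, 0.0)

    rows = []
    for level, conc in enumerate(spec.standard_concentrations, start=1):
        for rep in range(1, spec.n_replicates + 1):
            rows.append(
                {
                    "well_id": f"S{level}",
                    "role": "standard",
                    "concentration": conc,
                    "replicate": rep,
                    "od450": noisy(_four_pl(conc, spec.true_params)),
                }
            )
    for rep in range(1, spec.n_blanks + 1):
        rows.append(
            {
                "well_id": "BLK",
                "role": "blank",
                "concentration": 0.0,
                "replicate": rep,
                "od450": noisy(_four_pl(0.0, spec.true_params)),
            }
        )
    for sample_id in sorted(spec.sample_true_concentrations):
        conc = spec.sample_true_concentrations[sample_id]
        if conc < 0:
            raise InputError(f"sample {sample_id}: negative true concentration")
        for rep in range(1, spec.n_replicates + 1):
            rows.append(
                {
                    "well_id": sample_id,
                    "role": "sample",
                    "concentration": np.nan,
                    "replicate": rep,
                    "od450": noisy(_four_pl(conc, spec.true_params)),
                }
            )
    floor_od = spec.true_params[3]
    for rep in range(1, spec.n_negative_controls + 1):
        rows.append(
            {
                "well_id": "NEG",
                "role": "negative_control",
                "concentration": np.nan,
                "replicate": rep,
                "od450": noisy(floor_od),
            }
        )
    return pd.DataFrame(rows, columns=["well_id", "role", "concentration", "replicate", "od450"])


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------


def bundled_epitope_fixture() -> list[Epitope]:
    """The six literature-curated β-lactoglobulin candidate epitopes E1-E6."""
    from .io import read_epitope_table  # local import to avoid a cycle

    path = resources.files("epistab").joinpath("data/candidate_epitopes.tsv")
    with resources.as_file(path) as p:
        return read_epitope_table(p)


#: 1-based positions flagged stable in the synthetic full-chain mask below.
_MASK_STABLE_POSITIONS = frozenset(
    list(range(1, 9))  # 8 stable in 1-15
    + list(range(47, 54))  # 7 of the 10 stable in 47-60 ...
    + [58, 59, 60]  # ... and the 3 in the 58-60 overlap with E3
    + list(range(66, 70))  # E3 core
    + list(range(72, 78))  # E3/E4 overlap fully stable
    + [84, 85, 86]  # E4 C-terminal stable tail
    + [127, 128, 129, 143, 144]  # 5 stable in 127-144
    + list(range(145, 152))  # E6 tail (9 stable in 138-152 with 143, 144)
)


def reported_counts_mask() -> StabilityMask:
    """Synthetic full-chain stability mask matching the reported counts.

    A deterministic stable/unstable assignment over the 162-residue chain
    whose per-epitope stable counts equal ``REPORTED_STABLE_COUNTS`` for all
    six candidates (the original trajectories are not public, so the exact
    mask is under-determined; this reconstruction reproduces every count
    and the published fusion/trim outcome).
    """
    ids = np.arange(1, BLG_N_RESIDUES + 1)
    stable = np.array([int(i) in _MASK_STABLE_POSITIONS for i in ids])
    return StabilityMask(
        residue_ids=ids,
        stable=stable,
        threshold=1.0,
        condition_policy="single:synthetic-reported-counts",
    )


def sigma_from_mask(
    mask: StabilityMask, stable_sigma: float = 0.05, unstable_sigma: float = 0.30
) -> np.ndarray:
    """Per-residue fluctuation sigmas that induce a given stability mask.

    Low-sigma residues fall below the protein-mean RMSF and high-sigma
    residues above it, so classifying a long trajectory generated with
    these sigmas recovers ``mask`` with high probability.
    """
    if not 0 <= stable_sigma < unstable_sigma:
        raise InputError("need 0 <= stable_sigma < unstable_sigma")
    return np.where(mask.stable, stable_sigma, unstable_sigma).astype(float)
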