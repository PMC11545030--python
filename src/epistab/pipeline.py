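"""Declarative configuration and the end-to-end pipeline.

Stage order mirrors the assay-development workflow: per-condition RMSF ->
stability-mask aggregation -> epitope screening and peptide design ->
(optionally) plate calibration and performance analysis.  Every stage logs
its inputs and parameters so that paper-gap decisions (aggregation policy,
threshold, SD denominators) are auditable from the run log, and all
randomness is seeded, so a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as eio
from .assay import analyze_plate, plot_standard_curve
from .dynamics import compute_rmsf
from .errors import InputError
from .screen import aggregate_masks, classify_stable, screen_epitopes
from .synthetic import bundled_epitope_fixture

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a full pipeline run.

    ``trajectories`` maps condition labels to multi-model PDB paths.  With
    no ``epitope_table`` the bundled six-candidate fixture is used.  With no
    ``plate`` the run stops after screening.
    """

    out_dir: Path
    trajectories: dict[str, Path] = field(default_factory=dict)
    epitope_table: Path | None = None
    policy: str = "all_conditions"
    threshold_percent: int = 60
    superpose: bool = True
    reference_policy: str = "first_frame"
    discard_frames: int = 0
    plate: Path | None = None
    response: str = "b_over_b0"
    dilution_factor: float = 10.0
    blg_fraction: float = 0.10
    pn_cutoff: float = 2.1
    add_cterm_cys: bool = True
    seed: int = 0
    make_plot: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.threshold_percent <= 100:
            raise InputError("threshold_percent must be in [0, 100]")
        if self.dilution_factor <= 0:
            raise InputError("dilution_factor must be positive")
        if not 0 < self.blg_fraction <= 1:
            raise InputError("blg_fraction must be in (0, 1]")
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        object.__setattr__(
            self,
            "trajectories",
            {str(k): Path(v) for k, v in self.trajectories.items()},
        )
        if self.epitope_table is not None:
            object.__setattr__(self, "epitope_table", Path(self.epitope_table))
        if self.plate is not None:
            object.__setattr__(self, "plate", Path(self.plate))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides take precedence."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**data)
        except TypeError as exc:
            raise InputError(f"{path}: {exc}") from exc


def run_pipeline(config: RunConfig) -> Path:
    """Execute rmsf -> aggregate -> screen (-> assay) and write reports.

    Returns the run directory.  Stage failures propagate with the stage
    name prefixed.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: out=%s seed=%d", out, config.seed)

    masks = []
    for label, path in config.trajectories.items():
        try:
            traj = eio.read_trajectory_pdb(path, condition_label=label)
            profile = compute_rmsf(
                traj,
                superpose=config.superpose,
                reference_policy=config.reference_policy,
                discard_frames=config.discard_frames,
            )
        except Exception as exc:
            raise type(exc)(f"stage rmsf [{label}]: {exc}") from exc
        eio.write_rmsf_tsv(profile, out / f"rmsf_{label}.tsv")
        masks.append(classify_stable(profile))

    if not masks:
        raise InputError("stage rmsf: no trajectories configured")
    try:
        mask = aggregate_masks(masks, config.policy)
    except Exception as exc:
        raise type(exc)(f"stage aggregate: {exc}") from exc

    try:
        if config.epitope_table is not None:
            epitopes = eio.read_epitope_table(config.epitope_table)
        else:
            epitopes = bundled_epitope_fixture()
        result = screen_epitopes(
            epitopes,
            mask,
            threshold_percent=config.threshold_percent,
            add_cterm_cys=config.add_cterm_cys,
        )
    except Exception as exc:
        raise type(exc)(f"stage screen: {exc}") from exc
    eio.write_screen_report(result, out)

    if config.plate is not None:
        try:
            plate = eio.read_plate_csv(config.plate)
            analysis = analyze_plate(
                plate,
                dilution_factor=config.dilution_factor,
                blg_fraction=config.blg_fraction,
                pn_cutoff=config.pn_cutoff,
                response=config.response,
            )
        except Exception as exc:
            raise type(exc)(f"stage assay: {exc}") from exc
        eio.write_assay_report(analysis, out)
        if config.make_plot:
            plot_standard_curve(analysis.fit, plate, out / "standard_curve.png")

    echo = {
        "seed": config.seed,
        "policy": config.policy,
        "threshold_percent": config.threshold_percent,
        "superpose": config.superpose,
        "reference_policy": config.reference_policy,
        "discard_frames": config.discard_frames,
        "response": config.response,
        "dilution_factor": config.dilution_factor,
        "blg_fraction": config.blg_fraction,
        "pn_cutoff": config.pn_cutoff,
        "add_cterm_cys": config.add_cterm_cys,
        "trajectories": {k: str(v) for k, v in config.trajectories.items()},
        "epitope_table": str(config.epitope_table) if config.epitope_table else None,
        "plate": str(config.plate) if config.plate else None,
    }
    (out / "run_config.json").write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline done: %s", out)
    return out
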