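"""Readers and writers: multi-model PDB trajectories, TSV/CSV tables, reports.

The only trajectory dialect is multi-model PDB (MODEL/ENDMDL records, one
model per frame, C-alpha records).  Coordinates are stored in Angstrom in
the files (PDB convention) and converted to/from nanometres at the API
boundary.  All writers are atomic (write to a temporary file, then rename).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

from .assay import AssayAnalysis, validate_plate
from .dynamics import RmsfProfile, Trajectory
from .errors import InputError
from .screen import Epitope, ScreenResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_trajectory_pdb",
    "write_trajectory_pdb",
    "read_epitope_table",
    "write_epitope_table",
    "read_plate_csv",
    "write_plate_csv",
    "read_rmsf_tsv",
    "write_rmsf_tsv",
    "write_screen_report",
    "write_assay_report",
]

_NM_PER_ANGSTROM = 0.1


def _atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Multi-model PDB trajectories
# ---------------------------------------------------------------------------


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a C-alpha-only multi-model PDB file (Angstrom)."""
    n_frames, n_residues = traj.n_frames, traj.n_residues
    stack = struc.AtomArrayStack(n_frames, n_residues)
    stack.coord = traj.coords / _NM_PER_ANGSTROM
    stack.chain_id = np.full(n_residues, "A")
    stack.res_id = traj.residue_ids.copy()
    stack.res_name = np.array(
        [ProteinSequence.convert_letter_1to3(c) for c in traj.residue_codes]
    )
    stack.atom_name = np.full(n_residues, "CA")
    stack.element = np.full(n_residues, "C")
    stack.hetero = np.zeros(n_residues, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    path = Path(path)
    pdb.write(path)
    logger.info("wrote %d-frame trajectory to %s", n_frames, path)


def read_trajectory_pdb(path, condition_label: str | None = None) -> Trajectory:
    """Read a multi-model PDB file as a C-alpha trajectory (nm).

    A file without MODEL records is a one-frame trajectory.  Models are read
    individually and compared, so a residue missing from one model is
    reported by residue id.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"trajectory file not found: {path}")
    try:
        pdb = PDBFile.read(path)
        n_models = pdb.get_model_count()
    except Exception as exc:
        raise InputError(f"{path}: unparseable PDB: {exc}") from exc
    if n_models < 1:
        raise InputError(f"{path}: no coordinate models")

    frames = []
    reference_ids: np.ndarray | None = None
    codes: np.ndarray | None = None
    for model in range(1, n_models + 1):
        atoms = pdb.get_structure(model=model)
        ca = atoms[atoms.atom_name == "CA"]
        if ca.array_length() == 0:
            raise InputError(f"{path}: model {model} has no CA records")
        ids = ca.res_id
        if reference_ids is None:
            reference_ids = ids
            codes = np.array(
                [_three_to_one(name) for name in ca.res_name], dtype="U1"
            )
        elif not np.array_equal(ids, reference_ids):
            missing = sorted(set(reference_ids.tolist()) ^ set(ids.tolist()))
            raise InputError(
                f"{path}: model {model} residue set differs from model 1 "
                f"(mismatched residues: {missing})"
            )
        frames.append(ca.coord * _NM_PER_ANGSTROM)
    return Trajectory(
        condition_label=condition_label or path.stem,
        coords=np.stack(frames),
        residue_ids=reference_ids,
        residue_codes=codes,
    )


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name)
    except Exception:
        return "X"


# ---------------------------------------------------------------------------
# Epitope tables
# ---------------------------------------------------------------------------

_EPITOPE_COLUMNS = ("name", "sequence", "start", "end")


def read_epitope_table(path) -> list[Epitope]:
    """Read a TSV of candidate epitopes (name, sequence, start, end)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"epitope table not found: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"{path}: empty epitope table")
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _EPITOPE_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    if len(table) == 0:
        raise InputError(f"{path}: epitope table has a header but no rows")
    epitopes = []
    for idx, row in table.iterrows():
        line = idx + 2  # header is line 1
        try:
            epitopes.append(
                Epitope(
                    name=str(row["name"]),
                    sequence=str(row["sequence"]).strip(),
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"{path}: line {line}: {exc}") from exc
    return epitopes


def write_epitope_table(epitopes, path) -> None:
    lines = ["\t".join(_EPITOPE_COLUMNS)]
    for e in epitopes:
        lines.append(f"{e.name}\t{e.sequence}\t{e.start}\t{e.end}")
    _atomic_write_text(Path(path), "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Plate CSV
# ---------------------------------------------------------------------------


def read_plate_csv(path) -> pd.DataFrame:
    """Read and schema-validate a plate CSV.

    Columns: well_id, role in {standard, blank, sample, negative_control},
    concentration (empty for samples), replicate, od450.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"plate file not found: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"{path}: empty plate file")
    plate = pd.read_csv(path)
    try:
        return validate_plate(plate)
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_plate_csv(plate: pd.DataFrame, path) -> None:
    validate_plate(plate)
    _atomic_write_text(Path(path), plate.to_csv(index=False))


# ---------------------------------------------------------------------------
# RMSF TSV
# ---------------------------------------------------------------------------


def write_rmsf_tsv(profile: RmsfProfile, path) -> None:
    """TSV: residue_id, residue_code, rmsf_nm; mean in a trailing comment."""
    codes = (
        profile.residue_codes
        if profile.residue_codes is not None
        else np.full(profile.values.shape, "X")
    )
    lines = ["residue_id\tresidue_code\trmsf_nm"]
    for rid, code, value in zip(profile.residue_ids, codes, profile.values):
        lines.append(f"{rid}\t{code}\t{value:.6f}")
    lines.append(f"# condition={profile.condition_label}")
    lines.append(f"# mean_rmsf={profile.mean_rmsf:.6f}")
    _atomic_write_text(Path(path), "\n".join(lines) + "\n")


def read_rmsf_tsv(path) -> RmsfProfile:
    path = Path(path)
    if not path.exists():
        raise InputError(f"RMSF table not found: {path}")
    condition = path.stem
    ids, codes, values = [], [], []
    with open(path) as handle:
        header = handle.readline().strip().split("\t")
        if header != ["residue_id", "residue_code", "rmsf_nm"]:
            raise InputError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(handle, start=2):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# condition="):
                    condition = line.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(f"{path}: line {lineno}: expected 3 columns")
            try:
                ids.append(int(parts[0]))
                codes.append(parts[1])
                values.append(float(parts[2]))
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: {exc}") from exc
    if not ids:
        raise InputError(f"{path}: no RMSF rows")
    return RmsfProfile(
        condition_label=condition,
        residue_ids=np.asarray(ids),
        values=np.asarray(values),
        residue_codes=np.asarray(codes, dtype="U1"),
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_screen_report(result: ScreenResult, out_dir) -> None:
    """Write decisions.tsv (per-candidate scores) and peptides.fasta."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["name\tsequence\tposition\tstable\ttotal\tpercent\tdecision"]
    for s in result.scores:
        e = s.epitope
        lines.append(
            f"{e.name}\t{e.sequence}\t{e.start}-{e.end}\t{s.n_stable}\t"
            f"{s.n_total}\t{s.percent_display}\t{s.decision}"
        )
    _atomic_write_text(out_dir / "decisions.tsv", "\n".join(lines) + "\n")

    fasta_lines = []
    for design in result.designs:
        span = (
            f"{design.source_span[0]}-{design.source_span[1]}"
            if design.source_span
            else "?"
        )
        fasta_lines.append(
            f">{design.name} span={span} avg_mass={design.average_mass:.2f}Da "
            f"mono_mass={design.monoisotopic_mass:.4f}Da "
            f"cterm_cys={'yes' if design.conjugation_residue else 'no'}"
        )
        fasta_lines.append(design.final_sequence)
    _atomic_write_text(out_dir / "peptides.fasta", "\n".join(fasta_lines) + "\n")
    logger.info("screen report written to %s", out_dir)


def write_assay_report(analysis: AssayAnalysis, out_dir) -> None:
    """Write report.tsv (per-sample) and summary.json (fit, limits, P/N)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = analysis.samples.copy()
    for col in ("concentration_solution", "solution_sd", "concentration_food",
                "milk_protein_equivalent"):
        if col in table.columns:
            table[col] = table[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
    _atomic_write_text(out_dir / "report.tsv", table.to_csv(sep="\t", index=False))

    fit = analysis.fit
    summary: dict = {
        "four_pl": {
            "a": fit.a,
            "b": fit.b,
            "c": fit.c,
            "d": fit.d,
            "valid_range": list(fit.valid_range),
            "response_scale": fit.response_scale,
            "residuals": fit.residual_summary,
        },
        "b0": analysis.b0,
    }
    if analysis.limits is not None:
        limits = analysis.limits
        summary["detection_limits"] = {
            "lod_solution_ug_per_ml": limits.lod_solution,
            "loq_solution_ug_per_ml": limits.loq_solution,
            "lod_food_mg_per_kg": limits.lod_food,
            "loq_food_mg_per_kg": limits.loq_food,
            "lod_milk_protein_mg_per_kg": limits.lod_milk_protein,
            "loq_milk_protein_mg_per_kg": limits.loq_milk_protein,
            "blank_mean": limits.blank_mean,
            "blank_sd": limits.blank_sd,
            "n_blanks": limits.n_blanks,
            "dilution_factor": limits.dilution_factor,
            "blg_fraction": limits.blg_fraction,
        }
    if analysis.pn is not None:
        summary["pn_series"] = analysis.pn.to_dict(orient="records")
        summary["min_effective_concentration"] = analysis.min_effective
    _atomic_write_text(out_dir / "summary.json", json.dumps(summary, indent=2) + "\n")
    logger.info("assay report written to %s", out_dir)
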