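"""Stable-epitope screening, fusion/trimming and conjugation-peptide design.

The screening procedure for linear B-cell epitope candidates of
β-lactoglobulin works on a per-residue stability mask derived from RMSF
profiles:

1. A residue is *stable* when its RMSF is strictly below the protein-average
   RMSF of the same profile (ties count as unstable).
2. Each candidate epitope is scored by its proportion of stable residues;
   the displayed percentage is ``floor(100 * k / n)`` (truncation, which is
   the only convention consistent with displaying 5/18 as 27%).
3. Candidates whose displayed percentage is >= 60 are selected; others are
   rejected.
4. Selected candidates with overlapping spans are fused: the union span is
   formed and terminal regions are trimmed so that the retained sub-span
   starts and ends on stable residues and still meets the proportion
   threshold; among qualifying sub-spans the longest is kept, ties broken
   toward the later (higher-position) terminus.  This is what turns the
   overlapping candidates at 58-77 and 72-86 into the fusion peptide
   spanning 66-86 (CAQKKIIAEKTKIPAVFKIDA).
5. Each final peptide receives a supplementary C-terminal cysteine for
   maleimide coupling to the KLH carrier, and theoretical average and
   monoisotopic masses are computed for synthesis verification.

Positions are 1-based and inclusive throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.SeqUtils import molecular_weight

from .dynamics import RmsfProfile
from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_AMINO_ACIDS",
    "StabilityMask",
    "Epitope",
    "EpitopeScore",
    "FusedEpitope",
    "PeptideDesign",
    "ScreenResult",
    "classify_stable",
    "aggregate_masks",
    "score_epitope",
    "decide",
    "find_overlaps",
    "fuse_and_trim",
    "design_peptide",
    "peptide_mass",
    "screen_epitopes",
]

CANONICAL_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_THRESHOLD_PERCENT = 60


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StabilityMask:
    """Per-residue stable/unstable flags with the threshold that defined them.

    ``condition_policy`` records how multi-condition profiles were combined:
    ``"single:<label>"``, ``"all_conditions"`` or ``"any_condition"``.
    """

    residue_ids: np.ndarray
    stable: np.ndarray
    threshold: float
    condition_policy: str = "single:unlabelled"

    def __post_init__(self) -> None:
        ids = np.asarray(self.residue_ids, dtype=int)
        stable = np.asarray(self.stable, dtype=bool)
        if ids.shape != stable.shape:
            raise InputError("stable flags must match residue_ids in length")
        if ids.size == 0:
            raise InputError("empty stability mask")
        if ids.size > 1 and not np.all(np.diff(ids) > 0):
            raise InputError("residue_ids must be strictly increasing")
        object.__setattr__(self, "residue_ids", ids)
        object.__setattr__(self, "stable", stable)

    def covers(self, start: int, end: int) -> bool:
        """True when every position ``start..end`` (inclusive) is present."""
        present = set(self.residue_ids.tolist())
        return all(p in present for p in range(start, end + 1))

    def stable_at(self, positions) -> np.ndarray:
        """Boolean stability flags for the given 1-based positions."""
        positions = np.asarray(positions, dtype=int)
        index = {int(r): i for i, r in enumerate(self.residue_ids)}
        missing = [int(p) for p in positions if int(p) not in index]
        if missing:
            raise InputError(f"mask does not cover positions {missing}")
        return self.stable[[index[int(p)] for p in positions]]


@dataclass(frozen=True)
class Epitope:
    """A candidate linear epitope: name, sequence, 1-based inclusive span."""

    name: str
    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InputError(f"{self.name}: end < start")
        if len(self.sequence) != self.end - self.start + 1:
            raise InputError(
                f"{self.name}: sequence length {len(self.sequence)} does not "
                f"match span {self.start}-{self.end}"
            )
        bad = set(self.sequence) - CANONICAL_AMINO_ACIDS
        if bad:
            raise InputError(f"{self.name}: non-canonical letters {sorted(bad)}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def letter_at(self, position: int) -> str:
        if not self.start <= position <= self.end:
            raise InputError(f"position {position} outside {self.name}")
        return self.sequence[position - self.start]


@dataclass(frozen=True)
class EpitopeScore:
    """Stable-residue count of an epitope and the resulting decision."""

    epitope: Epitope
    n_stable: int
    n_total: int
    percent_display: int
    decision: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_stable <= self.n_total:
            raise InputError("need 0 <= n_stable <= n_total")


@dataclass(frozen=True)
class FusedEpitope:
    """Result of fusing two overlapping epitopes and trimming the termini."""

    parents: tuple[Epitope, Epitope]
    union_start: int
    union_end: int
    final_start: int
    final_end: int
    final_sequence: str
    removed_regions: tuple[tuple[int, int], ...] = field(default=())

    # Duck-type as an Epitope so fused products can be re-scored or re-fused.
    @property
    def name(self) -> str:
        return f"{self.parents[0].name}+{self.parents[1].name}"

    @property
    def sequence(self) -> str:
        return self.final_sequence

    @property
    def start(self) -> int:
        return self.final_start

    @property
    def end(self) -> int:
        return self.final_end

    def __len__(self) -> int:
        return self.final_end - self.final_start + 1


@dataclass(frozen=True)
class PeptideDesign:
    """A synthesis-ready peptide with theoretical masses (Da)."""

    name: str
    base_sequence: str
    conjugation_residue: str | None
    final_sequence: str
    average_mass: float
    monoisotopic_mass: float
    source_span: tuple[int, int] | None = None


@dataclass(frozen=True)
class ScreenResult:
    """Scores, final (possibly fused) epitopes, and designed peptides."""

    scores: tuple[EpitopeScore, ...]
    entities: tuple[object, ...]  # Epitope or FusedEpitope, ascending start
    designs: tuple[PeptideDesign, ...]
    threshold_percent: int


# ---------------------------------------------------------------------------
# Stability classification and scoring
# ---------------------------------------------------------------------------


def classify_stable(profile: RmsfProfile) -> StabilityMask:
    """Flag residues whose RMSF is strictly below the profile mean.

    A residue with RMSF equal to the mean is *not* stable (strict
    inequality); consequently a constant profile has no stable residues.
    """
    threshold = profile.mean_rmsf
    stable = profile.values < threshold
    logger.info(
        "classify_stable: condition=%s threshold=%.4f stable=%d/%d",
        profile.condition_label,
        threshold,
        int(stable.sum()),
        stable.size,
    )
    return StabilityMask(
        residue_ids=profile.residue_ids,
        stable=stable,
        threshold=threshold,
        condition_policy=f"single:{profile.condition_label}",
    )


def aggregate_masks(masks: list[StabilityMask], policy: str = "all_conditions") -> StabilityMask:
    """Combine per-condition masks into one.

    ``all_conditions`` (default): stable only if stable under every
    condition (logical AND).  ``any_condition``: logical OR.
    ``single:<label>``: pass through the mask whose policy label matches.
    """
    if not masks:
        raise InputError("no masks to aggregate")
    ids0 = masks[0].residue_ids
    for m in masks[1:]:
        if not np.array_equal(m.residue_ids, ids0):
            raise InputError("masks cover different residue sets")
    if policy.startswith("single:"):
        label = policy.split(":", 1)[1]
        for m in masks:
            if m.condition_policy == f"single:{label}":
                return m
        raise InputError(f"no mask with condition label {label!r}")
    if policy == "all_conditions":
        combined = np.logical_and.reduce([m.stable for m in masks])
    elif policy == "any_condition":
        combined = np.logical_or.reduce([m.stable for m in masks])
    else:
        raise InputError(f"unknown aggregation policy: {policy!r}")
    threshold = float(np.mean([m.threshold for m in masks]))
    return StabilityMask(
        residue_ids=ids0,
        stable=combined,
        threshold=threshold,
        condition_policy=policy,
    )


def _percent_display(n_stable: int, n_total: int) -> int:
    return math.floor(100 * n_stable / n_total)


def score_epitope(epitope: Epitope, mask: StabilityMask) -> EpitopeScore:
    """Count stable residues within the epitope span; floor-percent display."""
    flags = mask.stable_at(range(epitope.start, epitope.end + 1))
    k = int(flags.sum())
    n = int(flags.size)
    return EpitopeScore(
        epitope=epitope,
        n_stable=k,
        n_total=n,
        percent_display=_percent_display(k, n),
    )


def decide(
    score: EpitopeScore, threshold_percent: int = DEFAULT_THRESHOLD_PERCENT
) -> str:
    """``"selected"`` iff the displayed percentage is >= the threshold.

    The comparison is inclusive: a candidate at exactly 60% qualifies.
    """
    return "selected" if score.percent_display >= threshold_percent else "rejected"


# ---------------------------------------------------------------------------
# Overlap detection and fusion/trimming
# ---------------------------------------------------------------------------


def find_overlaps(epitopes) -> list[tuple[tuple[object, object], tuple[int, int]]]:
    """All unordered pairs with intersecting inclusive spans.

    Returns ``[((e1, e2), (overlap_start, overlap_end)), ...]``.
    """
    out = []
    items = list(epitopes)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i], items[j]
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if lo <= hi:
                out.append(((a, b), (lo, hi)))
    return out


def _union_letters(a, b) -> dict[int, str]:
    """Position -> letter map for a pair of overlapping/adjacent epitopes."""
    letters: dict[int, str] = {}
    for e in (a, b):
        for pos in range(e.start, e.end + 1):
            letter = e.letter_at(pos)
            if pos in letters and letters[pos] != letter:
                raise InputError(
                    f"{a.name}/{b.name} disagree at position {pos}: "
                    f"{letters[pos]} vs {letter}"
                )
            letters[pos] = letter
    return letters


def fuse_and_trim(
    pair,
    mask: StabilityMask,
    threshold_percent: int = DEFAULT_THRESHOLD_PERCENT,
) -> FusedEpitope:
    """Fuse two overlapping epitopes and trim unstable terminal regions.

    The union span is formed first (the pair must overlap or at least touch,
    and agree letter-for-letter on any overlap).  The retained sub-span is
    chosen among all contiguous sub-spans that

    * are reachable by deleting residues only from the termini,
    * begin and end on stable residues, and
    * have a floored stable percentage >= ``threshold_percent``,

    maximizing retained length; ties are broken toward retaining the later
    (higher-position) terminus.  Trimmed terminal regions are recorded in
    ``removed_regions`` (N-side first).
    """
    a, b = pair
    if max(a.start, b.start) > min(a.end, b.end) + 1:
        raise InputError(
            f"{a.name} ({a.start}-{a.end}) and {b.name} ({b.start}-{b.end}) "
            "neither overlap nor touch"
        )
    letters = _union_letters(a, b)
    union_start = min(a.start, b.start)
    union_end = max(a.end, b.end)
    positions = np.arange(union_start, union_end + 1)
    stable = mask.stable_at(positions)
    length = positions.size

    prefix = np.concatenate([[0], np.cumsum(stable.astype(int))])
    best: tuple[int, int, int] | None = None  # (span_length, end_idx, start_idx)
    for i in range(length):
        if not stable[i]:
            continue
        for j in range(i, length):
            if not stable[j]:
                continue
            n = j - i + 1
            k = int(prefix[j + 1] - prefix[i])
            if _percent_display(k, n) >= threshold_percent:
                key = (n, j, i)
                if best is None or key > best:
                    best = key
    if best is None:
        raise InputError(
            f"no sub-span of {a.name}+{b.name} ({union_start}-{union_end}) "
            f"meets the {threshold_percent}% stability threshold"
        )
    _, j, i = best
    final_start = int(positions[i])
    final_end = int(positions[j])
    removed: list[tuple[int, int]] = []
    if final_start > union_start:
        removed.append((union_start, final_start - 1))
    if final_end < union_end:
        removed.append((final_end + 1, union_end))
    final_sequence = "".join(letters[p] for p in range(final_start, final_end + 1))
    logger.info(
        "fuse_and_trim: %s+%s union=%d-%d retained=%d-%d removed=%s",
        a.name,
        b.name,
        union_start,
        union_end,
        final_start,
        final_end,
        removed or "none",
    )
    return FusedEpitope(
        parents=(a, b),
        union_start=union_start,
        union_end=union_end,
        final_start=final_start,
        final_end=final_end,
        final_sequence=final_sequence,
        removed_regions=tuple(removed),
    )


# ---------------------------------------------------------------------------
# Peptide design
# ---------------------------------------------------------------------------


def peptide_mass(sequence: str) -> tuple[float, float]:
    """Theoretical ``(average, monoisotopic)`` peptide mass in Daltons.

    Sum of residue masses plus one water; canonical one-letter codes only.
    """
    if not sequence:
        raise InputError("empty peptide sequence")
    bad = set(sequence) - CANONICAL_AMINO_ACIDS
    if bad:
        raise InputError(f"unknown amino-acid letters {sorted(bad)}")
    average = molecular_weight(sequence, seq_type="protein")
    mono = molecular_weight(sequence, seq_type="protein", monoisotopic=True)
    return float(average), float(mono)


def design_peptide(epitope, add_cterm_cys: bool = True, name: str | None = None) -> PeptideDesign:
    """Synthesis-ready peptide from an epitope or fused epitope.

    With ``add_cterm_cys`` on (the default) one cysteine is appended at the
    C-terminus as the dedicated maleimide-coupling handle for the KLH
    carrier.  The cysteine is appended even when the sequence already ends
    in C: the conjugation residue must be terminal and dedicated.
    """
    base = epitope.sequence
    if not base:
        raise InputError("cannot design a peptide from an empty sequence")
    if add_cterm_cys:
        if base.endswith("C"):
            logger.info(
                "design_peptide: %s already ends in C; appending a dedicated "
                "conjugation cysteine anyway",
                getattr(epitope, "name", "peptide"),
            )
        final = base + "C"
        conjugation = "C"
    else:
        final = base
        conjugation = None
    average, mono = peptide_mass(final)
    return PeptideDesign(
        name=name or getattr(epitope, "name", "peptide"),
        base_sequence=base,
        conjugation_residue=conjugation,
        final_sequence=final,
        average_mass=average,
        monoisotopic_mass=mono,
        source_span=(epitope.start, epitope.end),
    )


# ---------------------------------------------------------------------------
# End-to-end screening
# ---------------------------------------------------------------------------


def screen_epitopes(
    epitopes,
    mask: StabilityMask,
    threshold_percent: int = DEFAULT_THRESHOLD_PERCENT,
    add_cterm_cys: bool = True,
    design_prefix: str = "BLG",
) -> ScreenResult:
    """Score, select, fuse and design peptides in one pass.

    Candidates below the threshold are rejected.  Among the selected
    candidates, overlapping pairs are fused greedily (largest overlap
    first); after each fusion/trim the overlap graph is re-evaluated, so a
    trim that removes an overlap (as with the 58-65 deletion separating the
    fusion product from the candidate ending at 60) leaves the neighbours
    standalone.  Final peptides are named ``<prefix>-1..k`` by ascending
    start position.
    """
    epitopes = list(epitopes)
    if not epitopes:
        raise InputError("no candidate epitopes")
    scores: list[EpitopeScore] = []
    selected: list[object] = []
    decisions: dict[str, str] = {}
    for e in epitopes:
        s = score_epitope(e, mask)
        d = decide(s, threshold_percent)
        scores.append(replace(s, decision=d))
        decisions[e.name] = d
        if d == "selected":
            selected.append(e)
    if not selected:
        return ScreenResult(tuple(scores), (), (), threshold_percent)

    entities = list(selected)
    while True:
        overlaps = find_overlaps(entities)
        if not overlaps:
            break
        # Largest overlap first; ties toward the earliest position.
        (a, b), (lo, hi) = max(
            overlaps, key=lambda item: (item[1][1] - item[1][0] + 1, -item[1][0])
        )
        fused = fuse_and_trim((a, b), mask, threshold_percent)
        entities = [e for e in entities if e is not a and e is not b]
        entities.append(fused)
        for parent, partner in ((a, b), (b, a)):
            if parent.name in decisions:
                decisions[parent.name] = f"fused:{partner.name}"
    entities.sort(key=lambda e: e.start)

    scores = [replace(s, decision=decisions[s.epitope.name]) for s in scores]
    designs = tuple(
        design_peptide(e, add_cterm_cys=add_cterm_cys, name=f"{design_prefix}-{i + 1}")
        for i, e in enumerate(entities)
    )
    logger.info(
        "screen_epitopes: %d candidates -> %d selected -> %d peptides",
        len(epitopes),
        len(selected),
        len(designs),
    )
    return ScreenResult(tuple(scores), tuple(entities), designs, threshold_percent)
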