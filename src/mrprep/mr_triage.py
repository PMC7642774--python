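"""Molecular-replacement trial bookkeeping and success triage.

The phasing pipeline runs many molecular-replacement trials per target; each
trial reports a translation-function Z-score (TFZ) and log-likelihood gain
(LLG) from the placement search, and, after automated rebuilding, an R_free
and optionally a map correlation coefficient.  Success is judged strictly
on R_free < 0.45 after rebuilding: a high TFZ is encouraging but a placement
can score TFZ ≥ 8 and still be wrong, so TFZ alone never flips a verdict —
it only triggers an advisory asking for the rebuild to be confirmed.

B-factor assignment for the search models lives here too: either a flat
20 Å² for every atom, or the per-residue fluctuation-derived value
(8π²/3)·rmsf², which markedly improves map correlation for borderline
targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, PreconditionError
from .fluctuation import FluctuationProfile, rmsf_to_bfactor
from .model_io import CoarseModel

#: default success cutoff on R_free after model rebuilding
R_FREE_CUTOFF = 0.45

#: TFZ above which a placement is conventionally called confident
TFZ_CONFIDENT = 8.0

#: map-CC advisory bounds: below the first → likely failed, above the
#: second → likely correct
MAP_CC_FAILED = 0.1
MAP_CC_CORRECT = 0.25

TRIALS_COLUMNS = ("trial_id", "tfz", "llg", "r_free", "map_cc")


@dataclass(frozen=True)
class MRTrialRecord:
    """One molecular-replacement trial's statistics (absent values → None)."""

    trial_id: str
    tfz: float | None = None
    llg: float | None = None
    r_free: float | None = None
    map_cc: float | None = None

    def __post_init__(self):
        if all(v is None for v in (self.tfz, self.llg, self.r_free, self.map_cc)):
            raise PreconditionError(
                f"trial {self.trial_id!r}: at least one statistic must be present"
            )
        if self.tfz is not None and self.tfz < 0:
            raise PreconditionError("TFZ must be non-negative")
        if self.r_free is not None and not 0.0 <= self.r_free <= 1.0:
            raise PreconditionError("R_free must lie in [0, 1]")
        if self.map_cc is not None and not -1.0 <= self.map_cc <= 1.0:
            raise PreconditionError("map CC must lie in [-1, 1]")


@dataclass(frozen=True)
class TriageVerdict:
    """Success flag plus advisory notes for one trial."""

    success: bool
    confidence_notes: tuple = field(default_factory=tuple)


def assign_bfactors(
    model: CoarseModel,
    scheme: str = "uniform",
    profile: FluctuationProfile | None = None,
    uniform_value: float = 20.0,
) -> CoarseModel:
    """Return a copy of ``model`` with B factors set by the chosen scheme.

    ``uniform`` writes ``uniform_value`` (default 20 Å²) on every atom;
    ``rmsf`` writes each residue's fluctuation-derived B = (8π²/3)·rmsf² on
    all atoms of that residue.  Coordinates are untouched either way.
    """
    if scheme == "uniform":
        per_residue = np.full(len(model), float(uniform_value))
    elif scheme == "rmsf":
        if profile is None:
            raise PreconditionError("scheme='rmsf' requires a FluctuationProfile")
        if len(profile) != len(model) or not np.array_equal(
            profile.residue_index, model.residue_index
        ):
            raise ConsistencyError("profile does not cover the model roster")
        per_residue = rmsf_to_bfactor(profile.rmsf)
    else:
        raise PreconditionError(f"unknown B-factor scheme {scheme!r}")
    return model.with_bfactors(per_residue)


def evaluate_trial(
    record: MRTrialRecord,
    r_free_cutoff: float = R_FREE_CUTOFF,
    tfz_confident: float = TFZ_CONFIDENT,
) -> TriageVerdict:
    """Judge one trial: success iff R_free is present and strictly below cutoff.

    Advisories flag the known failure modes: a confident TFZ without a
    confirming rebuild, and map-CC values in the conventionally failed or
    correct ranges.  None of the advisories affect the success flag.
    """
    success = record.r_free is not None and record.r_free < r_free_cutoff
    notes = []
    if record.tfz is not None and record.tfz >= tfz_confident and not success:
        notes.append(
            f"high TFZ ({record.tfz:.1f} >= {tfz_confident:g}) without confirmed "
            "rebuild — placements at this TFZ can still be wrong"
        )
    if record.map_cc is not None:
        if record.map_cc < MAP_CC_FAILED:
            notes.append(f"map CC {record.map_cc:.2f} < {MAP_CC_FAILED} — likely failed")
        elif record.map_cc > MAP_CC_CORRECT:
            notes.append(
                f"map CC {record.map_cc:.2f} > {MAP_CC_CORRECT} — likely correct"
            )
    return TriageVerdict(success=success, confidence_notes=tuple(notes))


def summarize_trials(records, r_free_cutoff: float = R_FREE_CUTOFF) -> dict:
    """Roll up a set of trials into counts and best statistics.

    Returns a dict with n_trials, n_success, n_failure, success_fraction,
    best (lowest) R_free and best (highest) TFZ among present values.
    Iteration order is by trial_id, so the summary is deterministic
    regardless of input order.
    """
    records = sorted(records, key=lambda r: r.trial_id)
    if not records:
        raise PreconditionError("need at least one trial record")
    verdicts = [evaluate_trial(r, r_free_cutoff=r_free_cutoff) for r in records]
    n_success = sum(v.success for v in verdicts)
    r_frees = [r.r_free for r in records if r.r_free is not None]
    tfzs = [r.tfz for r in records if r.tfz is not None]
    return {
        "n_trials": len(records),
        "n_success": n_success,
        "n_failure": len(records) - n_success,
        "success_fraction": n_success / len(records),
        "best_r_free": min(r_frees) if r_frees else None,
        "best_tfz": max(tfzs) if tfzs else None,
    }


def read_trials_tsv(path) -> list:
    """Read a TSV of trial statistics into :class:`MRTrialRecord` objects.

    Expected header: ``trial_id  tfz  llg  r_free  map_cc`` (extra columns
    are ignored).  Empty cells become absent statistics; non-numeric cells
    raise a :class:`FormatError` naming the row and column.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise FormatError(f"cannot read trials table {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty trials table") from exc
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=1):
        values = {}
        for col in TRIALS_COLUMNS[1:]:
            raw = getattr(row, col)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                values[col] = None
                continue
            try:
                values[col] = float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric value {raw!r} at row {row_number}, "
                    f"column {col}"
                ) from exc
        records.append(MRTrialRecord(trial_id=str(row.trial_id), **values))
    return records


def write_trials_tsv(records, path) -> None:
    """Serialise trial records back to the TSV schema (round-trip safe)."""
    rows = []
    for r in records:
        rows.append(
            {
                "trial_id": r.trial_id,
                "tfz": "" if r.tfz is None else repr(r.tfz),
                "llg": "" if r.llg is None else repr(r.llg),
                "r_free": "" if r.r_free is None else repr(r.r_free),
                "map_cc": "" if r.map_cc is None else repr(r.map_cc),
            }
        )
    pd.DataFrame(rows, columns=list(TRIALS_COLUMNS)).to_csv(path, sep="\t", index=False)
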