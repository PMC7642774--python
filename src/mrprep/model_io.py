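"""Coarse-grained model containers and PDB input/output.

The in-memory representation keeps three fiducial atoms per residue — Cα
(always), Cβ (absent for glycine) and the backbone carbonyl O — which is the
resolution at which predicted search models are prepared, trimmed and scored
for molecular replacement.  Coordinates are in Å, B factors in Å².

PDB parsing and serialisation go through :mod:`gemmi`; this module only
enforces the coarse-grained contract on top (altloc policy, glycine rule,
roster consistency across MODEL blocks).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import ConsistencyError, FormatError, PreconditionError, RangeError

logger = logging.getLogger(__name__)

#: atom names retained in the coarse-grained representation
CG_ATOMS = ("CA", "CB", "O")

#: altloc identifiers accepted when collapsing to a single conformer
_ALTLOC_OK = ("", "\x00", "A")


@dataclass(frozen=True)
class CoarseModel:
    """One structure as an ordered list of coarse-grained residues.

    Parallel arrays indexed by residue position.  ``cb`` / ``o`` coordinates
    and B factors are NaN where the atom is absent (glycine never carries a
    Cβ; crystal references may lack O records).

    Parameters
    ----------
    residue_index : (n,) int array, 1-based, strictly increasing
    residue_name : length-n sequence of 3-letter codes
    ca, cb, o : (n, 3) float arrays, Å
    b_ca, b_cb, b_o : (n,) float arrays, Å²
    chain_id : single character
    label : free text provenance
    """

    residue_index: np.ndarray
    residue_name: tuple
    ca: np.ndarray
    cb: np.ndarray
    o: np.ndarray
    b_ca: np.ndarray
    b_cb: np.ndarray
    b_o: np.ndarray
    chain_id: str = "A"
    label: str = ""

    def __post_init__(self):
        idx = np.asarray(self.residue_index, dtype=int)
        object.__setattr__(self, "residue_index", idx)
        object.__setattr__(self, "residue_name", tuple(self.residue_name))
        for name in ("ca", "cb", "o"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1, 3)
            object.__setattr__(self, name, arr)
        for name in ("b_ca", "b_cb", "b_o"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            object.__setattr__(self, name, arr)
        self._validate()

    def _validate(self):
        n = len(self.residue_index)
        if len(self.residue_name) != n or any(
            arr.shape[0] != n
            for arr in (self.ca, self.cb, self.o, self.b_ca, self.b_cb, self.b_o)
        ):
            raise ConsistencyError("residue arrays have inconsistent lengths")
        if n and np.any(np.diff(self.residue_index) <= 0):
            raise ConsistencyError("residue indices must be strictly increasing")
        if not np.all(np.isfinite(self.ca)):
            raise ConsistencyError("Cα coordinates must be finite")
        for name, b, xyz in (
            ("CA", self.b_ca, self.ca),
            ("CB", self.b_cb, self.cb),
            ("O", self.b_o, self.o),
        ):
            present = ~np.isnan(b)
            if np.any(b[present] < 0):
                raise ConsistencyError(f"negative B factor on {name}")
            coords_present = ~np.any(np.isnan(xyz), axis=1)
            if name != "CA" and np.any(coords_present & ~np.isfinite(xyz).all(axis=1)):
                raise ConsistencyError(f"non-finite {name} coordinates")
        gly = np.array([rn == "GLY" for rn in self.residue_name])
        if gly.any() and np.any(~np.isnan(self.cb[gly]).all(axis=1)):
            raise ConsistencyError("glycine residues cannot carry a Cβ atom")

    # -- convenience views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.residue_index)

    @property
    def ca_coords(self) -> np.ndarray:
        """(n, 3) Cα coordinates — the trace used by every metric."""
        return self.ca

    def has_cb(self) -> np.ndarray:
        return ~np.any(np.isnan(self.cb), axis=1)

    def has_o(self) -> np.ndarray:
        return ~np.any(np.isnan(self.o), axis=1)

    def roster(self) -> tuple:
        """Hashable (index, name) roster used for frame-consistency checks."""
        return tuple(zip(self.residue_index.tolist(), self.residue_name))

    def subset(self, keep_mask: np.ndarray, label: str | None = None) -> "CoarseModel":
        """Return a copy retaining residues where ``keep_mask`` is True.

        Original residue numbering is preserved.
        """
        keep_mask = np.asarray(keep_mask, dtype=bool)
        if keep_mask.shape != (len(self),):
            raise ConsistencyError("mask length does not match roster")
        return CoarseModel(
            residue_index=self.residue_index[keep_mask],
            residue_name=tuple(rn for rn, k in zip(self.residue_name, keep_mask) if k),
            ca=self.ca[keep_mask],
            cb=self.cb[keep_mask],
            o=self.o[keep_mask],
            b_ca=self.b_ca[keep_mask],
            b_cb=self.b_cb[keep_mask],
            b_o=self.b_o[keep_mask],
            chain_id=self.chain_id,
            label=self.label if label is None else label,
        )

    def with_coords(self, ca=None, cb=None, o=None) -> "CoarseModel":
        return replace(
            self,
            ca=self.ca if ca is None else ca,
            cb=self.cb if cb is None else cb,
            o=self.o if o is None else o,
        )

    def with_bfactors(self, per_residue_b: np.ndarray) -> "CoarseModel":
        """Assign one B value per residue to every atom of that residue."""
        b = np.asarray(per_residue_b, dtype=float).reshape(-1)
        if b.shape != (len(self),):
            raise ConsistencyError("per-residue B array length mismatch")
        nan = float("nan")
        return replace(
            self,
            b_ca=b.copy(),
            b_cb=np.where(self.has_cb(), b, nan),
            b_o=np.where(self.has_o(), b, nan),
        )


@dataclass(frozen=True)
class Ensemble:
    """Ordered frames sharing one residue roster, e.g. annealing snapshots."""

    frames: tuple
    frame_energies: np.ndarray | None = None
    source: str = ""

    def __post_init__(self):
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise PreconditionError("an Ensemble needs at least one frame")
        roster = frames[0].roster()
        chain = frames[0].chain_id
        for k, fr in enumerate(frames[1:], start=2):
            if fr.chain_id != chain:
                raise ConsistencyError(f"frame {k}: chain {fr.chain_id!r} != {chain!r}")
            if fr.roster() != roster:
                mismatch = _first_roster_mismatch(roster, fr.roster())
                raise ConsistencyError(f"frame {k} roster differs from frame 1: {mismatch}")
        if self.frame_energies is not None:
            e = np.asarray(self.frame_energies, dtype=float).reshape(-1)
            if e.shape != (len(frames),):
                raise ConsistencyError("frame_energies must have one value per frame")
            object.__setattr__(self, "frame_energies", e)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> CoarseModel:
        return self.frames[i]

    @property
    def n_residues(self) -> int:
        return len(self.frames[0])

    def ca_trajectory(self) -> np.ndarray:
        """(n_frames, n_residues, 3) stacked Cα coordinates."""
        return np.stack([f.ca for f in self.frames])

    def with_energies(self, energies) -> "Ensemble":
        return Ensemble(self.frames, frame_energies=energies, source=self.source)


def _first_roster_mismatch(a: tuple, b: tuple) -> str:
    for i, (ra, rb) in enumerate(zip(a, b)):
        if ra != rb:
            return f"position {i + 1}: {ra} vs {rb}"
    return f"lengths differ ({len(a)} vs {len(b)})"


# ---------------------------------------------------------------------------
# PDB reading


def read_pdb(path, cg_only: bool = True, chain: str | None = None) -> Ensemble:
    """Read a single- or multi-model PDB file into an :class:`Ensemble`.

    One frame is produced per MODEL block (a single frame when the file has
    none).  Only ATOM records contribute; HETATM records and altlocs other
    than ' '/'A' are ignored, residues with an insertion code are rejected,
    and residues missing a Cα are dropped with a warning.

    Parameters
    ----------
    path : file path
    cg_only : when True (default), silently restrict to CA/CB/O; when False,
        the same atoms are extracted but any discarded non-CG atoms are
        reported in a warning.
    chain : chain identifier to select in multi-chain files.  Files with a
        single chain need no flag.
    """
    try:
        structure = gemmi.read_pdb(str(path))
    except (OSError, RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read PDB file {path}: {exc}") from exc

    frames = []
    for model in structure:
        frame = _extract_frame(model, path=path, cg_only=cg_only, chain=chain)
        if frame is not None:
            frames.append(frame)
    if not frames or all(len(f) == 0 for f in frames):
        raise FormatError(f"{path}: no usable ATOM records")

    roster = frames[0].roster()
    for k, fr in enumerate(frames[1:], start=2):
        if fr.roster() != roster:
            mismatch = _first_roster_mismatch(roster, fr.roster())
            raise ConsistencyError(
                f"{path}: MODEL {k} roster differs from MODEL 1 ({mismatch})"
            )
    return Ensemble(frames, source=str(path))


def _extract_frame(model, path, cg_only, chain) -> CoarseModel | None:
    chains = [ch.name for ch in model]
    if chain is None:
        if len(set(chains)) > 1:
            raise ConsistencyError(
                f"{path}: multiple chains {sorted(set(chains))}; select one with chain="
            )
    elif chain not in chains:
        raise ConsistencyError(f"{path}: chain {chain!r} not found (have {sorted(set(chains))})")

    rows = []
    n_dropped_atoms = 0
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.het_flag == "H":
                continue  # cofactors/waters are not part of the CG model
            if res.seqid.icode not in (" ", "\x00", ""):
                raise FormatError(
                    f"{path}: insertion code {res.seqid.icode!r} at residue "
                    f"{res.seqid.num} is not supported"
                )
            atoms = {}
            for atom in res:
                if atom.altloc not in _ALTLOC_OK:
                    continue
                if atom.name in CG_ATOMS and atom.name not in atoms:
                    atoms[atom.name] = atom
                elif atom.name not in CG_ATOMS:
                    n_dropped_atoms += 1
            if "CA" not in atoms:
                logger.warning(
                    "%s: residue %s %d has no CA; dropped", path, res.name, res.seqid.num
                )
                continue
            rows.append((res.seqid.num, res.name, atoms))

    if not cg_only and n_dropped_atoms:
        logger.warning(
            "%s: %d non-CG atoms present in file were not extracted",
            path,
            n_dropped_atoms,
        )
    if not rows:
        return None

    def pos(a):
        return (a.pos.x, a.pos.y, a.pos.z)

    n = len(rows)
    ca = np.empty((n, 3))
    cb = np.full((n, 3), math.nan)
    o = np.full((n, 3), math.nan)
    b_ca = np.empty(n)
    b_cb = np.full(n, math.nan)
    b_o = np.full(n, math.nan)
    for i, (_num, name, atoms) in enumerate(rows):
        ca[i] = pos(atoms["CA"])
        b_ca[i] = atoms["CA"].b_iso
        if "CB" in atoms and name != "GLY":
            cb[i] = pos(atoms["CB"])
            b_cb[i] = atoms["CB"].b_iso
        if "O" in atoms:
            o[i] = pos(atoms["O"])
            b_o[i] = atoms["O"].b_iso
    return CoarseModel(
        residue_index=np.array([r[0] for r in rows]),
        residue_name=tuple(r[1] for r in rows),
        ca=ca,
        cb=cb,
        o=o,
        b_ca=b_ca,
        b_cb=b_cb,
        b_o=b_o,
        chain_id=chain if chain is not None else (chains[0] if chains else "A"),
        label=str(path),
    )


# ---------------------------------------------------------------------------
# PDB writing


def write_pdb(model: CoarseModel, path) -> None:
    """Write a coarse model as standard PDB ATOM records.

    Occupancy is 1.00, the element column is populated, and B factors above
    999.99 Å² (the PDB field limit) raise :class:`RangeError` rather than
    silently corrupting the column.
    """
    for b in (model.b_ca, model.b_cb, model.b_o):
        present = ~np.isnan(b)
        if np.any(b[present] > 999.99):
            raise RangeError("B factor exceeds 999.99 Å² PDB field limit")

    structure = gemmi.Structure()
    structure.name = model.label or "mrprep model"
    gm = gemmi.Model("1")
    ch = gemmi.Chain(model.chain_id or "A")
    has_cb = model.has_cb()
    has_o = model.has_o()
    for i in range(len(model)):
        res = gemmi.Residue()
        res.name = model.residue_name[i]
        res.seqid = gemmi.SeqId(int(model.residue_index[i]), " ")
        res.het_flag = "A"
        entries = [("CA", model.ca[i], model.b_ca[i], "C")]
        if has_cb[i]:
            entries.append(("CB", model.cb[i], model.b_cb[i], "C"))
        if has_o[i]:
            entries.append(("O", model.o[i], model.b_o[i], "O"))
        for name, xyz, b, element in entries:
            atom = gemmi.Atom()
            atom.name = name
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = 0.0 if math.isnan(b) else float(b)
            atom.element = gemmi.Element(element)
            res.add_atom(atom)
        ch.add_residue(res)
    gm.add_chain(ch)
    structure.add_model(gm)
    structure.setup_entities()
    doc_path = str(path)
    structure.write_pdb(doc_path)


# ---------------------------------------------------------------------------
# Frame selection


def select_lowest_energy_frame(ensemble: Ensemble) -> CoarseModel:
    """Return the frame with minimal energy (ties → earliest frame).

    Mirrors the convention of taking the lowest-energy snapshot of each
    simulated-annealing run forward into trimming and phasing.
    """
    if ensemble.frame_energies is None:
        raise PreconditionError("ensemble has no frame_energies")
    idx = int(np.argmin(ensemble.frame_energies))
    return ensemble.frames[idx]
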