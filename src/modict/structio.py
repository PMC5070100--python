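"""Structure I/O: CA traces, Kabsch superposition, rmsd/weight/conservation files.

A protein model enters the pipeline as a PDB file; the only geometry consumed
downstream is the ordered alpha-carbon (CA) trace.  Superposition of a mutant
trace onto its wildtype reference is a least-squares rigid-body fit over *all*
matched CA atoms (Kabsch, via SVD); the per-residue deviations A_i and the
overall RMSD of the fit are what the scoring model consumes, carried around as
an :class:`RmsdProfile` together with optional per-residue weight and
conservation vectors.

Residue matching is strictly positional: both traces must have identical
position lists (the substitution case preserves length).  No sequence
alignment is attempted — a mismatch is an error, not a warning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import gemmi
import numpy as np

from .errors import ContractError, FormatError

__all__ = [
    "CaTrace",
    "SuperpositionResult",
    "RmsdProfile",
    "read_ca_trace",
    "superpose",
    "write_rmsd_file",
    "read_rmsd_file",
    "read_score_file",
    "write_pdb",
]

DEFAULT_WEIGHT = 10.0
DEFAULT_CONSERVATION = 1.0
CONSERVATION_MAX = 11.0


@dataclass(frozen=True)
class CaTrace:
    """Ordered alpha-carbon trace of one model.

    ``residues`` is a list of ``(position, residue_code, coord)`` with 1-based
    strictly increasing positions and coordinates in Å.
    """

    residues: tuple[tuple[int, str, tuple[float, float, float]], ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 3:
            raise ContractError(f"CA trace needs >= 3 residues, got {len(self.residues)}")
        positions = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ContractError("residue positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> list[int]:
        return [r[0] for r in self.residues]

    @property
    def coords(self) -> np.ndarray:
        """N x 3 float array of CA coordinates (Å)."""
        return np.asarray([r[2] for r in self.residues], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "CaTrace":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ContractError(f"expected coords of shape {(len(self), 3)}, got {coords.shape}")
        return CaTrace(
            tuple(
                (pos, code, (float(x), float(y), float(z)))
                for (pos, code, _), (x, y, z) in zip(self.residues, coords)
            )
        )


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid-body fit of a moving trace onto a reference.

    ``rotation`` is a proper rotation (det +1); ``per_residue_dev[i]`` is the
    Euclidean CA–CA distance of matched residue *i* after the fit, and
    ``overall_rmsd`` the root mean square of those deviations.
    """

    rotation: np.ndarray
    translation: np.ndarray
    per_residue_dev: np.ndarray
    overall_rmsd: float

    def to_profile(
        self,
        weights: Sequence[float] | None = None,
        conservation: Sequence[float] | None = None,
    ) -> "RmsdProfile":
        return RmsdProfile.from_deviations(
            self.per_residue_dev, weights=weights, conservation=conservation
        )


@dataclass(frozen=True)
class RmsdProfile:
    """Per-residue deviations plus overall RMSD; the input to all scoring.

    ``weights`` default to 10 and ``conservation`` to 1 per residue; both are
    rescaled internally before scoring, so only their relative shape matters.
    """

    deviations: np.ndarray
    overall_rmsd: float
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    conservation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        dev = np.asarray(self.deviations, dtype=float)
        object.__setattr__(self, "deviations", dev)
        n = dev.size
        if n == 0:
            raise ContractError("empty deviation vector")
        if np.any(dev < 0):
            raise ContractError("deviations must be non-negative")
        if self.overall_rmsd < 0:
            raise ContractError("overall_rmsd must be non-negative")
        w = self.weights
        w = np.full(n, DEFAULT_WEIGHT) if w is None else np.asarray(w, dtype=float)
        c = self.conservation
        c = np.full(n, DEFAULT_CONSERVATION) if c is None else np.asarray(c, dtype=float)
        if w.size != n or c.size != n:
            raise ContractError(
                f"weights ({w.size}) and conservation ({c.size}) must match deviations ({n})"
            )
        if np.any(w < 0):
            raise ContractError("weights must be >= 0")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "conservation", c)

    @property
    def n(self) -> int:
        return self.deviations.size

    @classmethod
    def from_deviations(
        cls,
        deviations: Sequence[float],
        weights: Sequence[float] | None = None,
        conservation: Sequence[float] | None = None,
    ) -> "RmsdProfile":
        dev = np.asarray(deviations, dtype=float)
        return cls(dev, float(np.sqrt(np.mean(dev**2))), weights, conservation)

    def with_weights(self, weights: Sequence[float]) -> "RmsdProfile":
        return RmsdProfile(self.deviations, self.overall_rmsd, weights, self.conservation)


def read_ca_trace(pdb_text: str, chain_id: str | None = None) -> CaTrace:
    """Extract the CA trace of one chain from PDB-format text.

    Only the first MODEL is read and HETATM records are ignored.  Alternate
    locations resolve to the highest occupancy (ties: first encountered);
    insertion-coded residues are numbered by order of appearance.  With
    ``chain_id`` omitted the file must contain exactly one chain.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise FormatError("no models in PDB input")
    model = structure[0]
    chains = [ch.name for ch in model]
    if chain_id is None:
        if len(chains) > 1:
            raise FormatError(
                f"multiple chains present ({', '.join(chains)}); specify chain_id"
            )
        if not chains:
            raise FormatError("no chains in PDB input")
        chain = model[0]
    else:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise FormatError(f"chain {chain_id!r} not found (have {', '.join(chains)})")

    residues: list[tuple[int, str, tuple[float, float, float]]] = []
    seen: set[tuple[int, str]] = set()
    for res in chain:
        if res.het_flag == "H":
            continue
        best = None
        for atom in res:
            if atom.name != "CA":
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        if best is None:
            continue
        key = (res.seqid.num, res.seqid.icode or " ")
        if key in seen:
            raise FormatError(
                f"duplicate residue {res.seqid.num}{res.seqid.icode or ''} after altloc resolution"
            )
        seen.add(key)
        residues.append((res.seqid.num, res.name, (best.pos.x, best.pos.y, best.pos.z)))
    if not residues:
        raise FormatError("no CA atoms found")
    # Insertion codes break strict numeric ordering: renumber by appearance.
    positions = [p for p, _, _ in residues]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        residues = [(i + 1, code, xyz) for i, (_, code, xyz) in enumerate(residues)]
    return CaTrace(tuple(residues))


def _kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimising ||ref - (mov R^T + t)||."""
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_c - rotation @ mov_c
    return rotation, translation


def superpose(reference: CaTrace, moving: CaTrace) -> SuperpositionResult:
    """Least-squares rigid-body fit of ``moving`` onto ``reference`` over all CA atoms.

    Raises :class:`ContractError` if the position lists differ (residues are
    matched positionally, never aligned).
    """
    if len(reference) != len(moving):
        raise ContractError(
            f"trace lengths differ ({len(reference)} vs {len(moving)}); "
            "positional matching requires equal-length models"
        )
    if reference.positions != moving.positions:
        raise ContractError("residue position lists differ; cannot pair residues")
    ref = reference.coords
    mov = moving.coords
    rotation, translation = _kabsch(ref, mov)
    fitted = mov @ rotation.T + translation
    dev = np.linalg.norm(fitted - ref, axis=1)
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        per_residue_dev=dev,
        overall_rmsd=float(np.sqrt(np.mean(dev**2))),
    )


def _open_for(src, mode: str):
    if hasattr(src, "read") or hasattr(src, "write"):
        return src, False
    return open(src, mode), True


def write_rmsd_file(profile: RmsdProfile, destination: str | Path | IO[str]) -> None:
    """Write one deviation per line with the overall RMSD on a '#overall=' header."""
    fh, close = _open_for(destination, "w")
    try:
        fh.write(f"#overall={profile.overall_rmsd:.9g}\n")
        for value in profile.deviations:
            fh.write(f"{value:.9g}\n")
    finally:
        if close:
            fh.close()


def read_rmsd_file(source: str | Path | IO[str]) -> RmsdProfile:
    """Read a per-residue rmsd file (one value per line, '#' headers allowed).

    Without a '#overall=' header the overall RMSD is recomputed as the RMS of
    the per-residue values.
    """
    fh, close = _open_for(source, "r")
    try:
        overall: float | None = None
        values: list[float] = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#overall="):
                    try:
                        overall = float(line.split("=", 1)[1])
                    except ValueError as exc:
                        raise FormatError(f"bad #overall header at line {lineno}") from exc
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise FormatError(f"non-numeric value {line!r} at line {lineno}") from exc
    finally:
        if close:
            fh.close()
    if not values:
        raise FormatError("empty rmsd file")
    dev = np.asarray(values)
    if overall is None:
        overall = float(np.sqrt(np.mean(dev**2)))
    return RmsdProfile(dev, overall)


def read_score_file(
    source: str | Path | IO[str] | None,
    kind: str,
    n_expected: int,
) -> np.ndarray:
    """Read a weight or conservation file; an absent source yields the default fill.

    ``kind`` is ``"weight"`` (default 10, bound >= 0) or ``"conservation"``
    (default 1, bounds [0, 11]).
    """
    if kind == "weight":
        default, lo, hi = DEFAULT_WEIGHT, 0.0, math.inf
    elif kind == "conservation":
        default, lo, hi = DEFAULT_CONSERVATION, 0.0, CONSERVATION_MAX
    else:
        raise ContractError(f"unknown score kind {kind!r}")
    if source is None:
        return np.full(n_expected, default)
    fh, close = _open_for(source, "r")
    try:
        values: list[float] = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                value = float(line)
            except ValueError as exc:
                raise FormatError(f"non-numeric value {line!r} at line {lineno}") from exc
            if not (lo <= value <= hi):
                raise FormatError(
                    f"{kind} value {value} at line {lineno} outside [{lo}, {hi}]"
                )
            values.append(value)
    finally:
        if close:
            fh.close()
    if len(values) != n_expected:
        raise FormatError(f"{kind} file has {len(values)} values, expected {n_expected}")
    return np.asarray(values)


def write_pdb(trace: CaTrace, destination: str | Path | IO[str], chain_id: str = "A") -> None:
    """Write a CA-only trace as minimal PDB ATOM records (for synthetic models)."""
    fh, close = _open_for(destination, "w")
    try:
        for serial, (pos, code, (x, y, z)) in enumerate(trace.residues, start=1):
            fh.write(
                f"ATOM  {serial:5d}  CA  {code:<3s} {chain_id}{pos:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
    finally:
        if close:
            fh.close()
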