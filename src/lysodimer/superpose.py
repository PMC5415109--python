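"""Least-squares rigid-body superposition and RMSD profiling.

Kabsch superposition (proper rotations only) plus the two trajectory
analyses built on it: a global backbone RMSD time series against a fixed
reference structure, and per-residue Calpha RMSD averages over a trailing
window. Structures are matched by (chain, residue_id, atom_name), so a
point mutation with a shared backbone maps cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

from .structures import (
    MappingError,
    Selection,
    Structure,
    Trajectory,
    select,
)


class DegenerateFitError(ValueError):
    """Fewer than 3 atoms or a collinear fit set."""


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Angstrom) against a fixed reference; time in ns."""

    time: np.ndarray
    rmsd: np.ndarray
    selection_label: str = ""
    reference_label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if self.time.shape != self.rmsd.shape:
            raise ValueError("time and rmsd must have equal lengths")
        if np.any(self.rmsd < 0):
            raise ValueError("rmsd must be non-negative")


@dataclass
class ResidueRmsdProfile:
    """Mean Calpha RMSD per residue over an averaging window of frames."""

    residue_ids: np.ndarray
    mean_rmsd: np.ndarray
    window: tuple[int, int]  # [start, stop) frame range

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.mean_rmsd = np.asarray(self.mean_rmsd, dtype=float)
        if self.residue_ids.shape != self.mean_rmsd.shape:
            raise ValueError("residue_ids and mean_rmsd must have equal lengths")
        if np.any(np.diff(self.residue_ids) <= 0):
            raise ValueError("residue_ids must be strictly ascending")
        if np.any(self.mean_rmsd < 0):
            raise ValueError("mean_rmsd must be non-negative")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with
    ``mobile @ rotation.T + translation`` the fitted coordinates. The
    rotation has determinant +1 (reflections excluded). Raises
    :class:`DegenerateFitError` for <3 points or collinear point sets.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be equal (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateFitError("superposition requires at least 3 atoms")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    # collinearity: centered coordinates of rank < 2 leave the fit degenerate
    if min(np.linalg.matrix_rank(P0, tol=1e-8), np.linalg.matrix_rank(Q0, tol=1e-8)) < 2:
        raise DegenerateFitError("fit set is collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    fitted = P0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q0) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ rotation.T + translation


def rmsd_no_fit(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD of matched coordinates, no superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have equal shapes")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _matched_backbone_indices(
    traj: Trajectory, reference: Structure
) -> tuple[np.ndarray, np.ndarray]:
    """1:1 backbone index maps between trajectory atom table and reference.

    Matching is by (chain, residue_id, atom_name) so residue-name differences
    at a mutated site do not break the map; any unmatched backbone atom on
    either side raises :class:`MappingError` listing the offenders.
    """
    tsel = select(traj, "backbone")
    rsel = select(reference, "backbone")
    tkeys = {traj.atom_table[i].key(): i for i in tsel.indices}
    rkeys = {reference.atoms[i].key(): i for i in rsel.indices}
    missing_in_ref = sorted(set(tkeys) - set(rkeys))
    missing_in_traj = sorted(set(rkeys) - set(tkeys))
    if missing_in_ref or missing_in_traj:
        raise MappingError(
            "backbone atoms could not be matched 1:1; "
            f"absent from reference: {missing_in_ref[:10]}; "
            f"absent from trajectory: {missing_in_traj[:10]}"
        )
    shared = sorted(tkeys)
    return (
        np.array([tkeys[k] for k in shared]),
        np.array([rkeys[k] for k in shared]),
    )


def backbone_rmsd_series(traj: Trajectory, reference: Structure) -> RmsdSeries:
    """Per-frame backbone RMSD against a fixed reference structure.

    Each frame is superposed on the reference over the backbone atoms
    (N, CA, C, O) and the RMSD is measured over the same atoms; the fit set
    equals the measurement set.
    """
    ti, ri = _matched_backbone_indices(traj, reference)
    ref_xyz = reference.coords[ri]
    rmsds = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, rmsds[f] = kabsch_superpose(traj.frames[f][ti], ref_xyz)
    return RmsdSeries(
        time=traj.times_ns(),
        rmsd=rmsds,
        selection_label="backbone",
        reference_label=reference.title or "reference",
    )


def structure_backbone_rmsd(mobile: Structure, reference: Structure) -> float:
    """Backbone RMSD between two superposed structures (e.g. two crystals)."""
    traj = Trajectory(
        atom_table=mobile.atoms,
        frames=mobile.coords[np.newaxis],
        frame_interval=1.0,
    )
    return float(backbone_rmsd_series(traj, reference).rmsd[0])


def residue_rmsd_profile(
    traj: Trajectory, reference: Structure, window: tuple[int, int]
) -> ResidueRmsdProfile:
    """Per-residue mean Calpha RMSD over ``window`` = [start, stop) frames.

    Frames are superposed globally on the backbone; each residue's Calpha
    deviation from the reference is then averaged per frame over the window
    (per-frame averaging, not deviation from a time-mean structure).
    """
    start, stop = window
    if start < 0 or stop > traj.n_frames or start >= stop:
        raise ValueError(f"window {window} outside trajectory of {traj.n_frames} frames")
    ti, ri = _matched_backbone_indices(traj, reference)
    ref_bb = reference.coords[ri]

    tca = select(traj, "calpha")
    tca_keys = {traj.atom_table[i].key(): i for i in tca.indices}
    rca_keys = {reference.atoms[i].key(): i for i in select(reference, "calpha").indices}
    shared = sorted(set(tca_keys) & set(rca_keys), key=lambda k: (k[0], k[1]))
    if not shared:
        raise MappingError("no Calpha atoms shared between trajectory and reference")
    tca_idx = np.array([tca_keys[k] for k in shared])
    rca_idx = np.array([rca_keys[k] for k in shared])
    ref_ca = reference.coords[rca_idx]

    acc = np.zeros(len(shared))
    for f in range(start, stop):
        R, t, _ = kabsch_superpose(traj.frames[f][ti], ref_bb)
        fitted_ca = apply_transform(traj.frames[f][tca_idx], R, t)
        acc += np.linalg.norm(fitted_ca - ref_ca, axis=1)
    mean = acc / (stop - start)
    residue_ids = np.array([k[1] for k in shared])
    if np.any(np.diff(residue_ids) <= 0):
        # multi-chain: keep ascending by offsetting chains is not meaningful;
        # report per first chain occurrence order requires unique ids
        raise MappingError("residue ids are not strictly ascending across chains; pass a single-chain trajectory")
    return ResidueRmsdProfile(residue_ids=residue_ids, mean_rmsd=mean, window=(start, stop))


def write_rmsd_series_tsv(series: RmsdSeries, stream: IO[str]) -> None:
    stream.write("time_ns\trmsd_A\n")
    for t, r in zip(series.time, series.rmsd):
        stream.write(f"{t:.6g}\t{r:.6f}\n")


def write_residue_profile_tsv(profile: ResidueRmsdProfile, stream: IO[str]) -> None:
    stream.write("residue_id\tmean_rmsd_A\n")
    for rid, r in zip(profile.residue_ids, profile.mean_rmsd):
        stream.write(f"{rid}\t{r:.6f}\n")
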