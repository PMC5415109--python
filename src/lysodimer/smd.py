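"""Steered-pulling work integration and Jarzynski free-energy reconstruction.

The constant-velocity stiff-spring protocol moves a harmonic restraint's
reference point as z_ref(t) = z0 + v t. The work along one realization is
the integral of the spring force over the reference displacement,

    W(z_ref) = \\int F dz_ref,   F = k_s (z_ref(t) - z(t)),

and the free-energy profile follows from the exponential work average

    exp(-dG(z)/kT) = < exp(-W(z)/kT) >,

evaluated with a max-shifted log-sum-exp. Under the stiff-spring
approximation dG is reported against the reference coordinate. No
finite-sample bias correction is applied; the exponential average is known
to overestimate profiles when work fluctuations are large relative to kT,
which is documented rather than corrected.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

BOLTZMANN_KCAL_PER_MOL_K = 0.0019872  # kcal/mol/K

DEFAULT_SPRING_CONSTANT = 50.0  # kcal/mol/A^2, stiff-spring regime
DEFAULT_PULL_VELOCITY = 1.0  # A/ns
DEFAULT_TEMPERATURE_K = 300.0
DEFAULT_GRID_SPACING = 0.1  # A
DEFAULT_PULL_SPAN = 15.0  # A, bound state to bulk
DEFAULT_N_TRACES = 10


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """kT in kcal/mol (0.5962 at 300 K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return BOLTZMANN_KCAL_PER_MOL_K * temperature


@dataclass(frozen=True)
class PullingProtocol:
    """Constant-velocity stiff-spring pulling parameters."""

    k_s: float = DEFAULT_SPRING_CONSTANT  # kcal/mol/A^2
    v: float = DEFAULT_PULL_VELOCITY  # A/ns
    z0: float = 0.0  # A
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    temperature: float = DEFAULT_TEMPERATURE_K  # K

    def __post_init__(self) -> None:
        if self.k_s <= 0:
            raise ValueError("spring constant must be positive")
        if self.v <= 0:
            raise ValueError("pulling velocity must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)


@dataclass
class PullLog:
    """One pulling realization: time (ns), coordinate z (A), optional force.

    The force (kcal/mol/A) is the spring force on the pulled group; when
    absent it is reconstructed as k_s (z_ref(t) - z(t)).
    """

    time: np.ndarray
    z: np.ndarray
    force: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.time.shape != self.z.shape or self.time.ndim != 1:
            raise ValueError("time and z must be equal-length 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)
            if self.force.shape != self.time.shape:
                raise ValueError("force must match time length")


@dataclass
class WorkTrace:
    """Cumulative work (kcal/mol) on an ascending reaction-coordinate grid."""

    z_grid: np.ndarray
    work: np.ndarray

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.work = np.asarray(self.work, dtype=float)
        if self.z_grid.shape != self.work.shape or self.z_grid.ndim != 1:
            raise ValueError("z_grid and work must be equal-length 1-D arrays")
        if np.any(np.diff(self.z_grid) <= 0):
            raise ValueError("z_grid must be strictly ascending")
        if abs(self.work[0]) > 1e-9:
            raise ValueError("work must start at 0")


@dataclass
class FreeEnergyProfile:
    """dG(z) in kcal/mol over a grid, anchored at dG(z_grid[0]) = 0."""

    z_grid: np.ndarray
    dG: np.ndarray
    n_traces: int
    kT: float

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        if self.z_grid.shape != self.dG.shape:
            raise ValueError("z_grid and dG must have equal lengths")
        if abs(self.dG[0]) > 1e-9:
            raise ValueError("dG must be anchored at 0")
        if self.n_traces < 1:
            raise ValueError("n_traces must be >= 1")
        if self.kT <= 0:
            raise ValueError("kT must be positive")


def reference_position(protocol: PullingProtocol, t: float | np.ndarray) -> float | np.ndarray:
    """Restraint reference position z_ref(t) = z0 + v t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = protocol.z0 + protocol.v * t
    return float(out) if out.ndim == 0 else out


def default_grid(protocol: PullingProtocol, span: float = DEFAULT_PULL_SPAN,
                 spacing: float = DEFAULT_GRID_SPACING) -> np.ndarray:
    """Reaction-coordinate grid [z0, z0 + span] at the default spacing."""
    n = int(round(span / spacing))
    return protocol.z0 + np.linspace(0.0, span, n + 1)


def work_trace(log: PullLog, protocol: PullingProtocol, z_grid: np.ndarray) -> WorkTrace:
    """Integrate the spring force over the reference displacement onto a grid.

    W at a grid point is the trapezoidal integral of the force against
    z_ref (dz_ref = v dt), linearly interpolated onto ``z_grid`` and
    anchored so W(z_grid[0]) = 0. The grid must lie inside the span of the
    log's reference coordinate.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    z_ref = reference_position(protocol, log.time)
    force = log.force
    if force is None:
        force = protocol.k_s * (z_ref - log.z)
    if z_grid[0] < z_ref[0] - 1e-9 or z_grid[-1] > z_ref[-1] + 1e-9:
        raise ValueError(
            f"grid [{z_grid[0]:g}, {z_grid[-1]:g}] outside logged reference span "
            f"[{z_ref[0]:g}, {z_ref[-1]:g}]"
        )
    cum = np.concatenate([[0.0], np.cumsum(np.diff(z_ref) * (force[1:] + force[:-1]) / 2.0)])
    w = np.interp(z_grid, z_ref, cum)
    return WorkTrace(z_grid=z_grid, work=w - w[0])


def jarzynski_profile(traces: Sequence[WorkTrace], kT: float) -> FreeEnergyProfile:
    """Exponential work average: dG(z) = -kT log < exp(-W(z)/kT) >.

    The average uses a max-stabilized log-sum-exp so arbitrarily large works
    do not overflow. All traces must share one grid.
    """
    if not traces:
        raise ValueError("at least one work trace is required")
    if kT <= 0:
        raise ValueError("kT must be positive")
    grid = traces[0].z_grid
    for tr in traces[1:]:
        if tr.z_grid.shape != grid.shape or not np.allclose(tr.z_grid, grid, atol=1e-9):
            raise ValueError("all work traces must share one z_grid")
    W = np.stack([tr.work for tr in traces])  # (n_traces, n_z)
    dG = -kT * (logsumexp(-W / kT, axis=0) - np.log(W.shape[0]))
    dG = dG - dG[0]
    return FreeEnergyProfile(z_grid=grid.copy(), dG=dG, n_traces=W.shape[0], kT=kT)


def mean_work_profile(traces: Sequence[WorkTrace]) -> np.ndarray:
    """<W(z)> over traces (upper bound on dG by Jensen's inequality)."""
    return np.stack([tr.work for tr in traces]).mean(axis=0)


def cumulant_profile(traces: Sequence[WorkTrace], kT: float) -> np.ndarray:
    """Second-order cumulant estimator <W> - var(W)/2kT (near-Gaussian works)."""
    W = np.stack([tr.work for tr in traces])
    return W.mean(axis=0) - W.var(axis=0) / (2.0 * kT)


def binding_affinity(profile: FreeEnergyProfile, bulk_window: tuple[float, float]) -> float:
    """Bulk plateau minus bound minimum of a dissociation profile, kcal/mol.

    The affinity is read as the mean dG over the bulk window (a z range near
    the profile's far end) minus the minimum dG over the whole grid; it is
    non-negative by construction.
    """
    lo, hi = bulk_window
    mask = (profile.z_grid >= lo) & (profile.z_grid <= hi)
    if not np.any(mask):
        raise ValueError(f"bulk window {bulk_window} contains no grid points")
    return float(np.mean(profile.dG[mask]) - np.min(profile.dG))


def rank_complexes(
    profiles: Mapping[str, FreeEnergyProfile],
    bulk_window: tuple[float, float],
    tie_tolerance: float = 1e-9,
) -> dict:
    """Order labeled complexes by descending binding affinity.

    Ties (affinities within ``tie_tolerance``) are broken by label order and
    reported in the result's ``ties`` list.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    affinities = {label: binding_affinity(p, bulk_window) for label, p in profiles.items()}
    order = sorted(affinities, key=lambda lab: (-affinities[lab], lab))
    ties = []
    for a, b in zip(order, order[1:]):
        if abs(affinities[a] - affinities[b]) <= tie_tolerance:
            ties.append([a, b])
    return {"order": order, "affinity_kcal_mol": affinities, "ties": ties}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pull_log_tsv(stream: IO[str]) -> PullLog:
    """Read a pulling log with headers time_ns, z_A [, force_kcal_mol_A]."""
    reader = csv.reader(stream, delimiter="\t")
    header = next(reader, None)
    if header is None or header[:2] != ["time_ns", "z_A"]:
        raise ValueError("expected tab-separated header: time_ns\tz_A[\tforce_kcal_mol_A]")
    has_force = len(header) >= 3 and header[2] == "force_kcal_mol_A"
    t, z, f = [], [], []
    for row in reader:
        if not row:
            continue
        t.append(float(row[0]))
        z.append(float(row[1]))
        if has_force:
            f.append(float(row[2]))
    return PullLog(
        time=np.array(t), z=np.array(z), force=np.array(f) if has_force else None
    )


def write_pull_log_tsv(log: PullLog, stream: IO[str]) -> None:
    if log.force is not None:
        stream.write("time_ns\tz_A\tforce_kcal_mol_A\n")
        for t, z, f in zip(log.time, log.z, log.force):
            stream.write(f"{t:.9g}\t{z:.9g}\t{f:.9g}\n")
    else:
        stream.write("time_ns\tz_A\n")
        for t, z in zip(log.time, log.z):
            stream.write(f"{t:.9g}\t{z:.9g}\n")


def read_namd_smd_log(
    stream: IO[str],
    protocol: PullingProtocol,
    timestep_fs: float = 2.0,
) -> PullLog:
    """Read the NAMD "SMD" output dialect.

    Lines of the form ``SMD <step> <x> <y> <z> <fx> <fy> <fz>`` (position in
    A, force in kcal/mol/A); position and force are projected onto the
    protocol's pulling direction and the step index is converted to ns via
    the MD timestep.
    """
    u = np.asarray(protocol.direction, dtype=float)
    t, z, f = [], [], []
    for line in stream:
        parts = line.split()
        if not parts or parts[0] != "SMD":
            continue
        if len(parts) < 8:
            raise ValueError(f"malformed SMD line: {line.rstrip()!r}")
        step = float(parts[1])
        pos = np.array([float(p) for p in parts[2:5]])
        frc = np.array([float(p) for p in parts[5:8]])
        t.append(step * timestep_fs * 1e-6)  # fs -> ns
        z.append(float(pos @ u))
        f.append(float(frc @ u))
    if not t:
        raise ValueError("no SMD lines found")
    return PullLog(time=np.array(t), z=np.array(z), force=np.array(f))


def write_profile_tsv(profile: FreeEnergyProfile, stream: IO[str]) -> None:
    stream.write("z_A\tdG_kcal_mol\n")
    for z, g in zip(profile.z_grid, profile.dG):
        stream.write(f"{z:.6g}\t{g:.6f}\n")


def write_ranking_json(ranking: dict, stream: IO[str]) -> None:
    json.dump(ranking, stream, indent=2, sort_keys=True)
    stream.write("\n")
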