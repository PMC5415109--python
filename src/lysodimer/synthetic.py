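"""Synthetic inputs with known ground truth.

Two generators stand behind every test of the analysis stages:

* a one-dimensional overdamped Langevin pulling engine (Euler-Maruyama)
  with closed-form potentials, for which the exact stiff-spring free
  energy is available by quadrature — the oracle for the Jarzynski
  reconstruction; and

* a mock-trajectory generator that decorates a reference structure with
  Ornstein-Uhlenbeck positional noise (elevated in designated loop
  residues), a per-frame Gaussian rigid loop opening, Poisson-placed
  pocket waters, and an optional dimer drift schedule — the oracle for
  the superposition and geometry analyses.

Also here: synthetic stand-in structures for the two lysozyme crystals
(wild type and the position-67 Asp-to-His variant), built from their
published residue-level facts; they are generated geometry, not
crystallographic coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import IO, Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .smd import PullLog, PullingProtocol, thermal_energy
from .structures import AtomRecord, Structure, Trajectory
from .superpose import kabsch_superpose

DEFAULT_CORRELATION_TIME_NS = 0.1  # OU correlation time of positional noise
DEFAULT_NOISE_AMPLITUDE_A = 0.25  # per-component RMS positional noise
DEFAULT_LOOP_MULTIPLIER = 3.0  # noise amplification in flexible loop residues


class ConfigurationError(ValueError):
    """Generator parameters violate a stated validity bound."""


# ---------------------------------------------------------------------------
# toy potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyPotential:
    """A 1-D potential with closed-form energy, gradient and curvature bound.

    Kinds: ``harmonic`` (0.5 k (z - z_min)^2), ``linear-ramp`` (slope * z)
    and ``double-well`` (quartic h ((x^2 - a^2)/a^2)^2 + tilt * x with
    x = z - center, a = separation/2). Energies in kcal/mol, z in Angstrom.
    """

    kind: str
    params: tuple[tuple[str, float], ...]

    @property
    def p(self) -> dict[str, float]:
        return dict(self.params)

    @classmethod
    def harmonic(cls, k: float, z_min: float = 0.0) -> "ToyPotential":
        if k <= 0:
            raise ConfigurationError("harmonic stiffness must be positive")
        return cls("harmonic", (("k", float(k)), ("z_min", float(z_min))))

    @classmethod
    def linear_ramp(cls, slope: float) -> "ToyPotential":
        return cls("linear-ramp", (("slope", float(slope)),))

    @classmethod
    def double_well(
        cls, barrier: float, separation: float, center: float = 0.0, tilt: float = 0.0
    ) -> "ToyPotential":
        if barrier <= 0 or separation <= 0:
            raise ConfigurationError("barrier and separation must be positive")
        return cls(
            "double-well",
            (
                ("barrier", float(barrier)),
                ("separation", float(separation)),
                ("center", float(center)),
                ("tilt", float(tilt)),
            ),
        )

    def energy(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        p = self.p
        if self.kind == "harmonic":
            out = 0.5 * p["k"] * (z - p["z_min"]) ** 2
        elif self.kind == "linear-ramp":
            out = p["slope"] * z
        elif self.kind == "double-well":
            a = p["separation"] / 2.0
            x = z - p["center"]
            out = p["barrier"] * ((x**2 - a**2) / a**2) ** 2 + p["tilt"] * x
        else:
            raise ConfigurationError(f"unknown potential kind {self.kind!r}")
        return float(out) if out.ndim == 0 else out

    def grad(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        p = self.p
        if self.kind == "harmonic":
            out = p["k"] * (z - p["z_min"])
        elif self.kind == "linear-ramp":
            out = np.full_like(z, p["slope"])
        elif self.kind == "double-well":
            a = p["separation"] / 2.0
            x = z - p["center"]
            out = p["barrier"] * 4.0 * x * (x**2 - a**2) / a**4 + p["tilt"]
        else:
            raise ConfigurationError(f"unknown potential kind {self.kind!r}")
        return float(out) if out.ndim == 0 else out

    def max_curvature(self, z_range: tuple[float, float]) -> float:
        """Upper bound on |U''| over a z range (for the stability bound)."""
        p = self.p
        if self.kind == "harmonic":
            return p["k"]
        if self.kind == "linear-ramp":
            return 0.0
        a = p["separation"] / 2.0
        x_ext = max(abs(z_range[0] - p["center"]), abs(z_range[1] - p["center"]))
        # U'' = 4 h (3 x^2 - a^2) / a^4, maximal at the range edge
        return p["barrier"] * 4.0 * max(3.0 * x_ext**2 - a**2, a**2) / a**4


def analytic_delta_g(
    potential: ToyPotential, z: np.ndarray | float, z_ref: float = 0.0
) -> np.ndarray | float:
    """Exact free-energy difference U(z) - U(z_ref) of the bare potential.

    For overdamped dynamics on a 1-D potential, the potential of mean force
    along z is the potential itself.
    """
    out = np.asarray(potential.energy(z), dtype=float) - potential.energy(z_ref)
    return float(out) if out.ndim == 0 else out


def stiff_spring_free_energy(
    potential: ToyPotential,
    protocol: PullingProtocol,
    z_ref_grid: np.ndarray,
    margin: float = 6.0,
    n_quad: int = 20001,
) -> np.ndarray:
    """Exact restraint free energy G(z_ref) by quadrature, anchored at grid[0].

    G(z_ref) = -kT log Int exp(-(U(z) + 0.5 k_s (z - z_ref)^2)/kT) dz — the
    quantity the exponential work average converges to under the
    constant-velocity protocol. For a stiff spring it tracks U(z_ref) up to
    a nearly constant width correction.
    """
    z_ref_grid = np.asarray(z_ref_grid, dtype=float)
    kT = protocol.kT
    lo = z_ref_grid.min() - margin
    hi = z_ref_grid.max() + margin
    z = np.linspace(lo, hi, n_quad)
    dz = z[1] - z[0]
    U = np.asarray(potential.energy(z))
    # (n_ref, n_quad) exponent; max-shifted log-trapezoid
    E = U[None, :] + 0.5 * protocol.k_s * (z[None, :] - z_ref_grid[:, None]) ** 2
    G = -kT * (logsumexp(-E / kT, axis=1) + np.log(dz))
    return G - G[0]


# ---------------------------------------------------------------------------
# overdamped Langevin pulling engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LangevinParams:
    """Overdamped-dynamics parameters: friction (kcal ns/mol/A^2), step (ns)."""

    gamma: float = 0.2
    dt: float = 2.5e-4
    temperature: float = 300.0  # K; 0 disables thermal noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.dt <= 0:
            raise ConfigurationError("gamma and dt must be positive")
        if self.temperature < 0:
            raise ConfigurationError("temperature must be non-negative")


def _check_stability(
    potential: ToyPotential,
    protocol: PullingProtocol,
    params: LangevinParams,
    z_range: tuple[float, float],
) -> None:
    bound = params.gamma / (potential.max_curvature(z_range) + protocol.k_s)
    if params.dt >= bound:
        raise ConfigurationError(
            f"dt = {params.dt:g} ns violates the stability bound "
            f"gamma/(max|U''| + k_s) = {bound:g} ns"
        )


def sample_equilibrium(
    potential: ToyPotential,
    protocol: PullingProtocol,
    n: int,
    rng: np.random.Generator,
    temperature: float | None = None,
    margin: float = 6.0,
) -> np.ndarray:
    """Draw initial coordinates from the Boltzmann density of U + spring at z0.

    Inverse-CDF sampling on a dense grid; at zero temperature returns the
    minimizer. Jarzynski requires equilibrium initial conditions, so the
    pulling engine starts every trace from this distribution.
    """
    T = protocol.temperature if temperature is None else temperature
    z = np.linspace(protocol.z0 - margin, protocol.z0 + margin, 20001)
    E = np.asarray(potential.energy(z)) + 0.5 * protocol.k_s * (z - protocol.z0) ** 2
    if T == 0:
        return np.full(n, z[np.argmin(E)])
    w = np.exp(-(E - E.min()) / thermal_energy(T))
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, z)


def simulate_pulling(
    potential: ToyPotential,
    protocol: PullingProtocol,
    params: LangevinParams,
    n_traces: int,
    span: float | None = None,
    output_stride: int = 10,
) -> list[PullLog]:
    """Constant-velocity pulls by Euler-Maruyama overdamped dynamics.

    dz = [-U'(z) + k_s (z_ref - z)] dt/gamma + sqrt(2 kT dt/gamma) xi,
    with z_ref(t) = z0 + v t swept over ``span`` Angstrom (default 15).
    Initial coordinates are equilibrium samples of U + spring at z0.
    Logs are sampled every ``output_stride`` steps; bit-identical per seed.
    """
    if n_traces < 1:
        raise ConfigurationError("n_traces must be >= 1")
    span = 15.0 if span is None else float(span)
    z_range = (protocol.z0 - 3.0, protocol.z0 + span + 3.0)
    _check_stability(potential, protocol, params, z_range)
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(span / (protocol.v * params.dt)))
    kT_sim = thermal_energy(params.temperature) if params.temperature > 0 else 0.0
    noise_scale = math.sqrt(2.0 * kT_sim * params.dt / params.gamma)
    z = sample_equilibrium(potential, protocol, n_traces, rng, params.temperature)
    rec_steps = list(range(0, n_steps + 1, output_stride))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_set = set(rec_steps)
    times = np.array(rec_steps) * params.dt
    zs = np.empty((len(rec_steps), n_traces))
    forces = np.empty_like(zs)
    ri = 0
    for step in range(n_steps + 1):
        z_ref = protocol.z0 + protocol.v * step * params.dt
        f_spring = protocol.k_s * (z_ref - z)
        if step in rec_set:
            zs[ri] = z
            forces[ri] = f_spring
            ri += 1
        if step == n_steps:
            break
        drift = (f_spring - potential.grad(z)) * (params.dt / params.gamma)
        if noise_scale > 0:
            z = z + drift + noise_scale * rng.standard_normal(n_traces)
        else:
            z = z + drift
    return [
        PullLog(time=times.copy(), z=zs[:, i].copy(), force=forces[:, i].copy())
        for i in range(n_traces)
    ]


def simulate_static(
    potential: ToyPotential,
    protocol: PullingProtocol,
    params: LangevinParams,
    n_steps: int,
    output_stride: int = 1,
) -> PullLog:
    """Dynamics with the restraint reference held at z0 (no pulling).

    Used for equilibrium checks: the long-run coordinate histogram must
    match the Boltzmann density of U + spring.
    """
    z_range = (protocol.z0 - 6.0, protocol.z0 + 6.0)
    _check_stability(potential, protocol, params, z_range)
    rng = np.random.default_rng(params.seed)
    kT_sim = thermal_energy(params.temperature) if params.temperature > 0 else 0.0
    noise_scale = math.sqrt(2.0 * kT_sim * params.dt / params.gamma)
    z = float(sample_equilibrium(potential, protocol, 1, rng, params.temperature)[0])
    ts, zs, fs = [], [], []
    for step in range(n_steps + 1):
        f_spring = protocol.k_s * (protocol.z0 - z)
        if step % output_stride == 0:
            ts.append(step * params.dt)
            zs.append(z)
            fs.append(f_spring)
        drift = (f_spring - potential.grad(z)) * (params.dt / params.gamma)
        z = z + drift + (noise_scale * rng.standard_normal() if noise_scale > 0 else 0.0)
    return PullLog(time=np.array(ts), z=np.array(zs), force=np.array(fs))


# ---------------------------------------------------------------------------
# synthetic lysozyme stand-ins
# ---------------------------------------------------------------------------

_N_RESIDUES = 130
_CYS_SITES = (6, 30, 65, 77, 81, 95, 116, 128)
_DISULFIDE_PAIRS = ((6, 128), (30, 116), (65, 81), (77, 95))
_SPECIAL_RESIDUES = {
    45: "TYR", 49: "ASP", 54: "TYR", 59: "ILE", 62: "ARG", 67: "ASP",
    69: "LYS", 70: "THR", 84: "LEU", 85: "LEU",
}
_SIDECHAIN_OFFSETS = {  # atom name -> (along normal, along binormal, along tangent), A
    "ASP": {"CB": (1.3, 0.6, 0.0), "CG": (2.3, 1.0, 0.0), "OD1": (3.1, 1.6, 0.4), "OD2": (3.1, 0.4, -0.4)},
    "TYR": {"CB": (1.3, 0.6, 0.0), "CG": (2.4, 1.0, 0.0), "CD1": (3.0, 1.8, 0.6), "CD2": (3.0, 0.2, -0.6),
            "CE1": (4.2, 1.8, 0.6), "CE2": (4.2, 0.2, -0.6), "CZ": (4.8, 1.0, 0.0), "OH": (6.1, 1.0, 0.0)},
    "HIS": {"CB": (1.3, 0.6, 0.0), "CG": (2.4, 1.0, 0.0), "ND1": (3.2, 1.8, 0.5), "CD2": (3.2, 0.2, -0.5),
            "CE1": (4.4, 1.5, 0.3), "NE2": (4.4, 0.5, -0.3)},
    "ARG": {"CB": (1.3, 0.6, 0.0), "CG": (2.3, 1.0, 0.0), "CD": (3.3, 1.4, 0.0), "NE": (4.3, 1.8, 0.0),
            "CZ": (5.3, 2.0, 0.0), "NH1": (6.1, 2.6, 0.5), "NH2": (6.1, 1.4, -0.5)},
    "LYS": {"CB": (1.3, 0.6, 0.0), "CG": (2.3, 1.0, 0.0), "CD": (3.3, 1.4, 0.0),
            "CE": (4.3, 1.8, 0.0), "NZ": (5.2, 2.2, 0.0)},
    "THR": {"CB": (1.3, 0.6, 0.0), "OG1": (2.2, 1.4, 0.5), "CG2": (2.2, 0.2, -0.5)},
    "ILE": {"CB": (1.3, 0.6, 0.0), "CG1": (2.3, 1.2, 0.4), "CG2": (2.0, -0.2, -0.6), "CD1": (3.4, 1.6, 0.4)},
    "LEU": {"CB": (1.3, 0.6, 0.0), "CG": (2.3, 1.0, 0.0), "CD1": (3.2, 1.6, 0.5), "CD2": (3.2, 0.4, -0.5)},
    "ALA": {"CB": (1.3, 0.6, 0.0)},
}
_ELEMENT_OF = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _default_ca_curve() -> np.ndarray:
    """130 Calpha positions on a compact toroidal coil, ~3.9 A apart."""
    i = np.arange(_N_RESIDUES)
    phi = 2.0 * np.pi * i / _N_RESIDUES  # once around the major circle
    psi = 2.0 * np.pi * i / 13.0  # ten tube windings
    R, r = 16.0, 8.0
    x = (R + r * np.cos(psi)) * np.cos(phi)
    y = (R + r * np.cos(psi)) * np.sin(phi)
    z = r * np.sin(psi)
    return np.column_stack([x, y, z])


def _local_frames(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tang = np.gradient(ca, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    ref = np.where(np.abs(tang[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    norm = np.cross(tang, ref)
    norm /= np.linalg.norm(norm, axis=1, keepdims=True)
    binorm = np.cross(tang, norm)
    return tang, norm, binorm


def _build_lysozyme(ca: np.ndarray, mutant: bool, chain_id: str = "A") -> Structure:
    """Full-atom synthetic structure from a Calpha trace.

    Backbone (N, CA, C, O) from local frames; side chains for the residues
    the analyses address; SG atoms of disulfide-bonded cysteines placed
    pairwise at 2.05 A bond geometry.
    """
    tang, norm, binorm = _local_frames(ca)
    sequence = {}
    for rid in range(1, _N_RESIDUES + 1):
        if rid in _CYS_SITES:
            sequence[rid] = "CYS"
        elif rid in _SPECIAL_RESIDUES:
            sequence[rid] = _SPECIAL_RESIDUES[rid]
        else:
            sequence[rid] = "ALA" if rid % 2 else "GLY"
    if mutant:
        sequence[67] = "HIS"
    sg_pos: dict[int, np.ndarray] = {}
    for ra, rb in _DISULFIDE_PAIRS:
        pa, pb = ca[ra - 1], ca[rb - 1]
        u = pb - pa
        u /= np.linalg.norm(u)
        mid = (pa + pb) / 2.0
        sg_pos[ra] = mid - 1.025 * u
        sg_pos[rb] = mid + 1.025 * u
    atoms: list[AtomRecord] = []
    serial = 1

    def add(name: str, rid: int, resname: str, pos: np.ndarray) -> None:
        nonlocal serial
        atoms.append(
            AtomRecord(
                serial=serial,
                atom_name=name,
                residue_name=resname,
                residue_id=rid,
                chain_id=chain_id,
                element=_ELEMENT_OF[name[0]] if name[0] in _ELEMENT_OF else name[0],
                position=pos,
            )
        )
        serial += 1

    for rid in range(1, _N_RESIDUES + 1):
        i = rid - 1
        resname = sequence[rid]
        t, n, b = tang[i], norm[i], binorm[i]
        add("N", rid, resname, ca[i] - 1.2 * t + 0.5 * n)
        add("CA", rid, resname, ca[i])
        add("C", rid, resname, ca[i] + 1.2 * t + 0.5 * n)
        add("O", rid, resname, ca[i] + 1.3 * t + 0.5 * n + 1.23 * b)
        offsets = _SIDECHAIN_OFFSETS.get(resname, {})
        for name, (dn, db, dt) in offsets.items():
            add(name, rid, resname, ca[i] + dn * n + db * b + dt * t)
        if resname == "CYS":
            add("CB", rid, resname, ca[i] + 1.3 * n + 0.6 * b)
            add("SG", rid, resname, sg_pos[rid])
    title = "synthetic stand-in: human lysozyme" + (" D67H variant" if mutant else "")
    return Structure(atoms=atoms, title=title)


def synthetic_hl_structure(mutant: bool = False) -> Structure:
    """Deterministic synthetic stand-in for the lysozyme crystal structure.

    Generated geometry encoding the published residue-level facts (130
    residues, the four disulfide bridges, the pocket and guard residues,
    His at position 67 in the variant); NOT crystallographic coordinates.
    """
    return _build_lysozyme(_default_ca_curve(), mutant=mutant)


def synthetic_hl_pair(
    target_backbone_rmsd: float = 1.87, seed: int = 0
) -> tuple[Structure, Structure]:
    """Wild-type / variant stand-in pair at a prescribed backbone RMSD.

    The variant's Calpha trace is the wild type's plus a smooth random
    displacement field, amplified threefold in the flexible 55-80 loop
    region, with net translation/rotation projected out and the amplitude
    iterated until the Kabsch-fitted backbone RMSD matches
    ``target_backbone_rmsd`` (default: the published 1.87 A difference
    between the two crystals).
    """
    ca = _default_ca_curve()
    wild = _build_lysozyme(ca, mutant=False)
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(ca.shape)
    # smooth along the chain so the displacement is a plausible loop motion
    kernel = np.array([0.25, 0.5, 0.25])
    for ax in range(3):
        raw[:, ax] = np.convolve(raw[:, ax], kernel, mode="same")
    weight = np.ones(_N_RESIDUES)
    weight[54:80] = 3.0
    disp = raw * weight[:, None]
    disp = _remove_rigid_modes(ca, disp)
    wild_bb = _backbone_coords(wild)
    scale = target_backbone_rmsd / _fitted_backbone_rmsd(ca, disp, wild_bb)
    for _ in range(4):  # secant-free fixed point; converges in 2-3 steps
        r = _fitted_backbone_rmsd(ca, scale * disp, wild_bb)
        scale *= target_backbone_rmsd / r
    variant = _build_lysozyme(ca + scale * disp, mutant=True)
    return wild, variant


def _backbone_coords(struct: Structure) -> np.ndarray:
    from .structures import select

    return struct.coords[select(struct, "backbone").as_array()]


def _fitted_backbone_rmsd(ca: np.ndarray, disp: np.ndarray, ref_bb: np.ndarray) -> float:
    mob = _backbone_coords(_build_lysozyme(ca + disp, mutant=True))
    return kabsch_superpose(mob, ref_bb)[2]


def _remove_rigid_modes(coords: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Project translations and infinitesimal rotations out of a displacement field."""
    c = coords - coords.mean(axis=0)
    n = coords.shape[0]
    modes = []
    for ax in range(3):
        m = np.zeros((n, 3))
        m[:, ax] = 1.0
        modes.append(m.ravel())
    for ax in range(3):
        omega = np.zeros(3)
        omega[ax] = 1.0
        modes.append(np.cross(omega, c).ravel())
    d = disp.ravel().copy()
    basis = []
    for m in modes:
        for b in basis:
            m = m - (m @ b) * b
        m /= np.linalg.norm(m)
        basis.append(m)
    for b in basis:
        d -= (d @ b) * b
    return d.reshape(n, 3)


# ---------------------------------------------------------------------------
# mock trajectory generator
# ---------------------------------------------------------------------------

@dataclass
class MockTrajectorySpec:
    """Recipe for a mock trajectory with recorded ground truth.

    Positional noise is an Ornstein-Uhlenbeck process per atom component
    (RMS ``noise_amplitude``, correlation time ``correlation_time_ns``),
    amplified ``loop_multiplier``-fold in ``loop_residues``. If
    ``target_mean_opening`` is set, the loop residues are rigidly displaced
    along the opening axis so the Calpha distance of ``opening_pair`` is
    drawn i.i.d. per frame from Normal(target, ``opening_sd``). If
    ``water_target`` is set, a Poisson(``water_target``) number of waters
    is placed uniformly inside ``water_radius`` of the center atom each
    frame, the rest of the water slots parked far away.
    """

    reference: Structure
    n_frames: int = 500
    frame_interval: float = 5.0  # ps
    noise_amplitude: float = DEFAULT_NOISE_AMPLITUDE_A
    loop_residues: tuple[int, ...] = tuple(range(65, 78))  # flexible loop
    loop_multiplier: float = DEFAULT_LOOP_MULTIPLIER
    correlation_time_ns: float = DEFAULT_CORRELATION_TIME_NS
    opening_pair: tuple[tuple[str, int], tuple[str, int]] = (("A", 70), ("A", 49))
    target_mean_opening: float | None = None
    opening_sd: float = 1.0
    water_target: float | None = None
    water_center: tuple[str, int, str] = ("A", 65, "SG")
    water_radius: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.noise_amplitude < 0 or self.loop_multiplier < 0:
            raise ConfigurationError("amplitudes must be non-negative")
        if self.opening_sd < 0:
            raise ConfigurationError("opening_sd must be non-negative")


def generate_mock_trajectory(spec: MockTrajectorySpec) -> tuple[Trajectory, dict]:
    """Build a mock trajectory and its ground-truth record.

    Returns ``(trajectory, truth)`` where ``truth`` holds every configured
    quantity (true opening mean/sd, expected fold classification by the
    20 A rule, water target) so tests recover parameters without reaching
    into the generator.
    """
    ref = spec.reference
    rng = np.random.default_rng(spec.seed)
    base = ref.coords
    n_atoms = len(ref)
    resid = np.array([a.residue_id for a in ref.atoms])
    loop_mask = np.isin(resid, spec.loop_residues)
    if spec.target_mean_opening is not None and not loop_mask.any():
        raise ConfigurationError("loop residues absent from reference structure")
    sigma = np.full(n_atoms, spec.noise_amplitude)
    sigma[loop_mask] *= spec.loop_multiplier

    dt_ns = spec.frame_interval / 1000.0
    phi = math.exp(-dt_ns / spec.correlation_time_ns) if spec.correlation_time_ns > 0 else 0.0
    innov = math.sqrt(1.0 - phi**2)

    opening_axis = None
    d_ref = None
    if spec.target_mean_opening is not None:
        (ch_a, ra), (ch_b, rb) = spec.opening_pair
        ia = ref.atom_index(ch_a, ra, "CA")
        ib = ref.atom_index(ch_b, rb, "CA")
        if not loop_mask[ia]:
            raise ConfigurationError(
                f"opening residue {ra} must belong to the displaced loop"
            )
        axis = base[ia] - base[ib]
        d_ref = float(np.linalg.norm(axis))
        opening_axis = axis / d_ref

    frames = np.empty((spec.n_frames, n_atoms, 3))
    noise = rng.standard_normal((n_atoms, 3)) * sigma[:, None]  # stationary start
    openings = (
        rng.normal(spec.target_mean_opening, spec.opening_sd, spec.n_frames)
        if spec.target_mean_opening is not None
        else None
    )
    for f in range(spec.n_frames):
        if f > 0:
            noise = phi * noise + innov * rng.standard_normal((n_atoms, 3)) * sigma[:, None]
        frames[f] = base + noise
        if openings is not None:
            frames[f, loop_mask] += (openings[f] - d_ref) * opening_axis

    atom_table = list(ref.atoms)
    if spec.water_target is not None:
        if spec.water_target < 0:
            raise ConfigurationError("water_target must be non-negative")
        n_slots = int(spec.water_target + 6 * math.sqrt(max(spec.water_target, 1.0)) + 8)
        ci = ref.atom_index(*spec.water_center)
        park = base.mean(axis=0) + np.array([120.0, 0.0, 0.0])
        wat_frames = np.empty((spec.n_frames, n_slots, 3))
        counts = np.minimum(rng.poisson(spec.water_target, spec.n_frames), n_slots)
        for f in range(spec.n_frames):
            k = counts[f]
            wat_frames[f] = park + np.arange(n_slots)[:, None] * np.array([4.0, 0.0, 0.0])
            if k:
                direc = rng.standard_normal((k, 3))
                direc /= np.linalg.norm(direc, axis=1, keepdims=True)
                radii = spec.water_radius * rng.random(k) ** (1.0 / 3.0)
                wat_frames[f, :k] = frames[f, ci] + direc * radii[:, None]
        serial0 = max(a.serial for a in atom_table)
        for w in range(n_slots):
            atom_table.append(
                AtomRecord(
                    serial=serial0 + w + 1,
                    atom_name="O",
                    residue_name="HOH",
                    residue_id=_N_RESIDUES + 1 + w,
                    chain_id="W",
                    element="O",
                    position=park,
                )
            )
        frames = np.concatenate([frames, wat_frames], axis=1)

    traj = Trajectory(
        atom_table=atom_table, frames=frames, frame_interval=spec.frame_interval
    )
    truth = {
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "frame_interval_ps": spec.frame_interval,
        "noise_amplitude_A": spec.noise_amplitude,
        "loop_residues": list(spec.loop_residues),
        "loop_multiplier": spec.loop_multiplier,
        "correlation_time_ns": spec.correlation_time_ns,
        "opening": None
        if spec.target_mean_opening is None
        else {
            "pair": [list(p) for p in spec.opening_pair],
            "target_mean_A": spec.target_mean_opening,
            "sd_A": spec.opening_sd,
            "expected_classification": "unfolded"
            if spec.target_mean_opening > 20.0
            else "folded",
        },
        "water": None
        if spec.water_target is None
        else {
            "target_mean_count": spec.water_target,
            "radius_A": spec.water_radius,
            "center": list(spec.water_center),
        },
    }
    return traj, truth


def generate_dissociating_dimer(
    monomer: Structure,
    separation: float = 30.0,
    drift: float = 2.0,  # A/ns
    onset_ns: float | None = 28.0,
    duration_ns: float = 100.0,
    frame_interval: float = 250.0,  # ps
    noise_amplitude: float = 0.05,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Two-chain trajectory whose COM separation drifts apart after an onset.

    Chain A is the monomer; chain B a translated copy. Separation is
    constant (plus noise) until ``onset_ns``, then grows linearly at
    ``drift`` A/ns. ``onset_ns`` of None or beyond the trajectory end, or
    zero drift, yields a stable dimer. Truth records the onset.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_ns * 1000.0 / frame_interval)) + 1
    times = np.arange(n_frames) * frame_interval / 1000.0
    offset = np.array([separation, 0.0, 0.0])

    def rechain(atoms: Sequence[AtomRecord], chain: str, shift: np.ndarray, s0: int) -> list[AtomRecord]:
        return [
            AtomRecord(
                serial=s0 + i,
                atom_name=a.atom_name,
                residue_name=a.residue_name,
                residue_id=a.residue_id,
                chain_id=chain,
                element=a.element,
                position=a.position + shift,
            )
            for i, a in enumerate(atoms, start=1)
        ]

    chain_a = rechain(monomer.atoms, "A", np.zeros(3), 0)
    chain_b = rechain(monomer.atoms, "B", offset, len(chain_a))
    atom_table = chain_a + chain_b
    base = np.array([a.position for a in atom_table])
    na = len(chain_a)
    frames = np.empty((n_frames, len(atom_table), 3))
    dissociating = onset_ns is not None and drift > 0 and onset_ns < times[-1]
    for f, t in enumerate(times):
        frames[f] = base + rng.standard_normal(base.shape) * noise_amplitude
        if dissociating and t > onset_ns:
            frames[f, na:, 0] += drift * (t - onset_ns)
    traj = Trajectory(atom_table=atom_table, frames=frames, frame_interval=frame_interval)
    truth = {
        "seed": seed,
        "separation_A": separation,
        "drift_A_per_ns": drift,
        "onset_ns": onset_ns if dissociating else None,
        "expected_verdict": "dissociated" if dissociating else "stable",
    }
    return traj, truth


def write_ground_truth(truth: dict, stream: IO[str]) -> None:
    """Sidecar JSON ground truth, so tests never re-derive it internally."""
    json.dump(truth, stream, indent=2, sort_keys=True)
    stream.write("\n")
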