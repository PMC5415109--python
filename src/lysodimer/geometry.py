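"""Distance-based trajectory analyses.

Guard-interaction (minimum cross-group) distance series, pocket hydration
shells, aromatic ring-centroid separations, mass-weighted center-of-mass
separation with a sustained-crossing dissociation rule, and the
loop-opening histogram / folded-unfolded classifier.

All distances use the orthorhombic minimum-image convention when the
trajectory carries a box; raw Euclidean distances otherwise.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
from scipy import stats

from .structures import EmptySelectionError, Selection, Structure, Trajectory, select

log = logging.getLogger("lysodimer")

UNFOLD_THRESHOLD_A = 20.0  # loop-opening distance above which a conformer counts as unfolded
DISSOCIATION_THRESHOLD_A = 10.0  # COM separation increase that terminates a dimer
HYDRATION_RADII_A = (3.0, 4.0, 5.0, 6.0)
HISTOGRAM_BIN_WIDTH_A = 0.5

# heavy-atom sets used for "element pair" contact distances between guard residues
SIDECHAIN_CONTACT_ATOMS = {
    ("ASP", "O"): ("OD1", "OD2"),
    ("GLU", "O"): ("OE1", "OE2"),
    ("TYR", "O"): ("OH",),
    ("THR", "O"): ("OG1",),
    ("SER", "O"): ("OG",),
    ("ARG", "N"): ("NE", "NH1", "NH2"),
    ("LYS", "N"): ("NZ",),
    ("HIS", "N"): ("ND1", "NE2"),
}

AROMATIC_RING_ATOMS = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098,
    "MG": 24.305, "CA": 40.078, "FE": 55.845, "ZN": 65.38,
}


class UnknownElementError(KeyError):
    """An element has no entry in the mass table."""


@dataclass
class DistanceSeries:
    """Per-frame distance in Angstrom; time in ns."""

    time: np.ndarray
    distance: np.ndarray
    pair_label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if self.time.shape != self.distance.shape:
            raise ValueError("time and distance must have equal lengths")
        if np.any(self.distance < 0):
            raise ValueError("distances must be non-negative")

    def window_mean(self, window: tuple[int, int] | None = None) -> float:
        sl = slice(*window) if window is not None else slice(None)
        return float(np.mean(self.distance[sl]))


@dataclass
class HydrationProfile:
    """Mean +/- sd water count per probe radius over an averaging window."""

    radii: np.ndarray
    mean_count: np.ndarray
    sd_count: np.ndarray
    center_label: str = ""
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.mean_count = np.asarray(self.mean_count, dtype=float)
        self.sd_count = np.asarray(self.sd_count, dtype=float)
        if not (len(self.radii) == len(self.mean_count) == len(self.sd_count)):
            raise ValueError("radii/mean/sd must have equal lengths")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly ascending")
        if np.any(np.diff(self.mean_count) < -1e-9):
            raise ValueError("mean counts must be non-decreasing with radius")
        if np.any(self.mean_count < 0) or np.any(self.sd_count < 0):
            raise ValueError("counts must be non-negative")

    def to_dict(self) -> dict:
        return {
            "center": self.center_label,
            "window": list(self.window) if self.window else None,
            "radii_A": self.radii.tolist(),
            "mean_count": self.mean_count.tolist(),
            "sd_count": self.sd_count.tolist(),
        }


@dataclass
class GaussianSummary:
    """Histogram plus moment (maximum-likelihood Gaussian) mean and sd."""

    mean: float
    sd: float
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray
    gaussian_fit_ok: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if int(np.sum(self.counts)) != self.n:
            raise ValueError("histogram counts must sum to n")


@dataclass
class DimerStabilityReport:
    """Dissociation verdict for a dimer COM-separation series.

    ``dissociation_time`` is the first sustained crossing of
    baseline + threshold (the event after which a run is terminated);
    ``onset_time`` backtracks from that crossing to the last frame still
    inside the baseline noise band, i.e. the estimated departure time.
    """

    com_series: DistanceSeries
    verdict: str  # "stable" | "dissociated"
    dissociation_time: float | None
    onset_time: float | None
    threshold: float

    def __post_init__(self) -> None:
        if self.verdict not in ("stable", "dissociated"):
            raise ValueError(f"invalid verdict {self.verdict!r}")
        if (self.verdict == "dissociated") != (self.dissociation_time is not None):
            raise ValueError("dissociation_time must be set iff verdict is 'dissociated'")

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "dissociation_time_ns": self.dissociation_time,
            "onset_time_ns": self.onset_time,
            "threshold_A": self.threshold,
        }


# ---------------------------------------------------------------------------
# distance primitives
# ---------------------------------------------------------------------------

def minimum_image_displacement(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the orthorhombic minimum image."""
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def pairwise_min_distance(
    xyz_a: np.ndarray, xyz_b: np.ndarray, box: np.ndarray | None = None
) -> float:
    """Minimum distance over the cross-product of two coordinate groups."""
    delta = xyz_a[:, None, :] - xyz_b[None, :, :]
    delta = minimum_image_displacement(delta, box)
    return float(np.sqrt(np.min(np.sum(delta**2, axis=-1))))


def sidechain_contact_selection(
    obj: Structure | Trajectory, chain: str, residue_id: int, element: str
) -> Selection:
    """Side-chain donor/acceptor atoms of one residue by contact element.

    E.g. the oxygen set of an ASP is (OD1, OD2); the nitrogen set of an ARG
    is (NE, NH1, NH2) — the atoms over which "O-O" / "N-O" contact distances
    are minimised.
    """
    atoms = obj.atoms
    resname = None
    for a in atoms:
        if a.chain_id == chain and a.residue_id == residue_id:
            resname = a.residue_name
            break
    if resname is None:
        raise EmptySelectionError(f"residue {chain}:{residue_id} not found")
    names = SIDECHAIN_CONTACT_ATOMS.get((resname, element.upper()))
    if names is None:
        raise ValueError(f"no {element}-contact atom set defined for {resname}")
    idx = [
        i
        for i, a in enumerate(atoms)
        if a.chain_id == chain and a.residue_id == residue_id and a.atom_name in names
    ]
    if not idx:
        raise EmptySelectionError(
            f"residue {chain}:{residue_id} ({resname}) has none of {names}"
        )
    return Selection(indices=tuple(idx), label=f"{resname}{residue_id}:{'/'.join(names)}")


def pair_distance_series(
    traj: Trajectory,
    group_a: Selection,
    group_b: Selection,
    label: str | None = None,
) -> DistanceSeries:
    """Per-frame minimum distance between two atom groups.

    The distance is the minimum over the cross-product of the groups, which
    is the standard contact definition when a pair is specified by element
    ("N-O") rather than by named atoms.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise EmptySelectionError("both groups must contain atoms")
    ia = group_a.as_array()
    ib = group_b.as_array()
    d = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d[f] = pairwise_min_distance(traj.frames[f][ia], traj.frames[f][ib], traj.box)
    return DistanceSeries(
        time=traj.times_ns(),
        distance=d,
        pair_label=label or f"{group_a.label}-{group_b.label}",
    )


def calpha_pair_series(
    traj: Trajectory, res_a: tuple[str, int], res_b: tuple[str, int]
) -> DistanceSeries:
    """Calpha-Calpha distance series between two residues (loop opening)."""
    sa = select(traj, ("atom", res_a[0], res_a[1], "CA"))
    sb = select(traj, ("atom", res_b[0], res_b[1], "CA"))
    return pair_distance_series(
        traj, sa, sb, label=f"CA {res_a[0]}:{res_a[1]}-{res_b[0]}:{res_b[1]}"
    )


# ---------------------------------------------------------------------------
# pocket hydration
# ---------------------------------------------------------------------------

def _water_oxygen_indices(traj: Trajectory) -> np.ndarray:
    try:
        return select(traj, "waters").as_array()
    except EmptySelectionError:
        return np.array([], dtype=int)


def count_pocket_waters(
    traj: Trajectory,
    center: Selection,
    radius: float,
    window: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Mean and sd of the water count inside a probe sphere.

    The sphere follows the center atom's current position; waters are
    represented by their oxygen; minimum-image distances when a box is set.
    A system without waters yields (0, 0) with a warning.
    """
    if len(center) != 1:
        raise ValueError("center must resolve to exactly one atom")
    if radius <= 0:
        raise ValueError("radius must be positive")
    wat = _water_oxygen_indices(traj)
    if wat.size == 0:
        warnings.warn("no water molecules in system; hydration count is zero")
        return 0.0, 0.0
    ci = center.indices[0]
    sl = slice(*window) if window is not None else slice(None)
    frames = traj.frames[sl]
    delta = frames[:, wat, :] - frames[:, ci : ci + 1, :]
    delta = minimum_image_displacement(delta, traj.box)
    within = np.sum(delta**2, axis=-1) <= radius**2
    counts = within.sum(axis=1)
    return float(counts.mean()), float(counts.std())


def hydration_shell_scan(
    traj: Trajectory,
    center: Selection,
    radii: Sequence[float] = HYDRATION_RADII_A,
    window: tuple[int, int] | None = None,
) -> HydrationProfile:
    """Water counts at several probe radii (sorted ascending on output)."""
    rs = sorted(float(r) for r in radii)
    means, sds = [], []
    for r in rs:
        m, s = count_pocket_waters(traj, center, r, window)
        means.append(m)
        sds.append(s)
    return HydrationProfile(
        radii=np.array(rs),
        mean_count=np.array(means),
        sd_count=np.array(sds),
        center_label=center.label,
        window=window,
    )


# ---------------------------------------------------------------------------
# aromatic rings, centers of mass
# ---------------------------------------------------------------------------

def _ring_indices(obj: Structure | Trajectory, chain: str, residue_id: int) -> np.ndarray:
    atoms = obj.atoms
    resname = None
    for a in atoms:
        if a.chain_id == chain and a.residue_id == residue_id:
            resname = a.residue_name
            break
    if resname is None:
        raise EmptySelectionError(f"residue {chain}:{residue_id} not found")
    ring = AROMATIC_RING_ATOMS.get(resname)
    if ring is None:
        raise ValueError(f"{resname}{residue_id} is not an aromatic (TYR/PHE/HIS) residue")
    idx = []
    for name in ring:
        found = [
            i
            for i, a in enumerate(atoms)
            if a.chain_id == chain and a.residue_id == residue_id and a.atom_name == name
        ]
        if not found:
            raise EmptySelectionError(
                f"ring atom {name} missing from {resname}{residue_id} (chain {chain})"
            )
        idx.extend(found)
    return np.array(idx, dtype=int)


def ring_centroid_distance_series(
    traj: Trajectory, res_a: tuple[str, int], res_b: tuple[str, int]
) -> DistanceSeries:
    """Distance between unweighted centroids of two aromatic rings (pi-stacking)."""
    ia = _ring_indices(traj, *res_a)
    ib = _ring_indices(traj, *res_b)
    ca = traj.frames[:, ia, :].mean(axis=1)
    cb = traj.frames[:, ib, :].mean(axis=1)
    delta = minimum_image_displacement(ca - cb, traj.box)
    return DistanceSeries(
        time=traj.times_ns(),
        distance=np.linalg.norm(delta, axis=1),
        pair_label=f"ring {res_a[0]}:{res_a[1]}-{res_b[0]}:{res_b[1]}",
    )


def _chain_masses_and_indices(traj: Trajectory, chain: str) -> tuple[np.ndarray, np.ndarray]:
    idx = [i for i, a in enumerate(traj.atom_table) if a.chain_id == chain]
    if not idx:
        raise EmptySelectionError(f"chain {chain!r} is empty")
    masses = []
    for i in idx:
        el = traj.atom_table[i].element
        try:
            masses.append(ATOMIC_MASSES[el])
        except KeyError as exc:
            raise UnknownElementError(f"no atomic mass for element {el!r}") from exc
    return np.array(idx, dtype=int), np.array(masses)


def com_separation_series(traj: Trajectory, chain_a: str, chain_b: str) -> DistanceSeries:
    """Mass-weighted centroid separation of two chains per frame."""
    ia, ma = _chain_masses_and_indices(traj, chain_a)
    ib, mb = _chain_masses_and_indices(traj, chain_b)
    coma = np.einsum("fij,i->fj", traj.frames[:, ia, :], ma) / ma.sum()
    comb = np.einsum("fij,i->fj", traj.frames[:, ib, :], mb) / mb.sum()
    delta = minimum_image_displacement(coma - comb, traj.box)
    return DistanceSeries(
        time=traj.times_ns(),
        distance=np.linalg.norm(delta, axis=1),
        pair_label=f"COM {chain_a}-{chain_b}",
    )


def classify_dimer_stability(
    com_series: DistanceSeries,
    baseline_window: tuple[int, int],
    threshold: float = DISSOCIATION_THRESHOLD_A,
) -> DimerStabilityReport:
    """Dissociation verdict by the sustained-crossing rule.

    The dimer counts as dissociated iff the separation exceeds
    (baseline mean + threshold) at some frame and never returns below that
    limit afterwards; a transient spike is not dissociation.
    ``dissociation_time`` is the first frame of that final excursion.
    ``onset_time`` is the last preceding frame still within the baseline
    noise band (mean + 3 sd), the estimated departure from the bound state.
    """
    b0, b1 = baseline_window
    if b0 >= b1 or b0 < 0 or b1 > len(com_series.distance):
        raise ValueError(f"invalid baseline window {baseline_window}")
    d = com_series.distance
    t = com_series.time
    baseline = float(np.mean(d[b0:b1]))
    baseline_sd = float(np.std(d[b0:b1]))
    limit = baseline + threshold
    below = np.nonzero(d <= limit)[0]
    last_below = int(below[-1]) if below.size else -1
    if last_below == len(d) - 1:
        return DimerStabilityReport(com_series, "stable", None, None, threshold)
    cross = last_below + 1  # first frame of the final sustained excursion
    band = baseline + 3.0 * max(baseline_sd, 1e-12)
    in_band = np.nonzero(d[: cross + 1] <= band)[0]
    onset = float(t[in_band[-1]]) if in_band.size else float(t[0])
    return DimerStabilityReport(
        com_series, "dissociated", float(t[cross]), onset, threshold
    )


# ---------------------------------------------------------------------------
# loop-opening histogram and classifiers
# ---------------------------------------------------------------------------

def opening_histogram(
    series: DistanceSeries | np.ndarray, bin_width: float = HISTOGRAM_BIN_WIDTH_A
) -> GaussianSummary:
    """Histogram of a distance series with a moment-based Gaussian summary.

    Mean and sd are the sample moments (the maximum-likelihood Gaussian
    fit). Strong non-Gaussianity — e.g. a bimodal mixture of two
    conformational states — is flagged via the sample skewness and excess
    kurtosis (|skew| > 0.5 or |kurtosis| > 1 clears ``gaussian_fit_ok``).
    """
    samples = series.distance if isinstance(series, DistanceSeries) else np.asarray(series, float)
    if samples.size < 2:
        raise ValueError("histogram requires at least 2 samples")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mean = float(samples.mean())
    sd = float(samples.std())
    if sd == 0:
        edges = np.array([samples[0] - bin_width / 2, samples[0] + bin_width / 2])
        counts = np.array([samples.size])
        return GaussianSummary(mean, 0.0, int(samples.size), edges, counts)
    lo = np.floor(samples.min() / bin_width) * bin_width
    hi = np.ceil(samples.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(samples, bins=edges)
    skew = float(stats.skew(samples))
    kurt = float(stats.kurtosis(samples))  # excess kurtosis
    ok = abs(skew) <= 0.5 and abs(kurt) <= 1.0
    note = "" if ok else f"poor Gaussian fit (skew={skew:.2f}, excess kurtosis={kurt:.2f})"
    return GaussianSummary(mean, sd, int(samples.size), edges, counts, ok, note)


def classify_unfolded(mean_distance: float, threshold: float = UNFOLD_THRESHOLD_A) -> str:
    """"unfolded" iff the window-mean opening distance strictly exceeds threshold."""
    return "unfolded" if mean_distance > threshold else "folded"


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def write_distance_series_tsv(series: DistanceSeries, stream: IO[str]) -> None:
    stream.write("time_ns\tdistance_A\n")
    for t, d in zip(series.time, series.distance):
        stream.write(f"{t:.6g}\t{d:.6f}\n")


def write_json_report(obj: dict, stream: IO[str]) -> None:
    json.dump(obj, stream, indent=2, sort_keys=True)
    stream.write("\n")
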