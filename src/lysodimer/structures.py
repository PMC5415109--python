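"""PDB structures, multi-model trajectories and atom selections.

Fixed-column PDB (v3) reading and writing, with the policies needed for
reproducible trajectory analysis: alternate locations resolved by highest
occupancy (lexicographically smallest code on ties), hydrogens parsed but
excluded from analysis selections, insertion codes rejected, and
multi-model files reordered onto the atom table of the first model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

log = logging.getLogger("lysodimer")

# residue names recognised as water; only the oxygen site represents the molecule
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SPC"})
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})
# hydrophobic pocket at the lysozyme alpha/beta domain interface
POCKET_RESIDUES = (54, 59, 65, 81, 84, 85)

DEFAULT_FRAME_INTERVAL_PS = 5.0  # trajectory save interval, ps
DISULFIDE_CUTOFF_A = 2.5  # SG-SG bond-detection cutoff, Angstrom


class PDBParseError(ValueError):
    """A fixed-column record could not be parsed; message names the line."""


class EmptyInputError(ValueError):
    """Stream contained no atoms."""


class EmptySelectionError(ValueError):
    """A selection query resolved to zero atoms."""


class TrajectoryStructureError(ValueError):
    """Models in a multi-model file have inconsistent atom tables."""


class MappingError(ValueError):
    """Atoms of two structures could not be matched one-to-one."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a parsed model; positions in Angstrom."""

    serial: int
    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str
    position: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.residue_id < 1:
            raise ValueError(f"atom {self.atom_name}: residue_id must be >= 1")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESNAMES

    def key(self) -> tuple[str, int, str]:
        """Identity key used for cross-structure atom matching."""
        return (self.chain_id, self.residue_id, self.atom_name)


@dataclass
class Structure:
    """An ordered atom list; after alt-loc resolution keys are unique."""

    atoms: list[AtomRecord]
    title: str = ""
    source_model_count: int = 1

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyInputError("structure must contain at least one atom")
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            k = a.key()
            if k in seen:
                raise ValueError(f"duplicate atom after alt-loc resolution: {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def residue_ids(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue_id) pairs."""
        out: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            k = (a.chain_id, a.residue_id)
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out

    def atom_index(self, chain_id: str, residue_id: int, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.key() == (chain_id, residue_id, atom_name):
                return i
        raise KeyError((chain_id, residue_id, atom_name))


@dataclass
class Trajectory:
    """Frames over a fixed atom table; frame interval in ps, box in Angstrom."""

    atom_table: list[AtomRecord]
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.atom_table):
            raise TrajectoryStructureError(
                f"frames of shape {self.frames.shape} do not match "
                f"{len(self.atom_table)}-atom table"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be a positive orthorhombic 3-vector")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times_ns(self) -> np.ndarray:
        """Frame times in ns (frame index x interval)."""
        return np.arange(self.n_frames) * (self.frame_interval / 1000.0)

    @property
    def atoms(self) -> list[AtomRecord]:
        # lets selection code treat Structure and Trajectory uniformly
        return self.atom_table


@dataclass(frozen=True)
class Selection:
    """Ordered, unique atom indices into a Structure/Trajectory atom table."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("selection indices must be ascending")
        if idx and idx[0] < 0:
            raise ValueError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        alt_loc = line[16:17].strip()
        residue_name = line[17:20].strip() or line[17:21].strip()
        chain_id = line[21:22].strip() or " "
        residue_id = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if icode:
        raise PDBParseError(
            f"insertion code {icode!r} at line {lineno} is not supported"
        )
    if not element:
        element = _element_from_name(atom_name)
    return AtomRecord(
        serial=serial,
        atom_name=atom_name,
        residue_name=residue_name,
        residue_id=residue_id,
        chain_id=chain_id,
        element=element,
        position=np.array([x, y, z]),
        alt_loc=alt_loc,
        occupancy=occupancy,
    )


def _element_from_name(atom_name: str) -> str:
    """Infer element when columns 77-78 are absent (PDB v3 naming)."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():  # e.g. 1HB2
        return "H"
    if len(name) >= 2 and name[:2].upper() in ("FE", "ZN", "MG", "NA", "CL", "MN", "CU", "CA"):
        # two-letter elements only when the name cannot be a remoteness code
        if name[:2].upper() in ("NA", "CL", "FE", "ZN", "MG", "MN", "CU") and len(name) <= 2:
            return name[:2].upper()
    return name[0].upper()


def _resolve_alt_locs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one location per site: highest occupancy, ties to the smallest code."""
    best: dict[tuple[str, int, str], AtomRecord] = {}
    order: list[tuple[str, int, str]] = []
    for a in atoms:
        k = a.key()
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            if (a.occupancy, _alt_rank(a.alt_loc)) > (b.occupancy, _alt_rank(b.alt_loc)):
                best[k] = a
    return [best[k] for k in order]


def _alt_rank(code: str) -> float:
    # higher is better; empty code outranks any letter, else smaller letter wins
    if not code:
        return 0.0
    return -ord(code)


def _iter_model_atoms(lines: Iterable[str]) -> Iterator[tuple[int, list[AtomRecord]]]:
    """Yield (model_number, atoms) blocks; implicit model 1 if no MODEL cards."""
    current: list[AtomRecord] = []
    model_no = 1
    in_model = False
    any_model_card = False
    for lineno, raw in enumerate(lines, start=1):
        rec = raw.rstrip("\n")
        tag = rec[:6].strip()
        if tag == "MODEL":
            any_model_card = True
            if current:
                yield model_no, current
                current = []
            try:
                model_no = int(rec[6:].split()[0])
            except (ValueError, IndexError):
                model_no += 1
            in_model = True
        elif tag == "ENDMDL":
            yield model_no, current
            current = []
            in_model = False
            model_no += 1
        elif tag in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(rec, lineno))
    if current or not any_model_card:
        if current:
            yield model_no, current


def _read_lines(source: IO[str] | str) -> list[str]:
    if isinstance(source, str):
        return source.splitlines()
    return source.read().splitlines()


def read_pdb(source: IO[str] | str) -> Structure:
    """Parse a PDB stream into a Structure.

    Multi-model files yield the first model; the model count is recorded on
    ``Structure.source_model_count`` and logged. Alternate locations are
    resolved by occupancy.
    """
    lines = _read_lines(source)
    title = ""
    for rec in lines:
        if rec.startswith("TITLE"):
            title = (title + " " + rec[10:].strip()).strip()
    models = list(_iter_model_atoms(lines))
    if not models or not models[0][1]:
        raise EmptyInputError("no ATOM/HETATM records found")
    if len(models) > 1:
        log.warning("multi-model input: using model %d of %d", models[0][0], len(models))
    atoms = _resolve_alt_locs(models[0][1])
    return Structure(atoms=atoms, title=title, source_model_count=len(models))


def read_multi_model_pdb(
    source: IO[str] | str, frame_interval: float = DEFAULT_FRAME_INTERVAL_PS
) -> Trajectory:
    """Parse a MODEL/ENDMDL-delimited stream into a Trajectory.

    All models must share one atom table; models whose atoms are permuted
    relative to the first model are reordered onto model-1 order. The frame
    interval (ps) is caller-supplied metadata.
    """
    lines = _read_lines(source)
    box = None
    for rec in lines:
        if rec.startswith("CRYST1"):
            try:
                box = np.array([float(rec[6:15]), float(rec[15:24]), float(rec[24:33])])
            except ValueError as exc:
                raise PDBParseError(f"malformed CRYST1 record: {exc}") from exc
            if np.any(box <= 0):
                box = None
            break
    models = [(n, _resolve_alt_locs(atoms)) for n, atoms in _iter_model_atoms(lines) if atoms]
    if not models:
        raise EmptyInputError("no ATOM/HETATM records found")
    ref_no, ref_atoms = models[0]
    ref_keys = [a.key() for a in ref_atoms]
    ref_index = {k: i for i, k in enumerate(ref_keys)}
    frames = np.empty((len(models), len(ref_atoms), 3))
    for fi, (model_no, atoms) in enumerate(models):
        if len(atoms) != len(ref_atoms):
            raise TrajectoryStructureError(
                f"model {model_no} has {len(atoms)} atoms, expected {len(ref_atoms)}"
            )
        keys = [a.key() for a in atoms]
        if keys == ref_keys:
            frames[fi] = [a.position for a in atoms]
        else:
            try:
                perm = [ref_index[k] for k in keys]
            except KeyError as exc:
                raise TrajectoryStructureError(
                    f"model {model_no} contains atom {exc.args[0]} absent from model {ref_no}"
                ) from exc
            if len(set(perm)) != len(perm):
                raise TrajectoryStructureError(f"model {model_no} repeats atoms")
            for a, j in zip(atoms, perm):
                frames[fi, j] = a.position
    return Trajectory(
        atom_table=ref_atoms, frames=frames, frame_interval=frame_interval, box=box
    )


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(a: AtomRecord, serial: int) -> str:
    name = a.atom_name
    # standard v3 justification: 1-letter elements start in column 14
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    record = "HETATM" if a.is_water else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4s}{a.alt_loc or ' ':1s}{a.residue_name:<4s}"
        f"{a.chain_id:1s}{a.residue_id:>4d}    "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
    )


def write_pdb(struct: Structure, stream: IO[str]) -> None:
    """Write a Structure as fixed-column PDB (positions to 3 decimals)."""
    if struct.title:
        stream.write(f"TITLE     {struct.title}\n")
    for i, a in enumerate(struct.atoms, start=1):
        stream.write(_format_atom_line(a, i) + "\n")
    stream.write("END\n")


def write_multi_model_pdb(traj: Trajectory, stream: IO[str]) -> None:
    """Write a Trajectory as a multi-model PDB."""
    if traj.box is not None:
        a, b, c = traj.box
        stream.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1\n")
    for fi in range(traj.n_frames):
        stream.write(f"MODEL     {fi + 1:>4d}\n")
        for i, atom in enumerate(traj.atom_table):
            moved = AtomRecord(
                serial=atom.serial,
                atom_name=atom.atom_name,
                residue_name=atom.residue_name,
                residue_id=atom.residue_id,
                chain_id=atom.chain_id,
                element=atom.element,
                position=traj.frames[fi, i],
                alt_loc=atom.alt_loc,
                occupancy=atom.occupancy,
            )
            stream.write(_format_atom_line(moved, i + 1) + "\n")
        stream.write("ENDMDL\n")
    stream.write("END\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select(obj: Structure | Trajectory, query, chain: str | None = None) -> Selection:
    """Resolve a named selection against a Structure or Trajectory atom table.

    ``query`` is one of the strings ``"backbone"``, ``"calpha"``, ``"waters"``,
    ``"pocket"``, or a tuple ``("residue", chain, id)`` /
    ``("atom", chain, id, name)``. Hydrogens are excluded from backbone,
    calpha and pocket selections; waters resolve to their oxygen atom only.
    An optional ``chain`` restricts string queries to one chain.
    """
    atoms = obj.atoms
    idx: list[int] = []
    if isinstance(query, tuple):
        kind = query[0]
        if kind == "residue":
            _, qchain, qid = query
            idx = [
                i
                for i, a in enumerate(atoms)
                if a.chain_id == qchain and a.residue_id == int(qid)
            ]
            label = f"residue {qchain}:{qid}"
        elif kind == "atom":
            _, qchain, qid, qname = query
            idx = [
                i
                for i, a in enumerate(atoms)
                if a.chain_id == qchain and a.residue_id == int(qid) and a.atom_name == qname
            ]
            label = f"atom {qchain}:{qid}:{qname}"
        else:
            raise ValueError(f"unknown selection tuple kind {kind!r}")
    elif query == "backbone":
        idx = [
            i
            for i, a in enumerate(atoms)
            if a.atom_name in BACKBONE_ATOMS and not a.is_hydrogen and not a.is_water
        ]
        label = "backbone"
    elif query == "calpha":
        idx = [
            i
            for i, a in enumerate(atoms)
            if a.atom_name == "CA" and not a.is_hydrogen and not a.is_water
        ]
        label = "calpha"
    elif query == "waters":
        idx = [i for i, a in enumerate(atoms) if a.is_water and a.element == "O"]
        label = "waters"
    elif query == "pocket":
        pocket = set(POCKET_RESIDUES)
        idx = [
            i
            for i, a in enumerate(atoms)
            if a.residue_id in pocket and not a.is_hydrogen and not a.is_water
        ]
        label = "pocket"
    else:
        raise ValueError(f"unknown selection query {query!r}")
    if chain is not None:
        idx = [i for i in idx if atoms[i].chain_id == chain]
        label = f"{label} (chain {chain})"
    if not idx:
        raise EmptySelectionError(f"selection {label!r} resolved to zero atoms")
    return Selection(indices=tuple(idx), label=label)


# ---------------------------------------------------------------------------
# Disulfide annotation
# ---------------------------------------------------------------------------

def find_disulfides(
    struct: Structure, cutoff: float = DISULFIDE_CUTOFF_A
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Detect disulfide bonds as CYS SG pairs within ``cutoff`` Angstrom.

    Greedy nearest-first matching; each SG joins at most one pair; distance
    ties break toward the lower (chain, residue_id). Returns unordered unique
    pairs of (chain, residue_id), each pair sorted, pairs sorted.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sgs = [
        (i, a)
        for i, a in enumerate(struct.atoms)
        if a.residue_name == "CYS" and a.atom_name == "SG"
    ]
    candidates = []
    for n, (i, a) in enumerate(sgs):
        for j, b in sgs[n + 1 :]:
            d = float(np.linalg.norm(a.position - b.position))
            if d <= cutoff:
                ra = (a.chain_id, a.residue_id)
                rb = (b.chain_id, b.residue_id)
                candidates.append((d, min(ra, rb), max(ra, rb)))
    candidates.sort()
    used: set[tuple[str, int]] = set()
    pairs = []
    for _, ra, rb in candidates:
        if ra in used or rb in used:
            continue
        used.update((ra, rb))
        pairs.append((ra, rb))
    return sorted(pairs)


def disulfide_residue_pairs(struct: Structure, cutoff: float = DISULFIDE_CUTOFF_A) -> list[tuple[int, int]]:
    """Disulfide pairs as sorted residue-id tuples (single-chain convenience)."""
    return sorted(tuple(sorted((a[1], b[1]))) for a, b in find_disulfides(struct, cutoff))
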