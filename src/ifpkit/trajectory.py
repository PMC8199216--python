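"""Multi-model PDB trajectory I/O, atom selection and report writing.

The reader understands the fixed-column ``MODEL``/``ENDMDL`` PDB dialect in
which each model is one trajectory frame of the same atom roster (hydrogens
explicit). Residue numbering is taken as author numbering, 1-based, exactly
as written in the file; no renumbering or topology inference is performed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from ifpkit.errors import FormatError, SelectionError

__all__ = [
    "Atom",
    "Trajectory",
    "AnalysisConfig",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "resolve_selection",
    "write_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Atom:
    """Identity of one atom; coordinates live in :attr:`Trajectory.coords`."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str

    def __post_init__(self):
        if not self.element:
            raise FormatError(f"atom serial {self.serial}: empty element symbol")


@dataclass
class Trajectory:
    """Ordered frames of a fixed atom roster.

    Attributes
    ----------
    atoms : list of Atom
    coords : ndarray, shape (n_frames, n_atoms, 3), Angstrom
    frame_labels : optional sequence of time stamps (ns)
    """

    atoms: list
    coords: np.ndarray
    frame_labels: Optional[Sequence[float]] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise FormatError("trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise FormatError(
                f"coords cover {self.coords.shape[1]} atoms but roster has {len(self.atoms)}"
            )
        if self.frame_labels is not None and len(self.frame_labels) != self.n_frames:
            raise FormatError("frame_labels length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i`` as an (n_atoms, 3) array."""
        return self.coords[i]


def _parse_atom_line(line: str, lineno: int):
    """Parse one ATOM/HETATM record (fixed columns). Returns (Atom, xyz, altloc, occ)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip() or " "
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: unparseable ATOM record field ({exc})") from exc
    occ_field = line[54:60].strip()
    occ = float(occ_field) if occ_field else 1.0
    element = line[76:78].strip() if len(line) >= 77 else ""
    if not element:
        # fall back on the leading alphabetic part of the atom name
        element = "".join(c for c in name if c.isalpha())[:1].upper() or "X"
    atom = Atom(serial=serial, name=name, element=element, residue_name=resname,
                residue_number=resnum, chain_id=chain)
    return atom, (x, y, z), altloc, occ


def read_multimodel_pdb(path) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Each ``MODEL``/``ENDMDL`` block becomes one frame; a file with no MODEL
    records is a single-frame trajectory. Every model must contain the same
    atoms in the same order. For atoms with alternate locations, the
    highest-occupancy altloc of the first model is kept (tie: first
    encountered); the choice is logged.

    Raises
    ------
    FormatError
        On inconsistent atom counts between models (naming the model index)
        or unparseable coordinate fields (naming the line number).
    """
    path = Path(path)
    models: list[list] = []
    current: Optional[list] = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    if saw_model:
                        raise FormatError(f"line {lineno}: ATOM record outside MODEL block")
                    current = []
                current.append((lineno,) + _parse_atom_line(line, lineno))
    if current is not None and not saw_model:
        models.append(current)
    if not models:
        raise FormatError(f"{path}: no coordinate records found")

    # altloc resolution based on the first model
    first = models[0]
    best: dict = {}
    has_alt = False
    for _, atom, _, altloc, occ in first:
        key = (atom.chain_id, atom.residue_number, atom.residue_name, atom.name)
        if altloc:
            has_alt = True
        if key not in best or (altloc and occ > best[key][1]):
            best[key] = (altloc, occ)
    if has_alt:
        chosen = sorted({v[0] for v in best.values() if v[0]})
        log.info("alternate locations present; keeping highest-occupancy altloc "
                 "per atom (chosen: %s)", ",".join(chosen))

    def keep(atom, altloc):
        key = (atom.chain_id, atom.residue_number, atom.residue_name, atom.name)
        return not altloc or altloc == best.get(key, ("",))[0]

    atoms = [a for _, a, _, alt, _ in first if keep(a, alt)]
    n_expected = len(atoms)
    coords = np.empty((len(models), n_expected, 3))
    for m, model in enumerate(models):
        rows = [(a, xyz) for _, a, xyz, alt, _ in model if keep(a, alt)]
        if len(rows) != n_expected:
            raise FormatError(f"model {m + 1}: {len(rows)} atoms, expected {n_expected}")
        for j, (atom, xyz) in enumerate(rows):
            ref = atoms[j]
            if (atom.name, atom.residue_number, atom.chain_id) != (
                    ref.name, ref.residue_number, ref.chain_id):
                raise FormatError(
                    f"model {m + 1}: atom {j + 1} is {atom.name} {atom.residue_name}"
                    f"{atom.residue_number}, expected {ref.name} {ref.residue_name}"
                    f"{ref.residue_number}")
            coords[m, j] = xyz
    return Trajectory(atoms=atoms, coords=coords)


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a fixed-column multi-model PDB file."""
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"MODEL     {i + 1:4d}\n")
            for j, atom in enumerate(traj.atoms):
                x, y, z = traj.coords[i, j]
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {atom.serial:5d} {name:<4.4s} {atom.residue_name:<3.3s} "
                    f"{atom.chain_id:1.1s}{atom.residue_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2.2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def resolve_selection(traj: Trajectory, selector: str) -> list:
    """Resolve a simple residue/atom-name selector to atom indices.

    Grammar: ``[CHAIN:]RESNAME RESNUM|* [NAME[,NAME...]|*]`` — e.g.
    ``"ASP 184 OD1,OD2"``, ``"LIG * N+"``, ``"A:PHE 141 *"``. Matching is
    exact on stripped atom names; ``*`` is a wildcard for the residue number
    or the name list. Results are ordered by atom serial.

    Raises
    ------
    SelectionError
        On a syntactically invalid selector or zero matches.
    """
    tokens = selector.split()
    if not 2 <= len(tokens) <= 3:
        raise SelectionError(f"invalid selector {selector!r}: expected "
                             "'[CHAIN:]RESNAME RESNUM [NAMES]'")
    resname_tok = tokens[0]
    chain = None
    if ":" in resname_tok:
        chain, resname_tok = resname_tok.split(":", 1)
    if tokens[1] == "*":
        resnum = None
    else:
        try:
            resnum = int(tokens[1])
        except ValueError as exc:
            raise SelectionError(f"invalid residue number in selector {selector!r}") from exc
    names = None
    if len(tokens) == 3 and tokens[2] != "*":
        names = {n.strip() for n in tokens[2].split(",") if n.strip()}

    hits = []
    for idx, atom in enumerate(traj.atoms):
        if atom.residue_name != resname_tok:
            continue
        if chain is not None and atom.chain_id != chain:
            continue
        if resnum is not None and atom.residue_number != resnum:
            continue
        if names is not None and atom.name not in names:
            continue
        hits.append((atom.serial, idx))
    if not hits:
        raise SelectionError(f"selector {selector!r} matched no atoms")
    return [idx for _, idx in sorted(hits)]


@dataclass
class AnalysisConfig:
    """Declarative analysis configuration (channels, cutoffs, selections).

    Loaded from YAML or JSON. ``channels`` entries are mappings with keys
    ``kind``, ``label`` and ``participants`` (role -> selector string, or a
    list of selector strings for ring roles on fused systems). ``cutoffs``
    overrides :class:`~ifpkit.interactions.InteractionSpec` defaults.
    """

    ligand: dict = field(default_factory=dict)
    channels: list = field(default_factory=list)
    cutoffs: dict = field(default_factory=dict)
    superposition: dict = field(default_factory=dict)
    compound: str = "compound"
    allow_no_hydrogen: bool = False

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = {"ligand", "channels", "cutoffs", "superposition", "compound",
                 "allow_no_hydrogen"}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        data = {"ligand": self.ligand, "channels": self.channels,
                "cutoffs": self.cutoffs, "superposition": self.superposition,
                "compound": self.compound,
                "allow_no_hydrogen": self.allow_no_hydrogen}
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(data, fh, indent=2)
            else:
                yaml.safe_dump(data, fh, sort_keys=False)

    def build(self, traj: Trajectory):
        """Resolve declarations against a trajectory.

        Returns ``(channels, spec)`` with every participant resolved to atom
        indices (ring roles to lists of rings).
        """
        from ifpkit.interactions import Channel, InteractionSpec, RING_ROLES

        spec = InteractionSpec(**self.cutoffs)
        channels = []
        for decl in self.channels:
            participants = {}
            for role, sel in decl["participants"].items():
                sels = sel if isinstance(sel, list) else [sel]
                resolved = [resolve_selection(traj, s) for s in sels]
                if role in RING_ROLES:
                    participants[role] = resolved
                else:
                    flat = [i for grp in resolved for i in grp]
                    participants[role] = flat
            channels.append(Channel(kind=decl["kind"], label=decl["label"],
                                    participants=participants))
        return channels, spec


def _sig(x, digits=9):
    """Format a float with enough digits to round-trip to printed precision."""
    if isinstance(x, float):
        return float(f"{x:.{digits}g}")
    return x


def write_report(report, path, format: str = "csv") -> None:
    """Write an occupancy / group-stats / dose-response report to disk.

    Any object exposing ``to_frame()`` (a pandas DataFrame view) and
    ``to_dict()`` is accepted. Numeric fields are written with >= 9
    significant digits so a read-back reproduces them to printed precision.
    """
    if format not in ("csv", "json"):
        raise ValueError(f"unknown report format {format!r}")
    if format == "csv":
        frame = report.to_frame()
        frame.to_csv(path, index=False, float_format="%.9g")
    else:
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=_sig)
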