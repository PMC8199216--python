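"""Per-frame geometric interaction detectors.

Implements the standard trajectory-analysis criteria for protein-ligand
contacts:

* hydrogen bond — donor-acceptor distance <= 3.0 A and donor-H-acceptor
  angle >= 135 deg (CPPTRAJ-style defaults);
* intramolecular hydrogen bond — same angle rule, distance cutoff extended
  to 3.5 A;
* salt bridge — minimum distance over all declared anion-oxygen /
  cation-nitrogen pairs <= 4.0 A;
* cation-pi — distance between the cationic nitrogen and the aromatic ring
  centroid <= 6.0 A, and angle between the ring-plane normal and the
  nitrogen-centroid vector <= 45 deg;
* pi-pi (face-to-face) — ring-centroid distance <= 5.5 A and interplanar
  angle <= 30 deg (a literature-conventional rule; configurable).

All cutoff comparisons are inclusive. For fused bicyclic aromatics (e.g.
tryptophan) both rings may be declared for one channel; the channel is
satisfied if either ring satisfies the criteria (OR reduction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, field

import numpy as np

from ifpkit.errors import ConfigurationError, GeometryError
from ifpkit.geometry import angle_vector_to_normal, ring_geometry

__all__ = [
    "InteractionSpec",
    "Channel",
    "detect_hbond",
    "detect_salt_bridge",
    "detect_cation_pi",
    "detect_pi_pi",
    "evaluate_channel",
    "RING_ROLES",
    "KIND_ROLES",
]

#: participant roles whose value is a list of rings (each a list of indices)
RING_ROLES = frozenset({"ring", "ring_a", "ring_b"})

#: required participant roles per channel kind
KIND_ROLES = {
    "hbond": ("donor", "hydrogen", "acceptor"),
    "intramol_hbond": ("donor", "hydrogen", "acceptor"),
    "salt_bridge": ("anion_oxygens", "cation_nitrogens"),
    "cation_pi": ("cation", "ring"),
    "pi_pi": ("ring_a", "ring_b"),
}


@dataclass(frozen=True)
class InteractionSpec:
    """Geometric cutoffs for all detectors (distances in A, angles in deg)."""

    hbond_distance_cutoff: float = 3.0
    hbond_angle_cutoff: float = 135.0
    intramol_hbond_distance_cutoff: float = 3.5
    salt_bridge_cutoff: float = 4.0
    cation_pi_distance_cutoff: float = 6.0
    cation_pi_angle_cutoff: float = 45.0
    pipi_distance_cutoff: float = 5.5
    pipi_angle_cutoff: float = 30.0

    def __post_init__(self):
        for name in ("hbond_distance_cutoff", "intramol_hbond_distance_cutoff",
                     "salt_bridge_cutoff", "cation_pi_distance_cutoff",
                     "pipi_distance_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("cation_pi_angle_cutoff", "pipi_angle_cutoff"):
            if not 0 < getattr(self, name) <= 90:
                raise ConfigurationError(f"{name} must be in (0, 90]")
        if not 0 < self.hbond_angle_cutoff <= 180:
            raise ConfigurationError("hbond_angle_cutoff must be in (0, 180]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Channel:
    """One declared interaction channel with resolved participants.

    ``participants`` maps role names to atom index lists; ring roles
    (``ring``, ``ring_a``, ``ring_b``) map to a list of rings, each a list
    of >= 5 atom indices, to support fused bicyclic systems.
    """

    kind: str
    label: str
    participants: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KIND_ROLES:
            raise ConfigurationError(f"unknown channel kind {self.kind!r}")
        missing = [r for r in KIND_ROLES[self.kind] if r not in self.participants]
        if missing:
            raise ConfigurationError(
                f"channel {self.label!r} ({self.kind}): missing roles {missing}")
        for role in KIND_ROLES[self.kind]:
            val = self.participants[role]
            if role in RING_ROLES:
                if not val or any(len(ring) < 5 for ring in val):
                    raise ConfigurationError(
                        f"channel {self.label!r}: ring role {role!r} needs >=1 "
                        "ring of >=5 atoms")
            elif not val:
                raise ConfigurationError(
                    f"channel {self.label!r}: role {role!r} resolved to no atoms")


def detect_hbond(frame, donor, hydrogen, acceptor, spec: InteractionSpec,
                 intramolecular: bool = False, allow_no_hydrogen: bool = False) -> bool:
    """Hydrogen-bond criterion on one frame.

    True iff donor-acceptor distance <= cutoff (3.0 A, extended to 3.5 A for
    intramolecular bonds) and the donor-hydrogen-acceptor angle >= 135 deg;
    both comparisons inclusive. ``allow_no_hydrogen`` downgrades to a
    distance-only check (a logged warning) for hydrogen-free inputs.
    """
    frame = np.asarray(frame, dtype=float)
    d = frame[donor]
    a = frame[acceptor]
    cutoff = (spec.intramol_hbond_distance_cutoff if intramolecular
              else spec.hbond_distance_cutoff)
    da = float(np.linalg.norm(a - d))
    if da == 0.0:
        raise GeometryError("donor and acceptor coincide")
    if da > cutoff:
        return False
    if hydrogen is None:
        if not allow_no_hydrogen:
            raise ConfigurationError(
                "hydrogen role missing; set allow_no_hydrogen for a "
                "distance-only hydrogen-bond check")
        warnings.warn("hydrogen bond evaluated on distance only (no hydrogen atom)",
                      stacklevel=2)
        return True
    h = frame[hydrogen]
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryError("hydrogen coincides with donor or acceptor")
    if float(np.linalg.norm(h - d)) > 1.5:
        warnings.warn(
            f"donor-hydrogen distance {np.linalg.norm(h - d):.2f} A exceeds "
            "1.5 A; hydrogen may not be covalently bound to the donor",
            stacklevel=2)
    cosang = float(np.dot(v1, v2) / (n1 * n2))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return angle >= spec.hbond_angle_cutoff


def detect_salt_bridge(frame, anion_oxygens, cation_nitrogens,
                       spec: InteractionSpec) -> bool:
    """True iff the minimum O-N distance over all declared pairs is <= 4.0 A."""
    if not len(anion_oxygens) or not len(cation_nitrogens):
        raise ConfigurationError("salt bridge needs non-empty O and N atom sets")
    frame = np.asarray(frame, dtype=float)
    O = frame[np.asarray(anion_oxygens, dtype=int)]
    N = frame[np.asarray(cation_nitrogens, dtype=int)]
    dmin = float(np.min(np.linalg.norm(O[:, None, :] - N[None, :, :], axis=2)))
    return dmin <= spec.salt_bridge_cutoff


def detect_cation_pi(frame, cation, ring, spec: InteractionSpec) -> bool:
    """Cation-pi criterion: centroid distance <= 6 A and normal angle <= 45 deg.

    ``ring`` is a list of >= 5 atom indices (one ring). The angle is taken
    between the ring-plane normal and the cation-to-centroid vector, folded
    into [0, 90] so the normal's sign is irrelevant.
    """
    if len(ring) < 5:
        raise GeometryError("aromatic ring needs >= 5 atoms")
    frame = np.asarray(frame, dtype=float)
    geom = ring_geometry(frame[np.asarray(ring, dtype=int)])
    v = frame[cation] - geom.centroid
    dist = float(np.linalg.norm(v))
    if dist > spec.cation_pi_distance_cutoff:
        return False
    return angle_vector_to_normal(geom.normal, v) <= spec.cation_pi_angle_cutoff


def detect_pi_pi(frame, ring_a, ring_b, spec: InteractionSpec) -> bool:
    """Face-to-face pi-stacking: centroid distance and interplanar angle rule."""
    if len(ring_a) < 5 or len(ring_b) < 5:
        raise GeometryError("aromatic ring needs >= 5 atoms")
    frame = np.asarray(frame, dtype=float)
    ga = ring_geometry(frame[np.asarray(ring_a, dtype=int)])
    gb = ring_geometry(frame[np.asarray(ring_b, dtype=int)])
    dist = float(np.linalg.norm(gb.centroid - ga.centroid))
    if dist > spec.pipi_distance_cutoff:
        return False
    return angle_vector_to_normal(ga.normal, gb.normal) <= spec.pipi_angle_cutoff


def _single(indices, role, label):
    if len(indices) != 1:
        raise ConfigurationError(
            f"channel {label!r}: role {role!r} must resolve to exactly one atom, "
            f"got {len(indices)}")
    return indices[0]


def evaluate_frame(frame, channel: Channel, spec: InteractionSpec,
                   allow_no_hydrogen: bool = False) -> bool:
    """Evaluate one channel on one frame; ring roles OR-reduce over rings."""
    p = channel.participants
    if channel.kind in ("hbond", "intramol_hbond"):
        return detect_hbond(
            frame,
            _single(p["donor"], "donor", channel.label),
            _single(p["hydrogen"], "hydrogen", channel.label) if p.get("hydrogen") else None,
            _single(p["acceptor"], "acceptor", channel.label),
            spec,
            intramolecular=(channel.kind == "intramol_hbond"),
            allow_no_hydrogen=allow_no_hydrogen,
        )
    if channel.kind == "salt_bridge":
        return detect_salt_bridge(frame, p["anion_oxygens"], p["cation_nitrogens"], spec)
    if channel.kind == "cation_pi":
        cation = _single(p["cation"], "cation", channel.label)
        return any(detect_cation_pi(frame, cation, ring, spec) for ring in p["ring"])
    if channel.kind == "pi_pi":
        return any(detect_pi_pi(frame, ra, rb, spec)
                   for ra in p["ring_a"] for rb in p["ring_b"])
    raise ConfigurationError(f"unknown channel kind {channel.kind!r}")


def evaluate_channel(traj, channel: Channel, spec: InteractionSpec,
                     allow_no_hydrogen: bool = False) -> np.ndarray:
    """Evaluate a channel on every frame; returns a boolean array of length n_frames.

    Errors raised by the detectors are re-raised with the offending frame
    index attached.
    """
    out = np.empty(traj.n_frames, dtype=bool)
    for i in range(traj.n_frames):
        try:
            out[i] = evaluate_frame(traj.coords[i], channel, spec,
                                    allow_no_hydrogen=allow_no_hydrogen)
        except (GeometryError, ConfigurationError) as exc:
            raise type(exc)(f"frame {i}, channel {channel.label!r}: {exc}") from exc
    return out
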