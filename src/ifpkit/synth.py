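"""Synthetic complexes, trajectories, score tables and dose-response data.

The toy complex is a minimal stand-in for a Tudor-domain aromatic-cage
binding site: two aromatic six-membered rings (Phe/Trp-like cage residues),
an aspartate-like carboxylate pair, a backbone-like carbonyl acceptor, and
a ligand carrying a pyrrolidinium-like cationic nitrogen, an amidinium
nitrogen pair, a donor-hydrogen pair, an intramolecular donor/acceptor pair
and an aromatic ring. The reference geometry satisfies every declared
interaction channel with a margin of at least 0.3 A / 5 deg.

Trajectories are generated channel by channel: each frame draws a Bernoulli
state per channel and places that channel's dedicated mobile atoms either
inside the satisfying region (minus margin) or beyond the cutoff (plus
margin), so planted occupancy probabilities are exact by construction and
independent across channels. Truncated positional jitter (|delta| <= 0.1 A)
and a global rigid per-frame motion are applied on top; neither can flip a
planted state. The generator emulates planted contact statistics only — no
force field, solvent, autocorrelation or physically continuous motion — so
recovery tests validate the detection and counting machinery, not MD
realism.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from ifpkit.errors import ConfigurationError
from ifpkit.trajectory import AnalysisConfig, Atom, Trajectory
from ifpkit.assay import four_param_logistic
from ifpkit.scores import ScoreTable

__all__ = [
    "ComplexTemplate",
    "ChannelPlan",
    "make_toy_complex",
    "simulate_trajectory",
    "simulate_scores",
    "simulate_dose_response",
    "DIST_MARGIN",
    "ANGLE_MARGIN",
    "JITTER_MAX",
]

DIST_MARGIN = 0.3     # A: clearance kept on both sides of distance cutoffs
ANGLE_MARGIN = 5.0    # deg: clearance on angle cutoffs
JITTER_MAX = 0.1      # A: hard bound on per-atom positional jitter


@dataclass
class ChannelDriver:
    """Placement rule for one channel's dedicated mobile atoms."""

    label: str
    mobile: list                      # atom indices moved by this channel
    place: Callable                   # place(rng, on: bool) -> (len(mobile), 3)
    rigid_jitter: bool = True         # jitter as one shared translation


@dataclass
class ChannelPlan:
    """Planted occupancy probabilities per channel label.

    ``probabilities`` maps channel labels to p in [0, 1]; ``jitter_sigma``
    scales the truncated positional noise (hard-bounded at 0.1 A).
    """

    probabilities: dict
    jitter_sigma: float = 0.05

    def __post_init__(self):
        for label, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"channel {label!r}: p={p} outside [0, 1]")
        if self.jitter_sigma < 0:
            raise ConfigurationError("jitter_sigma must be >= 0")


@dataclass
class ComplexTemplate:
    """Toy complex: reference trajectory, config, and channel drivers."""

    trajectory: Trajectory            # single reference frame
    config: AnalysisConfig
    drivers: list = field(default_factory=list)

    @property
    def channel_labels(self) -> list:
        return [d.label for d in self.drivers]


def _hexagon(center, radius=1.39, z_offset=0.0):
    ang = np.arange(6) * np.pi / 3.0
    pts = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                    np.zeros(6)], axis=1)
    return pts + np.asarray(center, dtype=float) + np.array([0.0, 0.0, z_offset])


def make_toy_complex() -> ComplexTemplate:
    """Deterministic toy complex whose reference frame satisfies all channels.

    Interaction clusters are spaced >= 15 A apart so each channel's mobile
    atoms never interfere with another channel's criteria. A self-check
    verifies every channel evaluates True on the reference geometry with the
    required margins.
    """
    roster = []   # (name, element, resname, resnum, chain, xyz)

    def add(name, element, resname, resnum, chain, xyz):
        roster.append((name, element, resname, resnum, chain, np.asarray(xyz, float)))

    # cage ring 1: Phe-like, hexagon in the z=0 plane at the origin
    for nm, xyz in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                       _hexagon((0.0, 0.0, 0.0))):
        add(nm, "C", "PHE", 141, "A", xyz)
    # cage ring 2: Trp-like six-membered ring at x=20
    for nm, xyz in zip(("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
                       _hexagon((20.0, 0.0, 0.0))):
        add(nm, "C", "TRP", 151, "A", xyz)
    # carboxylate pair (Asp-like) at x=40
    add("OD1", "O", "ASP", 184, "A", (40.0, 0.0, 0.0))
    add("OD2", "O", "ASP", 184, "A", (40.0, 2.2, 0.0))
    # backbone-like carbonyl acceptor at x=60
    add("O", "O", "GLY", 100, "A", (60.0, 0.0, 0.0))

    # ligand
    add("NP", "N", "LIG", 1, "L", (0.0, 0.0, 3.5))        # cationic N over ring 1
    for i, xyz in enumerate(_hexagon((20.0, 0.0, 0.0), z_offset=3.6), start=1):
        add(f"C{i}", "C", "LIG", 1, "L", xyz)             # ligand ring over ring 2
    add("N1", "N", "LIG", 1, "L", (40.0, 0.0, 3.0))       # amidinium N pair
    add("N2", "N", "LIG", 1, "L", (40.0, 2.2, 3.2))
    add("ND", "N", "LIG", 1, "L", (60.0, 0.0, 2.65))      # H-bond donor to GLY O
    add("HD", "H", "LIG", 1, "L", (60.0, 0.0, 1.65))
    add("NI", "N", "LIG", 1, "L", (80.0, 0.0, 3.1))       # intramolecular donor
    add("HI", "H", "LIG", 1, "L", (80.0, 0.0, 2.1))
    add("OM", "O", "LIG", 1, "L", (80.0, 0.0, 0.0))       # methoxy-like acceptor

    atoms = [Atom(serial=i + 1, name=nm, element=el, residue_name=rn,
                  residue_number=num, chain_id=ch)
             for i, (nm, el, rn, num, ch, _) in enumerate(roster)]
    coords = np.stack([xyz for *_, xyz in roster])[None, :, :]
    traj = Trajectory(atoms=atoms, coords=coords)

    idx = {(a.residue_name, a.residue_number, a.name): i
           for i, a in enumerate(traj.atoms)}

    config = AnalysisConfig(
        ligand={"resname": "LIG", "resnum": 1},
        compound="toy",
        superposition={
            "reference_frame": 0,
            # the toy protein has no backbone; fit on all cage-residue atoms
            "fit_selection": ["PHE 141 *", "TRP 151 *", "ASP 184 *", "GLY 100 O"],
            "report_selection": "LIG 1 *",
        },
        channels=[
            {"kind": "hbond", "label": "donor-Gly100",
             "participants": {"donor": "LIG 1 ND", "hydrogen": "LIG 1 HD",
                              "acceptor": "GLY 100 O"}},
            {"kind": "intramol_hbond", "label": "intramol-HB",
             "participants": {"donor": "LIG 1 NI", "hydrogen": "LIG 1 HI",
                              "acceptor": "LIG 1 OM"}},
            {"kind": "salt_bridge", "label": "amidine-Asp184",
             "participants": {"anion_oxygens": "ASP 184 OD1,OD2",
                              "cation_nitrogens": "LIG 1 N1,N2"}},
            {"kind": "cation_pi", "label": "pyrrolidinium-Phe141",
             "participants": {"cation": "LIG 1 NP",
                              "ring": "PHE 141 CG,CD1,CD2,CE1,CE2,CZ"}},
            {"kind": "pi_pi", "label": "ligandring-Trp151",
             "participants": {"ring_a": "LIG 1 C1,C2,C3,C4,C5,C6",
                              "ring_b": "TRP 151 CD2,CE2,CE3,CZ2,CZ3,CH2"}},
        ],
    )

    dm, jm = DIST_MARGIN, JITTER_MAX

    def place_hbond(rng, on):
        # donor+hydrogen move rigidly along the acceptor axis; angle stays 180
        d = rng.uniform(2.2, 3.0 - dm - jm) if on else rng.uniform(3.0 + dm + jm, 5.0)
        return np.array([[60.0, 0.0, d], [60.0, 0.0, d - 1.0]])

    def place_intramol(rng, on):
        # acceptor OM moves along -z below the fixed NI-HI donor pair
        d = rng.uniform(2.6, 3.5 - dm - jm) if on else rng.uniform(3.5 + dm + jm, 5.5)
        return np.array([[80.0, 0.0, 3.1 - d]])

    def place_salt_bridge(rng, on):
        # amidinium pair above the carboxylate; min pair distance = N1-OD1 = z
        z = rng.uniform(2.6, 4.0 - dm - jm) if on else rng.uniform(4.0 + dm + jm, 7.0)
        return np.array([[40.0, 0.0, z], [40.0, 2.2, z + 0.2]])

    def place_cation_pi(rng, on):
        if on:
            d = rng.uniform(3.0, 6.0 - dm - jm)
            theta = np.radians(rng.uniform(0.0, 45.0 - ANGLE_MARGIN - 3.0))
        else:
            d = rng.uniform(6.0 + dm + jm, 9.0)
            theta = np.radians(rng.uniform(0.0, 60.0))
        phi = rng.uniform(0.0, 2.0 * np.pi)
        v = d * np.array([np.sin(theta) * np.cos(phi),
                          np.sin(theta) * np.sin(phi), np.cos(theta)])
        return v[None, :]  # ring 1 centroid is the origin

    def place_pi_pi(rng, on):
        gap = rng.uniform(3.2, 5.5 - dm - 2 * jm) if on else rng.uniform(5.5 + dm + 2 * jm, 8.5)
        return _hexagon((20.0, 0.0, 0.0), z_offset=gap)

    drivers = [
        ChannelDriver("donor-Gly100",
                      [idx[("LIG", 1, "ND")], idx[("LIG", 1, "HD")]],
                      place_hbond),
        ChannelDriver("intramol-HB", [idx[("LIG", 1, "OM")]], place_intramol),
        ChannelDriver("amidine-Asp184",
                      [idx[("LIG", 1, "N1")], idx[("LIG", 1, "N2")]],
                      place_salt_bridge),
        ChannelDriver("pyrrolidinium-Phe141", [idx[("LIG", 1, "NP")]],
                      place_cation_pi),
        ChannelDriver("ligandring-Trp151",
                      [idx[("LIG", 1, f"C{i}")] for i in range(1, 7)],
                      place_pi_pi),
    ]

    template = ComplexTemplate(trajectory=traj, config=config, drivers=drivers)
    _self_check(template)
    return template


def _self_check(template: ComplexTemplate) -> None:
    """Verify every channel evaluates True on the reference geometry."""
    from ifpkit.interactions import evaluate_frame

    channels, spec = template.config.build(template.trajectory)
    frame = template.trajectory.coords[0]
    for ch in channels:
        if not evaluate_frame(frame, ch, spec):
            raise ConfigurationError(
                f"toy complex self-check failed: channel {ch.label!r} not "
                "satisfied on the reference geometry")


def _channel_rng(master_seed: int, label: str) -> np.random.Generator:
    """Independent, re-ordering-stable stream per channel."""
    digest = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return np.random.default_rng([int(master_seed), digest])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def simulate_trajectory(template: ComplexTemplate, plan: ChannelPlan,
                        n_frames: int, seed: int,
                        global_motion: bool = True) -> Trajectory:
    """Trajectory with per-channel Bernoulli-planted interaction states.

    Per frame and channel: draw state ~ Bernoulli(p); place the channel's
    mobile atoms uniformly inside the satisfying region minus the safety
    margin (ON) or beyond the cutoff plus margin (OFF); add truncated
    positional jitter; finally apply one global rigid rotation+translation
    to the whole frame. Identical seeds yield bitwise-identical output.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    known = set(template.channel_labels)
    unknown = set(plan.probabilities) - known
    if unknown:
        raise ConfigurationError(
            f"plan references unknown channels {sorted(unknown)}; "
            f"template has {sorted(known)}")
    active = [d for d in template.drivers if d.label in plan.probabilities]
    seen: set = set()
    for d in active:
        clash = seen & set(d.mobile)
        if clash:
            raise ConfigurationError(
                f"unsatisfiable plan: channel {d.label!r} shares mobile atoms "
                f"{sorted(clash)} with another channel")
        seen |= set(d.mobile)

    ref = template.trajectory.coords[0]
    coords = np.repeat(ref[None, :, :], n_frames, axis=0)
    for d in active:
        rng = _channel_rng(seed, d.label)
        p = plan.probabilities[d.label]
        states = rng.random(n_frames) < p
        for i in range(n_frames):
            placed = d.place(rng, bool(states[i]))
            if plan.jitter_sigma > 0:
                if d.rigid_jitter:
                    delta = rng.normal(0.0, plan.jitter_sigma, size=3)[None, :]
                else:
                    delta = rng.normal(0.0, plan.jitter_sigma, size=placed.shape)
                placed = placed + np.clip(delta, -JITTER_MAX, JITTER_MAX)
            coords[i, d.mobile] = placed
    if global_motion:
        grng = _channel_rng(seed, "__global_rigid__")
        for i in range(n_frames):
            R = _random_rotation(grng)
            t = grng.normal(0.0, 0.5, size=3)
            coords[i] = coords[i] @ R.T + t
    return Trajectory(atoms=template.trajectory.atoms, coords=coords)


def simulate_scores(mean_active: float = -76.3, sd_active: float = 4.0,
                    n_active: int = 17, mean_inactive: float = -60.35,
                    sd_inactive: float = 4.0, n_inactive: int = 3,
                    seed: int = 0, kind: str = "bfe") -> ScoreTable:
    """Two-Gaussian active/inactive score table (kcal/mol).

    Defaults emulate an MM-GBSA-style rescoring set: 17 actives around
    -76.3 kcal/mol and 3 inactives around -60.35 kcal/mol, SD 4.
    """
    if sd_active < 0 or sd_inactive < 0:
        raise ConfigurationError("standard deviations must be >= 0")
    rng = np.random.default_rng([int(seed), 0x5C0])
    act = mean_active + sd_active * rng.standard_normal(n_active)
    inact = mean_inactive + sd_inactive * rng.standard_normal(n_inactive)
    compounds = ([f"act{i + 1:02d}" for i in range(n_active)]
                 + [f"inact{i + 1:02d}" for i in range(n_inactive)])
    return ScoreTable(compounds=compounds,
                      scores=np.concatenate([act, inact]),
                      activities=["active"] * n_active + ["inactive"] * n_inactive,
                      kind=kind)


def simulate_dose_response(ic50: float = 182.6e-9, hill: float = 1.0,
                           top: float = 100.0, bottom: float = 0.0,
                           concentrations: Optional[np.ndarray] = None,
                           noise_sd: float = 2.0, replicates: int = 3,
                           seed: int = 0,
                           compound: str = "compound") -> pd.DataFrame:
    """Noisy 4PL dose-response rows (long format).

    Defaults emulate an FP competition assay: a 12-point half-log serial
    dilution bracketing an IC50 of 182.6 nM, measured in triplicate with
    Gaussian noise of 2 percentage points.

    Returns a DataFrame with columns compound, concentration, replicate,
    response (percent inhibition).
    """
    if concentrations is None:
        # 12 half-log dilutions centered on the planted IC50
        concentrations = ic50 * 10.0 ** (0.5 * (np.arange(12) - 5.5))
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0):
        raise ConfigurationError("concentrations must be > 0")
    rng = np.random.default_rng([int(seed), 0xD05E])
    rows = []
    mean = four_param_logistic(concentrations, bottom, top, np.log10(ic50), hill)
    for rep in range(1, replicates + 1):
        noise = rng.normal(0.0, noise_sd, size=len(concentrations)) if noise_sd > 0 \
            else np.zeros(len(concentrations))
        for c, y in zip(concentrations, mean + noise):
            rows.append({"compound": compound, "concentration": float(c),
                         "replicate": rep, "response": float(y)})
    return pd.DataFrame(rows)
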