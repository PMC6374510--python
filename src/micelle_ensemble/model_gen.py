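"""Synthetic micelle conformer generation.

Builds coarse-grained models of a hexameric micelle of a four-armed
calix[4]arene surfactant: one bead per heavy-atom group, a bowl of four
tilted aromatic panels with lower-rim oxygens, four cationic amine head
arms and four propyl-like tails.  Six molecules are placed on the faces
of a cube (tails inward), and pseudo-trajectories are produced by rigid
body jitter, per-atom thermal noise and occasional anisotropic
elongation of whole frames.  Analytic bead shapes (spheres, shells,
point pairs) are provided as oracles for the scattering stage.

All lengths are in Å.  All randomness flows through one explicitly
seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

GROUP_TAGS = ("CALIX_C", "CALIX_O", "AMINE_N", "TAIL", "HEAD_OTHER", "SOLVENT")

#: default panel tilt patterns (degrees from the micelle-outward axis)
C4V_TILTS = (45.0, 45.0, 45.0, 45.0)
#: two opposite panels nearly parallel to the axis, the other two strongly
#: tilted so their planes form close to a right angle
C2V_TILTS = (15.0, 75.0, 15.0, 75.0)

_RING_RADIUS = 3.0       # distance of aromatic panel centres from molecule axis
_PANEL_HALF = 1.4        # half-extent of a 3-bead aromatic panel
_O_RADIUS = 2.0          # lower-rim oxygen ring radius
_O_DROP = 2.2            # oxygen depth below the panel plane
_BEAD_STEP = 1.5         # bond-ish spacing between consecutive beads


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicelleSpec:
    """Parameters of the synthetic hexameric micelle generator.

    ``placement_radius`` is the distance of each molecule centroid from
    the micelle centre; ``perturbation_sigma`` controls both rigid-body
    and per-atom Gaussian jitter; a ``deform_fraction`` subset of frames
    is stretched by ``elongation_factor`` along a random axis
    (volume-preserving), emulating transient elongated micelles.
    """

    aggregation_number: int = 6
    placement_radius: float = 12.0
    ring_conformation: str = "C2v"
    ring_tilt_angles: Optional[tuple] = None
    tail_length_beads: int = 3
    head_arm_beads: int = 4
    perturbation_sigma: float = 0.5
    deform_fraction: float = 0.0
    elongation_factor: float = 1.5
    clash_distance: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.aggregation_number < 1:
            raise ValueError("aggregation_number must be >= 1")
        if self.placement_radius <= 0:
            raise ValueError("placement_radius must be > 0")
        if self.perturbation_sigma < 0:
            raise ValueError("perturbation_sigma must be >= 0")
        if not 0.0 <= self.deform_fraction <= 1.0:
            raise ValueError("deform_fraction must lie in [0, 1]")
        if self.elongation_factor < 1.0:
            raise ValueError("elongation_factor must be >= 1")
        if self.tail_length_beads < 1 or self.head_arm_beads < 1:
            raise ValueError("bead counts must be positive")
        if self.ring_conformation not in ("C2v", "C4v"):
            raise ValueError(f"unknown ring conformation {self.ring_conformation!r}")

    @property
    def tilts(self) -> np.ndarray:
        """Per-panel tilt angles in degrees, validated against the symmetry."""
        if self.ring_tilt_angles is not None:
            t = np.asarray(self.ring_tilt_angles, dtype=float)
            if t.shape != (4,):
                raise ValueError("ring_tilt_angles must have 4 entries")
        else:
            t = np.array(C4V_TILTS if self.ring_conformation == "C4v" else C2V_TILTS)
        if self.ring_conformation == "C4v":
            if not np.allclose(t, t[0]):
                raise ValueError("C4v requires four equal tilt angles")
        else:
            if len(set(np.round(t, 6))) != 2 or not (
                np.isclose(t[0], t[2]) and np.isclose(t[1], t[3])
            ):
                raise ValueError("C2v requires an (a, b, a, b) tilt pattern")
        return t


@dataclass
class AtomicModel:
    """One conformer frame: bead coordinates plus per-bead labelling.

    ``scatterer`` labels must resolve to form-factor entries in the
    scattering stage; ``group_tag`` carries the chemical role used for
    selections (Fig-8-style pair distributions etc.).
    """

    coords: np.ndarray
    scatterer: np.ndarray
    group_tag: np.ndarray
    molecule_id: np.ndarray
    formal_charge: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.scatterer = np.asarray(self.scatterer, dtype="U8")
        self.group_tag = np.asarray(self.group_tag, dtype="U12")
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.formal_charge = np.asarray(self.formal_charge, dtype=int)
        for name in ("scatterer", "group_tag", "molecule_id", "formal_charge"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match coords")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        bad = set(self.group_tag) - set(GROUP_TAGS)
        if bad:
            raise ValueError(f"unknown group tags: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def selection_mask(self, selection=None) -> np.ndarray:
        """Boolean mask from a tag name, sequence of tags, or explicit mask."""
        if selection is None:
            return np.ones(self.n_atoms, dtype=bool)
        if isinstance(selection, str):
            selection = (selection,)
        arr = np.asarray(selection)
        if arr.dtype == bool:
            return arr
        if arr.dtype.kind in "iu":
            mask = np.zeros(self.n_atoms, dtype=bool)
            mask[arr] = True
            return mask
        return np.isin(self.group_tag, arr)

    def subset(self, selection) -> "AtomicModel":
        m = self.selection_mask(selection)
        if not m.any():
            raise ValueError("empty selection")
        return AtomicModel(self.coords[m], self.scatterer[m], self.group_tag[m],
                           self.molecule_id[m], self.formal_charge[m])

    def transformed(self, rotation: Optional[Rotation] = None,
                    translation=(0.0, 0.0, 0.0)) -> "AtomicModel":
        xyz = self.coords
        if rotation is not None:
            xyz = rotation.apply(xyz)
        xyz = xyz + np.asarray(translation, dtype=float)
        return replace(self, coords=xyz)

    def copy(self) -> "AtomicModel":
        return AtomicModel(self.coords.copy(), self.scatterer.copy(),
                           self.group_tag.copy(), self.molecule_id.copy(),
                           self.formal_charge.copy())

    @property
    def total_charge(self) -> int:
        return int(self.formal_charge.sum())

    @staticmethod
    def concatenate(models: Sequence["AtomicModel"]) -> "AtomicModel":
        return AtomicModel(
            np.vstack([m.coords for m in models]),
            np.concatenate([m.scatterer for m in models]),
            np.concatenate([m.group_tag for m in models]),
            np.concatenate([m.molecule_id for m in models]),
            np.concatenate([m.formal_charge for m in models]),
        )


@dataclass
class ConformerPool:
    """Ordered frames standing in for an MD trajectory."""

    frames: list
    frame_index: np.ndarray
    time_ps: Optional[np.ndarray] = None
    deformed: Optional[np.ndarray] = None  # per-frame elongation flag

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if len(self.frames) != len(self.frame_index):
            raise ValueError("frame_index length mismatch")
        if len(self.frames) == 0:
            raise ValueError("empty pool")
        if np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")
        n0 = self.frames[0].n_atoms
        for i, f in enumerate(self.frames):
            if f.n_atoms != n0:
                raise ValueError(f"frame {i} has {f.n_atoms} atoms, expected {n0}")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> AtomicModel:
        return self.frames[i]


# ---------------------------------------------------------------------------
# surfactant and micelle construction
# ---------------------------------------------------------------------------

def build_surfactant(spec: MicelleSpec) -> AtomicModel:
    """One coarse surfactant molecule, centred at the origin, tails along -z.

    Geometry: four aromatic panels (3 CALIX_C beads each) around the
    molecular axis, tilted per the ring conformation; four CALIX_O beads
    at the lower rim; from each oxygen a tail of TAIL beads along -z;
    from each panel top a head arm of HEAD_OTHER beads ending in a
    protonated AMINE_N bead (formal charge +1, so +4 per molecule).
    """
    tilts = np.deg2rad(spec.tilts)
    coords, scat, tags, charges = [], [], [], []

    def add(p, label, tag, q=0):
        coords.append(p)
        scat.append(label)
        tags.append(tag)
        charges.append(q)

    for k in range(4):
        phi = np.pi / 2.0 * k
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        centre = _RING_RADIUS * radial
        # panel axis tilted away from +z toward the radial direction
        u = np.cos(tilts[k]) * np.array([0.0, 0.0, 1.0]) + np.sin(tilts[k]) * radial
        for s in (-1.0, 0.0, 1.0):
            add(centre + s * _PANEL_HALF * u, "CH", "CALIX_C")
        # lower-rim oxygen below the panel, pulled toward the axis
        add(_O_RADIUS * radial + np.array([0.0, 0.0, -_O_DROP]), "O", "CALIX_O")
        # tail: beads descending from the oxygen along -z
        for j in range(1, spec.tail_length_beads + 1):
            add(_O_RADIUS * radial + np.array([0.0, 0.0, -_O_DROP - j * _BEAD_STEP]),
                "CH2", "TAIL")
        # head arm: from the panel top, outward and up
        top = centre + _PANEL_HALF * u
        w = 0.45 * radial + np.array([0.0, 0.0, 0.9])
        w /= np.linalg.norm(w)
        for j in range(1, spec.head_arm_beads + 1):
            p = top + j * _BEAD_STEP * w
            if j == spec.head_arm_beads:
                add(p, "NH3", "AMINE_N", q=+1)
            else:
                add(p, "CH", "HEAD_OTHER")

    return AtomicModel(np.array(coords), np.array(scat), np.array(tags),
                       np.zeros(len(coords), dtype=int), np.array(charges))


def placement_directions(n: int) -> np.ndarray:
    """Unit vectors for molecule placement: cube faces for n=6, otherwise
    centres of a good spherical-cap covering (exact small cases, Fibonacci
    lattice as the general fallback)."""
    e = np.eye(3)
    if n == 1:
        return e[2:3]
    if n == 2:
        return np.array([e[2], -e[2]])
    if n == 3:
        ang = 2 * np.pi * np.arange(3) / 3
        return np.stack([np.cos(ang), np.sin(ang), np.zeros(3)], axis=1)
    if n == 4:  # tetrahedron
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        return v / np.sqrt(3)
    if n == 6:  # octahedron = cube-face centres
        return np.array([e[0], -e[0], e[1], -e[1], e[2], -e[2]])
    if n == 12:  # icosahedron
        g = (1 + np.sqrt(5)) / 2
        v = np.array([[0, 1, g], [0, 1, -g], [0, -1, g], [0, -1, -g],
                      [1, g, 0], [1, -g, 0], [-1, g, 0], [-1, -g, 0],
                      [g, 0, 1], [-g, 0, 1], [g, 0, -1], [-g, 0, -1]], float)
        return v / np.linalg.norm(v[0])
    # Fibonacci sphere
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z ** 2)
    phi = np.pi * (1 + np.sqrt(5)) * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _rotation_to(direction: np.ndarray) -> Rotation:
    """Rotation carrying +z onto ``direction``."""
    z = np.array([0.0, 0.0, 1.0])
    d = direction / np.linalg.norm(direction)
    c = float(np.dot(z, d))
    if c > 1 - 1e-12:
        return Rotation.identity()
    if c < -1 + 1e-12:
        return Rotation.from_rotvec(np.pi * np.array([1.0, 0.0, 0.0]))
    axis = np.cross(z, d)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(np.arccos(c) * axis)


def assemble_micelle(spec: MicelleSpec) -> AtomicModel:
    """Place ``aggregation_number`` copies on a sphere of ``placement_radius``,
    tails pointing inward; raise if any inter-molecule contact falls below
    the clash distance."""
    mol = build_surfactant(spec)
    dirs = placement_directions(spec.aggregation_number)
    copies = []
    for i, d in enumerate(dirs):
        rot = _rotation_to(d)
        c = mol.transformed(rotation=rot, translation=spec.placement_radius * d)
        c.molecule_id = np.full(c.n_atoms, i, dtype=int)
        copies.append(c)
    micelle = AtomicModel.concatenate(copies)
    _check_clashes(micelle, spec.clash_distance)
    return micelle


def _check_clashes(model: AtomicModel, clash: float) -> None:
    tree = cKDTree(model.coords)
    for i, j in tree.query_pairs(clash):
        if model.molecule_id[i] != model.molecule_id[j]:
            d = np.linalg.norm(model.coords[i] - model.coords[j])
            raise ValueError(
                f"steric clash: atoms {i}/{j} of molecules "
                f"{model.molecule_id[i]}/{model.molecule_id[j]} at {d:.2f} Å"
            )


# ---------------------------------------------------------------------------
# pseudo-trajectory generation
# ---------------------------------------------------------------------------

def generate_pool(spec: MicelleSpec, n_frames: int,
                  rng_seed: Optional[int] = None) -> ConformerPool:
    """Pseudo-trajectory: the ideal micelle perturbed per frame.

    Each molecule gets a rigid-body rotation (angle scale
    ``perturbation_sigma / placement_radius`` rad) and translation
    (scale ``perturbation_sigma``), every bead gets isotropic Gaussian
    jitter, and a Bernoulli(``deform_fraction``) subset of frames is
    stretched by ``elongation_factor`` along a random axis with
    volume-preserving lateral compression.  Deterministic under seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    seed = spec.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    ideal = assemble_micelle(spec)
    sig = spec.perturbation_sigma
    rot_sigma = sig / spec.placement_radius

    frames, deformed = [], np.zeros(n_frames, dtype=bool)
    mol_ids = np.unique(ideal.molecule_id)
    for t in range(n_frames):
        frame = ideal.copy()
        if sig > 0:
            for m in mol_ids:
                sel = frame.molecule_id == m
                xyz = frame.coords[sel]
                centroid = xyz.mean(axis=0)
                rot = Rotation.from_rotvec(rng.normal(0.0, rot_sigma, 3))
                shift = rng.normal(0.0, sig, 3)
                frame.coords[sel] = rot.apply(xyz - centroid) + centroid + shift
            frame.coords += rng.normal(0.0, sig, frame.coords.shape)
        if spec.deform_fraction > 0 and rng.random() < spec.deform_fraction:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            f = spec.elongation_factor
            par = frame.coords @ axis
            perp = frame.coords - np.outer(par, axis)
            frame.coords = perp / np.sqrt(f) + np.outer(f * par, axis)
            deformed[t] = True
        frames.append(frame)
    return ConformerPool(frames, np.arange(n_frames), deformed=deformed)


# ---------------------------------------------------------------------------
# analytic oracle shapes
# ---------------------------------------------------------------------------

def analytic_shape(kind: str, **params) -> AtomicModel:
    """Bead models with closed-form properties, for oracle tests.

    ``solid_sphere(radius, spacing, jitter, rng_seed)`` — quasi-uniform
    jittered-grid filling of a ball; ``hollow_shell(r_inner, r_outer,
    spacing, ...)``; ``two_points(d)`` — two beads at distance d.
    All beads carry the unit scatterer label ``"B"`` (f = 1, zero
    excluded volume).
    """
    if kind == "two_points":
        d = float(params["d"])
        if d <= 0:
            raise ValueError("d must be > 0")
        xyz = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]])
    elif kind in ("solid_sphere", "hollow_shell"):
        if kind == "solid_sphere":
            r_in, r_out = 0.0, float(params["radius"])
        else:
            r_in, r_out = float(params["r_inner"]), float(params["r_outer"])
        if r_out <= r_in or r_out <= 0:
            raise ValueError("invalid radii")
        spacing = float(params.get("spacing", 1.5))
        jitter = float(params.get("jitter", 0.3))
        rng = np.random.default_rng(params.get("rng_seed", 0))
        ax = np.arange(-r_out, r_out + spacing, spacing)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        xyz = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        if jitter > 0:
            xyz = xyz + rng.uniform(-jitter * spacing, jitter * spacing, xyz.shape)
        r = np.linalg.norm(xyz, axis=1)
        xyz = xyz[(r <= r_out) & (r >= r_in)]
    else:
        raise ValueError(f"unknown analytic shape {kind!r}")
    n = len(xyz)
    return AtomicModel(xyz, np.full(n, "B"), np.full(n, "HEAD_OTHER"),
                       np.zeros(n, dtype=int), np.zeros(n, dtype=int))
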