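"""Structural characterisation of conformer pools and selected ensembles.

Per-frame radius of gyration and maximum dimension (for full-pool vs
selected-ensemble histogram comparisons), tagged-atom pair distance
distributions with intra-/inter-molecule splitting, an octahedral
packing-order score for the hexameric arrangement, Kabsch RMSD series,
and a radial distribution function.

"Hexagonal packing" of the six molecules is operationalised as the
RMSD of the six molecule centroids from the best-fit ideal octahedron
(cube-face centres), minimised over rotation, vertex assignment and
uniform scale; 0 means a perfect cube-face arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .model_gen import AtomicModel, ConformerPool
from .saxs_forward import PairDistribution, rg_from_coords


@dataclass
class DistributionSummary:
    """Per-frame scalar series with its histogram and summary statistics."""

    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    mode: float     # centre of the most populated bin

    @classmethod
    def from_values(cls, values, bins=30, range_=None) -> "DistributionSummary":
        values = np.asarray(values, dtype=float)
        counts, edges = np.histogram(values, bins=bins, range=range_)
        centres = 0.5 * (edges[:-1] + edges[1:])
        return cls(values, edges, counts, float(values.mean()),
                   float(values.std(ddof=0)), float(centres[np.argmax(counts)]))


def per_frame_descriptors(pool: ConformerPool, selection=None,
                          weights="unit") -> Tuple[np.ndarray, np.ndarray]:
    """(Rg series, Dmax series) over all frames; Dmax is the exact
    maximum pairwise distance."""
    rg = np.empty(len(pool))
    dmax = np.empty(len(pool))
    for i, frame in enumerate(pool.frames):
        sub = frame.subset(selection)
        rg[i] = rg_from_coords(frame, selection, weights=weights)
        dmax[i] = float(pdist(sub.coords).max()) if sub.n_atoms > 1 else 0.0
    return rg, dmax


def compare_distributions(full: DistributionSummary,
                          selected: DistributionSummary) -> dict:
    """Summary deltas between a full-pool and a selected-ensemble
    distribution computed on identical binning."""
    if not np.array_equal(full.bin_edges, selected.bin_edges):
        raise ValueError("distributions must share binning")
    return {
        "delta_mean": selected.mean - full.mean,
        "delta_sd": selected.sd - full.sd,
        "sd_ratio": selected.sd / full.sd if full.sd > 0 else np.inf,
        "mode_shift": selected.mode - full.mode,
        "n_full": int(full.counts.sum()),
        "n_selected": int(selected.counts.sum()),
    }


def group_pair_distribution(frames, tag: str, bin_width: float = 0.5,
                            pairs: str = "all") -> PairDistribution:
    """Pair distance distribution of one atom group, pooled over frames.

    ``pairs`` restricts to "intra" (same molecule), "inter" (different
    molecules) or "all"; the first sharp peaks of such histograms are
    intra-molecular, later ones inter-molecular.
    """
    if pairs not in ("all", "intra", "inter"):
        raise ValueError(f"unknown pair filter {pairs!r}")
    if isinstance(frames, ConformerPool):
        frames = frames.frames
    elif isinstance(frames, AtomicModel):
        frames = [frames]
    dists = []
    for frame in frames:
        mask = frame.group_tag == tag
        if not mask.any():
            raise ValueError(f"tag {tag!r} absent from frame")
        xyz = frame.coords[mask]
        mol = frame.molecule_id[mask]
        i, j = np.triu_indices(len(xyz), k=1)
        if pairs == "intra":
            keep = mol[i] == mol[j]
        elif pairs == "inter":
            keep = mol[i] != mol[j]
        else:
            keep = slice(None)
        d = np.linalg.norm(xyz[i] - xyz[j], axis=1)[keep]
        dists.append(d)
    d = np.concatenate(dists)
    if len(d) == 0:
        raise ValueError("no pairs after filtering")
    n_bins = max(1, int(np.ceil(d.max() / bin_width)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    p, _ = np.histogram(d, bins=edges)
    occupied = np.nonzero(p)[0]
    dmax = float(edges[occupied[-1] + 1]) if len(occupied) else 0.0
    return PairDistribution(0.5 * (edges[:-1] + edges[1:]), p.astype(float),
                            dmax, bin_width)


# ---------------------------------------------------------------------------
# packing order
# ---------------------------------------------------------------------------

_OCTAHEDRON = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)


def _fixed_rotation_starts(n_random: int = 8) -> list:
    rng = np.random.default_rng(20260925)
    starts = [Rotation.identity()]
    for axis in ([0, 0, 1], [0, 1, 0], [1, 0, 0], [1, 1, 1]):
        a = np.asarray(axis, float)
        starts.append(Rotation.from_rotvec(np.pi / 4 * a / np.linalg.norm(a)))
    starts.extend(Rotation.random(n_random, random_state=rng))
    return starts


_STARTS = _fixed_rotation_starts()


def packing_order_score(frame: AtomicModel, tags=("CALIX_C", "CALIX_O")) -> float:
    """Dimensionless deviation of the 6 molecule centroids from the
    ideal cube-face (octahedral) arrangement.

    Centroids of the calixarene beads of each molecule are centred and
    scaled to unit mean radius, then fitted to the octahedron vertices
    minimising RMSD over rotation, vertex assignment (Hungarian) and a
    uniform scale.  0 for the ideal hexamer; invariant to rigid motion
    and uniform scaling of the frame.
    """
    mask = np.isin(frame.group_tag, tags)
    mols = np.unique(frame.molecule_id[mask])
    if len(mols) != 6:
        raise ValueError(f"packing order defined for 6 molecules, got {len(mols)}")
    cent = np.array([frame.coords[mask & (frame.molecule_id == m)].mean(axis=0)
                     for m in mols])
    cent = cent - cent.mean(axis=0)
    radius = np.linalg.norm(cent, axis=1).mean()
    if radius == 0:
        return float(np.sqrt((cent ** 2).sum() / 6 + 1.0))
    x = cent / radius

    best = np.inf
    for r0 in _STARTS:
        rot = r0
        prev = None
        for _ in range(30):
            target = rot.apply(_OCTAHEDRON)
            cost = cdist(x, target) ** 2
            row, col = linear_sum_assignment(cost)
            t = _OCTAHEDRON[col]
            rot, _ = Rotation.align_vectors(x, t)
            rt = rot.apply(t)
            s = float((x * rt).sum() / (rt * rt).sum())
            rmsd = float(np.sqrt(((x - s * rt) ** 2).sum() / 6))
            if prev is not None and abs(prev - rmsd) < 1e-14:
                break
            prev = rmsd
        best = min(best, rmsd)
    return best


# ---------------------------------------------------------------------------
# RMSD and RDF
# ---------------------------------------------------------------------------

def rmsd_series(pool: ConformerPool, reference, selection=None,
                superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD to a reference frame (index or model), after
    least-squares (Kabsch) superposition unless disabled."""
    if isinstance(reference, (int, np.integer)):
        reference = pool.frames[int(reference)]
    ref = reference.subset(selection)
    out = np.empty(len(pool))
    ref_xyz = ref.coords - ref.coords.mean(axis=0)
    for i, frame in enumerate(pool.frames):
        sub = frame.subset(selection)
        if sub.n_atoms != ref.n_atoms:
            raise ValueError(f"frame {i}: atom count mismatch")
        if superpose:
            xyz = sub.coords - sub.coords.mean(axis=0)
            _, rssd = Rotation.align_vectors(ref_xyz, xyz)
            out[i] = rssd / np.sqrt(ref.n_atoms)
        else:
            out[i] = float(np.sqrt(((sub.coords - ref.coords) ** 2)
                                   .sum(axis=1).mean()))
    return out


def rdf(frame: AtomicModel, selection_a, selection_b, bin_width: float,
        r_max: float, box: Optional[float] = None,
        volume: Optional[float] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) of group b around group a.

    With ``box`` (cubic edge length), distances use the minimum-image
    convention and r_max must not exceed half the box; otherwise a
    sampling ``volume`` must be supplied for the ideal-gas
    normalisation.  Returns (bin centres, g).
    """
    a = frame.subset(selection_a)
    b = frame.subset(selection_b)
    if box is not None:
        if r_max > box / 2:
            raise ValueError("r_max exceeds half the periodic box")
        vol = box ** 3
        tree_a = cKDTree(a.coords % box, boxsize=box)
        tree_b = cKDTree(b.coords % box, boxsize=box)
    else:
        if volume is None:
            raise ValueError("non-periodic RDF needs an explicit volume")
        vol = volume
        tree_a = cKDTree(a.coords)
        tree_b = cKDTree(b.coords)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    cum = tree_a.count_neighbors(tree_b, edges)
    # first edge at 0: exact self-pairs (d = 0) fall outside every (lo, hi] bin
    counts = np.diff(cum).astype(float)
    shell_vol = 4.0 / 3.0 * np.pi * np.diff(edges ** 3)
    rho_b = b.n_atoms / vol
    expected = a.n_atoms * rho_b * shell_vol
    g = counts / expected
    return 0.5 * (edges[:-1] + edges[1:]), g
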