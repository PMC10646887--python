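"""Frame-level interaction analyses.

Hydrogen-bond detection (3.0 Å donor–acceptor, 20° acceptor–donor–hydrogen
criteria), radial distribution functions with 0.1 Å spherical shells,
COM distance time series, angle–distance conformational maps, Voronoi
contact surface areas under periodic boundaries, and switched nonbonded
interaction energies (12-6 LJ with Lorentz–Berthelot combination plus
Coulomb, both smoothly truncated by the CHARMM switching polynomial
between 10 and 12 Å).  Group interaction energies realize the
complex-minus-parts contract E_int = E(complex) − E(receptor) − E(ligand)
at the level of cross-group nonbonded terms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi

from .core import Frame, Topology, Trajectory, center_of_mass, minimum_image
from .units import COULOMB_KCAL

__all__ = [
    "HBond",
    "RDFProfile",
    "ConformationMap",
    "EnergyDecomposition",
    "detect_hbonds",
    "rdf",
    "com_distance_series",
    "angle_distance_map",
    "nonbonded_energy",
    "switching_function",
    "contact_surface_area",
    "interaction_report",
]

HBOND_MAX_DA = 3.0      # Å
HBOND_MAX_ANGLE = 20.0  # degrees
RDF_SHELL_DEFAULT = 0.1  # Å
CUTOFF_DEFAULT = 12.0    # Å
SWITCH_ON_DEFAULT = 10.0  # Å


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float


@dataclass
class RDFProfile:
    r: np.ndarray
    g: np.ndarray
    shell_width: float
    reference: str = ""
    targets: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("g(r) must be nonnegative")
        steps = np.diff(self.r)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("shell centers must increase with constant step")


@dataclass
class ConformationMap:
    d_edges: np.ndarray
    theta_edges: np.ndarray
    counts: np.ndarray
    series: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


@dataclass
class EnergyDecomposition:
    e_vdw: float
    e_elec: float
    group_a: str = "A"
    group_b: str = "B"
    cutoff: float = CUTOFF_DEFAULT
    switch_on: float = SWITCH_ON_DEFAULT

    @property
    def total(self) -> float:
        return self.e_vdw + self.e_elec


# ---------------------------------------------------------------------------
# hydrogen bonds


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    donors: Iterable[int] | None = None,
    acceptors: Iterable[int] | None = None,
    max_da: float = HBOND_MAX_DA,
    max_angle: float = HBOND_MAX_ANGLE,
) -> list[HBond]:
    """All (donor, hydrogen, acceptor) triples meeting the geometric criteria.

    A hydrogen bond requires d(D,A) ≤ ``max_da`` and an acceptor–donor–
    hydrogen angle (vertex at the donor) ≤ ``max_angle``.  Donor hydrogens
    are resolved through the covalent bond list; a donor without a bonded
    hydrogen is skipped with a warning.  Results are sorted by
    (donor, acceptor).
    """
    if donors is None:
        if topology.donor is None:
            raise ValueError("no donor flags on topology and no donors given")
        donors = np.flatnonzero(topology.donor)
    if acceptors is None:
        if topology.acceptor is None:
            raise ValueError("no acceptor flags on topology and no acceptors given")
        acceptors = np.flatnonzero(topology.acceptor)
    donors = sorted(int(i) for i in donors)
    acceptors = np.array(sorted(int(i) for i in acceptors), dtype=int)
    if acceptors.size == 0 or not donors:
        return []

    pos = frame.coordinates
    out: list[HBond] = []
    for d in donors:
        hydrogens = topology.donor_hydrogens(d)
        if not hydrogens:
            warnings.warn(f"donor atom {d} has no bonded hydrogen; skipped")
            continue
        da = minimum_image(pos[acceptors] - pos[d], frame.box)
        dist = np.linalg.norm(da, axis=1)
        near = (dist <= max_da) & (acceptors != d)
        for h in hydrogens:
            dh = minimum_image(pos[h] - pos[d], frame.box)
            for j in np.flatnonzero(near):
                a = int(acceptors[j])
                if a == h:
                    continue
                ang = _angle_deg(da[j], dh)
                if ang <= max_angle:
                    out.append(
                        HBond(donor=d, hydrogen=int(h), acceptor=a,
                              distance=float(dist[j]), angle=ang)
                    )
    out.sort(key=lambda hb: (hb.donor, hb.acceptor, hb.hydrogen))
    return out


# ---------------------------------------------------------------------------
# radial distribution function


def rdf(
    trajectory: Trajectory,
    reference: Iterable[int],
    targets: Iterable[int],
    r_max: float,
    shell: float = RDF_SHELL_DEFAULT,
) -> RDFProfile:
    """Frame-averaged g(r) with spherical shells of width ``shell`` (0.1 Å).

    Shell counts around each reference atom are normalized by the exact
    shell volume and the target number density N_target/V.  The reference
    may be a single atom (nanoparticle-center convention) or a group
    (all-pairs average); identical atom indices are excluded pairwise.
    Requires a periodic box; ``r_max`` must not exceed half the smallest
    box length.
    """
    ref = np.array(sorted(set(int(i) for i in reference)), dtype=int)
    tgt = np.array(sorted(set(int(i) for i in targets)), dtype=int)
    if ref.size == 0 or tgt.size == 0:
        raise ValueError("reference and target groups must be non-empty")
    edges = np.arange(0.0, r_max + 0.5 * shell, shell)
    counts = np.zeros(edges.size - 1)
    n_frames = 0
    for frame in trajectory:
        if frame.box is None:
            raise ValueError("rdf requires a periodic box")
        if r_max > 0.5 * frame.box.min():
            raise ValueError("r_max exceeds half the smallest box length")
        rho = tgt.size / np.prod(frame.box)
        if rho <= 0:
            raise ValueError("zero target density")
        tpos = frame.coordinates[tgt]
        # chunk the reference axis to bound the pair-matrix memory
        chunk = max(1, int(2_000_000 / max(tgt.size, 1)))
        for start in range(0, ref.size, chunk):
            rc = ref[start:start + chunk]
            delta = minimum_image(
                tpos[None, :, :] - frame.coordinates[rc][:, None, :], frame.box
            )
            dist = np.linalg.norm(delta, axis=2)
            same = rc[:, None] == tgt[None, :]
            dist = dist[~same]
            counts += np.histogram(dist, bins=edges)[0]
        n_frames += 1
    shell_volumes = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (n_frames * ref.size * shell_volumes * rho)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFProfile(r=centers, g=g, shell_width=shell)


# ---------------------------------------------------------------------------
# COM distances and angle–distance maps


def com_distance_series(
    trajectory: Trajectory,
    group_a: Iterable[int],
    group_b: Iterable[int],
) -> np.ndarray:
    """Per-frame minimum-image distance between two group COMs (Å)."""
    ga = list(group_a)
    gb = list(group_b)
    out = np.empty(len(trajectory))
    for k, frame in enumerate(trajectory):
        ca = center_of_mass(frame, ga, trajectory.topology)
        cb = center_of_mass(frame, gb, trajectory.topology)
        out[k] = np.linalg.norm(minimum_image(cb - ca, frame.box))
    return out


def angle_distance_map(
    trajectory: Trajectory,
    center_atom: int,
    molecules: Sequence[tuple[Iterable[int], int, int]],
    d_bins: np.ndarray | int = 50,
    theta_bins: np.ndarray | int = 36,
) -> ConformationMap:
    """2D (distance, angle) histogram of molecular poses around a center atom.

    For each molecule (COM group, tail atom, head atom) and frame,
    d = |COM − center| and θ = the angle at the tail vertex between the
    tail→center and tail→head directions (degrees).  Degenerate zero-length
    vectors skip that molecule/frame with a warning.
    """
    mols = [(list(g), int(t), int(h)) for g, t, h in molecules]
    for _, t, h in mols:
        if t == h:
            raise ValueError("tail and head atoms must be distinct")
    series: list[tuple[list[float], list[float]]] = [([], []) for _ in mols]
    top = trajectory.topology
    for frame in trajectory:
        c = frame.coordinates[center_atom]
        for m, (group, tail, head) in enumerate(mols):
            com = center_of_mass(frame, group, top)
            d = float(np.linalg.norm(minimum_image(com - c, frame.box)))
            v1 = minimum_image(c - frame.coordinates[tail], frame.box)
            v2 = minimum_image(frame.coordinates[head] - frame.coordinates[tail],
                               frame.box)
            if np.linalg.norm(v1) < 1e-12 or np.linalg.norm(v2) < 1e-12:
                warnings.warn(f"degenerate geometry for molecule {m}; frame skipped")
                continue
            series[m][0].append(d)
            series[m][1].append(_angle_deg(v1, v2))
    all_d = np.concatenate([np.asarray(s[0]) for s in series]) if mols else np.array([])
    all_t = np.concatenate([np.asarray(s[1]) for s in series]) if mols else np.array([])
    if isinstance(theta_bins, int):
        theta_bins = np.linspace(0.0, 180.0, theta_bins + 1)
    counts, d_edges, t_edges = np.histogram2d(all_d, all_t,
                                              bins=[d_bins, theta_bins])
    return ConformationMap(
        d_edges=d_edges, theta_edges=t_edges, counts=counts,
        series=[(np.asarray(s[0]), np.asarray(s[1])) for s in series],
    )


# ---------------------------------------------------------------------------
# nonbonded energies


def switching_function(
    r: np.ndarray, switch_on: float = SWITCH_ON_DEFAULT,
    cutoff: float = CUTOFF_DEFAULT,
) -> np.ndarray:
    """CHARMM switching polynomial: 1 below ``switch_on``, 0 beyond ``cutoff``,
    C¹-continuous in between."""
    r = np.asarray(r, dtype=float)
    r2, on2, off2 = r**2, switch_on**2, cutoff**2
    mid = ((off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2)) / (off2 - on2) ** 3
    return np.where(r <= switch_on, 1.0, np.where(r >= cutoff, 0.0, mid))


def nonbonded_energy(
    frame: Frame,
    topology: Topology,
    group_a: Iterable[int],
    group_b: Iterable[int],
    cutoff: float = CUTOFF_DEFAULT,
    switch_on: float = SWITCH_ON_DEFAULT,
) -> EnergyDecomposition:
    """Cross-group switched nonbonded energies (kcal mol⁻¹).

    Sums over all A×B pairs within the cutoff: CHARMM-form 12-6 LJ,
    ε_ij = √(ε_i ε_j), Rmin_ij = Rmin/2_i + Rmin/2_j, plus Coulomb with
    the 332.0637 Å·kcal mol⁻¹ e⁻² prefactor and dielectric 1; both terms
    are multiplied by the switching polynomial on [switch_on, cutoff].
    Symmetric in its group arguments and additive over partitions of
    either group.
    """
    ia = np.array(sorted(set(int(i) for i in group_a)), dtype=int)
    ib = np.array(sorted(set(int(i) for i in group_b)), dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups must be disjoint")
    for name, arr in (("charges", topology.charges),
                      ("epsilon", topology.epsilon),
                      ("rmin_half", topology.rmin_half)):
        if arr is None:
            raise ValueError(f"topology lacks {name} parameters")
        needed = np.concatenate([ia, ib])
        if not np.all(np.isfinite(np.asarray(arr)[needed])):
            bad = needed[~np.isfinite(np.asarray(arr)[needed])]
            raise ValueError(f"missing {name} for atoms {bad.tolist()}")

    delta = minimum_image(
        frame.coordinates[ib][None, :, :] - frame.coordinates[ia][:, None, :],
        frame.box,
    )
    r = np.linalg.norm(delta, axis=2)
    within = r <= cutoff
    if not within.any():
        return EnergyDecomposition(0.0, 0.0, cutoff=cutoff, switch_on=switch_on)
    r_sel = r[within]
    s = switching_function(r_sel, switch_on, cutoff)
    qq = np.outer(topology.charges[ia], topology.charges[ib])[within]
    e_elec = float(np.sum(s * COULOMB_KCAL * qq / r_sel))
    eps = np.sqrt(np.outer(topology.epsilon[ia], topology.epsilon[ib]))[within]
    rmin = (topology.rmin_half[ia][:, None] + topology.rmin_half[ib][None, :])[within]
    ratio6 = (rmin / r_sel) ** 6
    e_vdw = float(np.sum(s * eps * (ratio6**2 - 2.0 * ratio6)))
    return EnergyDecomposition(
        e_vdw=e_vdw, e_elec=e_elec, cutoff=cutoff, switch_on=switch_on
    )


# ---------------------------------------------------------------------------
# Voronoi contact surface area

_SLIVER_AREA = 1e-9  # Å²; drop numerical sliver facets


def _polygon_area(vertices: np.ndarray) -> float:
    """Area of a planar polygon in 3D (fan triangulation)."""
    if len(vertices) < 3:
        return 0.0
    v0 = vertices[0]
    cross = np.cross(vertices[1:-1] - v0, vertices[2:] - v0)
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def contact_surface_area(
    frame: Frame,
    topology: Topology,
    group_a: Iterable[int],
    group_b: Iterable[int],
) -> float:
    """Summed area (Å²) of Voronoi facets shared between two atom groups.

    The Voronoi tessellation of all atoms is built under periodic boundary
    conditions by explicit replication of the box in the 26 neighboring
    images; each physical A|B facet is counted once (from the side whose A
    atom lies in the central image).  Standard (unweighted) tessellation.
    """
    if frame.box is None:
        raise ValueError("contact surface area requires a periodic box")
    ia = frozenset(int(i) for i in group_a)
    ib = frozenset(int(i) for i in group_b)
    if not ia or not ib:
        raise ValueError("groups must be non-empty")
    if ia & ib:
        raise ValueError("groups must be disjoint")

    coords = np.mod(frame.coordinates, frame.box)
    n = coords.shape[0]
    # perturb coincident atoms
    from scipy.spatial.distance import pdist as _pdist
    if n > 1 and _pdist(coords).min() < 1e-9:
        warnings.warn("coincident atoms perturbed by 1e-6 Å")
        rng = np.random.default_rng(0)
        coords = coords + rng.normal(0.0, 1e-6, coords.shape)

    shifts = [np.zeros(3)] + [
        np.array(s, dtype=float) * frame.box
        for s in itertools.product((-1, 0, 1), repeat=3)
        if s != (0, 0, 0)
    ]
    points = np.concatenate([coords + s for s in shifts])
    try:
        vor = Voronoi(points)
    except Exception as exc:
        raise RuntimeError(f"Voronoi tessellation failed: {exc}") from exc

    in_a = np.zeros(n, dtype=bool)
    in_b = np.zeros(n, dtype=bool)
    in_a[list(ia)] = True
    in_b[list(ib)] = True

    area = 0.0
    for (u, v), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in ridge:
            continue
        ou, ov = u % n, v % n
        count = (u < n and in_a[ou] and in_b[ov]) or (
            v < n and in_a[ov] and in_b[ou]
        )
        if not count:
            continue
        facet = _polygon_area(vor.vertices[ridge])
        if facet > _SLIVER_AREA:
            area += facet
    return float(area)


# ---------------------------------------------------------------------------
# windowed report


def interaction_report(
    trajectory: Trajectory,
    topology: Topology,
    group_pairs: Sequence[tuple[str, str]],
    window: int | None = None,
    cutoff: float = CUTOFF_DEFAULT,
    switch_on: float = SWITCH_ON_DEFAULT,
) -> pd.DataFrame:
    """Time-averaged interaction summary over the last ``window`` frames.

    For each (label_a, label_b) pair of topology groups, reports the mean
    and standard deviation of E_vdw, E_elec (kcal mol⁻¹) and the H-bond
    count (donors of either group to acceptors of the other).
    """
    n_frames = len(trajectory)
    if window is None:
        window = n_frames
    if window < 1 or window > n_frames:
        raise ValueError("window must be within the trajectory length")
    frames = trajectory.frames[-window:]

    rows = []
    for la, lb in group_pairs:
        ga, gb = topology.groups[la], topology.groups[lb]
        evdw, eelec, nhb = [], [], []
        don = (np.flatnonzero(topology.donor)
               if topology.donor is not None else np.array([], int))
        acc = (np.flatnonzero(topology.acceptor)
               if topology.acceptor is not None else np.array([], int))
        for frame in frames:
            e = nonbonded_energy(frame, topology, ga, gb, cutoff, switch_on)
            evdw.append(e.e_vdw)
            eelec.append(e.e_elec)
            count = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for dset, aset in ((ga, gb), (gb, ga)):
                    hb = detect_hbonds(
                        frame, topology,
                        donors=[i for i in don if i in dset],
                        acceptors=[i for i in acc if i in aset],
                    )
                    count += len(hb)
            nhb.append(count)
        rows.append({
            "group_a": la, "group_b": lb,
            "e_vdw_mean": float(np.mean(evdw)), "e_vdw_std": float(np.std(evdw)),
            "e_elec_mean": float(np.mean(eelec)), "e_elec_std": float(np.std(eelec)),
            "hbonds_mean": float(np.mean(nhb)), "hbonds_std": float(np.std(nhb)),
            "n_frames": window,
        })
    return pd.DataFrame(rows)
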