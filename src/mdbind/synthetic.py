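"""Synthetic inputs with known ground truth.

Everything the analysis layer consumes can be generated here: biased
Brownian samples of a 1D reaction coordinate from analytic potentials
(umbrella windows), feature matrices with planted Gaussian microstates,
and toy molecular frames with planted hydrogen bonds, reference lattice /
ideal-gas configurations, and two-group contact geometries.

All generators are pure functions of their arguments including the seed:
rerunning with the same seed reproduces results bitwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .core import Frame, Topology
from .pmf import UmbrellaWindow
from .som import FeatureMatrix
from .units import (
    BIAS_K_DEFAULT,
    TEMPERATURE_DEFAULT,
    WINDOW_SPACING_DEFAULT,
    kBT,
)

__all__ = [
    "Potential1D",
    "SyntheticUmbrellaSet",
    "PlantedMicrostates",
    "ToyComplex",
    "IntegrationError",
    "PlacementError",
    "simulate_langevin_window",
    "generate_umbrella_set",
    "generate_planted_features",
    "generate_toy_complex",
    "generate_reference_configs",
]

DEFAULT_SEED = 1234


class IntegrationError(RuntimeError):
    """The Brownian-dynamics step size is unstable for this potential."""


class PlacementError(RuntimeError):
    """Atoms or cluster centers could not be placed under the constraints."""


@dataclass
class Potential1D:
    """Analytic 1D potential U(ξ) (kcal mol⁻¹, ξ in Å) on a finite domain."""

    kind: str
    energy_fn: Callable[[np.ndarray], np.ndarray]
    force_fn: Callable[[np.ndarray], np.ndarray]
    max_curvature: float
    domain: tuple[float, float]
    parameters: dict = field(default_factory=dict)

    def energy(self, xi):
        return self.energy_fn(np.asarray(xi, dtype=float))

    def force(self, xi):
        return self.force_fn(np.asarray(xi, dtype=float))

    def describe(self) -> dict:
        return {"kind": self.kind, "domain": list(self.domain), **self.parameters}

    # ---- factories -------------------------------------------------------

    @classmethod
    def flat(cls, domain=(-10.0, 10.0)) -> "Potential1D":
        return cls(
            kind="flat",
            energy_fn=lambda x: np.zeros_like(x),
            force_fn=lambda x: np.zeros_like(x),
            max_curvature=0.0,
            domain=tuple(domain),
        )

    @classmethod
    def harmonic(cls, a: float, center: float = 0.0, domain=None) -> "Potential1D":
        """U = ½·a·(ξ−ξ*)², curvature ``a`` in kcal mol⁻¹ Å⁻²."""
        if domain is None:
            domain = (center - 10.0, center + 10.0)
        return cls(
            kind="harmonic",
            energy_fn=lambda x: 0.5 * a * (x - center) ** 2,
            force_fn=lambda x: -a * (x - center),
            max_curvature=abs(a),
            domain=tuple(domain),
            parameters={"a": a, "center": center},
        )

    @classmethod
    def double_well(
        cls, barrier: float, center: float = 0.0, half_width: float = 3.0,
        domain=None,
    ) -> "Potential1D":
        """Symmetric quartic double well: minima at center±half_width, barrier
        height ``barrier`` (kcal mol⁻¹) at the center."""
        h, w = float(barrier), float(half_width)
        if domain is None:
            domain = (center - 2.5 * w, center + 2.5 * w)

        def u(x):
            s = x - center
            return h * (s**2 - w**2) ** 2 / w**4

        def fo(x):
            s = x - center
            return -4.0 * h * s * (s**2 - w**2) / w**4

        # |U''| is largest at the domain edges; at the wells it is 8h/w²
        span = max(abs(domain[0] - center), abs(domain[1] - center))
        curv = 4.0 * h * (3.0 * span**2 - w**2) / w**4
        return cls(
            kind="double-well", energy_fn=u, force_fn=fo,
            max_curvature=max(curv, 8.0 * h / w**2), domain=tuple(domain),
            parameters={"barrier": h, "center": center, "half_width": w},
        )

    @classmethod
    def tabulated(cls, xi_grid, energies) -> "Potential1D":
        xi_grid = np.asarray(xi_grid, dtype=float)
        energies = np.asarray(energies, dtype=float)
        if np.any(np.diff(xi_grid) <= 0):
            raise ValueError("tabulated ξ grid must be strictly increasing")
        if not np.all(np.isfinite(energies)):
            raise ValueError("tabulated energies must be finite")
        spline = CubicSpline(xi_grid, energies)
        d1, d2 = spline.derivative(1), spline.derivative(2)
        dense = np.linspace(xi_grid[0], xi_grid[-1], 2048)
        return cls(
            kind="tabulated",
            energy_fn=spline,
            force_fn=lambda x: -d1(x),
            max_curvature=float(np.max(np.abs(d2(dense)))),
            domain=(float(xi_grid[0]), float(xi_grid[-1])),
            parameters={"n_points": int(xi_grid.size)},
        )


@dataclass
class SyntheticUmbrellaSet:
    """Umbrella windows drawn from a known potential, with that ground truth."""

    windows: list[UmbrellaWindow]
    potential: Potential1D
    temperature: float
    seed: int
    overlap_ok: bool = True
    sufficient: bool = True


@dataclass
class PlantedMicrostates:
    """Feature matrix with known per-frame cluster labels."""

    features: FeatureMatrix
    labels: np.ndarray
    centers: np.ndarray
    spread: float
    seed: int


@dataclass
class ToyComplex:
    """Toy molecular frame with its planted H-bond ground truth."""

    frame: Frame
    topology: Topology
    planted_hbonds: list[tuple[int, int, int]]


# ---------------------------------------------------------------------------
# Brownian dynamics along ξ


def simulate_langevin_window(
    potential: Potential1D,
    bias_center: float,
    bias_k: float = BIAS_K_DEFAULT,
    temperature: float = TEMPERATURE_DEFAULT,
    n_steps: int = 100_000,
    dt: float = 0.01,
    friction: float = 1.0,
    seed: int = DEFAULT_SEED,
    stride: int = 10,
    burn_in_fraction: float = 0.1,
) -> UmbrellaWindow:
    """Overdamped Langevin (Euler–Maruyama) sampling of one umbrella window.

    The coordinate evolves as dξ = F(ξ)/γ·dt + √(2 kBT dt/γ)·N(0,1) with
    total force F from the potential plus the harmonic bias ½k(ξ−ξ₀)².
    After discarding the first ``burn_in_fraction`` of steps, every
    ``stride``-th position is recorded, emulating trajectory saving.
    Samples follow exp(−[U(ξ)+½k(ξ−ξ₀)²]/kBT); excursions beyond the
    potential's domain are reflected and counted (warning above 1%).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if bias_k < 0:
        raise ValueError("bias_k must be nonnegative")
    if dt <= 0 or friction <= 0:
        raise ValueError("dt and friction must be positive")
    max_curv = potential.max_curvature + bias_k
    if max_curv > 0 and dt * max_curv / friction >= 0.5:
        raise IntegrationError(
            f"unstable step: dt·max|U''|/γ = {dt * max_curv / friction:.3g} >= 0.5"
        )

    rng = np.random.default_rng(seed)
    lo, hi = potential.domain
    mobility = dt / friction
    noise_scale = np.sqrt(2.0 * kBT(temperature) * mobility)
    noise = rng.standard_normal(n_steps)

    x = float(np.clip(bias_center, lo, hi))
    burn_in = int(burn_in_fraction * n_steps)
    samples = np.empty((n_steps - burn_in - 1) // stride + 1)
    n_rec = 0
    n_reflect = 0
    force_fn = potential.force_fn
    for step in range(n_steps):
        f_total = float(force_fn(x)) - bias_k * (x - bias_center)
        x = x + mobility * f_total + noise_scale * noise[step]
        if x < lo:
            x = 2.0 * lo - x
            n_reflect += 1
        elif x > hi:
            x = 2.0 * hi - x
            n_reflect += 1
        if step >= burn_in and (step - burn_in) % stride == 0:
            samples[n_rec] = x
            n_rec += 1
    if n_reflect > 0.01 * n_steps:
        warnings.warn(
            f"{n_reflect / n_steps:.1%} of steps reflected at the domain boundary"
        )
    return UmbrellaWindow(
        bias_center=bias_center, bias_k=bias_k,
        samples=samples[:n_rec], temperature=temperature,
    )


def generate_umbrella_set(
    potential: Potential1D,
    centers: Sequence[float] | None = None,
    bias_k: float = BIAS_K_DEFAULT,
    temperature: float = TEMPERATURE_DEFAULT,
    samples_per_window: int = 10_000,
    seed: int = DEFAULT_SEED,
    dt: float = 0.01,
    friction: float = 1.0,
    stride: int = 10,
) -> SyntheticUmbrellaSet:
    """Umbrella set across windows spaced 0.1 nm, biased at k = 1000 kJ mol⁻¹ nm⁻².

    Defaults mirror the umbrella protocol this package emulates (see the
    methods note); ``centers`` defaults to 11 windows spaced 1 Å about the
    potential's domain midpoint.  Adjacent-window histogram overlap is
    verified post hoc; a set without overlap is flagged but still returned.
    """
    if centers is None:
        mid = 0.5 * (potential.domain[0] + potential.domain[1])
        centers = mid + WINDOW_SPACING_DEFAULT * (np.arange(11) - 5)
    centers = np.asarray(centers, dtype=float)
    if centers.size >= 2 and np.any(np.diff(centers) <= 0):
        raise ValueError("window centers must be strictly increasing")

    n_steps = int(np.ceil(samples_per_window * stride / 0.9)) + stride
    seeds = np.random.SeedSequence(seed).spawn(centers.size)
    windows = []
    for c, ss in zip(centers, seeds):
        w = simulate_langevin_window(
            potential, float(c), bias_k, temperature, n_steps, dt, friction,
            seed=int(ss.generate_state(1)[0] % (2**31)), stride=stride,
        )
        w.samples = w.samples[:samples_per_window]
        windows.append(w)

    sufficient = centers.size >= 2
    overlap_ok = True
    if sufficient:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        edges = np.linspace(lo, hi, 201)
        hists = [np.histogram(w.samples, bins=edges)[0] for w in windows]
        for i in range(len(windows) - 1):
            if not np.any((hists[i] > 0) & (hists[i + 1] > 0)):
                overlap_ok = False
        if not overlap_ok:
            warnings.warn(
                "adjacent umbrella windows have non-overlapping histograms; "
                "WHAM may be unreliable"
            )
    else:
        warnings.warn("single-window set: insufficient for profile estimation")
    return SyntheticUmbrellaSet(
        windows=windows, potential=potential, temperature=temperature,
        seed=seed, overlap_ok=overlap_ok, sufficient=sufficient,
    )


# ---------------------------------------------------------------------------
# planted microstates


def generate_planted_features(
    n_clusters: int,
    n_features: int = 10,
    n_frames: int = 2000,
    separation: float = 5.0,
    spread: float = 0.5,
    weights: Sequence[float] | None = None,
    seed: int = DEFAULT_SEED,
    max_tries: int = 1000,
) -> PlantedMicrostates:
    """Frames drawn from isotropic Gaussian blobs in distance-feature space.

    Blob centers are placed pairwise at least ``separation`` (Å) apart;
    frames scatter around them with standard deviation ``spread`` per
    feature and are clipped non-negative (they are distances).  The default
    separation/spread ratio of 10 emulates well-resolved conformational
    microstates.
    """
    if separation <= 0 or spread <= 0:
        raise ValueError("separation and spread must be positive")
    if weights is None:
        weights = np.full(n_clusters, 1.0 / n_clusters)
    weights = np.asarray(weights, dtype=float)
    if weights.size != n_clusters or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must have one entry per cluster and sum to 1")

    rng = np.random.default_rng(seed)
    low = 4.0 * spread + 1.0  # keep blobs clear of the non-negativity clip
    high = low + max(2.0 * separation, separation * n_clusters ** (1.0 / n_features) * 2.0)
    centers = np.empty((n_clusters, n_features))
    for c in range(n_clusters):
        for _ in range(max_tries):
            cand = rng.uniform(low, high, n_features)
            if c == 0 or np.min(
                np.linalg.norm(centers[:c] - cand, axis=1)
            ) >= separation:
                centers[c] = cand
                break
        else:
            raise PlacementError(
                f"could not place cluster center {c} with separation {separation}"
            )

    labels = rng.choice(n_clusters, size=n_frames, p=weights)
    values = centers[labels] + rng.normal(0.0, spread, (n_frames, n_features))
    np.clip(values, 0.0, None, out=values)
    features = FeatureMatrix(
        values=values,
        labels=[f"d{k:02d}" for k in range(n_features)],
        frame_indices=np.arange(n_frames),
    )
    return PlantedMicrostates(
        features=features, labels=labels, centers=centers, spread=spread, seed=seed
    )


# ---------------------------------------------------------------------------
# toy molecular frames

_DA_MAX_PLANT = 2.8     # planted donor–acceptor distance ceiling (Å)
_ANGLE_MAX_PLANT = 10.0  # planted A–D–H angle ceiling (deg)
_SITE_CLEARANCE = 5.2    # min distance between independent sites (Å)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _place_site(
    rng: np.random.Generator, occupied: list[np.ndarray], box: float,
    clearance: float, max_tries: int,
) -> np.ndarray:
    for _ in range(max_tries):
        p = rng.uniform(0.0, box, 3)
        ok = True
        for q in occupied:
            d = p - q
            d -= box * np.round(d / box)
            if np.linalg.norm(d) < clearance:
                ok = False
                break
        if ok:
            return p
    raise PlacementError("could not place atoms without steric overlap")


def _tilted_direction(rng, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Unit vector at the given angle from ``axis``."""
    perp = np.cross(axis, _random_unit(rng))
    norm = np.linalg.norm(perp)
    while norm < 1e-8:
        perp = np.cross(axis, _random_unit(rng))
        norm = np.linalg.norm(perp)
    perp /= norm
    a = np.deg2rad(angle_deg)
    return np.cos(a) * axis + np.sin(a) * perp


def _verify_toy_margins(
    coords: np.ndarray,
    elements: list[str],
    bonds: list[tuple[int, int]],
    donor_flags: list[bool],
    acceptor_flags: list[bool],
    planted: set[tuple[int, int, int]],
    box: float,
) -> bool:
    """Every non-planted (D,H,A) triple must miss the criteria with margin.

    Planted triples satisfy d ≤ 2.8 Å and angle ≤ 8°; everything else must
    have d ≥ 3.3 Å or angle ≥ 35°, so the detected count is stable under
    coordinate jitter well beyond 0.05 Å.
    """
    hydrogens = {d: h for d, h in bonds}
    box_vec = np.full(3, box)
    for d, is_don in enumerate(donor_flags):
        if not is_don or d not in hydrogens:
            continue
        h = hydrogens[d]
        dh = coords[h] - coords[d]
        dh -= box_vec * np.round(dh / box_vec)
        for a, is_acc in enumerate(acceptor_flags):
            if not is_acc or a == d:
                continue
            da = coords[a] - coords[d]
            da -= box_vec * np.round(da / box_vec)
            dist = np.linalg.norm(da)
            cosang = np.dot(da, dh) / (dist * np.linalg.norm(dh))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if (d, h, a) in planted:
                if dist > _DA_MAX_PLANT or angle > _ANGLE_MAX_PLANT:
                    return False
            elif dist < 3.3 and angle < 35.0:
                return False
    return True


def generate_toy_complex(
    n_planted_hbonds: int,
    n_decoy_atoms: int = 20,
    box: float = 30.0,
    seed: int = DEFAULT_SEED,
    max_tries: int = 2000,
) -> ToyComplex:
    """A frame with exactly ``n_planted_hbonds`` donor–H···acceptor triplets.

    Planted triplets satisfy d(D,A) ≤ 2.8 Å and A–D–H angle ≤ 10°; decoys
    miss at least one criterion with a margin (≥0.3 Å in distance or ≥15°
    in angle) so small coordinate jitter cannot flip the count.  Decoy
    types cycle through far acceptors, misaligned donor triplets, and
    inert carbons.  Sites are kept apart, and the whole construction is
    re-drawn if any accidental cross-site geometry lands inside the margin
    band.
    """
    for attempt_seed in np.random.SeedSequence(seed).spawn(50):
        toy = _build_toy_complex(
            n_planted_hbonds, n_decoy_atoms, box,
            np.random.default_rng(attempt_seed), max_tries,
        )
        if toy is not None:
            return toy
    raise PlacementError("could not realize margin-safe toy complex")


def _build_toy_complex(
    n_planted_hbonds: int,
    n_decoy_atoms: int,
    box: float,
    rng: np.random.Generator,
    max_tries: int,
) -> ToyComplex | None:
    volume_per_site = (np.pi / 6.0) * _SITE_CLEARANCE**3
    if (n_planted_hbonds + n_decoy_atoms) * volume_per_site > 0.3 * box**3:
        raise PlacementError("box too small for the requested site count")
    coords: list[np.ndarray] = []
    elements: list[str] = []
    bonds: list[tuple[int, int]] = []
    donor_flags: list[bool] = []
    acceptor_flags: list[bool] = []
    planted: list[tuple[int, int, int]] = []
    sites: list[np.ndarray] = []

    def add_atom(pos, element, donor=False, acceptor=False) -> int:
        coords.append(np.asarray(pos, dtype=float))
        elements.append(element)
        donor_flags.append(donor)
        acceptor_flags.append(acceptor)
        return len(coords) - 1

    def add_triplet(max_angle, da_distance):
        site = _place_site(rng, sites, box, _SITE_CLEARANCE, max_tries)
        sites.append(site)
        axis = _random_unit(rng)
        d_idx = add_atom(site, "O", donor=True)
        a_idx = add_atom(site + da_distance * axis, "O", acceptor=True)
        tilt = rng.uniform(0.0, max_angle)
        h_dir = _tilted_direction(rng, axis, tilt)
        h_idx = add_atom(site + 1.0 * h_dir, "H")
        bonds.append((d_idx, h_idx))
        return d_idx, h_idx, a_idx

    for _ in range(n_planted_hbonds):
        d, h, a = add_triplet(
            max_angle=0.8 * _ANGLE_MAX_PLANT,
            da_distance=rng.uniform(2.6, _DA_MAX_PLANT),
        )
        planted.append((d, h, a))

    for k in range(n_decoy_atoms):
        mode = k % 3
        if mode == 0:  # lone far acceptor
            site = _place_site(rng, sites, box, _SITE_CLEARANCE, max_tries)
            sites.append(site)
            add_atom(site, "O", acceptor=True)
        elif mode == 1:  # donor triplet with a badly misaligned hydrogen
            add_triplet(max_angle=0.0, da_distance=rng.uniform(2.6, _DA_MAX_PLANT))
            # retilt the hydrogen we just added to >= 35 degrees
            d_idx, h_idx = bonds[-1]
            axis = coords[-2] - coords[d_idx]
            axis = axis / np.linalg.norm(axis)
            bad = _tilted_direction(rng, axis, rng.uniform(35.0, 120.0))
            coords[h_idx] = coords[d_idx] + 1.0 * bad
        else:  # inert carbon
            site = _place_site(rng, sites, box, _SITE_CLEARANCE, max_tries)
            sites.append(site)
            add_atom(site, "C")

    coord_arr = np.array(coords) if coords else np.zeros((0, 3))
    if not _verify_toy_margins(
        coord_arr, elements, bonds, donor_flags, acceptor_flags,
        set(planted), float(box),
    ):
        return None
    frame = Frame(coord_arr, box=np.full(3, float(box)))
    donors = frozenset(i for i, f in enumerate(donor_flags) if f)
    acceptors = frozenset(i for i, f in enumerate(acceptor_flags) if f)
    topology = Topology(
        elements=elements,
        bonds=bonds,
        donor=np.array(donor_flags, dtype=bool),
        acceptor=np.array(acceptor_flags, dtype=bool),
        groups={"DON": donors, "ACC": acceptors,
                "ALL": frozenset(range(len(elements)))},
    )
    return ToyComplex(frame=frame, topology=topology, planted_hbonds=planted)


# ---------------------------------------------------------------------------
# reference configurations


def generate_reference_configs(
    kind: str, n: int, box: float, seed: int = DEFAULT_SEED
) -> tuple[Frame, Topology]:
    """Reference fixtures for rdf and contact-area analyses.

    ``ideal-gas``: n uniformly random atoms (group ALL); g(r) ≈ 1.
    ``simple-cubic``: lattice with constant a = box/⌈n^(1/3)⌉, first rdf
    peak at a.  ``two-slab``: two mirror-symmetric half-box lattices
    (groups A and B) meeting at the x = box/2 plane, plus a thin separator
    layer (group SEP) at the periodic seam so the only A|B Voronoi
    interface is the central plane of area box².
    """
    if n < 2:
        raise ValueError("need at least two atoms")
    if box <= 0:
        raise ValueError("box must be positive")
    rng = np.random.default_rng(seed)
    box_vec = np.full(3, float(box))

    if kind == "ideal-gas":
        coords = rng.uniform(0.0, box, (n, 3))
        top = Topology(
            elements=["Ar"] * n, groups={"ALL": frozenset(range(n))}
        )
        return Frame(coords, box=box_vec), top

    if kind == "simple-cubic":
        m = int(np.ceil(n ** (1.0 / 3.0)))
        a = box / m
        grid = np.arange(m) * a + 0.5 * a
        pts = np.array(np.meshgrid(grid, grid, grid, indexing="ij"))
        coords = pts.reshape(3, -1).T[:n]
        top = Topology(
            elements=["Ar"] * len(coords),
            groups={"ALL": frozenset(range(len(coords)))},
        )
        return Frame(coords, box=box_vec), top

    if kind == "two-slab":
        m = max(2, int(round((n / 2.0) ** (1.0 / 3.0))))
        h = (box / 2.0) / m           # lattice spacing inside each half
        trans = np.arange(m) * h + 0.5 * h  # transverse grid (y, z)
        yy, zz = np.meshgrid(trans, trans, indexing="ij")
        layers = np.arange(m) * h + 0.5 * h  # depth from the central plane
        coords_a, coords_b = [], []
        for depth in layers:
            xa = box / 2.0 - depth
            xb = box / 2.0 + depth
            for y, z in zip(yy.ravel(), zz.ravel()):
                coords_a.append((xa, y, z))
                coords_b.append((xb, y, z))
        sep = [(0.0, y, z) for y, z in zip(yy.ravel(), zz.ravel())]
        coords = np.array(coords_a + coords_b + sep)
        na, nb = len(coords_a), len(coords_b)
        top = Topology(
            elements=["Ar"] * len(coords),
            groups={
                "A": frozenset(range(na)),
                "B": frozenset(range(na, na + nb)),
                "SEP": frozenset(range(na + nb, len(coords))),
            },
        )
        return Frame(coords, box=box_vec), top

    raise ValueError(
        f"unknown reference kind {kind!r}; expected 'ideal-gas', "
        "'simple-cubic', or 'two-slab'"
    )
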