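"""Readers and writers for trajectories and topology tables.

Coordinate I/O (multi-model PDB and XYZ) goes through MDAnalysis; the
topology table is a plain whitespace-delimited text format with an
``[atoms]`` section (index, element, mass, charge, epsilon, rmin_half,
donor, acceptor, groups) and an optional ``[bonds]`` section of index
pairs.  Group membership is written as a ``;``-separated label list per
atom (``-`` for none).

The PDB reader accepts single-altloc, single-chain-per-group files; chain
and altloc records beyond that are not interpreted.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Frame, Topology, Trajectory

__all__ = [
    "TrajectoryParseError",
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "write_topology",
    "read_window_table",
    "write_umbrella_set",
]


class TrajectoryParseError(ValueError):
    """A trajectory file could not be parsed as the named format."""


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "xyz"):
            raise ValueError(f"unsupported trajectory format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "xyz"):
        return suffix
    raise ValueError(f"cannot infer trajectory format from {path!r}")


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    topology: Topology | None = None,
    dt: float = 1.0,
) -> Trajectory:
    """Read a multi-model PDB or XYZ file into a :class:`Trajectory`.

    One frame per MODEL/snapshot, atom order preserved.  When no
    ``topology`` is supplied a minimal one (elements, standard masses,
    residue names/ids when present) is built from the file.
    """
    import MDAnalysis as mda

    fmt = _infer_format(path, format)
    path = str(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path, format=fmt)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise TrajectoryParseError(f"failed to parse {path} as {fmt}: {exc}") from exc

    if topology is None:
        try:
            elements = [str(e) for e in u.atoms.elements]
        except Exception:
            # fall back to the leading letters of atom names
            elements = [
                "".join(c for c in name if c.isalpha())[:2].capitalize() or "X"
                for name in u.atoms.names
            ]
        kwargs = {}
        if hasattr(u.atoms, "resids"):
            kwargs["resids"] = np.array(u.atoms.resids, dtype=int)
        if hasattr(u.atoms, "resnames"):
            kwargs["resnames"] = [str(r) for r in u.atoms.resnames]
        topology = Topology(elements=elements, **kwargs)
    elif topology.n_atoms != len(u.atoms):
        raise TrajectoryParseError(
            f"{path}: file has {len(u.atoms)} atoms, topology has "
            f"{topology.n_atoms}"
        )

    frames: list[Frame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, ts in enumerate(u.trajectory):
            box = None
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                box = np.array(ts.dimensions[:3], dtype=float)
            time = float(ts.time) if np.isfinite(ts.time) and ts.time > 0 else k * dt
            frames.append(
                Frame(np.array(ts.positions, dtype=float), box=box, time=time)
            )
    # guard against non-increasing times from the reader
    times = [f.time for f in frames]
    if any(b <= a for a, b in zip(times, times[1:])):
        for k, f in enumerate(frames):
            f.time = k * dt
    return Trajectory(frames=frames, topology=topology, dt=dt)


def write_trajectory(
    trajectory: Trajectory, path: str | Path, format: str | None = None
) -> None:
    """Write a trajectory as multi-model PDB or XYZ (via MDAnalysis)."""
    import MDAnalysis as mda

    fmt = _infer_format(path, format)
    path = str(path)
    top = trajectory.topology
    n = top.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        elements = [e.capitalize() for e in top.elements]
        u.add_TopologyAttr("names", [f"{e}{i + 1}"[:4] for i, e in enumerate(elements)])
        u.add_TopologyAttr("elements", elements)
        u.add_TopologyAttr("resnames", ["MOL"])
        with mda.Writer(path, n_atoms=n, format=fmt) as w:
            for frame in trajectory.frames:
                u.atoms.positions = frame.coordinates
                if frame.box is not None:
                    u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# topology tables

_ATOM_COLUMNS = [
    "index", "element", "mass", "charge", "epsilon", "rmin_half",
    "donor", "acceptor", "groups",
]


def write_topology(topology: Topology, path: str | Path) -> None:
    n = topology.n_atoms
    eps = topology.epsilon if topology.epsilon is not None else np.zeros(n)
    rmh = topology.rmin_half if topology.rmin_half is not None else np.zeros(n)
    don = topology.donor if topology.donor is not None else np.zeros(n, bool)
    acc = topology.acceptor if topology.acceptor is not None else np.zeros(n, bool)
    member: list[list[str]] = [[] for _ in range(n)]
    for label in sorted(topology.groups):
        for i in sorted(topology.groups[label]):
            member[i].append(label)
    with open(path, "w") as fh:
        fh.write("[atoms]\n")
        fh.write(" ".join(_ATOM_COLUMNS) + "\n")
        for i in range(n):
            groups = ";".join(member[i]) if member[i] else "-"
            fh.write(
                f"{i} {topology.elements[i]} {topology.masses[i]:.6g} "
                f"{topology.charges[i]:.8g} {eps[i]:.8g} {rmh[i]:.8g} "
                f"{int(don[i])} {int(acc[i])} {groups}\n"
            )
        if topology.bonds:
            fh.write("[bonds]\n")
            for i, j in topology.bonds:
                fh.write(f"{i} {j}\n")


def read_topology(path: str | Path) -> Topology:
    text = Path(path).read_text()
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].lower()
            sections[current] = []
            continue
        if current is None:
            raise ValueError(f"{path}: content before any [section] header")
        sections[current].append(line)
    if "atoms" not in sections or len(sections["atoms"]) < 2:
        raise ValueError(f"{path}: missing [atoms] section")
    atoms = pd.read_csv(
        _io.StringIO("\n".join(sections["atoms"])), sep=r"\s+",
    )
    missing = set(_ATOM_COLUMNS) - set(atoms.columns)
    if missing:
        raise ValueError(f"{path}: [atoms] missing columns {sorted(missing)}")
    atoms = atoms.sort_values("index").reset_index(drop=True)
    groups: dict[str, set[int]] = {}
    for i, entry in zip(atoms["index"], atoms["groups"]):
        if entry == "-" or pd.isna(entry):
            continue
        for label in str(entry).split(";"):
            groups.setdefault(label, set()).add(int(i))
    bonds = [
        tuple(int(x) for x in line.split()[:2])
        for line in sections.get("bonds", [])
    ]
    return Topology(
        elements=list(atoms["element"]),
        masses=atoms["mass"].to_numpy(float),
        charges=atoms["charge"].to_numpy(float),
        epsilon=atoms["epsilon"].to_numpy(float),
        rmin_half=atoms["rmin_half"].to_numpy(float),
        donor=atoms["donor"].to_numpy(bool),
        acceptor=atoms["acceptor"].to_numpy(bool),
        bonds=bonds,
        groups={k: frozenset(v) for k, v in groups.items()},
    )


# ---------------------------------------------------------------------------
# umbrella-window files (two-column time/ξ layout of standard pull files)


def read_window_table(meta_path: str | Path):
    """Read a window-metadata table plus the per-window time/ξ files.

    The metadata table (CSV) has columns ``file, center, k, temperature``;
    paths are resolved relative to the table.  Returns a list of
    :class:`~mdbind.pmf.UmbrellaWindow`.
    """
    from .pmf import UmbrellaWindow

    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path)
    windows = []
    for _, row in meta.iterrows():
        data = np.loadtxt(meta_path.parent / str(row["file"]))
        samples = data[:, 1] if data.ndim == 2 else data
        windows.append(
            UmbrellaWindow(
                bias_center=float(row["center"]),
                bias_k=float(row["k"]),
                samples=samples,
                temperature=float(row.get("temperature", 303.0)),
            )
        )
    return windows


def write_umbrella_set(umbrella_set, outdir: str | Path) -> Path:
    """Write per-window time/ξ CSVs, a metadata table and a ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, w in enumerate(umbrella_set.windows):
        fname = f"window_{k:03d}.csv"
        t = np.arange(len(w.samples), dtype=float)
        np.savetxt(outdir / fname, np.column_stack([t, w.samples]), fmt="%.8g")
        rows.append(
            {"file": fname, "center": w.bias_center, "k": w.bias_k,
             "temperature": w.temperature}
        )
    pd.DataFrame(rows).to_csv(outdir / "windows.csv", index=False)
    manifest = {
        "potential": umbrella_set.potential.describe(),
        "temperature": umbrella_set.temperature,
        "seed": umbrella_set.seed,
        "overlap_ok": bool(umbrella_set.overlap_ok),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "windows.csv"
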