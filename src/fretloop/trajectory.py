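"""Trajectory ingestion and per-frame geometric observables.

Reads MD trajectories of fluorophore-labeled peptides (via MDAnalysis) and
computes the geometric quantities that FRET analysis needs per frame: the
donor-acceptor end-to-end distance ``R_ee`` (midpoint of the Trp indole
fusion bond to midpoint of the Dbo diazo group), the terminal Calpha-Calpha
distance, the mass-weighted radius of gyration, and the orientational
factor kappa^2 of the donor/acceptor transition dipoles.

Units are nm for lengths and ps for times throughout; Angstrom-based file
formats are converted on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Frame",
    "LabelMap",
    "DistanceTrace",
    "DipolePairSeries",
    "read_trajectory",
    "end_to_end_distance",
    "ca_ca_distance",
    "radius_of_gyration",
    "kappa_squared",
    "extract_traces",
    "write_trace",
    "read_trace",
]

_ANGSTROM_TO_NM = 0.1


@dataclass(frozen=True)
class Frame:
    """One trajectory snapshot: coordinates in nm, time in ps.

    ``box`` holds the orthorhombic box edge lengths (nm) or ``None`` when
    the source format carries no box. Intramolecular distances are computed
    on unwrapped coordinates; no minimum-image convention is applied (the
    peptides of interest are far smaller than half the box).
    """

    coordinates: np.ndarray
    time: float
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (n_atoms, 3), got {coords.shape}")
        if self.time < 0:
            raise ValueError(f"frame time must be non-negative, got {self.time}")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class LabelMap:
    """Atom-index bookkeeping for a labeled peptide.

    ``indole_bond`` and ``diazo_group`` are the two-atom groups whose
    midpoints define the donor and acceptor positions; ``donor_dipole`` and
    ``acceptor_dipole`` are atom pairs whose difference vector defines each
    transition-dipole direction (sign immaterial, kappa^2 is even under
    dipole inversion); ``terminal_ca`` are the terminal-residue Calpha
    atoms. Indices are 0-based.
    """

    indole_bond: tuple[int, int]
    diazo_group: tuple[int, int]
    donor_dipole: tuple[int, int]
    acceptor_dipole: tuple[int, int]
    terminal_ca: tuple[int, int]
    heavy_atoms: tuple[int, ...] = ()
    masses: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        for name in ("indole_bond", "diazo_group", "donor_dipole",
                     "acceptor_dipole", "terminal_ca"):
            pair = tuple(int(i) for i in getattr(self, name))
            if len(pair) != 2:
                raise ValueError(f"{name} must be an atom index pair")
            if pair[0] == pair[1]:
                raise ValueError(f"{name} is degenerate: {pair}")
            if min(pair) < 0:
                raise ValueError(f"{name} has a negative index: {pair}")
            object.__setattr__(self, name, pair)
        object.__setattr__(self, "heavy_atoms",
                           tuple(int(i) for i in self.heavy_atoms))

    def validate(self, n_atoms: int) -> None:
        """Check every index against a topology of ``n_atoms`` atoms."""
        indices = [*self.indole_bond, *self.diazo_group, *self.donor_dipole,
                   *self.acceptor_dipole, *self.terminal_ca, *self.heavy_atoms]
        bad = [i for i in indices if not (0 <= i < n_atoms)]
        if bad:
            raise IndexError(f"label indices {bad} outside topology of {n_atoms} atoms")
        if self.masses.size and self.masses.size != n_atoms:
            raise ValueError("masses length does not match topology atom count")


@dataclass
class DistanceTrace:
    """Uniformly sampled scalar time series (times in ps, values in nm)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if self.times.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        steps = np.diff(self.times)
        dt = steps[0]
        if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=0.0):
            raise ValueError("trace must be uniformly sampled with dt > 0")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


@dataclass
class DipolePairSeries:
    """Per-frame unit vectors: donor dipole, acceptor dipole, R_ee direction."""

    donor_unit: np.ndarray
    acceptor_unit: np.ndarray
    ree_unit: np.ndarray

    def __post_init__(self) -> None:
        for name in ("donor_unit", "acceptor_unit", "ree_unit"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must be (n, 3)")
            norms = np.linalg.norm(arr, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError(f"{name} contains non-unit vectors")
            setattr(self, name, arr)
        if not (len(self.donor_unit) == len(self.acceptor_unit) == len(self.ree_unit)):
            raise ValueError("dipole series must have equal lengths")

    def __len__(self) -> int:
        return self.donor_unit.shape[0]


def read_trajectory(trajectory_path: str | Path, topology_path: str | Path,
                    dt: float | None = None) -> list[Frame]:
    """Read a trajectory into a list of :class:`Frame` (nm / ps units).

    Any trajectory/topology pair MDAnalysis understands is accepted
    (XTC/TRR/DCD with GRO/PDB topology, multi-model PDB as both, ...).
    ``dt`` (ps) overrides the per-frame time spacing for formats that do
    not store time, such as multi-model PDB.
    """
    import MDAnalysis as mda

    trajectory_path = Path(trajectory_path)
    topology_path = Path(topology_path)
    for p in (trajectory_path, topology_path):
        if not p.exists():
            raise FileNotFoundError(p)
    if trajectory_path == topology_path:
        universe = mda.Universe(str(topology_path))
    else:
        universe = mda.Universe(str(topology_path), str(trajectory_path))

    frames: list[Frame] = []
    n_atoms = len(universe.atoms)
    for i, ts in enumerate(universe.trajectory):
        if ts.positions.shape[0] != n_atoms:
            raise ValueError("atom count mismatch between topology and trajectory")
        time = float(i * dt) if dt is not None else float(ts.time)
        box = None
        if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
            box = np.asarray(ts.dimensions[:3], dtype=float) * _ANGSTROM_TO_NM
        frames.append(Frame(ts.positions.astype(float) * _ANGSTROM_TO_NM, time, box))
    if not frames:
        raise ValueError(f"zero frames in {trajectory_path}")
    times = [f.time for f in frames]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("frame times are not monotonically increasing")
    return frames


def _midpoint(frame: Frame, pair: tuple[int, int]) -> np.ndarray:
    return 0.5 * (frame.coordinates[pair[0]] + frame.coordinates[pair[1]])


def end_to_end_distance(frame: Frame, labels: LabelMap) -> float:
    """Donor-acceptor distance: indole-bond midpoint to diazo-group midpoint (nm)."""
    labels.validate(frame.n_atoms)
    return float(np.linalg.norm(_midpoint(frame, labels.indole_bond)
                                - _midpoint(frame, labels.diazo_group)))


def ca_ca_distance(frame: Frame, labels: LabelMap) -> float:
    """Distance between the terminal-residue Calpha atoms (nm)."""
    labels.validate(frame.n_atoms)
    i, j = labels.terminal_ca
    return float(np.linalg.norm(frame.coordinates[i] - frame.coordinates[j]))


def radius_of_gyration(frame: Frame, labels: LabelMap) -> float:
    """Mass-weighted radius of gyration about the center of mass (nm).

    Uses ``labels.masses`` when provided; otherwise all atoms carry unit
    mass. Restricted to ``labels.heavy_atoms`` when that list is non-empty.
    """
    labels.validate(frame.n_atoms)
    idx = np.asarray(labels.heavy_atoms or range(frame.n_atoms), dtype=int)
    coords = frame.coordinates[idx]
    masses = labels.masses[idx] if labels.masses.size else np.ones(len(idx))
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * coords).sum(axis=0) / total
    sq = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / total))


def kappa_squared(donor: np.ndarray, acceptor: np.ndarray, ree: np.ndarray,
                  atol: float = 1e-6) -> float | np.ndarray:
    """Orientational factor kappa^2 of the Forster rate.

    kappa^2 = (cos theta_T - 3 cos theta_D cos theta_A)^2 where theta_D and
    theta_A are the angles of the donor and acceptor transition dipoles to
    the donor-acceptor separation vector and theta_T is the angle between
    the two dipoles. Lies in [0, 4]; the isotropic dynamic average is 2/3.
    Inputs must be unit vectors; arrays of shape (n, 3) are broadcast to a
    vector of n values.
    """
    d = np.asarray(donor, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    r = np.asarray(ree, dtype=float)
    scalar = d.ndim == 1
    d, a, r = np.atleast_2d(d), np.atleast_2d(a), np.atleast_2d(r)
    for name, v in (("donor", d), ("acceptor", a), ("ree", r)):
        if not np.allclose(np.linalg.norm(v, axis=-1), 1.0, atol=atol):
            raise ValueError(f"{name} vector(s) not unit-norm within {atol}")
    cos_t = np.einsum("ij,ij->i", d, a)
    cos_d = np.einsum("ij,ij->i", d, r)
    cos_a = np.einsum("ij,ij->i", a, r)
    k2 = (cos_t - 3.0 * cos_d * cos_a) ** 2
    return float(k2[0]) if scalar else k2


def extract_traces(frames: Sequence[Frame], labels: LabelMap,
                   ) -> tuple[DistanceTrace, DistanceTrace, DistanceTrace,
                              DipolePairSeries]:
    """Apply the per-frame geometry to a whole trajectory.

    Returns aligned series of R_ee, terminal Calpha-Calpha distance, R_g,
    and the donor/acceptor/R_ee unit-vector triplets.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    times = np.array([f.time for f in frames])
    ree = np.array([end_to_end_distance(f, labels) for f in frames])
    rca = np.array([ca_ca_distance(f, labels) for f in frames])
    rg = np.array([radius_of_gyration(f, labels) for f in frames])

    def _unit(vectors: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero-length direction vector")
        return vectors / norms

    coords = np.stack([f.coordinates for f in frames])
    donor = _unit(coords[:, labels.donor_dipole[1]] - coords[:, labels.donor_dipole[0]])
    acceptor = _unit(coords[:, labels.acceptor_dipole[1]]
                     - coords[:, labels.acceptor_dipole[0]])
    d_mid = 0.5 * (coords[:, labels.indole_bond[0]] + coords[:, labels.indole_bond[1]])
    a_mid = 0.5 * (coords[:, labels.diazo_group[0]] + coords[:, labels.diazo_group[1]])
    ree_vec = _unit(a_mid - d_mid)
    return (DistanceTrace(times, ree, "R_ee"),
            DistanceTrace(times, rca, "R_CaCa"),
            DistanceTrace(times, rg, "R_g"),
            DipolePairSeries(donor, acceptor, ree_vec))


def write_trace(trace: DistanceTrace, path: str | Path) -> None:
    """Write a trace as delimited text with a ``time_ps,value_nm`` header."""
    data = np.column_stack([trace.times, trace.values])
    np.savetxt(path, data, delimiter=",", header="time_ps,value_nm",
               comments="", fmt="%.10g")


def read_trace(path: str | Path, label: str = "") -> DistanceTrace:
    """Read a two-column delimited trace file (time ps, value nm)."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns time_ps,value_nm")
    return DistanceTrace(data[:, 0], data[:, 1], label or str(path))
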