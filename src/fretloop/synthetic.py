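"""Synthetic inputs with known ground truth for every analysis stage.

Microsecond MD trajectories of labeled peptides are large and not
redistributable, so each analysis stage gets a generator that emulates the
statistical character of its input with a known answer baked in:

* Ornstein-Uhlenbeck distance traces (tunable relaxation time) for
  contact-kinetics and ACF analysis;
* fractional Gaussian noise (exact circulant-embedding synthesis) with a
  prescribed Hurst exponent for R/S analysis;
* power-law (1/f^alpha) noise by spectral synthesis for PSD analysis;
* rejection samples from the R^2-weighted three-Gaussian end-to-end
  density for the mixture fit;
* isotropic dipole orientations for the kappa^2 ensemble average;
* an overdamped bead chain with harmonic bonds and angular stiffness —
  flexible at low stiffness (Gly/Ser-like), extended at high stiffness
  (polyproline-like) — exercising geometry, clustering, and landscapes
  end to end;
* a noisy cosine velocity profile with known shear viscosity for the
  NEMD analysis.

All generators take an integer seed that fully determines their output.
"""

from __future__ import annotations

import numpy as np

from .cluster import ClusterResult  # noqa: F401  (re-exported convenience)
from .ensembles import SkewedGaussianComponent, skewed_gaussian_density
from .trajectory import DipolePairSeries, DistanceTrace, Frame, LabelMap
from .viscosity import PeriodicPerturbation, VelocityProfile

__all__ = [
    "gen_ou_trace",
    "gen_fgn",
    "gen_powerlaw_noise",
    "gen_mixture_samples",
    "gen_random_dipoles",
    "gen_bead_chain",
    "gen_velocity_profile",
    "write_frames_pdb",
]


def gen_ou_trace(mean: float = 0.9, relaxation_time: float = 100.0,
                 stationary_std: float = 0.2, n: int = 10000, dt: float = 1.0,
                 seed: int = 0, label: str = "ou") -> DistanceTrace:
    """Stationary Ornstein-Uhlenbeck distance trace (nm, ps).

    Exact discretization: x_{t+1} = mu + (x_t - mu) e^{-dt/tau}
    + s sqrt(1 - e^{-2 dt/tau}) xi. Started from the stationary
    distribution. Distances must stay positive, so values are clipped at a
    1e-3 nm floor; clipping is rare for the default parameterization
    (mean 0.9 nm, std 0.2 nm) and the clip count is recorded on the
    returned trace as ``trace.n_clipped``.
    """
    if relaxation_time <= 0:
        raise ValueError("relaxation_time must be positive")
    if stationary_std < 0:
        raise ValueError("stationary_std must be non-negative")
    rng = np.random.default_rng(seed)
    decay = np.exp(-dt / relaxation_time)
    innovation = stationary_std * np.sqrt(1.0 - decay ** 2)
    x = np.empty(n)
    x[0] = mean + stationary_std * rng.standard_normal()
    noise = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = mean + (x[i - 1] - mean) * decay + innovation * noise[i - 1]
    floor = 1e-3
    n_clipped = int(np.sum(x < floor))
    np.clip(x, floor, None, out=x)
    trace = DistanceTrace(np.arange(n) * dt, x, label)
    trace.n_clipped = n_clipped  # type: ignore[attr-defined]
    return trace


def gen_fgn(H: float, n: int, seed: int = 0) -> np.ndarray:
    """Unit-variance fractional Gaussian noise by circulant embedding.

    Exact synthesis (Davies-Harte): the length-2n circulant built from the
    fGn autocovariance gamma(k) = (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2
    has non-negative eigenvalues for 0 < H < 1, so filtering complex white
    noise through their square roots yields a Gaussian series with exactly
    that covariance. ``n`` should be a power of two for best FFT behavior.
    """
    if not 0.0 < H < 1.0:
        raise ValueError("H must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H)
                   + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # guard tiny negative round-off
    m = row.size
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[n] = np.sqrt(lam[n] / m) * rng.standard_normal()
    re = rng.standard_normal(n - 1)
    im = rng.standard_normal(n - 1)
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (re + 1j * im)
    w[m - 1:n:-1] = np.conjugate(w[1:n])
    return np.fft.fft(w).real[:n]


def gen_powerlaw_noise(alpha: float, n: int, seed: int = 0) -> np.ndarray:
    """Gaussian noise with target spectrum S(f) ~ f^-alpha, unit variance.

    Spectral synthesis: independent random phases with Fourier amplitudes
    proportional to f^{-alpha/2}; alpha = 0 gives white noise, alpha = 2
    Brownian-like noise.
    """
    if not 0.0 <= alpha <= 2.5:
        raise ValueError("alpha must lie in [0, 2.5]")
    if n < 8:
        raise ValueError("n must be >= 8")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amplitude = np.zeros_like(freqs)
    amplitude[1:] = freqs[1:] ** (-alpha / 2.0)
    spectrum = amplitude * (rng.standard_normal(freqs.size)
                            + 1j * rng.standard_normal(freqs.size))
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = spectrum[-1].real
    x = np.fft.irfft(spectrum, n)
    return x / x.std()


def gen_mixture_samples(components: tuple[SkewedGaussianComponent, ...],
                        n: int, seed: int = 0) -> np.ndarray:
    """Rejection samples from the R^2-weighted Gaussian mixture density.

    The proposal is uniform on (0, r_max) with r_max = max(r0) + 6 max
    sigma; the envelope is 1.1x the density maximum on a fine grid. All
    samples are strictly positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    amp = np.array([c.amplitude for c in components])
    r0 = np.array([c.r0 for c in components])
    sig = np.array([c.sigma for c in components])
    r_hi = float(np.max(r0) + 6.0 * np.max(sig))
    grid = np.linspace(1e-6, r_hi, 4096)
    envelope = 1.1 * skewed_gaussian_density(grid, amp, r0, sig).max()
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        batch = max(4 * (n - out.size), 1024)
        r = rng.uniform(0.0, r_hi, batch)
        u = rng.uniform(0.0, envelope, batch)
        keep = r[(u < skewed_gaussian_density(r, amp, r0, sig)) & (r > 0)]
        out = np.concatenate([out, keep])
    return out[:n]


def gen_random_dipoles(n: int, seed: int = 0) -> DipolePairSeries:
    """Donor/acceptor/R_ee unit vectors i.i.d. uniform on the sphere."""
    rng = np.random.default_rng(seed)

    def sphere(count: int) -> np.ndarray:
        v = rng.standard_normal((count, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    return DipolePairSeries(sphere(n), sphere(n), sphere(n))


def _bead_chain_forces(coords: np.ndarray, bond_length: float,
                       k_bond: float, k_bend: float) -> np.ndarray:
    """Forces of a harmonic-bond chain with angular (cosine) stiffness.

    U = k_bond/2 sum (|b_i| - l0)^2 + k_bend sum (1 - cos theta_i), with
    theta_i the angle between successive bond vectors.
    """
    n = coords.shape[0]
    forces = np.zeros_like(coords)
    bonds = coords[1:] - coords[:-1]
    lengths = np.linalg.norm(bonds, axis=1)
    # Harmonic bonds.
    f_pair = (k_bond * (lengths - bond_length) / lengths)[:, None] * bonds
    forces[:-1] += f_pair
    forces[1:] -= f_pair
    # Bending: F = -dU/dr = k_bend * d(cos theta)/dr.
    for i in range(n - 2):
        a = bonds[i]
        b = bonds[i + 1]
        la, lb = lengths[i], lengths[i + 1]
        cos_t = (a @ b) / (la * lb)
        dca = b / (la * lb) - cos_t * a / la ** 2
        dcb = a / (la * lb) - cos_t * b / lb ** 2
        forces[i] += -k_bend * dca
        forces[i + 1] += k_bend * (dca - dcb)
        forces[i + 2] += k_bend * dcb
    return forces


def gen_bead_chain(n_beads: int = 8, bond_length: float = 0.38,
                   bending_stiffness: float = 0.0, n_frames: int = 100,
                   dt: float = 1.0, seed: int = 0, steps_per_frame: int = 20,
                   ) -> tuple[list[Frame], LabelMap]:
    """Toy 3-D bead-chain trajectory plus an auto-built label map.

    Overdamped Euler-Maruyama dynamics (kT = 1, friction = 1) of a chain
    with stiff harmonic bonds and an angular term of ``bending_stiffness``
    (in kT): near zero the chain is a flexible coil, large values give an
    extended rod. Schematic by design — no excluded volume, no solvent —
    it exists to exercise the geometry, clustering, and landscape code
    paths end to end. The label map uses the first and last bonds as the
    donor/acceptor groups and dipoles and the terminal beads as the
    Calpha pair.
    """
    if n_beads < 4:
        raise ValueError("need at least 4 beads")
    rng = np.random.default_rng(seed)
    k_bond = 500.0  # kT / nm^2: nearly rigid bonds
    step = 2e-4     # integration step in reduced time units
    coords = np.zeros((n_beads, 3))
    coords[:, 0] = np.arange(n_beads) * bond_length
    coords += 0.05 * bond_length * rng.standard_normal(coords.shape)
    frames: list[Frame] = []
    for frame_i in range(n_frames):
        for _ in range(steps_per_frame):
            f = _bead_chain_forces(coords, bond_length, k_bond,
                                   bending_stiffness)
            coords = (coords + step * f
                      + np.sqrt(2.0 * step) * rng.standard_normal(coords.shape))
        frames.append(Frame(coords.copy(), frame_i * dt))
    labels = LabelMap(
        indole_bond=(0, 1),
        diazo_group=(n_beads - 2, n_beads - 1),
        donor_dipole=(0, 1),
        acceptor_dipole=(n_beads - 2, n_beads - 1),
        terminal_ca=(0, n_beads - 1),
        heavy_atoms=tuple(range(n_beads)),
        masses=np.ones(n_beads),
    )
    return frames, labels


def gen_velocity_profile(eta_true: float, perturbation: PeriodicPerturbation,
                         rho: float = 972.0, noise_std: float = 0.0,
                         n_points: int = 64, seed: int = 0) -> VelocityProfile:
    """Cosine velocity profile whose amplitude encodes a known viscosity.

    v_z(x) = [rho A / (eta_true k^2)] cos(k x) + Gaussian noise, inverting
    the same steady-state relation the analysis solves, so the noiseless
    round trip is exact. ``eta_true`` in mPa s, ``rho`` in kg m^-3
    (default a typical simple-point-charge water density).
    """
    if eta_true <= 0:
        raise ValueError("eta_true must be positive")
    rng = np.random.default_rng(seed)
    k = perturbation.wavenumber
    inv_eta_si = 1000.0 / eta_true  # m s kg^-1
    # V [nm/ps] = (1/eta) * rho * A / k^2 / 1e6  (inverse of the analysis)
    V = inv_eta_si * rho * perturbation.amplitude / k ** 2 / 1e6
    x = np.linspace(0.0, perturbation.box_length, n_points, endpoint=False)
    vz = V * np.cos(k * x) + noise_std * rng.standard_normal(n_points)
    return VelocityProfile(x, vz, rho)


def write_frames_pdb(frames: list[Frame], path: str) -> None:
    """Write frames as a multi-model PDB (coordinates nm -> Angstrom).

    The file doubles as topology and trajectory for ``read_trajectory``;
    pass the frame spacing there as ``dt`` since PDB stores no times.
    """
    import MDAnalysis as mda

    n_atoms = frames[0].n_atoms
    u = mda.Universe.empty(n_atoms, trajectory=True)
    u.add_TopologyAttr("names", [f"C{i}" for i in range(n_atoms)])
    u.add_TopologyAttr("resnames", ["BEA"])
    with mda.Writer(str(path), n_atoms, multiframe=True) as writer:
        for frame in frames:
            u.atoms.positions = frame.coordinates * 10.0
            writer.write(u.atoms)
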