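"""Three-shell spherical volume-conductor forward model.

Dipolar sources inside three concentric shells (brain, skull, scalp) with
piecewise-constant conductivity generate scalp potentials that admit a
Legendre-series solution.  For each harmonic order n the radial profile in
each shell is ``A r^n + B r^-(n+1)``; imposing continuity of potential and
radial current at the two interior interfaces and zero current at the scalp
yields a 5x5 linear system whose solution gives the transfer factor from
the source's multipole coefficient to the scalp surface.  The angular
dependence is the classic dipole decomposition into a radial part
(``P_n``) and a tangential part (``P_n^1``, no Condon-Shortley phase).

Electrode positions are built geometrically from 10-20/10-10 arc
proportions on the unit sphere: the 10% circumferential ring sits at 72 deg
inclination, midline electrodes on the nasion-inion great circle, and
intermediate rows by great-circle interpolation between ring and midline
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre

__all__ = [
    "HeadModel",
    "standard_montage_32",
    "three_shell_potential",
    "gain_matrix",
    "forward_project",
    "sample_source_positions",
]

BRAIN_RADIUS = 0.88
SKULL_RADIUS = 0.92
SCALP_RADIUS = 1.0
CONDUCTIVITIES = (0.33, 0.0042, 0.33)
SOURCE_RADIUS = 0.8


def _sph(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector: inclination from +z (vertex), azimuth ccw from +x (right ear)."""
    th = np.deg2rad(inclination_deg)
    ph = np.deg2rad(azimuth_deg)
    return np.array([np.cos(ph) * np.sin(th), np.sin(ph) * np.sin(th), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, f: float) -> np.ndarray:
    """Point a fraction f along the great circle from a to b (unit vectors)."""
    ang = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if ang < 1e-12:
        return a.copy()
    return (np.sin((1 - f) * ang) * a + np.sin(f * ang) * b) / np.sin(ang)


def standard_montage_32() -> tuple[list[str], np.ndarray]:
    """A 32-electrode 10-20/10-10 montage on the unit sphere.

    Returns (labels, positions) with positions of unit norm, constructed
    from the standard arc proportions (see module docstring).
    """
    pos: dict[str, np.ndarray] = {}
    ring = {  # 10% circumferential ring, inclination 72 deg
        "Fpz": 90, "Fp2": 72, "F8": 36, "T8": 0, "P8": -36, "O2": -72,
        "Oz": -90, "O1": -108, "P7": -144, "T7": 180, "Fp1": 108, "F7": 144,
    }
    for name, az in ring.items():
        pos[name] = _sph(72, az)
    midline = {"Fz": (36, 90), "FCz": (18, 90), "Cz": (0, 0),
               "CPz": (18, -90), "Pz": (36, -90), "POz": (54, -90)}
    for name, (inc, az) in midline.items():
        pos[name] = _sph(inc, az)
    pos["C3"] = _sph(36, 180)
    pos["C4"] = _sph(36, 0)
    for name, (a, b, f) in {
        "F3": ("F7", "Fz", 0.5), "F4": ("F8", "Fz", 0.5),
        "P3": ("P7", "Pz", 0.5), "P4": ("P8", "Pz", 0.5),
    }.items():
        pos[name] = _slerp(pos[a], pos[b], f)
    helpers = {"FT7": _sph(72, 162), "FT8": _sph(72, 18),
               "TP7": _sph(72, 198), "TP8": _sph(72, -18)}
    for name, (a, b, f) in {
        "FC5": ("FT7", "FCz", 0.25), "FC1": ("FT7", "FCz", 0.75),
        "FC6": ("FT8", "FCz", 0.25), "FC2": ("FT8", "FCz", 0.75),
        "CP5": ("TP7", "CPz", 0.25), "CP1": ("TP7", "CPz", 0.75),
        "CP6": ("TP8", "CPz", 0.25), "CP2": ("TP8", "CPz", 0.75),
    }.items():
        a_vec = helpers[a] if a in helpers else pos[a]
        pos[name] = _slerp(a_vec, pos[b], f)
    labels = [
        "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
        "FC5", "FC1", "FCz", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
        "CP5", "CP1", "CPz", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
        "POz", "O1", "Oz", "O2",
    ]
    P = np.array([pos[name] for name in labels])
    P /= np.linalg.norm(P, axis=1, keepdims=True)
    return labels, P


@dataclass
class HeadModel:
    """Three concentric shells plus electrode and source geometry."""

    radii: tuple = (BRAIN_RADIUS, SKULL_RADIUS, SCALP_RADIUS)
    conductivities: tuple = CONDUCTIVITIES
    electrode_positions: np.ndarray | None = None
    electrode_names: list[str] = field(default_factory=list)
    source_positions: np.ndarray | None = None
    source_orientations: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if r.shape != (3,) or np.any(np.diff(r) <= 0) or abs(r[2] - 1.0) > 1e-12:
            raise ValueError("radii must be strictly increasing and end at 1")
        if self.electrode_positions is None:
            self.electrode_names, self.electrode_positions = standard_montage_32()
        self.electrode_positions = np.asarray(self.electrode_positions, dtype=float)
        norms = np.linalg.norm(self.electrode_positions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("electrodes must lie on the unit sphere")
        if self.source_positions is not None:
            self.source_positions = np.asarray(self.source_positions, dtype=float)
            rs = np.linalg.norm(self.source_positions, axis=1)
            if np.any(np.abs(rs - SOURCE_RADIUS) > 1e-9):
                raise ValueError(f"sources must sit at radius {SOURCE_RADIUS}")
            if np.any(self.source_positions[:, 2] <= 0):
                raise ValueError("sources must lie in the upper (z > 0) hemisphere")
            if self.source_orientations is None:
                # radial orientation: outward unit vector at the source
                self.source_orientations = self.source_positions / rs[:, None]
            self.source_orientations = np.asarray(self.source_orientations, dtype=float)
            on = np.linalg.norm(self.source_orientations, axis=1)
            if np.any(np.abs(on - 1.0) > 1e-9):
                raise ValueError("orientations must be unit vectors")

    @property
    def n_sources(self) -> int:
        return 0 if self.source_positions is None else self.source_positions.shape[0]


def sample_source_positions(M: int, rng: np.random.Generator) -> np.ndarray:
    """M positions uniform on the upper-hemisphere cap at the source radius."""
    z = rng.uniform(0.0, 1.0, size=M)
    ph = rng.uniform(0.0, 2 * np.pi, size=M)
    s = np.sqrt(1.0 - z**2)
    return SOURCE_RADIUS * np.column_stack([s * np.cos(ph), s * np.sin(ph), z])


def _transfer_factors(head: HeadModel, n_terms: int) -> np.ndarray:
    """Per-order factor mapping the source coefficient of r^-(n+1) in the
    innermost shell to the potential profile value at the scalp surface."""
    r1, r2, c = head.radii
    s1, s2, s3 = head.conductivities
    f = np.empty(n_terms + 1)
    f[0] = 0.0
    for n in range(1, n_terms + 1):
        M = np.array([
            # A1, A2, B2, A3, B3
            [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0, 0.0],
            [s1 * n * r1 ** (n - 1), -s2 * n * r1 ** (n - 1),
             s2 * (n + 1) * r1 ** -(n + 2), 0.0, 0.0],
            [0.0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))],
            [0.0, s2 * n * r2 ** (n - 1), -s2 * (n + 1) * r2 ** -(n + 2),
             -s3 * n * r2 ** (n - 1), s3 * (n + 1) * r2 ** -(n + 2)],
            [0.0, 0.0, 0.0, n * c ** (n - 1), -(n + 1) * c ** -(n + 2)],
        ])
        rhs = np.array([
            -(r1 ** -(n + 1)),
            s1 * (n + 1) * r1 ** -(n + 2),
            0.0, 0.0, 0.0,
        ])
        A1, A2, B2, A3, B3 = np.linalg.solve(M, rhs)
        f[n] = A3 * c**n + B3 * c ** -(n + 1)
    return f


def three_shell_potential(
    source_pos: np.ndarray,
    moment: np.ndarray,
    electrode_pos: np.ndarray,
    head: HeadModel | None = None,
    n_terms: int = 60,
) -> float | np.ndarray:
    """Scalp potential of a current dipole inside the three-shell sphere.

    ``electrode_pos`` may be a single position or an (E, 3) array; the
    result is linear in ``moment``.  Raises if the source is at or outside
    the innermost shell.
    """
    if head is None:
        head = HeadModel()
    source_pos = np.asarray(source_pos, dtype=float)
    moment = np.asarray(moment, dtype=float)
    E = np.atleast_2d(np.asarray(electrode_pos, dtype=float))
    b = np.linalg.norm(source_pos)
    if b >= head.radii[0]:
        raise ValueError("source must lie strictly inside the innermost shell")
    s1 = head.conductivities[0]
    if b < 1e-12:
        rhat = np.array([0.0, 0.0, 1.0])  # central dipole: any axis works
    else:
        rhat = source_pos / b
    m_r = moment @ rhat
    q_t = moment - m_r * rhat

    ehat = E / np.linalg.norm(E, axis=1, keepdims=True)
    cosg = np.clip(ehat @ rhat, -1.0, 1.0)
    # tangential unit vector in the source-electrode plane, per electrode
    t_vec = ehat - cosg[:, None] * rhat
    t_norm = np.linalg.norm(t_vec, axis=1)
    safe = t_norm > 1e-12
    t_hat = np.zeros_like(t_vec)
    t_hat[safe] = t_vec[safe] / t_norm[safe, None]
    mt = t_hat @ q_t  # |q_t| cos(beta) per electrode

    f = _transfer_factors(head, n_terms)
    ns = np.arange(1, n_terms + 1)
    Pn = np.stack([eval_legendre(n, cosg) for n in ns], axis=1)  # (E, N)
    Pn_prev = np.stack([eval_legendre(n - 1, cosg) for n in ns], axis=1)
    # P_n^1 without Condon-Shortley phase: sqrt(1-x^2) P_n'(x)
    sing = 1.0 - cosg**2
    with np.errstate(divide="ignore", invalid="ignore"):
        Pn1 = -ns[None, :] * (cosg[:, None] * Pn - Pn_prev) / np.sqrt(
            np.where(sing > 0, sing, 1.0)
        )[:, None]
    Pn1[sing <= 1e-24] = 0.0

    bpow = b ** (ns - 1.0) if b > 0 else np.where(ns == 1, 1.0, 0.0)
    coef = f[ns] * bpow / (4.0 * np.pi * s1)
    V = (coef * ns * m_r * Pn).sum(axis=1) + (coef * Pn1).sum(axis=1) * mt
    return V[0] if np.asarray(electrode_pos).ndim == 1 else V


def gain_matrix(head: HeadModel, n_terms: int = 60) -> np.ndarray:
    """(n_electrodes, M) lead field for the head model's dipoles."""
    if head.source_positions is None:
        raise ValueError("head model has no sources")
    cols = [
        three_shell_potential(
            head.source_positions[j], head.source_orientations[j],
            head.electrode_positions, head, n_terms,
        )
        for j in range(head.n_sources)
    ]
    return np.column_stack(cols)


def forward_project(source_data: np.ndarray, head: HeadModel, n_terms: int = 60) -> np.ndarray:
    """Project (M, n, d) source data to (n_electrodes, n, d) scalp data."""
    source_data = np.asarray(source_data, dtype=float)
    G = gain_matrix(head, n_terms)
    if source_data.shape[0] != G.shape[1]:
        raise ValueError("source count does not match head model")
    return np.einsum("em,mnd->end", G, source_data)
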