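"""Synthetic input generators.

Every analysis stage in this package can be exercised on data generated
here: ideal α-helical backbones built from internal coordinates, helix
bundles at controlled crossing angles, Gaussian-perturbed ensembles,
drifting trajectories, RDC sets from a known alignment tensor, and
two-state fast-exchange titration peak tables with exchange-broadening
attenuation.  Generators are pure functions of their arguments: the same
seed reproduces the same output bit for bit.

Structures are backbone-only (N, CA, C, O and amide H); nothing in the
analysis needs side chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structio import (Atom, Chain, Model, PeakRecord, RdcRecord, Residue,
                       Structure, TalosRecord)

__all__ = [
    "GeneratorConfig",
    "build_ideal_helix",
    "build_bundle",
    "perturb_ensemble",
    "synth_trajectory",
    "synth_rdc",
    "synth_titration",
    "synth_talos_records",
    "fraction_bound",
]

# standard peptide internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.02
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0


@dataclass
class GeneratorConfig:
    """Default study conditions for the synthetic generators.

    The titration block reflects a sub-stoichiometric ligand series:
    0.3 mM ¹⁵N-labelled peptide titrated at protein:ligand molar ratios
    40:1 … 7:1 with K_d = 1 μM, which puts essentially all added ligand
    in the bound state and keeps the bound fraction of the observed
    peptide small.
    """

    seed: int = 0
    n_residues: int = 30
    n_models: int = 10
    n_frames: int = 100
    coord_sigma: float = 0.5       # Å, ensemble perturbation
    drift_per_frame: float = 0.02  # Å, trajectory drift step
    rdc_noise_hz: float = 1.0
    phi: float = -60.0
    psi: float = -45.0
    crossing_angle: float = 47.0   # degrees
    # two-state binding / titration
    kd_molar: float = 1e-6
    protein_molar: float = 3e-4
    molar_ratios: tuple[float, ...] = (40, 30, 20, 15, 10, 7)
    attenuation_k: float = 5.0     # exchange-broadening coefficient per ppm


# ---------------------------------------------------------------------------
# internal-coordinate chain building
# ---------------------------------------------------------------------------


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d with |cd| = bond, ∠(b,c,d) = angle and torsion
    (a,b,c,d) = dihedral (natural-extension reference frame)."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(theta),
                        bond * math.sin(theta) * math.cos(chi),
                        bond * math.sin(theta) * math.sin(chi)])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_ideal_helix(length: int, phi: float = -60.0, psi: float = -45.0,
                      chain_id: str = "A", first_resid: int = 1,
                      resname: str = "ALA", with_h: bool = True) -> Structure:
    """Build a backbone at uniform (φ, ψ) — the α_R region near
    (−60°, −45°) by default — with standard bond lengths and angles.

    The builder is the exact inverse of the torsion measurement: computing
    backbone dihedrals on the result recovers (φ, ψ) to numerical precision
    on interior residues.
    """
    if length < 2:
        raise ValueError("need at least 2 residues")
    # seed the first residue in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    th = math.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([math.cos(th), math.sin(th), 0.0])
    ns, cas, cs = [n0], [ca0], [c0]
    for i in range(1, length):
        n_next = _place_atom(ns[-1], cas[-1], cs[-1], BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = _place_atom(cas[-1], cs[-1], n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_next = _place_atom(cs[-1], n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi)
        ns.append(n_next)
        cas.append(ca_next)
        cs.append(c_next)
    residues = []
    for i in range(length):
        atoms = [Atom("N", "N", ns[i]), Atom("CA", "C", cas[i]), Atom("C", "C", cs[i])]
        # carbonyl O: anti to the next amide N (or at psi+180 for the last residue)
        o_dihedral = psi + 180.0
        atoms.append(Atom("O", "O",
                          _place_atom(ns[i], cas[i], cs[i], BOND_C_O,
                                      ANGLE_CA_C_O, o_dihedral)))
        if with_h and i > 0:
            # amide H along the bisector opposite C'(i-1) and CA(i)
            u = cs[i - 1] - ns[i]
            v = cas[i] - ns[i]
            h_dir = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
            h_dir /= np.linalg.norm(h_dir)
            atoms.append(Atom("H", "H", ns[i] + BOND_N_H * h_dir))
        residues.append(Residue(first_resid + i, resname, atoms))
    return Structure([Model([Chain(chain_id, residues)])])


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def _orient_along_z(structure: Structure) -> Structure:
    """Rigidly rotate a single-chain helix so its fitted axis lies on +z
    and its centroid at the origin."""
    from .geometry import helix_axis  # local import avoids a cycle

    st = structure.copy()
    chain = st.models[0].chains[0]
    rng = (chain.residues[0].index, chain.residues[-1].index)
    ax = helix_axis(st, rng, chain=chain.id)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(ax.direction, z)
    s = np.linalg.norm(v)
    c = float(np.dot(ax.direction, z))
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else _rotation_about([1, 0, 0], 180.0)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    m = st.models[0]
    coords = m.coords()
    m.set_coords((coords - ax.centroid) @ rot.T)
    return st


def build_bundle(helix_lengths, crossing_angle: float,
                 separation: float = 10.0, phi: float = -60.0,
                 psi: float = -45.0, layout: str = "pair") -> Structure:
    """Place two (or four) ideal helices at a requested crossing angle.

    Helices are built, aligned to z, then displaced along x by
    ±``separation``/2 and rotated about the x (separation) axis by
    ±``crossing_angle``/2, so the inter-axis angle of the pair equals the
    requested value.  ``layout='quad'`` adds a second pair displaced along
    y, giving the side-by-side four-helix arrangement; ``layout='pair'``
    is the default two-helix crossing.
    """
    helix_lengths = list(helix_lengths)
    if layout == "pair" and len(helix_lengths) != 2:
        raise ValueError("pair layout needs exactly 2 helix lengths")
    if layout == "quad" and len(helix_lengths) != 4:
        raise ValueError("quad layout needs exactly 4 helix lengths")
    chains = []
    chain_ids = "ABCD"
    for k, ln in enumerate(helix_lengths):
        st = _orient_along_z(build_ideal_helix(ln, phi, psi, chain_id=chain_ids[k]))
        m = st.models[0]
        sign = 1.0 if k % 2 == 0 else -1.0
        rot = _rotation_about([1, 0, 0], sign * crossing_angle / 2.0)
        offset = np.array([sign * separation / 2.0, 0.0, 0.0])
        if layout == "quad":
            offset = offset + np.array([0.0, separation * (k // 2), 0.0])
        coords = m.coords() @ rot.T + offset
        m.set_coords(coords)
        chains.append(m.chains[0])
    return Structure([Model(chains)])


# ---------------------------------------------------------------------------
# ensembles and trajectories
# ---------------------------------------------------------------------------


def perturb_ensemble(structure: Structure, sigma_angstrom: float,
                     n_models: int, seed: int = 0) -> Structure:
    """Multi-model copy of ``structure`` (model 0) with i.i.d. isotropic
    Gaussian displacement of every atom in every model."""
    if sigma_angstrom < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    base = structure.models[0]
    coords = base.coords()
    models = []
    for _ in range(n_models):
        st = Structure([base]).copy()
        m = st.models[0]
        m.set_coords(coords + rng.normal(0.0, sigma_angstrom, coords.shape))
        models.append(m)
    return Structure(models)


def synth_trajectory(structure: Structure, n_frames: int,
                     jitter_sigma: float, drift_per_frame: float,
                     seed: int = 0) -> Structure:
    """Trajectory with cumulative conformational drift plus per-frame jitter.

    Frame t's mean coordinates are the seed structure displaced by a random
    walk of step SD ``drift_per_frame`` per atom; independent jitter of SD
    ``jitter_sigma`` is added on top.  With both zero the trajectory is
    static.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    base = structure.models[0]
    coords = base.coords()
    center = coords.copy()
    models = []
    for _ in range(n_frames):
        frame = center + rng.normal(0.0, jitter_sigma, coords.shape) \
            if jitter_sigma > 0 else center.copy()
        st = Structure([base]).copy()
        st.models[0].set_coords(frame)
        models.append(st.models[0])
        if drift_per_frame > 0:
            center = center + rng.normal(0.0, drift_per_frame, coords.shape)
    return Structure(models)


# ---------------------------------------------------------------------------
# RDC and titration generators
# ---------------------------------------------------------------------------


def synth_rdc(structure: Structure, tensor, noise_sigma_hz: float,
              seed: int = 0, residue_set=None, chain: str | None = None,
              model_index: int = 0) -> list[RdcRecord]:
    """Observed RDCs = back-calculated couplings from ``tensor`` plus
    Gaussian noise of SD ``noise_sigma_hz``."""
    from .rdc import backcalc_rdc  # local import avoids a cycle

    calc = backcalc_rdc(structure, model_index, tensor,
                        residue_set=residue_set, chain=chain)
    rng = np.random.default_rng(seed)
    out = []
    for resid in sorted(calc):
        d = calc[resid] + (rng.normal(0.0, noise_sigma_hz)
                           if noise_sigma_hz > 0 else 0.0)
        out.append(RdcRecord(resid, float(d), float(noise_sigma_hz)))
    return out


def fraction_bound(protein_molar: float, ligand_molar: float,
                   kd_molar: float) -> float:
    """Bound fraction of the observed (labelled) species from the exact
    two-state equilibrium: the quadratic solution for [PL]."""
    if kd_molar <= 0:
        raise ValueError("K_d must be positive")
    if protein_molar <= 0 or ligand_molar < 0:
        raise ValueError("concentrations must be physical")
    s = protein_molar + ligand_molar + kd_molar
    pl = (s - math.sqrt(s * s - 4.0 * protein_molar * ligand_molar)) / 2.0
    return pl / protein_molar


def synth_titration(config: GeneratorConfig,
                    bound_shifts: dict[int, tuple[float, float]] | None = None,
                    overlapped: tuple[int, ...] = (),
                    nitrogen_scale: float = 6.5) -> dict[str, list[PeakRecord]]:
    """Two-state fast-exchange titration peak tables.

    Observed shifts move by f_bound·Δδ_bound toward the bound-state position;
    intensities attenuate as I/I₀ = exp(−k·f_bound·Δδ_bound) with the
    compound Δδ_bound (¹⁵N scaled by ``nitrogen_scale``) standing in for the
    exchange-broadening contribution.  Non-binding residues keep their free
    positions and intensities.  ``overlapped`` residues are emitted with
    status ``overlapped`` and no usable intensity.

    Returns ``{"free": [...], "40:1": [...], ...}`` keyed by molar-ratio tag.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_residues
    if bound_shifts is None:
        # binding interface: the C-terminal half, graded bound-state shifts
        bound_shifts = {}
        for resid in range(n // 2 + 1, n + 1):
            scale = (resid - n // 2) / (n - n // 2)
            bound_shifts[resid] = (0.12 * scale, 0.8 * scale)
    free_dh = 7.5 + 1.0 * rng.random(n)
    free_dn = 110.0 + 15.0 * rng.random(n)
    free_i = 0.8 + 0.4 * rng.random(n)
    tables: dict[str, list[PeakRecord]] = {}

    def emit(tag: str, f_bound: float) -> list[PeakRecord]:
        rows = []
        for idx in range(n):
            resid = idx + 1
            ddh, ddn = bound_shifts.get(resid, (0.0, 0.0))
            compound = math.hypot(ddh, ddn / nitrogen_scale)
            dh = free_dh[idx] + f_bound * ddh
            dn = free_dn[idx] + f_bound * ddn
            inten = free_i[idx] * math.exp(-config.attenuation_k * f_bound * compound)
            if resid in overlapped:
                rows.append(PeakRecord(resid, dh, dn, math.nan, tag, "overlapped"))
            else:
                rows.append(PeakRecord(resid, dh, dn, inten, tag, "ok"))
        return rows

    tables["free"] = emit("free", 0.0)
    for ratio in config.molar_ratios:
        ligand = config.protein_molar / ratio
        fb = fraction_bound(config.protein_molar, ligand, config.kd_molar)
        tag = f"{ratio:g}:1"
        tables[tag] = emit(tag, fb)
    return tables


def synth_talos_records(n_residues: int, phi: float = -60.0, psi: float = -45.0,
                        s2_core: float = 0.85, s2_tail: float = 0.4,
                        n_tail: int = 0, dphi: float = 6.0, dpsi: float = 6.0,
                        seed: int = 0,
                        angle_sigma: float = 0.0) -> list[TalosRecord]:
    """Torsion-prediction records for a uniform helix, optionally with a
    flexible N-terminal tail (low RCI-S², ``Dyn`` class) of ``n_tail``
    residues and Gaussian scatter on the predicted angles."""
    rng = np.random.default_rng(seed)
    records = []
    for resid in range(1, n_residues + 1):
        tail = resid <= n_tail
        p = phi + (rng.normal(0, angle_sigma) if angle_sigma > 0 else 0.0)
        s = psi + (rng.normal(0, angle_sigma) if angle_sigma > 0 else 0.0)
        records.append(TalosRecord(
            resid=resid, resname="ALA",
            phi=float(np.clip(p, -180.0, 179.999)),
            psi=float(np.clip(s, -180.0, 179.999)),
            dphi=dphi, dpsi=dpsi, dist=0.0,
            s2=s2_tail if tail else s2_core,
            count=10, cls="Dyn" if tail else "Good"))
    return records
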