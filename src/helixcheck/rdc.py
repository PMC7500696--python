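"""Residual dipolar coupling extraction, alignment-tensor fitting,
back-calculation, and dipolar-wave analysis.

An RDC reports the orientation of an N–H bond vector relative to a weak
alignment frame: D(i) = D_max · v̂ᵢᵀ S v̂ᵢ with S the symmetric traceless
Saupe order matrix (5 free parameters) and v̂ᵢ the unit N–H vector.  With
five or more independent vectors S is determined by linear least squares;
agreement between observed and back-calculated couplings is summarised by
the RMSD (Hz) and the Cornilescu Q-factor
Q = rms(D_calc − D_obs)/rms(D_obs).

Because the fit is linear, the overall dipolar scale D_max is absorbed
into the tensor by default (D_max = 1): fitted quality metrics are
invariant to the choice, and the reported tensor is the product form.

Along a regular α-helix sequential RDCs trace a "dipolar wave",
D(n) = A_v + A_II·cos(2πn/3.6 + φ); the mean level A_v and amplitude A_II
characterise the helix orientation in the alignment frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structio import Structure

__all__ = [
    "SaupeTensor",
    "RdcFitReport",
    "DipolarWaveFit",
    "rdc_from_splittings",
    "nh_unit_vectors",
    "fit_alignment_tensor",
    "backcalc_rdc",
    "dipolar_wave_fit",
]


@dataclass
class SaupeTensor:
    """Symmetric traceless order tensor in the 5-element parameterisation
    (Sxx, Syy, Sxy, Sxz, Syz); Szz = −Sxx − Syy."""

    sxx: float
    syy: float
    sxy: float
    sxz: float
    syz: float
    d_max_hz: float = 1.0  # dipolar scale carried with the tensor

    @property
    def elements(self) -> np.ndarray:
        return np.array([self.sxx, self.syy, self.sxy, self.sxz, self.syz])

    @property
    def matrix(self) -> np.ndarray:
        return np.array([
            [self.sxx, self.sxy, self.sxz],
            [self.sxy, self.syy, self.syz],
            [self.sxz, self.syz, -self.sxx - self.syy],
        ])

    @classmethod
    def from_matrix(cls, m: np.ndarray, d_max_hz: float = 1.0) -> "SaupeTensor":
        m = np.asarray(m, float)
        if m.shape != (3, 3) or not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("Saupe tensor must be a symmetric 3x3 matrix")
        if abs(np.trace(m)) > 1e-8 * max(1.0, np.abs(m).max()):
            raise ValueError("Saupe tensor must be traceless")
        return cls(m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2], d_max_hz)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)

    def predict(self, unit_vectors: np.ndarray) -> np.ndarray:
        v = np.asarray(unit_vectors, float)
        return self.d_max_hz * np.einsum("ni,ij,nj->n", v, self.matrix, v)


@dataclass
class RdcFitReport:
    tensor: SaupeTensor
    residues: list[int]
    d_obs: np.ndarray  # Hz
    d_calc: np.ndarray  # Hz
    n_used: int

    @property
    def residuals(self) -> np.ndarray:
        return self.d_calc - self.d_obs

    @property
    def rmsd_hz(self) -> float:
        return float(np.sqrt(np.mean(self.residuals ** 2)))

    @property
    def q_factor(self) -> float:
        denom = float(np.sqrt(np.mean(self.d_obs ** 2)))
        if denom == 0:
            raise ZeroDivisionError("Q-factor undefined for all-zero observations")
        return self.rmsd_hz / denom

    def as_table(self):
        import pandas as pd
        return pd.DataFrame({"resid": self.residues, "d_obs_hz": self.d_obs,
                             "d_calc_hz": self.d_calc,
                             "residual_hz": self.residuals})


def rdc_from_splittings(splitting_oriented_hz, splitting_isotropic_hz):
    """RDC from the ¹H-¹⁵N splitting in oriented vs isotropic media:
    D = J+D − J, i.e. oriented minus isotropic (elementwise on arrays)."""
    oriented = np.asarray(splitting_oriented_hz, float)
    isotropic = np.asarray(splitting_isotropic_hz, float)
    if not (np.all(np.isfinite(oriented)) and np.all(np.isfinite(isotropic))):
        raise ValueError("splittings must be finite")
    d = oriented - isotropic
    return float(d) if d.ndim == 0 else d


# ---------------------------------------------------------------------------
# NH vectors
# ---------------------------------------------------------------------------

_H_NAMES = ("H", "HN", "1H")


def nh_unit_vectors(structure: Structure, model_index: int = 0,
                    residue_set=None, chain: str | None = None,
                    build_h: bool = True) -> dict[int, np.ndarray]:
    """Unit N→H bond vectors per residue.

    When the amide proton is absent from the coordinates and ``build_h`` is
    set, it is constructed geometrically: 1.02 Å from N along the bisector
    opposite the C'(i−1)–N and Cα–N bonds (planar amide).  Residues without
    a preceding peptide bond are skipped.
    """
    model = structure.models[model_index]
    chains = [c for c in model.chains if chain is None or c.id == chain]
    out: dict[int, np.ndarray] = {}
    for c in chains:
        for i, r in enumerate(c.residues):
            if residue_set is not None and r.index not in residue_set:
                continue
            n_atom = r.atom("N")
            if n_atom is None:
                continue
            h_atom = None
            for name in _H_NAMES:
                h_atom = r.atom(name)
                if h_atom is not None:
                    break
            if h_atom is not None:
                v = h_atom.xyz - n_atom.xyz
            elif build_h and i > 0:
                prev_c = c.residues[i - 1].atom("C")
                ca = r.atom("CA")
                if prev_c is None or ca is None:
                    continue
                u = prev_c.xyz - n_atom.xyz
                w = ca.xyz - n_atom.xyz
                v = -(u / np.linalg.norm(u) + w / np.linalg.norm(w))
            else:
                continue
            norm = np.linalg.norm(v)
            if norm == 0:
                continue
            out[r.index] = v / norm
    return out


# ---------------------------------------------------------------------------
# tensor fitting and back-calculation
# ---------------------------------------------------------------------------


def _design_matrix(vectors: np.ndarray) -> np.ndarray:
    vx, vy, vz = vectors[:, 0], vectors[:, 1], vectors[:, 2]
    return np.column_stack([vx**2 - vz**2, vy**2 - vz**2,
                            2 * vx * vy, 2 * vx * vz, 2 * vy * vz])


def fit_alignment_tensor(structure: Structure, model_index: int,
                         rdc_records, residue_set=None,
                         chain: str | None = None,
                         d_max_hz: float = 1.0) -> RdcFitReport:
    """Linear least-squares fit of the five Saupe-tensor elements to
    observed RDCs, with back-calculated couplings, RMSD and Q-factor.

    Uses residues that have both an observed coupling and a resolvable
    N–H vector (amide H built geometrically when absent).  Requires at
    least 5 such residues and a full-rank design (non-degenerate vector
    distribution).
    """
    obs = {r.resid: r.d_obs_hz for r in rdc_records}
    wanted = set(obs) if residue_set is None else set(residue_set) & set(obs)
    vectors = nh_unit_vectors(structure, model_index, wanted, chain)
    residues = sorted(set(vectors) & wanted)
    if len(residues) < 5:
        raise ValueError(
            f"need >= 5 residues with RDCs and N-H vectors, got {len(residues)}")
    v = np.array([vectors[r] for r in residues])
    d_obs = np.array([obs[r] for r in residues])
    a = d_max_hz * _design_matrix(v)
    rank = np.linalg.matrix_rank(a)
    if rank < 5:
        raise ValueError(f"rank-deficient design matrix (rank {rank}); "
                         "N-H vectors too degenerate for a tensor fit")
    sol, *_ = np.linalg.lstsq(a, d_obs, rcond=None)
    tensor = SaupeTensor(*sol, d_max_hz=d_max_hz)
    d_calc = a @ sol
    return RdcFitReport(tensor, residues, d_obs, d_calc, len(residues))


def backcalc_rdc(structure: Structure, model_index: int, tensor: SaupeTensor,
                 residue_set=None, chain: str | None = None) -> dict[int, float]:
    """Deterministic D_max·v̂ᵀSv̂ evaluation per residue with an N–H vector."""
    vectors = nh_unit_vectors(structure, model_index, residue_set, chain)
    if not vectors:
        raise ValueError("no residues with N-H vectors in the selection")
    residues = sorted(vectors)
    v = np.array([vectors[r] for r in residues])
    d = tensor.predict(v)
    return {r: float(val) for r, val in zip(residues, d)}


# ---------------------------------------------------------------------------
# dipolar wave
# ---------------------------------------------------------------------------


@dataclass
class DipolarWaveFit:
    """Sinusoidal fit D(n) = A_v + A_II·cos(2πn/period + phase)."""

    a_v: float          # mean RDC level, Hz
    a_ii: float         # dominant sinusoid amplitude, Hz (>= 0)
    phase_deg: float
    period: float       # residues
    a_v_err: float
    a_ii_err: float
    a_i: float = 0.0    # optional second-harmonic amplitude, Hz
    a_i_err: float = 0.0
    rmsd_hz: float = 0.0


def dipolar_wave_fit(rdc_by_residue: dict[int, float], period: float = 3.6,
                     second_harmonic: bool = False) -> DipolarWaveFit:
    """Fit the dipolar wave over a contiguous helical stretch.

    With the period fixed (default 3.6 residues/turn) the model is linear
    in (A_v, a, b) with A_II·cos(ωn + φ) = a·cos ωn + b·sin ωn, so the fit
    is an exact least-squares solve; parameter uncertainties come from the
    residual-variance-scaled covariance.  Requires ≥6 consecutive residues.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    residues = sorted(rdc_by_residue)
    if len(residues) < 6:
        raise ValueError("need at least 6 residues for a dipolar-wave fit")
    if residues[-1] - residues[0] != len(residues) - 1:
        raise ValueError("residues must be consecutive")
    n = np.array(residues, float)
    d = np.array([rdc_by_residue[r] for r in residues])
    w = 2.0 * math.pi / period
    cols = [np.ones_like(n), np.cos(w * n), np.sin(w * n)]
    if second_harmonic:
        cols += [np.cos(2 * w * n), np.sin(2 * w * n)]
    a = np.column_stack(cols)
    if len(residues) < a.shape[1]:
        raise ValueError("fewer points than fit parameters")
    sol, *_ = np.linalg.lstsq(a, d, rcond=None)
    resid = d - a @ sol
    dof = len(d) - a.shape[1]
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(a.T @ a)
    amp = math.hypot(sol[1], sol[2])
    phase = math.degrees(math.atan2(-sol[2], sol[1]))
    if amp > 0:
        # first-order error propagation onto the amplitude
        g = np.array([sol[1] / amp, sol[2] / amp])
        amp_err = math.sqrt(max(0.0, g @ cov[1:3, 1:3] @ g))
    else:
        amp_err = math.sqrt(max(0.0, 0.5 * (cov[1, 1] + cov[2, 2])))
    a_i = a_i_err = 0.0
    if second_harmonic:
        a_i = math.hypot(sol[3], sol[4])
        if a_i > 0:
            g2 = np.array([sol[3] / a_i, sol[4] / a_i])
            a_i_err = math.sqrt(max(0.0, g2 @ cov[3:5, 3:5] @ g2))
    return DipolarWaveFit(
        a_v=float(sol[0]), a_ii=amp, phase_deg=phase, period=period,
        a_v_err=math.sqrt(max(0.0, cov[0, 0])), a_ii_err=amp_err,
        a_i=a_i, a_i_err=a_i_err,
        rmsd_hz=float(np.sqrt(np.mean(resid ** 2))))
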