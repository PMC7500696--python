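"""Backbone dihedrals, superposition/RMSD machinery, helix geometry, and
the contour-length formula.

Conventions
-----------
* Torsions follow the IUPAC sign convention (trans = 180°); values are
  reported in degrees in [−180, 180).
* Angular differences are wrapped circularly before squaring, so a ψ of
  179° and one of −179° differ by 2°, never 358°.
* RMSDs are unweighted over the selected atoms; ensemble summaries report
  mean, SD and SEM over the n(n−1)/2 unordered model pairs with
  SEM = SD/√(n_pairs).
* A helix axis is the dominant principal component of the Cα positions
  after 4-point sliding-window averaging, which removes the ~3.6-residue
  helical wobble before the line fit.  The inter-axis angle is taken
  between the direction vectors without absolute value, so antiparallel
  helices score 180°.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import AtomSelection, Structure

__all__ = [
    "DihedralSet",
    "SuperpositionResult",
    "HelixAxis",
    "MetricSeries",
    "dihedral_angle",
    "backbone_dihedrals",
    "kabsch_superpose",
    "pairwise_ensemble_rmsd",
    "rolling_rmsd",
    "dihedral_rmsd_to_target",
    "helix_axis",
    "interhelix_angle",
    "assign_helix_by_dihedrals",
    "contour_length",
    "wrap_angle",
]

ALPHA_PHI_WINDOW = (-100.0, -30.0)
ALPHA_PSI_WINDOW = (-80.0, -5.0)
ALPHA_MIN_RUN = 4


def wrap_angle(deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle difference(s) into [−180, 180)."""
    return (np.asarray(deg) + 180.0) % 360.0 - 180.0


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle p0–p1–p2–p3 in degrees, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    # components of b0, b2 perpendicular to the central bond
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class DihedralSet:
    """Per-residue backbone (φ, ψ) in degrees; ``None`` marks angles that
    are undefined at chain termini or because of missing atoms."""

    phi: dict[int, float | None] = field(default_factory=dict)
    psi: dict[int, float | None] = field(default_factory=dict)

    @property
    def residues(self) -> list[int]:
        return sorted(self.phi)

    def defined(self, resid: int) -> bool:
        return self.phi.get(resid) is not None and self.psi.get(resid) is not None


def backbone_dihedrals(structure: Structure, model_index: int = 0,
                       chain: str | None = None) -> DihedralSet:
    """Compute φ/ψ for each residue of one model.

    φ of the first residue of a chain and ψ of the last are undefined.
    A residue missing any of N/CA/C is marked undefined with a warning.
    With multiple chains and no ``chain`` argument, residue indices must
    be unique across chains.
    """
    model = structure.models[model_index]
    chains = [c for c in model.chains if chain is None or c.id == chain]
    if chain is not None and not chains:
        raise ValueError(f"chain {chain!r} not found")
    dset = DihedralSet()
    seen: set[int] = set()
    for c in chains:
        n = len(c.residues)
        bb = []
        for r in c.residues:
            trio = (r.atom("N"), r.atom("CA"), r.atom("C"))
            if any(a is None for a in trio):
                warnings.warn(f"residue {c.id}:{r.index} missing backbone atoms; "
                              "dihedrals undefined", stacklevel=2)
                bb.append(None)
            else:
                bb.append(tuple(a.xyz for a in trio))
        for i, r in enumerate(c.residues):
            if r.index in seen:
                raise ValueError(
                    f"residue index {r.index} occurs in more than one chain; "
                    "pass chain= to disambiguate")
            seen.add(r.index)
            phi = psi = None
            if bb[i] is not None:
                ni, cai, ci = bb[i]
                if i > 0 and bb[i - 1] is not None:
                    phi = dihedral_angle(bb[i - 1][2], ni, cai, ci)
                if i < n - 1 and bb[i + 1] is not None:
                    psi = dihedral_angle(ni, cai, ci, bb[i + 1][0])
            dset.phi[r.index] = phi
            dset.psi[r.index] = psi
    return dset


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    """Optimal rigid fit of a mobile onto a reference coordinate set."""

    rotation: np.ndarray  # (3,3), proper
    translation: np.ndarray  # (3,)
    rmsd_fit: float  # Å over the fit atoms
    rmsd_calc: float  # Å over the calc atoms after applying the fit
    degenerate: bool = False  # collinear / rank-deficient fit set

    def transform(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose_coords(ref: np.ndarray, mob: np.ndarray) -> SuperpositionResult:
    """Kabsch fit of paired coordinate arrays (rotation proper, det = +1)."""
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("paired (n,3) coordinate arrays required")
    if len(ref) < 3:
        raise ValueError("at least 3 fit atoms required")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    a = ref - ref_c
    b = mob - mob_c
    sv = np.linalg.svd(a, compute_uv=False)
    degenerate = bool(sv[1] < 1e-8 * max(sv[0], 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(a, b)
    rmat = rot.as_matrix()
    trans = ref_c - rmat @ mob_c
    fitted = mob @ rmat.T + trans
    return SuperpositionResult(rmat, trans, _rmsd(ref, fitted), _rmsd(ref, fitted),
                               degenerate)


def kabsch_superpose(reference: Structure, mobile: Structure,
                     fit_selection: AtomSelection,
                     calc_selection: AtomSelection | None = None,
                     ref_model: int = 0, mob_model: int = 0) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The rotation/translation minimise RMSD over ``fit_selection``;
    ``rmsd_calc`` is then evaluated over ``calc_selection`` (defaults to the
    fit selection) without refitting.
    """
    calc_selection = calc_selection or fit_selection
    ref_fit = fit_selection.coords(reference, ref_model)
    mob_fit = fit_selection.coords(mobile, mob_model)
    if ref_fit.shape != mob_fit.shape:
        raise ValueError("fit selection resolves to different atom counts")
    res = superpose_coords(ref_fit, mob_fit)
    ref_calc = calc_selection.coords(reference, ref_model)
    mob_calc = calc_selection.coords(mobile, mob_model)
    if ref_calc.shape != mob_calc.shape:
        raise ValueError("calc selection resolves to different atom counts")
    res.rmsd_calc = _rmsd(ref_calc, res.transform(mob_calc))
    return res


def pairwise_ensemble_rmsd(ensemble: Structure, fit_selection: AtomSelection,
                           calc_selection: AtomSelection | None = None,
                           ) -> tuple[np.ndarray, dict[str, float]]:
    """All-against-all model RMSD matrix and summary statistics.

    Returns the symmetric n×n matrix (zero diagonal) and
    ``{"mean", "sd", "sem", "n_pairs"}`` over the upper-triangle values,
    with SEM = SD/√(n_pairs).
    """
    n = ensemble.n_models
    if n < 2:
        raise ValueError("ensemble needs at least 2 models")
    calc_selection = calc_selection or fit_selection
    fit = np.array([fit_selection.coords(ensemble, i) for i in range(n)])
    calc = np.array([calc_selection.coords(ensemble, i) for i in range(n)])
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = superpose_coords(fit[i], fit[j])
            mat[i, j] = mat[j, i] = _rmsd(calc[i], res.transform(calc[j]))
    vals = mat[np.triu_indices(n, k=1)]
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    stats = {"mean": float(vals.mean()), "sd": sd,
             "sem": sd / np.sqrt(len(vals)), "n_pairs": float(len(vals))}
    return mat, stats


@dataclass
class MetricSeries:
    """A per-frame scalar metric with summary statistics."""

    name: str
    values: np.ndarray
    frames: np.ndarray  # frame indices the values belong to

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(len(self.values)) if len(self.values) else 0.0

    def summary(self) -> dict[str, float]:
        return {"mean": self.mean, "sd": self.sd, "sem": self.sem,
                "n": float(len(self.values))}


def rolling_rmsd(trajectory: Structure, lag_frames: int,
                 fit_selection: AtomSelection,
                 calc_selection: AtomSelection | None = None) -> MetricSeries:
    """Drift metric: RMSD between frame t and frame t−lag after superposing
    the earlier frame onto the current one over ``fit_selection``.

    Rigid-body motion is removed by the superposition, so a trajectory of
    pure rotations/translations scores zero.
    """
    if lag_frames <= 0:
        raise ValueError("lag must be a positive number of frames")
    n = trajectory.n_models
    if n <= lag_frames:
        raise ValueError("trajectory shorter than the lag")
    calc_selection = calc_selection or fit_selection
    fit = np.array([fit_selection.coords(trajectory, i) for i in range(n)])
    calc = np.array([calc_selection.coords(trajectory, i) for i in range(n)])
    vals = []
    for t in range(lag_frames, n):
        res = superpose_coords(fit[t], fit[t - lag_frames])
        vals.append(_rmsd(calc[t], res.transform(calc[t - lag_frames])))
    return MetricSeries("rolling_rmsd", np.array(vals),
                        np.arange(lag_frames, n))


def dihedral_rmsd_to_target(dihedral_set: DihedralSet, targets,
                            residue_set) -> float:
    """RMSD (degrees) between observed (φ, ψ) and predicted targets over
    ``residue_set``, pooling φ and ψ equally with circular differences."""
    residue_set = sorted(set(residue_set))
    if not residue_set:
        raise ValueError("empty residue set")
    target_map = {t.resid: t for t in targets}
    diffs = []
    for resid in residue_set:
        if resid not in target_map:
            raise ValueError(f"residue {resid} has no target angles")
        phi = dihedral_set.phi.get(resid)
        psi = dihedral_set.psi.get(resid)
        if phi is None or psi is None:
            raise ValueError(f"residue {resid} has undefined observed angles")
        t = target_map[resid]
        diffs.append(wrap_angle(phi - t.phi))
        diffs.append(wrap_angle(psi - t.psi))
    return float(np.sqrt(np.mean(np.square(diffs))))


# ---------------------------------------------------------------------------
# helix geometry
# ---------------------------------------------------------------------------


@dataclass
class HelixAxis:
    direction: np.ndarray  # unit vector
    centroid: np.ndarray  # Å
    residue_range: tuple[int, int]


def helix_axis(structure: Structure, residue_range: tuple[int, int],
               chain: str | None = None, model_index: int = 0,
               window: int = 4) -> HelixAxis:
    """Fit the axis of a helical segment from its Cα trace.

    Cα positions are smoothed with a ``window``-point sliding average
    (default 4, close to one helical turn) and the dominant principal
    component of the smoothed points is taken as the axis; its sign points
    from the N- to the C-terminal end of the segment.
    """
    lo, hi = residue_range
    sel = AtomSelection(chain=chain, ranges=((lo, hi),), atoms=frozenset({"CA"}))
    ca = sel.coords(structure, model_index)
    if len(ca) < 5:
        raise ValueError("need at least 5 CA atoms for an axis fit")
    w = min(window, len(ca) - 1)
    kernel = np.ones(w) / w
    smooth = np.column_stack([np.convolve(ca[:, k], kernel, mode="valid")
                              for k in range(3)])
    centered = smooth - smooth.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-8:
        raise ValueError("degenerate helix geometry (coincident points)")
    direction = vt[0]
    if np.dot(direction, smooth[-1] - smooth[0]) < 0:
        direction = -direction
    return HelixAxis(direction / np.linalg.norm(direction),
                     ca.mean(axis=0), (lo, hi))


def interhelix_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Angle (degrees, [0, 180]) between two helix direction vectors.

    The directions are signed (N→C), so antiparallel helices give 180°.
    """
    cosang = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def assign_helix_by_dihedrals(dihedral_set: DihedralSet) -> dict[int, str]:
    """Label residues helix/coil from their (φ, ψ).

    A residue is helical when it sits inside the α window
    (φ ∈ [−100, −30], ψ ∈ [−80, −5]) within a run of at least 4 consecutive
    such residues; all other residues — including termini with undefined
    angles — are coil.
    """
    residues = dihedral_set.residues
    in_window = []
    for r in residues:
        phi, psi = dihedral_set.phi.get(r), dihedral_set.psi.get(r)
        ok = (phi is not None and psi is not None
              and ALPHA_PHI_WINDOW[0] <= phi <= ALPHA_PHI_WINDOW[1]
              and ALPHA_PSI_WINDOW[0] <= psi <= ALPHA_PSI_WINDOW[1])
        in_window.append(ok)
    labels = {r: "coil" for r in residues}
    i = 0
    while i < len(residues):
        if in_window[i]:
            j = i
            while j < len(residues) and in_window[j] and \
                    (j == i or residues[j] == residues[j - 1] + 1):
                j += 1
            if j - i >= ALPHA_MIN_RUN:
                for k in range(i, j):
                    labels[residues[k]] = "helix"
            i = j
        else:
            i += 1
    return labels


def contour_length(n_coil: int, n_helix: int) -> float:
    """Maximum end-to-end extension (Å) of a segment with ``n_coil``
    random-coil residues and ``n_helix`` α-helical residues:
    L = 4 Å·n_coil + 1.5 Å·n_helix."""
    if n_coil < 0 or n_helix < 0:
        raise ValueError("residue counts must be non-negative")
    if int(n_coil) != n_coil or int(n_helix) != n_helix:
        raise ValueError("residue counts must be integers")
    return 4.0 * n_coil + 1.5 * n_helix
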