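"""Composite ensemble/trajectory procedures: topology discrimination
between candidate helix packings, simulated-annealing convergence
statistics, and ensemble summaries.

These routines compose the geometry primitives into the reports used to
decide between structural topologies (which candidate's trajectory stays
closest to its torsion targets and drifts least) and to demonstrate that
two independently annealed ensembles converged to the same structure
(small RMSD between ensemble-average structures, consistent pooled
pairwise statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import (backbone_dihedrals, dihedral_rmsd_to_target,
                       kabsch_superpose, pairwise_ensemble_rmsd, rolling_rmsd,
                       superpose_coords)
from .structio import AtomSelection, Structure

__all__ = [
    "ConvergenceReport",
    "topology_metrics_report",
    "average_structure",
    "annealing_convergence",
    "ensemble_summary",
    "count_interchain_contacts",
]


def topology_metrics_report(trajectories: Mapping[str, Structure],
                            talos_targets, fit_selection: AtomSelection,
                            calc_selection: AtomSelection,
                            dihedral_residues, lag_frames: int = 1,
                            chain: str | None = None) -> pd.DataFrame:
    """Per-trajectory drift and torsion-agreement metrics.

    For each named candidate trajectory: the rolling-RMSD mean ± SD
    (conformational drift over a fixed frame lag) and the mean per-frame
    dihedral RMSD against the predicted (φ, ψ) targets.  Pairwise ratios
    of the dihedral-RMSD means between candidates are attached
    (``df.attrs['dihedral_rmsd_ratios']``) — the discriminator that
    flags a topology whose torsions sit far from their targets — and the
    candidate with the lowest dihedral RMSD is marked most consistent.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    rows = {}
    for name, traj in trajectories.items():
        rolling = rolling_rmsd(traj, lag_frames, fit_selection, calc_selection)
        dih_vals = []
        for frame in range(traj.n_models):
            dset = backbone_dihedrals(traj, frame, chain=chain)
            dih_vals.append(dihedral_rmsd_to_target(dset, talos_targets,
                                                    dihedral_residues))
        rows[name] = {
            "rolling_rmsd_mean": rolling.mean,
            "rolling_rmsd_sd": rolling.sd,
            "dihedral_rmsd_mean": float(np.mean(dih_vals)),
            "dihedral_rmsd_sd": float(np.std(dih_vals, ddof=1)) if len(dih_vals) > 1 else 0.0,
            "n_frames": traj.n_models,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    best = df["dihedral_rmsd_mean"].idxmin()
    df["most_consistent"] = [name == best for name in df.index]
    ratios = {}
    for a, b in combinations(df.index, 2):
        num = df.loc[a, "dihedral_rmsd_mean"]
        den = df.loc[b, "dihedral_rmsd_mean"]
        ratios[f"{a}/{b}"] = float(num / den) if den > 0 else float("inf")
    df.attrs["dihedral_rmsd_ratios"] = ratios
    return df


def average_structure(ensemble: Structure,
                      fit_selection: AtomSelection) -> Structure:
    """Coordinate-average structure of an ensemble.

    Every model is superposed onto the first over ``fit_selection`` and the
    per-atom mean is taken.  The result is a raw coordinate mean — bond
    geometry is not re-idealised — which is adequate for RMSD comparisons
    between ensemble averages.
    """
    n = ensemble.n_models
    if n < 2:
        raise ValueError("ensemble needs at least 2 models")
    ref_fit = fit_selection.coords(ensemble, 0)
    acc = np.zeros_like(ensemble.models[0].coords())
    for i in range(n):
        coords = ensemble.models[i].coords()
        if i == 0:
            acc += coords
            continue
        res = superpose_coords(ref_fit, fit_selection.coords(ensemble, i))
        acc += res.transform(coords)
    out = Structure([ensemble.models[0]]).copy()
    out.models[0].set_coords(acc / n)
    return out


def count_interchain_contacts(structure: Structure, model_index: int = 0,
                              cutoff: float = 5.0) -> int:
    """Number of inter-chain heavy-atom pairs within ``cutoff`` Å."""
    model = structure.models[model_index]
    per_chain = []
    for c in model.chains:
        xyz = np.array([a.xyz for r in c.residues for a in r.atoms
                        if a.element != "H"])
        per_chain.append(xyz)
    total = 0
    for i in range(len(per_chain)):
        for j in range(i + 1, len(per_chain)):
            if not len(per_chain[i]) or not len(per_chain[j]):
                continue
            d = np.linalg.norm(per_chain[i][:, None, :] - per_chain[j][None, :, :],
                               axis=-1)
            total += int(np.count_nonzero(d < cutoff))
    return total


@dataclass
class ConvergenceReport:
    """Agreement between two independently generated ensembles."""

    between_global_rmsd: float   # Å, average structures over calc_sel_global
    between_subunit_rmsd: float  # Å, average structures over calc_sel_subunit
    pooled_pairwise: dict[str, float]  # mean/sd/sem over all retained pairs
    within_a: dict[str, float]
    within_b: dict[str, float]
    excluded: dict[str, list[int]]  # ensemble tag -> 0-based model indices

    def as_dict(self) -> dict:
        return {
            "between_global_rmsd": self.between_global_rmsd,
            "between_subunit_rmsd": self.between_subunit_rmsd,
            "pooled_pairwise": self.pooled_pairwise,
            "within_a": self.within_a,
            "within_b": self.within_b,
            "excluded": self.excluded,
        }


def _filter_dissociated(ensemble: Structure, contact_cutoff: float,
                        min_contacts: int) -> tuple[Structure, list[int]]:
    keep, dropped = [], []
    for i, m in enumerate(ensemble.models):
        n = count_interchain_contacts(ensemble, i, contact_cutoff)
        (keep if n >= min_contacts else dropped).append(i)
    if len(keep) < 2:
        raise ValueError("fewer than 2 models retained after the "
                         "dissociation filter")
    return Structure([ensemble.models[i] for i in keep]).copy(), dropped


def annealing_convergence(ensemble_a: Structure, ensemble_b: Structure,
                          fit_selection: AtomSelection,
                          calc_selection_global: AtomSelection,
                          calc_selection_subunit: AtomSelection | None = None,
                          contact_cutoff: float = 5.0,
                          min_contacts: int = 10) -> ConvergenceReport:
    """Convergence statistics for two independently annealed ensembles.

    Replicas whose chains dissociated — fewer than ``min_contacts``
    inter-chain heavy-atom contacts within ``contact_cutoff`` Å — are
    excluded and reported.  Each retained ensemble is averaged; the two
    averages are superposed over ``fit_selection`` and RMSDs reported over
    the global and subunit calc selections.  Pooled pairwise statistics
    (mean ± SEM over all unordered pairs of retained models from both
    ensembles) quantify the combined spread.  All reported scalars are
    symmetric in the ensemble order.
    """
    a_kept, a_drop = _filter_dissociated(ensemble_a, contact_cutoff, min_contacts)
    b_kept, b_drop = _filter_dissociated(ensemble_b, contact_cutoff, min_contacts)
    calc_selection_subunit = calc_selection_subunit or calc_selection_global
    avg_a = average_structure(a_kept, fit_selection)
    avg_b = average_structure(b_kept, fit_selection)
    fit = kabsch_superpose(avg_a, avg_b, fit_selection, calc_selection_global)
    sub = kabsch_superpose(avg_a, avg_b, fit_selection, calc_selection_subunit)
    pooled = Structure(a_kept.models + b_kept.models).copy()
    _, pooled_stats = pairwise_ensemble_rmsd(pooled, fit_selection,
                                             calc_selection_global)
    _, within_a = pairwise_ensemble_rmsd(a_kept, fit_selection,
                                         calc_selection_global)
    _, within_b = pairwise_ensemble_rmsd(b_kept, fit_selection,
                                         calc_selection_global)
    return ConvergenceReport(
        between_global_rmsd=fit.rmsd_calc,
        between_subunit_rmsd=sub.rmsd_calc,
        pooled_pairwise=pooled_stats,
        within_a=within_a, within_b=within_b,
        excluded={"a": a_drop, "b": b_drop},
    )


def ensemble_summary(ensemble: Structure, fit_selection: AtomSelection,
                     calc_selection: AtomSelection | None = None) -> dict:
    """Pairwise-RMSD summary of a deposited/generated ensemble
    (mean, SD, SEM over all unordered model pairs) plus the full matrix."""
    mat, stats = pairwise_ensemble_rmsd(ensemble, fit_selection, calc_selection)
    return {"n_models": ensemble.n_models, "matrix": mat, **stats}
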