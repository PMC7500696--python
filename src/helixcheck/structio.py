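"""Coordinate and tabular I/O for the NMR structural-analysis pipeline.

The coordinate container is a lightweight chain → residue → atom hierarchy
with one or more models (an NMR-style ensemble or a trajectory written as a
multi-model PDB file).  PDB parsing and writing are delegated to :mod:`gemmi`;
this module enforces the invariants the downstream analysis relies on
(identical atom topology across models, finite coordinates, fixed-width
format limits).

Tabular inputs mirror the spreadsheets that accompany an NMR study:

* TALOS+-style per-residue torsion predictions (``phi``/``psi`` with
  uncertainties, the RCI-S² order parameter and a classification label),
* per-residue ¹H/¹⁵N peak lists with intensities for titration states,
* per-residue ¹H-¹⁵N residual dipolar couplings with uncertainties.

Tables may be comma- or whitespace-delimited and must carry a header row.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Model",
    "Structure",
    "AtomSelection",
    "TalosRecord",
    "DihedralRestraint",
    "PeakRecord",
    "RdcRecord",
    "PdbParseError",
    "TopologyError",
    "PdbFormatError",
    "TableFormatError",
    "read_pdb",
    "write_pdb",
    "read_talos_table",
    "write_talos_table",
    "read_rdc_table",
    "write_rdc_table",
    "read_peak_table",
    "write_peak_table",
    "classify_rigid_residues",
    "write_dihedral_restraints",
    "render_restraints",
]

BACKBONE = ("N", "CA", "C")

TALOS_CLASSES = ("None", "Good", "Warn", "Dyn")
PEAK_STATUSES = ("ok", "overlapped", "missing")


class PdbParseError(ValueError):
    """Raised for malformed PDB records."""


class TopologyError(ValueError):
    """Raised when models of a multi-model file disagree in atom topology."""


class PdbFormatError(ValueError):
    """Raised when a structure cannot be rendered in fixed-width PDB fields."""


class TableFormatError(ValueError):
    """Raised for malformed or out-of-contract tabular input."""


# ---------------------------------------------------------------------------
# coordinate containers
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # Å, shape (3,)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite floats")


@dataclass
class Residue:
    index: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, index: int) -> Residue | None:
        for r in self.residues:
            if r.index == index:
                return r
        return None


@dataclass
class Model:
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def topology_key(self) -> tuple:
        return tuple(
            (c.id, r.index, r.name, a.name)
            for c, r, a in self.iter_atoms()
        )

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for _, _, a in self.iter_atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        atoms = [a for _, _, a in self.iter_atoms()]
        if len(atoms) != len(xyz):
            raise ValueError("coordinate array length mismatch")
        for a, v in zip(atoms, xyz):
            a.xyz = np.asarray(v, dtype=float)


@dataclass
class Structure:
    """An ordered set of models sharing one atom topology."""

    models: list[Model] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_models(self) -> int:
        return len(self.models)

    def validate(self) -> None:
        if not self.models:
            return
        ref = self.models[0].topology_key()
        for i, m in enumerate(self.models[1:], start=2):
            if m.topology_key() != ref:
                raise TopologyError(
                    f"model {i} atom topology differs from model 1 "
                    f"({len(m.topology_key())} vs {len(ref)} atoms or mismatched names)"
                )

    def copy(self) -> "Structure":
        models = []
        for m in self.models:
            chains = [
                Chain(c.id, [
                    Residue(r.index, r.name, [Atom(a.name, a.element, a.xyz.copy()) for a in r.atoms])
                    for r in c.residues
                ])
                for c in m.chains
            ]
            models.append(Model(chains))
        return Structure(models)


# ---------------------------------------------------------------------------
# atom selections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomSelection:
    """A chain / residue-range / atom-name selection.

    ``chain=None`` matches every chain; ``ranges=None`` every residue;
    ``atoms=None`` every atom name.  Resolution order follows file order,
    so repeated resolution against the same model is deterministic.

    The string syntax is ``chain:start-end:atoms``, e.g. ``A:17-39:N,CA,C``.
    Multiple residue ranges are comma-separated (``A:17-24,27-39:CA``);
    ``*`` acts as a wildcard for any field.
    """

    chain: str | None = None
    ranges: tuple[tuple[int, int], ...] | None = None
    atoms: frozenset[str] | None = None

    @classmethod
    def parse(cls, text: str) -> "AtomSelection":
        parts = text.strip().split(":")
        if len(parts) > 3:
            raise ValueError(f"bad selection syntax: {text!r}")
        while len(parts) < 3:
            parts.append("*")
        chain = None if parts[0] in ("", "*") else parts[0]
        ranges: tuple[tuple[int, int], ...] | None
        if parts[1] in ("", "*"):
            ranges = None
        else:
            out = []
            for token in parts[1].split(","):
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", token.strip())
                if not m:
                    raise ValueError(f"bad residue range {token!r} in {text!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                if hi < lo:
                    raise ValueError(f"descending residue range {token!r}")
                out.append((lo, hi))
            ranges = tuple(out)
        atoms = None if parts[2] in ("", "*") else frozenset(
            a.strip() for a in parts[2].split(",") if a.strip()
        )
        return cls(chain=chain, ranges=ranges, atoms=atoms)

    def _match_residue(self, index: int) -> bool:
        if self.ranges is None:
            return True
        return any(lo <= index <= hi for lo, hi in self.ranges)

    def resolve(self, model: Model) -> list[Atom]:
        picked = []
        for c, r, a in model.iter_atoms():
            if self.chain is not None and c.id != self.chain:
                continue
            if not self._match_residue(r.index):
                continue
            if self.atoms is not None and a.name not in self.atoms:
                continue
            picked.append(a)
        if not picked:
            raise ValueError(f"selection {self} matched no atoms")
        return picked

    def coords(self, structure: Structure, model_index: int = 0) -> np.ndarray:
        return np.array([a.xyz for a in self.resolve(structure.models[model_index])])


def backbone_selection(chain: str | None = None,
                       start: int | None = None,
                       stop: int | None = None) -> AtomSelection:
    """Convenience N/CA/C selection over an optional residue range."""
    ranges = None if start is None else ((start, stop if stop is not None else start),)
    return AtomSelection(chain=chain, ranges=ranges, atoms=frozenset(BACKBONE))


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------


def _from_gemmi(st: gemmi.Structure, include_hetatm: bool) -> Structure:
    models = []
    for gm in st:
        chains = []
        for gc in gm:
            residues = []
            for gr in gc:
                if not include_hetatm and gr.het_flag == "H":
                    continue
                atoms = []
                for ga in gr:
                    if ga.altloc not in ("", "A", "\0"):
                        continue  # keep blank/'A' altlocs only
                    atoms.append(Atom(ga.name, ga.element.name,
                                      np.array([ga.pos.x, ga.pos.y, ga.pos.z])))
                if atoms:
                    residues.append(Residue(gr.seqid.num, gr.name, atoms))
            if residues:
                chains.append(Chain(gc.name, residues))
        models.append(Model(chains))
    return Structure(models)


def read_pdb(path: str | Path, include_hetatm: bool = False) -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    Only ATOM records are kept by default; altlocs other than blank/'A' are
    dropped; residue numbering is taken verbatim from the file.  A topology
    mismatch between models raises :class:`TopologyError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise PdbParseError(f"{path}: {exc}") from exc
    structure = _from_gemmi(st, include_hetatm)
    if not structure.models or not any(m.chains for m in structure.models):
        raise PdbParseError(f"{path}: no ATOM records found")
    return structure


_COORD_LIMIT = 9999.999


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as a PDB file re-readable by :func:`read_pdb`.

    Single-model structures are written without MODEL/ENDMDL records.
    Coordinates outside the fixed-width field (|x| > 9999.999 Å) raise
    :class:`PdbFormatError`.
    """
    structure.validate()
    for m in structure.models:
        coords = m.coords()
        if coords.size and (np.abs(coords).max() > _COORD_LIMIT):
            raise PdbFormatError(
                "coordinate magnitude exceeds the 8.3 fixed-width PDB field"
            )
    st = gemmi.Structure()
    st.name = "helixcheck"
    for i, m in enumerate(structure.models, start=1):
        gm = gemmi.Model(i)
        for c in m.chains:
            gc = gemmi.Chain(c.id)
            for r in c.residues:
                gr = gemmi.Residue()
                gr.name = r.name
                gr.seqid = gemmi.SeqId(r.index, " ")
                gr.het_flag = "A"
                for a in r.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.xyz)
                    ga.occ = 1.0
                    ga.b_iso = 0.0
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    doc_opts = gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
    st.write_pdb(str(path), doc_opts)


# ---------------------------------------------------------------------------
# tabular records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TalosRecord:
    """One row of a TALOS+-style torsion prediction table."""

    resid: int
    resname: str
    phi: float  # deg
    psi: float  # deg
    dphi: float  # deg, prediction SD
    dpsi: float  # deg
    dist: float  # database matching score
    s2: float  # RCI-S², 0–1
    count: int
    cls: str  # one of TALOS_CLASSES

    def __post_init__(self) -> None:
        if not (-180.0 <= self.phi < 180.0 and -180.0 <= self.psi < 180.0):
            raise TableFormatError(
                f"residue {self.resid}: torsions must lie in [-180, 180)"
            )
        if not (0.0 <= self.s2 <= 1.0):
            raise TableFormatError(f"residue {self.resid}: S2 must lie in [0, 1]")
        if self.cls not in TALOS_CLASSES:
            raise TableFormatError(
                f"residue {self.resid}: unknown CLASS token {self.cls!r}"
            )


@dataclass(frozen=True)
class DihedralRestraint:
    """A flat-bottom backbone torsion restraint."""

    resid: int
    angle: str  # "phi" | "psi"
    target: float  # deg
    half_width: float  # deg
    rk2: float  # kcal·mol⁻¹·rad⁻¹
    rk3: float

    def __post_init__(self) -> None:
        if self.rk2 <= 0 or self.rk3 <= 0:
            raise ValueError("force constants must be positive")
        if self.angle not in ("phi", "psi"):
            raise ValueError(f"unknown angle name {self.angle!r}")


@dataclass(frozen=True)
class PeakRecord:
    """A ¹H-¹⁵N cross-peak for one residue under one condition."""

    resid: int
    dh_ppm: float
    dn_ppm: float
    intensity: float  # arbitrary units; NaN when not measurable
    condition: str
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status not in PEAK_STATUSES:
            raise TableFormatError(f"residue {self.resid}: bad status {self.status!r}")
        if self.status == "ok" and not (self.intensity >= 0):
            raise TableFormatError(
                f"residue {self.resid}: 'ok' peak needs a non-negative intensity"
            )


@dataclass(frozen=True)
class RdcRecord:
    """An observed ¹H-¹⁵N residual dipolar coupling."""

    resid: int
    d_obs_hz: float
    sigma_hz: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_hz >= 0):
            raise TableFormatError(
                f"residue {self.resid}: RDC uncertainty must be >= 0"
            )


# ---------------------------------------------------------------------------
# table readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    text = path.read_text()
    stripped = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not stripped:
        return pd.DataFrame(columns=list(required))
    if "," not in stripped[0]:  # normalise whitespace-delimited to CSV
        stripped = [",".join(ln.split()) for ln in stripped]
    df = pd.read_csv(io.StringIO("\n".join(stripped)),
                     float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    return df


def read_talos_table(path: str | Path) -> list[TalosRecord]:
    """Parse a torsion-prediction table (columns resid, resname, phi, psi,
    dphi, dpsi, dist, s2, count, class)."""
    df = _read_table(path, ["resid", "resname", "phi", "psi", "dphi", "dpsi",
                            "dist", "s2", "count", "class"])
    records = []
    for _, row in df.iterrows():
        records.append(TalosRecord(
            resid=int(row["resid"]), resname=str(row["resname"]),
            phi=float(row["phi"]), psi=float(row["psi"]),
            dphi=float(row["dphi"]), dpsi=float(row["dpsi"]),
            dist=float(row["dist"]), s2=float(row["s2"]),
            count=int(row["count"]), cls=str(row["class"]).strip(),
        ))
    return records


def write_talos_table(records: Iterable[TalosRecord], path: str | Path) -> None:
    rows = [(r.resid, r.resname, r.phi, r.psi, r.dphi, r.dpsi, r.dist,
             r.s2, r.count, r.cls) for r in records]
    df = pd.DataFrame(rows, columns=["resid", "resname", "phi", "psi", "dphi",
                                     "dpsi", "dist", "s2", "count", "class"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_rdc_table(path: str | Path) -> list[RdcRecord]:
    """Parse an RDC table (columns resid, d_obs_hz, sigma_hz)."""
    df = _read_table(path, ["resid", "d_obs_hz", "sigma_hz"])
    return [RdcRecord(int(r["resid"]), float(r["d_obs_hz"]), float(r["sigma_hz"]))
            for _, r in df.iterrows()]


def write_rdc_table(records: Iterable[RdcRecord], path: str | Path) -> None:
    df = pd.DataFrame([(r.resid, r.d_obs_hz, r.sigma_hz) for r in records],
                      columns=["resid", "d_obs_hz", "sigma_hz"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Parse a peak table (columns resid, dh_ppm, dn_ppm, intensity,
    condition, status).  Overlapped/missing rows may leave intensity empty."""
    df = _read_table(path, ["resid", "dh_ppm", "dn_ppm", "intensity",
                            "condition", "status"])
    records = []
    for _, row in df.iterrows():
        inten = row["intensity"]
        inten = float(inten) if pd.notna(inten) and str(inten).strip() != "" else math.nan
        records.append(PeakRecord(
            resid=int(row["resid"]),
            dh_ppm=float(row["dh_ppm"]) if pd.notna(row["dh_ppm"]) else math.nan,
            dn_ppm=float(row["dn_ppm"]) if pd.notna(row["dn_ppm"]) else math.nan,
            intensity=inten,
            condition=str(row["condition"]).strip(),
            status=str(row["status"]).strip(),
        ))
    return records


def write_peak_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.resid, r.dh_ppm, r.dn_ppm,
          "" if math.isnan(r.intensity) else r.intensity,
          r.condition, r.status) for r in records],
        columns=["resid", "dh_ppm", "dn_ppm", "intensity", "condition", "status"])
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# rigidity classification and restraint generation
# ---------------------------------------------------------------------------


def classify_rigid_residues(records: Sequence[TalosRecord],
                            threshold: float = 0.7) -> set[int]:
    """Residues whose chemical-shift order parameter RCI-S² is at or above
    ``threshold`` (default 0.7, the conventional well-structured cutoff)."""
    if not records:
        raise ValueError("no records to classify")
    return {r.resid for r in records if r.s2 >= threshold}


def write_dihedral_restraints(records: Sequence[TalosRecord],
                              rigid_set: Iterable[int],
                              rk: float = 32.0,
                              half_width_min: float = 10.0,
                              exclude: Iterable[int] = ()) -> list[DihedralRestraint]:
    """Generate flat-bottom φ/ψ restraints for rigid residues.

    Each rigid residue contributes a φ and a ψ restraint targeted at its
    predicted torsions with force constants ``rk2 = rk3 = rk``
    (default 32.0 kcal·mol⁻¹·rad⁻¹).  φ is restrained only when residue
    i−1 is present in the table and ψ only when i+1 is, since the torsions
    are undefined at chain termini.  Residues in ``exclude`` are left
    unrestrained.  Half-width = max(prediction SD, ``half_width_min``).
    """
    by_resid = {r.resid: r for r in records}
    rigid = set(rigid_set)
    excluded = set(exclude)
    missing = rigid - set(by_resid)
    if missing:
        raise ValueError(f"rigid residues absent from prediction table: {sorted(missing)}")
    restraints: list[DihedralRestraint] = []
    for resid in sorted(rigid - excluded):
        rec = by_resid[resid]
        if resid - 1 in by_resid:  # phi needs C' of the preceding residue
            restraints.append(DihedralRestraint(
                resid, "phi", rec.phi, max(rec.dphi, half_width_min), rk, rk))
        if resid + 1 in by_resid:  # psi needs N of the following residue
            restraints.append(DihedralRestraint(
                resid, "psi", rec.psi, max(rec.dpsi, half_width_min), rk, rk))
    return restraints


def render_restraints(restraints: Sequence[DihedralRestraint],
                      style: str = "generic") -> str:
    """Render restraints as text.

    ``generic`` emits one line per restraint:
    ``resid angle target half_width rk2 rk3``.  ``amber`` emits namelist-like
    blocks carrying the flat-bottom well bounds (r2 = target − hw,
    r3 = target + hw) — a formatting convenience, not a semantic change.
    """
    if style == "generic":
        lines = ["# resid angle target_deg half_width_deg rk2 rk3"]
        for r in restraints:
            lines.append(f"{r.resid:5d} {r.angle:3s} {r.target:9.2f} "
                         f"{r.half_width:7.2f} {r.rk2:6.2f} {r.rk3:6.2f}")
        return "\n".join(lines) + "\n"
    if style == "amber":
        blocks = []
        for r in restraints:
            blocks.append(
                " &rst\n"
                f"  ! residue {r.resid} {r.angle}\n"
                f"  r1={r.target - r.half_width - 180.0:.2f}, "
                f"r2={r.target - r.half_width:.2f}, "
                f"r3={r.target + r.half_width:.2f}, "
                f"r4={r.target + r.half_width + 180.0:.2f},\n"
                f"  rk2={r.rk2:.1f}, rk3={r.rk3:.1f},\n"
                " /"
            )
        return "\n".join(blocks) + "\n"
    raise ValueError(f"unknown restraint rendering style {style!r}")
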