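"""Chemical-shift perturbation, titration attenuation, and quartile-based
effect classification.

The compound CSP combines the amide ¹H and ¹⁵N shift changes on a common
ppm scale, Δδ = [(Δδ_H)² + (Δδ_N/6.5)²]^½; the 6.5 scale reflects the
relative ¹⁵N shift dispersion and is configurable.  Titration attenuation
is the peak-intensity ratio I/I₀ against a reference (ligand-free)
condition.  For mapping onto a sequence, scored residues are divided into
four effect classes at the quartiles of the score distribution; q4 is
always the strongest-effect class, so for attenuation (where a *smaller*
I/I₀ means a stronger effect) the ordering is inverted.  Residues whose
peaks are overlapped or missing are classed ``undetermined``.

Quartiles use linear interpolation between order statistics (numpy's
default, Hyndman–Fan type 7); ties at a boundary fall to the lower class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structio import PeakRecord

__all__ = [
    "CspResult",
    "AttenuationResult",
    "EffectClasses",
    "compound_csp",
    "attenuation_series",
    "quartile_classes",
    "map_to_sequence",
]

CLASS_ORDER = ("q1", "q2", "q3", "q4")


@dataclass
class CspResult:
    """Per-residue compound and component shift changes (ppm)."""

    delta: dict[int, float]      # compound Δδ; only residues scored ok
    delta_h: dict[int, float]
    delta_n: dict[int, float]
    undetermined: set[int]
    nitrogen_scale: float = 6.5


@dataclass
class AttenuationResult:
    """Per-residue I/I₀ per titration condition."""

    ratios: dict[str, dict[int, float]]  # condition -> resid -> I/I0
    reference: str
    undetermined: dict[str, set[int]]

    def condition(self, label: str) -> dict[int, float]:
        return self.ratios[label]


@dataclass
class EffectClasses:
    """Quartile-based per-residue effect classes; q4 = strongest."""

    classes: dict[int, str]  # resid -> q1..q4 | undetermined
    quartiles: tuple[float, float, float]
    larger_is_stronger: bool

    def residues_in(self, cls: str) -> list[int]:
        return sorted(r for r, c in self.classes.items() if c == cls)


def _index_ok(peaks: Iterable[PeakRecord]) -> tuple[dict[int, PeakRecord], set[int]]:
    ok: dict[int, PeakRecord] = {}
    bad: set[int] = set()
    for p in peaks:
        if p.status == "ok" and math.isfinite(p.dh_ppm) and math.isfinite(p.dn_ppm):
            ok[p.resid] = p
        else:
            bad.add(p.resid)
    return ok, bad


def compound_csp(peaks_free: Sequence[PeakRecord],
                 peaks_bound: Sequence[PeakRecord],
                 nitrogen_scale: float = 6.5) -> CspResult:
    """Compound chemical-shift perturbation between two states.

    Residues are matched by index; a residue is scored only when its peak
    is ``ok`` in both states, otherwise it is reported undetermined.
    The result uses absolute shift differences and is therefore symmetric
    in which state is called free or bound.
    """
    if nitrogen_scale <= 0:
        raise ValueError("nitrogen scale must be positive")
    free_ok, free_bad = _index_ok(peaks_free)
    bound_ok, bound_bad = _index_ok(peaks_bound)
    matched = set(free_ok) & set(bound_ok)
    undetermined = (set(free_ok) | set(bound_ok) | free_bad | bound_bad) - matched
    delta, dh, dn = {}, {}, {}
    for resid in sorted(matched):
        f, b = free_ok[resid], bound_ok[resid]
        ddh = abs(b.dh_ppm - f.dh_ppm)
        ddn = abs(b.dn_ppm - f.dn_ppm)
        dh[resid] = ddh
        dn[resid] = ddn
        delta[resid] = math.hypot(ddh, ddn / nitrogen_scale)
    return CspResult(delta, dh, dn, undetermined, nitrogen_scale)


def attenuation_series(titration: Mapping[str, Sequence[PeakRecord]],
                       reference_condition: str) -> AttenuationResult:
    """Peak-intensity attenuation I/I₀ for every condition of a titration.

    I₀ is the intensity in the reference (ligand-free) condition; the
    reference condition itself is reported as exactly 1 for every scored
    residue.  Residues with I₀ = 0, or with an overlapped/missing peak in
    either condition, are undetermined for that condition.
    """
    if reference_condition not in titration:
        raise ValueError(f"reference condition {reference_condition!r} missing")
    ref_ok, ref_bad = _index_ok(titration[reference_condition])
    ref_i = {r: p.intensity for r, p in ref_ok.items()
             if math.isfinite(p.intensity)}
    ratios: dict[str, dict[int, float]] = {}
    undetermined: dict[str, set[int]] = {}
    for label, peaks in titration.items():
        ok, bad = _index_ok(peaks)
        cond_ratios: dict[int, float] = {}
        cond_bad = set(bad) | ref_bad
        for resid, p in ok.items():
            i0 = ref_i.get(resid)
            if i0 is None or i0 == 0 or not math.isfinite(p.intensity):
                cond_bad.add(resid)
                continue
            if label == reference_condition:
                cond_ratios[resid] = 1.0
            else:
                cond_ratios[resid] = p.intensity / i0
        ratios[label] = cond_ratios
        undetermined[label] = cond_bad - set(cond_ratios)
    return AttenuationResult(ratios, reference_condition, undetermined)


def quartile_classes(values: Mapping[int, float],
                     larger_is_stronger: bool = True) -> EffectClasses:
    """Partition scored residues into four classes at the quartiles.

    Residues mapping to NaN/None are excluded from the quartile computation
    and labelled ``undetermined``.  Scores are oriented so that q4 is the
    strongest effect: for attenuation ratios pass
    ``larger_is_stronger=False``.  Classification is rank-based and thus
    invariant under strictly increasing transforms of the scores.
    """
    scored = {r: v for r, v in values.items()
              if v is not None and math.isfinite(v)}
    if len(scored) < 4:
        raise ValueError("need at least 4 scored residues for quartiles")
    resids = sorted(scored)
    raw = np.array([scored[r] for r in resids], float)
    oriented = raw if larger_is_stronger else -raw
    q1, q2, q3 = np.percentile(oriented, [25, 50, 75])  # linear interpolation
    classes: dict[int, str] = {}
    for resid, v in zip(resids, oriented):
        if v <= q1:
            classes[resid] = "q1"
        elif v <= q2:
            classes[resid] = "q2"
        elif v <= q3:
            classes[resid] = "q3"
        else:
            classes[resid] = "q4"
    for resid in set(values) - set(scored):
        classes[resid] = "undetermined"
    return EffectClasses(classes, (float(q1), float(q2), float(q3)),
                         larger_is_stronger)


_CLASS_SYMBOL = {"q1": "1", "q2": "2", "q3": "3", "q4": "4",
                 "undetermined": "x"}


def map_to_sequence(classes: EffectClasses | Mapping[int, str],
                    sequence: str, first_resid: int = 1) -> dict:
    """Annotate a one-letter sequence with per-residue effect classes.

    Returns a report with a per-residue table and a two-line text strip:
    the sequence over a class line (``1``–``4`` for the quartile classes,
    ``x`` for undetermined, ``.`` for unscored residues).
    """
    cmap = classes.classes if isinstance(classes, EffectClasses) else dict(classes)
    last = first_resid + len(sequence) - 1
    out_of_range = [r for r in cmap if not (first_resid <= r <= last)]
    if out_of_range:
        raise IndexError(f"class residues outside the sequence: {sorted(out_of_range)}")
    rows = []
    strip = []
    for offset, aa in enumerate(sequence):
        resid = first_resid + offset
        cls = cmap.get(resid)
        rows.append({"resid": resid, "aa": aa, "class": cls})
        strip.append(_CLASS_SYMBOL.get(cls, "."))
    return {
        "first_resid": first_resid,
        "residues": rows,
        "strip": sequence + "\n" + "".join(strip),
    }


def report_json(result: dict) -> str:
    return json.dumps(result, indent=2)
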