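"""qPCR quantification models: standard curves, efficiency, interference.

Amplification efficiency is estimated from the slope of the standard curve
of Ct against log10 template copies,

    E (%) = (10^(-1/slope) - 1) x 100,

so perfect per-cycle doubling gives slope -1/log10(2) ≈ -3.3219 and 100%.
A curve is accepted for quantification only when R² > 0.96 and the
efficiency lies within 85–115%.

Cross-amplification between a primer set and non-target amplicons is
quantified by the *relative efficiency*

    RE = 2^-ΔCt,   ΔCt = Ct(non-target template) - Ct(own target template),

with both templates supplied at equal copy number and assuming 100%
amplification efficiency. A 10-cycle delay corresponds to RE = 2^-10
(0.1% at one decimal); detected combinations at or above that level are
classified as interfering, detected combinations below it as negligible,
and undetected combinations as having no interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RE_THRESHOLD",
    "StandardCurve",
    "InterferenceEntry",
    "InterferenceMatrix",
    "fit_standard_curve",
    "copies_from_mass",
    "relative_efficiency",
    "classify_interference",
    "interference_matrix",
]

#: Classification boundary: RE at a 10-cycle Ct delay.
RE_THRESHOLD = 2.0 ** -10

#: Average mass of one double-stranded base pair, g/mol.
DS_BP_G_PER_MOL = 660.0

AVOGADRO = 6.02214e23

R2_MIN = 0.96
EFFICIENCY_RANGE = (85.0, 115.0)


@dataclass
class StandardCurve:
    points: list[tuple[float, float]]  # (log10 copies, Ct), replicates included
    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float | None
    valid: bool
    diagnostic: str = ""


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Ct on log10 copies over all replicate points.

    Replicates are fitted individually (not as level means) so that replicate
    scatter is reflected in R². Efficiency is defined only for a negative
    slope; a non-negative slope yields ``efficiency_pct=None`` and
    ``valid=False`` with a diagnostic.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if any(not (math.isfinite(x) and math.isfinite(y)) for x, y in pts):
        raise ValueError("all points must be finite")
    levels = {x for x, _ in pts}
    if len(levels) < 2:
        raise ValueError("at least two distinct dilution levels are required")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    if fit.slope >= 0:
        return StandardCurve(
            pts, float(fit.slope), float(fit.intercept), r2, None, False,
            "non-negative slope: Ct must decrease with template copies",
        )
    eff = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    lo, hi = EFFICIENCY_RANGE
    valid = r2 > R2_MIN and lo <= eff <= hi
    diag = "" if valid else (
        f"R²={r2:.3f} (require >{R2_MIN})" if r2 <= R2_MIN
        else f"efficiency {eff:.1f}% outside {lo:g}-{hi:g}%"
    )
    return StandardCurve(pts, float(fit.slope), float(fit.intercept), r2, float(eff), valid, diag)


def copies_from_mass(mass_ng: float, length_bp: float) -> float:
    """Template copy number from dsDNA mass and amplicon length.

    copies = mass[g] / (length_bp x 660 g/mol/bp) x N_A.
    """
    if mass_ng <= 0:
        raise ValueError("mass_ng must be positive")
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    return mass_ng * 1e-9 / (length_bp * DS_BP_G_PER_MOL) * AVOGADRO


def relative_efficiency(ct_observed: float, ct_reference: float) -> float:
    """RE = 2^-(ct_observed - ct_reference); equal copies assumed."""
    if not (math.isfinite(ct_observed) and math.isfinite(ct_reference)):
        raise ValueError("both Ct values must be finite")
    return 2.0 ** -(ct_observed - ct_reference)


def classify_interference(re: float | None) -> str:
    """'none' when undetected, 'negligible' below 2^-10, else 'interfering'."""
    if re is None:
        return "none"
    if re <= 0:
        raise ValueError("relative efficiency must be positive when detected")
    return "negligible" if re < RE_THRESHOLD else "interfering"


@dataclass
class InterferenceEntry:
    primer_set: str
    template_clade: str
    ct_observed: float | None
    ct_reference: float
    relative_efficiency: float | None
    classification: str


@dataclass
class InterferenceMatrix:
    entries: list[InterferenceEntry]
    per_primer_sum: dict[str, float]  # sum of nonspecific REs per primer set
    class_fractions: dict[str, float]  # percent of non-target entries per class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "primer_set": e.primer_set,
                    "template_clade": e.template_clade,
                    "ct_observed": e.ct_observed,
                    "ct_reference": e.ct_reference,
                    "relative_efficiency": e.relative_efficiency,
                    "classification": e.classification,
                }
                for e in self.entries
            ]
        )


def interference_matrix(
    ct_table: pd.DataFrame, own_target: Mapping[str, str]
) -> InterferenceMatrix:
    """Classify every primer-set x non-target-template combination.

    ``ct_table`` needs columns ``primer_set``, ``template_clade``, ``ct``
    (NaN/None = undetected); replicate rows are averaged. ``own_target``
    maps each primer set to its target clade, whose entry supplies the
    reference Ct and is excluded from classification and from the
    per-primer nonspecific RE sums. Class fractions are reported as
    percentages of non-target entries, rounded to one decimal.
    """
    required = {"primer_set", "template_clade", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")
    mean_ct = (
        ct_table.groupby(["primer_set", "template_clade"])["ct"]
        .mean()  # NaN-skipping: undetected replicates don't drag the mean
        .to_dict()
    )
    entries: list[InterferenceEntry] = []
    sums: dict[str, float] = {}
    for primer in sorted(ct_table["primer_set"].unique()):
        if primer not in own_target:
            raise ValueError(f"no target clade declared for primer set {primer!r}")
        ref_key = (primer, own_target[primer])
        ct_ref = mean_ct.get(ref_key)
        if ct_ref is None or not math.isfinite(ct_ref):
            raise ValueError(
                f"missing reference Ct for {primer!r} on its own target "
                f"{own_target[primer]!r}"
            )
        sums[primer] = 0.0
        clades = sorted(
            ct_table.loc[ct_table["primer_set"] == primer, "template_clade"].unique()
        )
        for clade in clades:
            if clade == own_target[primer]:
                continue
            ct_obs = mean_ct[(primer, clade)]
            if ct_obs is None or not math.isfinite(ct_obs):
                entries.append(
                    InterferenceEntry(primer, clade, None, ct_ref, None, "none")
                )
                continue
            re = relative_efficiency(ct_obs, ct_ref)
            sums[primer] += re
            entries.append(
                InterferenceEntry(primer, clade, ct_obs, ct_ref, re, classify_interference(re))
            )
    n = len(entries)
    fractions = {
        cls: round(100.0 * sum(1 for e in entries if e.classification == cls) / n, 1)
        if n else 0.0
        for cls in ("none", "negligible", "interfering")
    }
    return InterferenceMatrix(entries, sums, fractions)
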