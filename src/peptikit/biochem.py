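"""Peptide mass arithmetic and hydrolysate assay calculations.

Masses
------
Monoisotopic and average peptide masses are computed from a pinned residue
constants table (6 decimal places) plus one water; ions are protonated,
m/z(z) = (M + z * m_proton) / z. Pinning the constants makes the printed
2-decimal masses of MS peptide-matching workflows bit-stable across runs.

Assay formulas
--------------
Degree of hydrolysis (DH) from free amino groups measured by the OPA
(o-phthalaldehyde) method against a Gly-Gly-Gly standard:

    DH% = (NH2_tx - NH2_t0) / (NH2_total - NH2_t0) * 100

ACE inhibition from the FAPGG kinetic assay (decrease in absorbance at
345 nm per minute, with and without inhibitor):

    ACE% = (slope_control - slope_sample) / slope_control * 100

DPP-IV inhibition from the Gly-Pro-p-nitroanilide endpoint assay
(absorbance around 405 nm):

    DPPIV% = [1 - (A_sample - A_blank) / (A_pos - A_neg)] * 100

Inhibition efficiency ratio (IER) normalises an inhibition percentage by
the peptide content of the sample, in %/(mg/mL).

Computed inhibitions outside [0, 100] (e.g. a sample slope exceeding the
control) are returned as-is with a warning rather than clamped — clamping
would hide assay problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import validate_sequence

#: Monoisotopic residue (amino-acid minus water) masses, Da, pinned to the
#: standard IUPAC/Unimod values at 6 decimals.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047678, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

#: Average residue masses, Da (standard atomic weights).
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONOISOTOPIC = 18.010565
WATER_AVERAGE = 18.01528
PROTON_MASS = 1.007276


@dataclass(frozen=True)
class MassResult:
    """Masses and charge states of one peptide."""

    peptide: str
    monoisotopic_mass: float
    average_mass: float
    mz_by_charge: dict[int, float]


def peptide_mass(peptide: str, charges: list[int] | None = None) -> MassResult:
    """Monoisotopic/average mass and protonated m/z values of a peptide.

    >>> round(peptide_mass("IDSLEGSVSR").monoisotopic_mass, 2)
    1061.54
    """
    seq = validate_sequence(peptide)
    charges = list(charges or [])
    if any(z < 1 for z in charges):
        raise ValueError("charges must be >= 1")
    mono = sum(MONOISOTOPIC_RESIDUE_MASS[r] for r in seq) + WATER_MONOISOTOPIC
    avg = sum(AVERAGE_RESIDUE_MASS[r] for r in seq) + WATER_AVERAGE
    mz = {z: (mono + z * PROTON_MASS) / z for z in charges}
    return MassResult(peptide=seq, monoisotopic_mass=mono,
                      average_mass=avg, mz_by_charge=mz)


# ---------------------------------------------------------------------------
# Assay readouts and formulas

@dataclass(frozen=True)
class HydrolysisReadout:
    """Free amino-group measurements (Gly-Gly-Gly equivalents, one unit
    system across all three fields)."""

    nh2_tx: float
    nh2_t0: float
    nh2_total: float

    def __post_init__(self) -> None:
        if self.nh2_total <= self.nh2_t0:
            raise ValueError(
                "nh2_total must exceed nh2_t0 (complete acid hydrolysis "
                "frees more amino groups than time zero)")
        if not (self.nh2_t0 <= self.nh2_tx <= self.nh2_total):
            warnings.warn(
                f"nh2_tx={self.nh2_tx} outside the expected range "
                f"[{self.nh2_t0}, {self.nh2_total}]", stacklevel=3)


@dataclass(frozen=True)
class AceReadout:
    """FAPGG assay slopes (absorbance change per minute at 345 nm)."""

    slope_control: float
    slope_sample: float

    def __post_init__(self) -> None:
        if self.slope_control == 0:
            raise ValueError("slope_control must be nonzero")


@dataclass(frozen=True)
class DppivReadout:
    """Gly-Pro-p-nitroanilide assay endpoint absorbances."""

    a_sample: float
    a_blank: float
    a_pos_control: float
    a_neg_control: float

    def __post_init__(self) -> None:
        if self.a_pos_control == self.a_neg_control:
            raise ValueError("positive and negative controls are identical")


def degree_of_hydrolysis(readout: HydrolysisReadout) -> float:
    """Percent of peptide bonds cleaved, from free amino groups."""
    return ((readout.nh2_tx - readout.nh2_t0)
            / (readout.nh2_total - readout.nh2_t0) * 100.0)


def ace_inhibition(readout: AceReadout) -> float:
    """Percent inhibition of ACE from kinetic slopes."""
    value = ((readout.slope_control - readout.slope_sample)
             / readout.slope_control * 100.0)
    _warn_out_of_range(value, "ACE inhibition")
    return value


def dppiv_inhibition(readout: DppivReadout) -> float:
    """Percent inhibition of DPP-IV from endpoint absorbances."""
    value = (1.0 - (readout.a_sample - readout.a_blank)
             / (readout.a_pos_control - readout.a_neg_control)) * 100.0
    _warn_out_of_range(value, "DPP-IV inhibition")
    return value


def _warn_out_of_range(value: float, label: str) -> None:
    if not (0.0 <= value <= 100.0):
        warnings.warn(f"{label} of {value:.2f}% is outside [0, 100]; "
                      "check the readouts", stacklevel=3)


def inhibition_efficiency_ratio(inhibition_percent: float,
                                peptide_content: float) -> float:
    """Inhibition percentage per unit peptide content, %/(mg/mL)."""
    if peptide_content <= 0:
        raise ValueError("peptide_content must be positive")
    return inhibition_percent / peptide_content


@dataclass(frozen=True)
class OpaQuantification:
    """Result of standard-curve quantification."""

    concentrations: list[float]
    slope: float
    intercept: float
    r_squared: float
    extrapolated: list[bool] = field(default_factory=list)


def opa_quantify(standards: list[tuple[float, float]],
                 samples: list[float]) -> OpaQuantification:
    """Quantify samples through a linear Gly-Gly-Gly standard curve.

    Ordinary least squares of absorbance on concentration over the
    standards; sample absorbances are inverted through the fitted line.
    Samples outside the standard absorbance range are still returned but
    flagged and warned as extrapolations.

    Raises
    ------
    ValueError
        With fewer than two distinct standard concentrations (singular
        fit), or a zero fitted slope.
    """
    conc = np.asarray([c for c, _ in standards], dtype=float)
    absb = np.asarray([a for _, a in standards], dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least two distinct standard concentrations")
    fit = stats.linregress(conc, absb)
    if fit.slope == 0:
        raise ValueError("standard curve has zero slope")
    lo, hi = float(absb.min()), float(absb.max())
    out, extrapolated = [], []
    for a in samples:
        out.append((a - fit.intercept) / fit.slope)
        extra = not (lo <= a <= hi)
        extrapolated.append(extra)
        if extra:
            warnings.warn(
                f"sample absorbance {a} outside the standard range "
                f"[{lo}, {hi}]; extrapolating", stacklevel=2)
    return OpaQuantification(
        concentrations=out, slope=float(fit.slope),
        intercept=float(fit.intercept), r_squared=float(fit.rvalue ** 2),
        extrapolated=extrapolated)
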