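"""Published reference values for the Trp-(GS)n-Dbo peptide series.

Experimental mean first-contact times come from time-resolved FRET
quenching measurements in heavy water; the simulated values and optimized
sink radii are the benchmark results this analysis reproduces
arithmetically (viscosity correction, error propagation, percent
deviation). Viscosities: experimental D2O at ambient conditions versus
the SPC water model from periodic-perturbation NEMD.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ETA_D2O_MPAS",
    "ETA_SPC_MPAS",
    "SPC_MEAN_INVERSE_VISCOSITY",
    "KineticReference",
    "KINETIC_REFERENCE",
]

#: Experimental shear viscosity of D2O at ambient conditions (mPa s).
ETA_D2O_MPAS = 1.10

#: Shear viscosity of SPC water from NEMD (mPa s).
ETA_SPC_MPAS = 0.445

#: Mean inverse viscosity of SPC water from NEMD (m s kg^-1).
SPC_MEAN_INVERSE_VISCOSITY = 2245.61


@dataclass(frozen=True)
class KineticReference:
    """One peptide's simulated and experimental contact-formation times."""

    peptide: str
    r_opt: float      # optimized sink radius, nm
    T_md: float       # uncorrected simulated MFCT, ns
    sigma_md: float   # its statistical uncertainty, ns
    T_exp: float      # experimental MFCT, ns
    sigma_exp: float  # experimental uncertainty, ns


#: Benchmark kinetic table for the Gly/Ser peptide series.
KINETIC_REFERENCE: tuple[KineticReference, ...] = (
    KineticReference("trpDbo", 0.497, 8.64, 0.84, 22.0, 0.7),
    KineticReference("(GS)", 0.441, 5.11, 0.48, 13.0, 0.4),
    KineticReference("(GS)2", 0.441, 7.12, 0.86, 17.0, 0.5),
    KineticReference("(GS)3", 0.441, 8.95, 1.34, 24.0, 0.7),
)
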