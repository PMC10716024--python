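"""Physical constants and canonical defaults shared across the package.

Mass photometry reports one dimensionless ratiometric contrast value per
landing event.  By the sign convention used throughout this package a
mass-binding event has *negative* contrast, and more mass (or more bases)
means a more negative value.
"""

from __future__ import annotations

#: kDa of encapsidated single-stranded DNA per base (chain-residue mass).
PER_BASE_MASS_KDA: float = 0.309

#: The mass-to-bases conversion factor: 309 kDa corresponds to 1,000 bases.
KDA_PER_1000_BASES: float = 309.0

#: Bases per base pair when converting double-stranded ladder lengths.
BASES_PER_BP: float = 2.0

#: Contrast magnitude of a released ~4,658-base ssDNA genome (anchor point).
RELEASED_GENOME_CONTRAST: float = 0.041
RELEASED_GENOME_BASES: float = 4658.0

#: Contrast per base of free linear ssDNA, anchored to the released-genome peak.
ALPHA_FREE_SS: float = RELEASED_GENOME_CONTRAST / RELEASED_GENOME_BASES  # ~8.80e-6

#: Contrast per kDa for protein shells (capsids, protein calibrants, HMW
#: standard).  Chosen so that one encapsidated base contributes the same
#: contrast through the mass route (alpha_capsid * 0.309 kDa) as one free
#: ssDNA base, which places the 3,700 kDa empty capsid near -0.105 contrast,
#: inside the -0.1 .. -0.2 band where intact AAVs are observed.
ALPHA_CAPSID: float = ALPHA_FREE_SS / PER_BASE_MASS_KDA  # ~2.848e-5

#: Empty AAV capsid mass (60-mer shell, no genome), kDa.
EMPTY_CAPSID_MASS_KDA: float = 3700.0

#: High-molecular-weight reference standard mass, kDa.
HMW_STANDARD_MASS_KDA: float = 3643.0

#: Chain-residue masses (Da) of the four deoxynucleotide monophosphates,
#: i.e. the free acid minus one water lost on phosphodiester bond formation.
DNMP_RESIDUE_MASS_DA: dict[str, float] = {
    "dAMP": 313.21,
    "dCMP": 289.18,
    "dGMP": 329.21,
    "dTMP": 304.20,
}

#: Default histogram/KDE bandwidths, in declared calibrated units.
BANDWIDTH_INTACT_KDA: float = 40.0
BANDWIDTH_INTACT_BASES: float = 120.0
BANDWIDTH_RELEASED_BASES: float = 50.0

#: Expected genome lengths (bases) of the five filled AAV study samples.
STUDY_GENOME_LENGTHS: dict[str, float] = {
    "AAV2": 3793.0,
    "AAV3": 4142.0,
    "AAV4": 4504.0,
    "AAV5": 4596.0,
    "AAV6": 4658.0,
}
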