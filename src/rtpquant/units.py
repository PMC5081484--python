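"""Unit conversions used for absolute quantification.

The single place where fmol of a spiked standard is turned into molecule
counts: copies = (light/heavy ratio) x fmol x FMOL_TO_MOL x AVOGADRO / cells.
Every module converting between amounts and copies imports these constants so
the units audit lives here and nowhere else.
"""

AVOGADRO = 6.02214076e23  # molecules per mol
FMOL_TO_MOL = 1e-15

MOLECULES_PER_FMOL = AVOGADRO * FMOL_TO_MOL


def fmol_to_molecules(fmol: float) -> float:
    """Molecule count in ``fmol`` femtomoles."""
    return fmol * MOLECULES_PER_FMOL


def molecules_to_fmol(molecules: float) -> float:
    """Femtomoles corresponding to a molecule count."""
    return molecules / MOLECULES_PER_FMOL
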