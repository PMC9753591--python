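"""Physical constants and unit conversions (single source of truth)."""

#: Bohr radius in Angstrom; XYZ files are Angstrom, everything internal is bohr.
BOHR_TO_ANGSTROM = 0.52917721092
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: Hartree to kcal/mol, used for all reported interaction energies.
HARTREE_TO_KCAL = 627.509474

#: Atomic unit of magnetic flux density, in tesla (B0 = hbar e^-1 a0^-2).
B0_IN_TESLA = 2.3505e5

#: Element symbols -> nuclear charge, for the species this package handles.
ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17,
    "Ar": 18,
}
Z_TO_ELEMENT = {z: s for s, z in ELEMENT_Z.items()}

#: Covalent radii (bohr) for fragment auto-detection (Cordero et al. values, converted).
COVALENT_RADIUS = {
    "H": 0.31 * ANGSTROM_TO_BOHR,
    "He": 0.28 * ANGSTROM_TO_BOHR,
    "Li": 1.28 * ANGSTROM_TO_BOHR,
    "Be": 0.96 * ANGSTROM_TO_BOHR,
    "B": 0.84 * ANGSTROM_TO_BOHR,
    "C": 0.76 * ANGSTROM_TO_BOHR,
    "N": 0.71 * ANGSTROM_TO_BOHR,
    "O": 0.66 * ANGSTROM_TO_BOHR,
    "F": 0.57 * ANGSTROM_TO_BOHR,
    "Ne": 0.58 * ANGSTROM_TO_BOHR,
    "Na": 1.66 * ANGSTROM_TO_BOHR,
    "Mg": 1.41 * ANGSTROM_TO_BOHR,
    "P": 1.07 * ANGSTROM_TO_BOHR,
    "S": 1.05 * ANGSTROM_TO_BOHR,
    "Cl": 1.02 * ANGSTROM_TO_BOHR,
    "Ar": 1.06 * ANGSTROM_TO_BOHR,
}

#: Rigid water geometry used by the synthetic cluster generator: the TIP3P
#: internal geometry (gas-phase experimental r_OH and HOH angle), since the
#: cluster snapshots this generator emulates come from TIP3P dynamics.
WATER_R_OH_ANGSTROM = 0.9572
WATER_THETA_HOH_DEG = 104.52
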