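"""Unit conversions.

Internal units are Hartree atomic units everywhere (lengths in bohr, energies
in hartree, dipoles in e*bohr).  Angstrom and kcal/mol appear only at I/O
boundaries; Debye only when reporting dipole magnitudes.
"""

BOHR_PER_ANGSTROM = 1.8897261254578281
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

HARTREE_TO_KCALMOL = 627.509
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL

DEBYE_PER_EBOHR = 2.541746473


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR
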