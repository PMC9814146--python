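"""Physical constants and unit conversions pinned in one place.

All scattering is computed in Hartree atomic units internally; the public
interfaces speak eV, degrees and Angstrom.
"""

#: Hartree energy in eV (CODATA).
HARTREE_EV = 27.211386

#: One Angstrom expressed in Bohr radii.
BOHR_PER_ANGSTROM = 1.8897261

#: Thomas-Fermi screening prefactor: alpha_Z = Z**(1/3) / TF_SCREENING_B (bohr^-1).
TF_SCREENING_B = 0.88534
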