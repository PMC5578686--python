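"""Unit conventions and conversion factors.

Internal mechanical units are Å (length), pN (force), pN·Å (energy) and
pN/Å² (stress).  Interaction energies are exchanged with users in kcal/mol,
stresses in reports optionally in MPa.
"""

#: 1 kcal/mol/Å expressed in pN (consistent with 12 kcal/mol/Å² = ~840 pN/Å).
PN_PER_KCAL_MOL_A = 69.48

#: 1 pN/Å² expressed in MPa.
MPA_PER_PN_A2 = 100.0


def kcalmol_per_a_to_pn(f: float) -> float:
    """Convert a force from kcal/mol/Å to pN."""
    return f * PN_PER_KCAL_MOL_A


def pn_to_kcalmol_per_a(f: float) -> float:
    """Convert a force from pN to kcal/mol/Å."""
    return f / PN_PER_KCAL_MOL_A


def pn_a2_to_mpa(s: float) -> float:
    """Convert a stress from pN/Å² to MPa."""
    return s * MPA_PER_PN_A2


def mpa_to_pn_a2(s: float) -> float:
    """Convert a stress from MPa to pN/Å²."""
    return s / MPA_PER_PN_A2
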