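"""Unit conventions and centralized conversions.

The package exchanges data with users in microscopy/biophysics units and keeps
one consistent internal system:

* lengths in micrometres (um)
* moduli and stresses in kilopascal (kPa)
* forces in nanonewton (nN)
* energies in picojoule (pJ)
* times in minutes

These are mutually consistent for mechanics: 1 kPa = 1 nN/um^2, so a stress in
kPa times an area in um^2 is a force in nN, and a force in nN times a length
in um is an energy in femtojoule (1e-3 pJ).  All conversion factors live here
and nowhere else.
"""

# force x length
FJ_PER_NN_UM = 1.0          # 1 nN*um = 1 fJ
PJ_PER_NN_UM = 1e-3         # 1 nN*um = 1e-3 pJ

# stress
KPA_PER_PA = 1e-3
PA_PER_KPA = 1e3
NN_PER_UM2_PER_KPA = 1.0    # 1 kPa = 1 nN/um^2 (exact)

# stiffness
NN_PER_UM_PER_N_PER_M = 1e3  # 1 N/m = 1000 nN/um (exact)

# energy
J_PER_PJ = 1e-12
PJ_PER_J = 1e12


def kpa_to_pa(x: float) -> float:
    return x * PA_PER_KPA


def pa_to_kpa(x: float) -> float:
    return x * KPA_PER_PA


def n_per_m_to_nn_per_um(x: float) -> float:
    return x * NN_PER_UM_PER_N_PER_M


def nn_um_to_pj(x: float) -> float:
    return x * PJ_PER_NN_UM


def pj_to_joule(x: float) -> float:
    return x * J_PER_PJ
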