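"""Physical constants and unit conversions.

Internal unit system: length Å, time fs, energy eV, mass amu.
In these units kinetic energy is ``0.5 * m[amu] * v[Å/fs]**2 * KE_CONV`` eV.
"""

# 1 amu * (Å/fs)^2 expressed in eV:
#   1.66053906660e-27 kg * (1e-10 m / 1e-15 s)^2 / 1.602176634e-19 J/eV
KE_CONV = 1.66053906660e-27 * 1.0e10 / 1.602176634e-19  # 103.642696...

# Boltzmann constant, eV/K (CODATA 2018)
K_B = 8.617333262e-5

# Acceleration: a[Å/fs^2] = F[eV/Å] / (m[amu] * KE_CONV)
ACC_CONV = 1.0 / KE_CONV

FS_PER_PS = 1000.0
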