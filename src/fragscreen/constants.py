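"""Physical constants and default thermodynamic conditions.

All energies in kcal/mol, lengths in Å, temperatures in K, concentrations
in mol/L unless noted otherwise.
"""

#: Boltzmann constant, kcal/(mol·K).
K_B = 0.0019872

#: Default simulation temperature for probe sampling and map construction, K.
DEFAULT_TEMPERATURE = 298.0

#: Default temperature of the docking Metropolis stage, K.
DOCKING_TEMPERATURE = 300.0

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Conversion: particles per Å^3 for a 1 mol/L solution.
#: 1 Å^3 = 1e-27 L, so c [mol/L] * N_A * 1e-27 = particles/Å^3.
PARTICLES_PER_A3_PER_MOLAR = N_AVOGADRO * 1e-27

#: Default bulk probe concentration targeted by the GCMC stage, mol/L.
DEFAULT_CONCENTRATION = 0.25

#: Default grid free energy assigned to unsampled voxels, kcal/mol.
DEFAULT_GFE_CAP = 3.0
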