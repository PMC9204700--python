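"""Reference constants for sequence-based intrinsic amide exchange rates.

Provenance
----------
Transcribed from the poly-DL-alanine reference rates and side-chain
inductive/steric factors of Bai, Milne, Mayne & Englander, *Proteins*
17:75-86 (1993), with the Connelly et al. (1993) update for acid-side
factors, as propagated by the Englander-lab intrinsic-rate spreadsheet
lineage (hx2.med.upenn.edu).  Version: table v1 (2026-09).

Conventions
-----------
* ``LAMBDA``/``RHO`` are log10 factors: lambda is the contribution of a
  residue's side chain to its *own* amide; rho is its contribution to
  the amide of the *following* residue.
* Columns per residue: (acid lambda, acid rho, base lambda, base rho).
* Reference rates are for exchange into D2O at 293 K, in M^-1 min^-1
  (acid/base) and min^-1 (water).
* Asp, Glu and His factors depend on side-chain ionization; protonated
  and deprotonated variants are blended by the Henderson-Hasselbalch
  fraction at the working pD using the D2O side-chain pKa values below.
"""

# log10 reference rates, poly-DL-alanine, 293 K
LOG_KA_REF = 2.04     # acid-catalyzed, M^-1 min^-1
LOG_KB_REF = 10.36    # base-catalyzed, M^-1 min^-1
LOG_KW_REF = -1.5     # water-catalyzed, min^-1

T_REF = 293.0         # K
PKD_D2O = 15.05       # autoionization of D2O at 293 K

# Arrhenius activation energies, kcal/mol
EA_ACID = 14.0
EA_BASE = 17.0
EA_WATER = 19.0
R_GAS = 1.987e-3      # kcal mol^-1 K^-1

# Side-chain pKa values in D2O used for ionization blending
SIDECHAIN_PKA = {"D": 4.48, "E": 4.93, "H": 7.42}

# (acid lambda, acid rho, base lambda, base rho) per residue.
# Ionizable residues appear as charged / neutral variants.
FACTORS = {
    "A":  (0.00,  0.00,  0.00,  0.00),
    "R":  (-0.59, -0.32,  0.08,  0.22),
    "N":  (-0.58, -0.13,  0.49,  0.32),
    "D-": (0.90,  0.58, -0.30, -0.18),   # aspartate (deprotonated)
    "D0": (-0.90, -0.12,  0.69,  0.60),  # aspartic acid (protonated)
    "C":  (-0.54, -0.46,  0.62,  0.55),
    "E-": (-0.90,  0.31, -0.51, -0.15),  # glutamate (deprotonated)
    "E0": (-0.60, -0.27,  0.24,  0.39),  # glutamic acid (protonated)
    "Q":  (-0.47, -0.27,  0.06,  0.20),
    "G":  (-0.22,  0.22,  0.27,  0.17),
    "H+": (-0.80, -0.51,  0.80,  0.83),  # histidinium
    "H0": (0.00,  0.00, -0.10,  0.14),   # neutral histidine
    "I":  (-0.91, -0.59, -0.73, -0.23),
    "L":  (-0.57, -0.13, -0.58, -0.21),
    "K":  (-0.56, -0.29, -0.04,  0.12),
    "M":  (-0.64, -0.28, -0.01,  0.11),
    "F":  (-0.52, -0.43, -0.24,  0.06),
    "P":  (0.00, -0.19,  0.00, -0.24),   # trans proline (rho only; no amide NH)
    "S":  (-0.44, -0.39,  0.37,  0.30),
    "T":  (-0.79, -0.47, -0.07,  0.20),
    "W":  (-0.40, -0.44, -0.41, -0.11),
    "Y":  (-0.41, -0.37, -0.27,  0.05),
    "V":  (-0.74, -0.30, -0.70, -0.14),
}

# Chain-terminus contributions (log10).  The protonated N-terminal amine
# acts as a rho factor on the second residue's amide; the deprotonated
# C-terminal carboxylate as a lambda factor on the last residue's amide.
NTERM_RHO_ACID = -1.32
NTERM_RHO_BASE = 1.62
CTERM_LAMBDA_ACID = 0.96
CTERM_LAMBDA_BASE = -1.80
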