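"""Physical constants and model defaults (kcal/mol, Å, radians, reduced time).

Energy/temperature bridging uses k_B = 0.0019872 kcal/(mol·K), so
k_B·T = 0.596 kcal/mol at 300 K. Time is measured in the reduced Langevin
unit tau_L with a uniform bead mass m = 1; friction and timestep defaults
are expressed in these reduced units.
"""

# Boltzmann constant, kcal/(mol*K)
KB = 0.0019872

# 1 kcal/(mol*Angstrom) expressed in piconewton
KCAL_PER_MOL_ANG_IN_PN = 69.48

# Bonded force field constants
K_BOND = 20.0       # kcal/(mol*A^2)
K_ANGLE = 20.0      # kcal/(mol*rad^2)
K_DIHEDRAL_1 = 1.0  # kcal/mol
K_DIHEDRAL_3 = 0.5  # kcal/mol

# Nonbonded constants
CONTACT_CUTOFF = 8.0        # A, native-contact definition
MIN_SEQ_SEPARATION = 3      # |i-j| > 3 within a chain
EPSILON_HIGH = 1.8          # kcal/mol, upper neck + motor-track interface
EPSILON_LOW = 1.0           # kcal/mol, generic contacts
EPSILON_ASYMMETRIC = 1.0    # kcal/mol, default depth of A-basin contacts
REPULSION_SIGMA = 4.0       # A
REPULSION_EPSILON = 1.0     # kcal/mol

# Ncd-specific residue boundaries (author numbering)
NECK_THRESHOLD = 331            # both residues < 331 -> epsilon_high
JUNCTION_STALK_RANGE = (341, 345)
JUNCTION_HEAD_RANGE = (346, 351)
HEAD_STALK_BOUNDARY = 346       # stalk/neck < 346 <= motor head

# Langevin defaults (reduced units)
TEMPERATURE = 300.0  # K
FRICTION = 0.05      # m/tau_L
TIMESTEP = 0.0025    # tau_L
MASS = 1.0

# Geometry
CA_SPACING = 3.8     # A, consecutive C-alpha distance
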