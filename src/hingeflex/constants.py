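"""Physical constants and coarse-grained unit conventions.

Units used throughout the package:

* length     -- Angstrom (A)
* energy     -- kcal/mol
* charge     -- elementary charges (e)
* time, mass -- dimensionless coarse-grained units; simulation output is
  reported per integration step, so no mapping to seconds is assumed.
"""

from scipy import constants as _si

#: Boltzmann constant, kcal/(mol K).
KB_KCAL = _si.k * _si.N_A / (_si.calorie * 1000.0)  # ~0.0019872

#: Coulomb prefactor e^2/(4 pi eps0) in kcal A / (mol e^2).
COULOMB_KCAL = 332.0637

#: Default solvent dielectric constant (dimensionless).
DEFAULT_DIELECTRIC = 78.0

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Default uniform bead mass, CG mass units (dimensionless; sets the time
#: scale together with the friction coefficient -- see docs/methods.md).
DEFAULT_MASS = 10.0

#: Langevin friction coefficient, 1/CG-time.
DEFAULT_FRICTION = 0.843

#: Langevin time step, CG time units.
DEFAULT_TIMESTEP = 0.2

# --- default force-field parameters -------------------------------------

#: Harmonic bond coefficient k_b in U = k_b (r - r0)^2, kcal/(mol A^2).
#: Chosen so the bond period stays well resolved at the default timestep
#: and bead mass (dt * omega ~ 0.6).
DEFAULT_BOND_K = 50.0
#: Harmonic angle coefficient in U = k_a (theta - theta0)^2, kcal/(mol rad^2).
DEFAULT_ANGLE_K = 20.0
#: Periodic dihedral coefficient in U = k_d (1 - cos(phi - phi0)), kcal/mol.
DEFAULT_DIHEDRAL_K = 1.0
#: Go-contact well depth, kcal/mol.
DEFAULT_CONTACT_EPS = 1.0
#: Excluded-volume prefactor, kcal/mol.
DEFAULT_EXCLUDED_EPS = 0.6
#: Native-contact distance cutoff for proteins, A (Calpha-Calpha).
DEFAULT_CONTACT_CUTOFF = 6.5
#: Debye-Hueckel cutoff in units of the Debye length.
DEFAULT_DH_CUTOFF_FACTOR = 5.0

#: Default bead radii by bead class, A (CA radius chosen so the CA-CA
#: excluded-volume contact distance is ~4 A, below the Go-contact range).
DEFAULT_RADIUS_CA = 2.0
DEFAULT_RADIUS_PHOSPHATE = 2.0
DEFAULT_RADIUS_SUGAR = 2.4
DEFAULT_RADIUS_BASE = 2.2

#: Default phosphate charge after counterion condensation, e.
DEFAULT_PHOSPHATE_CHARGE = -0.6

# --- ideal B-DNA helix (configurable via build_bdna_duplex) --------------

BDNA_RISE = 3.38          # A per base pair
BDNA_TWIST_DEG = 34.3     # degrees per base pair
BDNA_RADIUS_PHOSPHATE = 8.9
BDNA_RADIUS_SUGAR = 6.9
BDNA_RADIUS_BASE = 2.0
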