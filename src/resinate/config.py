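"""Shared physical constants and package-wide defaults.

Defaults mirror the acquisition conditions of the characterization study the
package models: a 9.4 T spectrometer spinning at 9800 Hz, glycine carbonyl
referencing at 176.03 ppm, and cross-polarization contact times spanning
20-50,000 us.
"""

#: Glycine carbonyl 13C shift used for chemical-shift referencing (ppm).
GLYCINE_CO_PPM = 176.03

#: 13C gyromagnetic ratio over 2*pi (MHz / T). Used to derive the Larmor
#: frequency when only the field strength is known.
GAMMA_13C_MHZ_PER_T = 10.7084

#: Default static field (T) and the matching 13C Larmor frequency (MHz).
DEFAULT_FIELD_T = 9.4
DEFAULT_LARMOR_MHZ = 100.61  # instrument-reported; ~GAMMA_13C * 9.4 T

#: Magic-angle spinning rate (Hz) chosen so sidebands clear the isotropic lines.
DEFAULT_SPIN_RATE_HZ = 9800.0

#: Recycle delay between scans (s).
DEFAULT_RECYCLE_DELAY_S = 20.0

#: Cross-polarization contact-time range (us) of the variable-contact-time
#: experiment, and the default grid size.
CONTACT_TIME_RANGE_US = (20.0, 50_000.0)
DEFAULT_N_CONTACT_TIMES = 24

#: Default Lorentzian linewidths (Hz, FWHM) used by the synthetic generator:
#: narrow crystalline drug lines, broad amorphous resin envelope.
DRUG_LINEWIDTH_HZ = 60.0
RESIN_LINEWIDTH_HZ = 300.0

#: Integration window used when synthesizing truncated lineshapes:
#: center +/- this many linewidths.
LINESHAPE_TRUNCATION_LW = 5.0

#: Nearest-center gate (ppm) for joining picked peaks to an assignment table.
ASSIGNMENT_MATCH_GATE_PPM = 0.5

#: Mixing-state classifier thresholds (dimensionless ratios): a complex must
#: show drug T1rho(H) reduced at least `reduction_factor`-fold relative to the
#: pure drug and converged to within `convergence_factor` of the resin's.
REDUCTION_FACTOR = 2.0
CONVERGENCE_FACTOR = 5.0

#: Bounds for the CP-dynamics fit, internal microsecond time base.
TCH_BOUNDS_US = (1.0, 1e5)
T1RHO_BOUNDS_MS = (0.1, 1e4)
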