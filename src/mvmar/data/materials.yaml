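# Linear attenuation coefficients mu(E) in 1/mm on a shared energy grid.
# Values assembled from standard published mass-attenuation tables
# (mu/rho times nominal density), rounded; the package's tests depend only on
# orderings and ratios, not on the exact entries.  "amalgam" is a dense
# silver/mercury-like dental alloy; "lung" is low-density lung-equivalent
# foam (~0.3 g/cm3); "soft_tissue" is slightly denser than water (~+40 HU).
energies_kev: [40, 50, 60, 80, 100, 120, 200, 500, 1000, 1500]
materials:
  air:
    mu_per_mm: [3.22e-5, 2.72e-5, 2.47e-5, 2.20e-5, 2.05e-5, 1.94e-5, 1.64e-5, 1.16e-5, 8.48e-6, 6.90e-6]
  water:
    mu_per_mm: [0.02683, 0.02269, 0.02059, 0.01837, 0.01707, 0.01614, 0.01370, 0.00969, 0.00707, 0.00575]
  soft_tissue:
    mu_per_mm: [0.02790, 0.02360, 0.02141, 0.01910, 0.01775, 0.01679, 0.01425, 0.01008, 0.00735, 0.00598]
  lung:
    mu_per_mm: [0.00805, 0.00681, 0.00618, 0.00551, 0.00512, 0.00484, 0.00411, 0.00291, 0.00212, 0.00173]
  bone:
    mu_per_mm: [0.12780, 0.08140, 0.06040, 0.04280, 0.03560, 0.03150, 0.02510, 0.01790, 0.01260, 0.01020]
  bone_spongy:
    mu_per_mm: [0.07227, 0.04911, 0.03851, 0.02936, 0.02541, 0.02305, 0.01883, 0.01338, 0.00956, 0.00775]
  titanium:
    mu_per_mm: [0.25800, 0.16100, 0.11500, 0.07440, 0.05930, 0.05100, 0.04020, 0.03190, 0.02660, 0.02240]
  steel:
    mu_per_mm: [2.85600, 1.54100, 0.94800, 0.46800, 0.29300, 0.22000, 0.11500, 0.06620, 0.04720, 0.03840]
  amalgam:
    mu_per_mm: [3.00000, 1.70000, 1.10000, 0.55000, 0.36000, 0.27000, 0.13000, 0.05500, 0.03500, 0.02800]
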