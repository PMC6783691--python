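# Cytosolic Ca2+ buffering and diffusion parameters.
#
# All kinetic defaults live here; nothing is hard-coded in the solver.
# Values are standard rat-ventricular cytosol parameters from the calcium
# spark modeling literature (Smith et al. 1998, Biophys J; Izu et al. 2001,
# Biophys J; Picht et al. 2011).
#
# Units: concentrations uM, k_on 1/(uM ms), k_off 1/ms, diffusivities um^2/ms.
#
# The fluorescent indicator (a fluo-family Ca2+ dye) has `total: null`:
# its total concentration is derived at initialization from the resting
# bound level FCa = 2.08 uM and the resting free Ca2+ of 0.1 uM, so the
# resting fluorescence matches the imaging background exactly.

d_ca: 0.22   # effective free Ca2+ diffusivity

buffers:
  fluo:
    total: null          # derived from fca_rest (see above)
    k_on: 0.08
    k_off: 0.09          # Kd = 1.125 uM
    d_free: 0.042
    d_bound: 0.042
    mobile: true
  calmodulin:
    total: 24.0
    k_on: 0.1
    k_off: 0.038         # Kd = 0.38 uM
    d_free: 0.025
    d_bound: 0.025
    mobile: true
  atp:
    total: 455.0
    k_on: 0.225
    k_off: 45.0          # Kd = 200 uM
    d_free: 0.14
    d_bound: 0.14
    mobile: true
  troponin_c:
    total: 70.0
    k_on: 0.039
    k_off: 0.02          # Kd = 0.51 uM
    d_free: 0.0          # immobile
    d_bound: 0.0
    mobile: false
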