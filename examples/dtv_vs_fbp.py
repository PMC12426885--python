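"""The headline experiment: three reconstructions of one 9 s dynamic scan.

Simulates a long reference scan of the dry skewer slice and a fast
continuous scan (180 x 50 ms at 20 deg/s) of a partially water-filled
state, then reconstructs the *same* dynamic data three ways:

  conventional      FBP of the log attenuation data
  analytical PR     FBP of the phase-retrieved data
  regularised PR    directional-TV PDHG against the dry reference

and prints the water-vs-air CNR of each chain plus the edge widths that
show where the structure prior helps and where it cannot.
"""

from dtvtomo.metrics import FWHM_PER_SIGMA, cnr, erf_fwhm
from dtvtomo.scenes import dynamic_slice_scene

scene = dynamic_slice_scene(seed=1)

print("water-vs-air CNR of the three chains (same raw dynamic data):")
for name, vol in [("conventional (attenuation FBP)", scene.recon_conventional),
                  ("analytical phase-retrieved FBP", scene.recon_analytical),
                  ("dTV-regularised phase-retrieved", scene.recon_regularised)]:
    water, air = scene.cnr_samples(vol)
    print(f"  {name:34s} CNR = {cnr(water, air):5.2f}")

system_fwhm = FWHM_PER_SIGMA * scene.geom.system_sigma_um
static = erf_fwhm(scene.static_edge_profile(scene.recon_regularised))
waterline = erf_fwhm(scene.waterline_profile(scene.recon_regularised))
print()
print(f"system resolution (FWHM)             : {system_fwhm:6.1f} um")
print(f"prior-aligned wood edge (dTV)        : {static:6.1f} um")
print(f"prior-absent waterline edge (dTV)    : {waterline:6.1f} um")
print()
print("Edges the reference volume knows about stay sharp under dTV; the")
print("moving water level, absent from the reference, pays the full TV")
print("penalty and blurs -- the price of regularising with a static prior.")
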