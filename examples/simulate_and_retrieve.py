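"""Simulate a phase-contrast scan and undo it with Paganin retrieval.

Builds a small dry vessel phantom, simulates one noisy projection set
with near-field propagation (TIE), retrieves the phase of each
projection with the single-distance filter, and reports how well the
retrieved phase matches the projected ground truth.
"""

import numpy as np

from dtvtomo.geometry import SystemGeometry
from dtvtomo.phantom import build_phantom, optics_maps
from dtvtomo.retrieval import retrieve_phase
from dtvtomo.simulate import ScanProtocol, contact_image, simulate_scan

geom = SystemGeometry(R1=320, R2=140, sigma_s=70, sigma_d=30,
                      pixel_pitch=15, lambda_eff=6.53e-11, delta_beta=1000.0)
vox = geom.effective_pixel_um
phantom = build_phantom(n_vessels=6, grid_shape=(96, 96), voxel_size=vox, seed=3)

protocol = ScanProtocol(mode="static", n_projections=30, angular_range=180.0,
                        exposure=1.0, photons_per_pixel=50_000, seed=3)
scan = simulate_scan(phantom, protocol, geom)
print(f"simulated {scan.n_projections} projections, "
      f"{scan.intensity.shape[-1]} detector pixels of {vox:.1f} um")

# retrieve each corrected projection and compare to the true phase
delta, beta = optics_maps(phantom)
corrected = scan.corrected()
errors = []
for i in range(scan.n_projections):
    _, phi_true = contact_image(delta, beta, scan.angles_deg[i], geom, vox)
    phi_ret = retrieve_phase(corrected[i], geom, spacing=vox)
    err = (np.sqrt(np.mean((phi_ret - (-phi_true)) ** 2))
           / np.sqrt(np.mean(phi_true ** 2)))
    errors.append(err)
print(f"relative RMS phase error per projection: "
      f"median {np.median(errors):.3f}, worst {np.max(errors):.3f}")
print()
print("The error is noise- and blur-limited: the Fourier filter inverts the")
print("propagation exactly for a weak homogeneous object, so what remains is")
print("photon noise smoothed by the retrieval low-pass plus the system PSF.")
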