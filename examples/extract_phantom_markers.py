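"""Extract the 26-marker panel from a synthetic thorax phantom.

Builds a digital thorax with a tracer-avid myocardial wall (SUV 12), blurs
it with an 8 mm FWHM point-spread function, and runs the full marker
extraction.  Prints the myocardial and LV markers next to the noiseless
ground truth so the effect of SPECT resolution on each marker family is
visible: SUVmax drops under blur (peak smearing), while amyloid activity —
a regional uptake *integral* over the 10-mm-expanded mask — is far more
stable because spill-out stays inside the expanded region.
"""

import dpdquant as dq

spec = dq.default_thorax(psf_fwhm_mm=8.0, noise=dq.NoiseModel("gaussian", 0.1), seed=1)
volume, structures, truth = dq.generate_phantom(spec)
panel = dq.extract_panel(volume, structures)

print(f"{'marker':32s} {'measured':>10s} {'truth':>10s}")
for name in dq.MARKER_NAMES:
    if name.endswith(("_MYOCARDIUM", "_LV")) or name == "RETENTION_INDEX":
        print(f"{name:32s} {panel[name]:10.2f} {truth.panel[name]:10.2f}")

print(
    "\nSUV metrics are in SUV, amyloid activity in SUV*mL, affected volume in mL.\n"
    "Measured values differ from truth only through the simulated 8 mm PSF and\n"
    "noise; rerun with psf_fwhm_mm=0.0 and NoiseModel() to reproduce truth exactly."
)
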