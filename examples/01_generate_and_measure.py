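"""Generate one synthetic CCTA phantom and measure noise at the LM ostium.

Builds a contrast-filled aortic-root phantom with a known injected noise SD,
locates the left-main contact point from the ground-truth mask, assembles the
seven-slice measurement zone, and prints attenuation (mean HU), noise (SD of
HU) and SNR.  The measured values should sit within sampling error of the
injected ground truth (attenuation 500 HU, noise 35 HU -> SNR ~14.3).
"""

import noisekit as nk
from noisekit.phantom import PhantomSpec

phantom = nk.generate_phantom(PhantomSpec(aorta_attenuation=500.0,
                                          noise_sd=35.0, seed=42))
contact, center = nk.find_contact_point(phantom.labels)
zone = nk.build_zone(phantom.labels)
m = nk.measure(phantom.volume, zone)

print(f"contact point: {int(contact.sum())} voxels, centre slice {center}")
print(f"zone: {zone.n_slices} slices, {zone.n_voxels} voxels")
print(f"attenuation: {m.attenuation:.1f} HU   (injected {phantom.true_attenuation})")
print(f"noise:       {m.noise:.1f} HU   (injected {phantom.true_noise_sd})")
print(f"SNR:         {m.snr:.1f}")
print("SNR is mean attenuation over noise SD; higher means cleaner images.")
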