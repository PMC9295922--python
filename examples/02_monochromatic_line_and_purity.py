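"""Construct monochromatic lines and see why spectral purity is fragile.

The boundary of the colour space is the line of single-wavelength lights.
Its shape depends on construction choices the literature rarely reports:
the intensity given to each light, whether the ultraviolet beta band of the
receptors is included, and where the line starts. This script builds the
line several ways and shows how strongly those choices move the purity
denominator.
"""

import warnings

import hexapure as hp

bee = hp.standard_system("honeybee")
bee_no_beta = hp.standard_system("honeybee", include_beta=False)

line = hp.monochromatic_line(bee)                      # beta on, outer envelope
line_nb = hp.monochromatic_line(bee_no_beta, lambda_start=350)

print("distance from achromatic centre to the monochromatic locus:")
print(f"{'nm':>5} {'beta on':>9} {'beta off (line from 350)':>26}")
for wl in (310, 330, 350, 370, 390, 440, 540):
    d_beta = line.distance_at(wl)
    d_nb = line_nb.distance_at(wl) if wl >= 350 else float("nan")
    print(f"{wl:>5} {d_beta:9.3f} {d_nb:26.3f}")
print()
print("With the beta band all three receptors share ultraviolet sensitivity,")
print("so the 300-390 nm loci collapse towards the centre (the 'hook'")
print("artefact); without it the ultraviolet end stays far out.")
print()

flower = hp.flower_spectrum("white_sigmoid", 2.0, 0.7, label="white_flower")
locus = hp.locus_for_stimulus(flower, bee)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = hp.spectral_purity(locus.xy, line)
print(f"white flower: contrast a = {res.a:.3f}, boundary leg b = {res.b:.3f}")
print(f"spectral purity a/(a+b) = {res.purity:.3f}")
print("Note that the numerator a IS the flower's colour contrast: purity can")
print("never be independent of contrast, whatever the boundary looks like.")
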