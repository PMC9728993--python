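"""Erosion-shell radial profiling of a peripherally biased nucleus.

Simulates a single-slice nucleus image whose probe intensity grows
towards the periphery (probe ∝ (r/R)², as a chromosome territory near
the nuclear envelope would), partitions the nucleus mask into five
equal-area shells from periphery (bin 1) to centre (bin 5), and prints
the DAPI-normalised intensity per shell plus a Kruskal-Wallis test for
a radial trend across 30 noisy nuclei.
"""

from ecspat import equal_area_shells, shell_profile, shell_trend_test, simulate_radial_image

probe, dapi, mask = simulate_radial_image(256, 100, radial_bias=2.0)
shells = equal_area_shells(mask > 0, 5)
prof = shell_profile({"probe": probe}, dapi, shells, nucleus_id="demo")
print("shell areas (px):", [int(a) for a in prof.areas_px])
for k, v in enumerate(prof.normalized["probe"], start=1):
    print(f"  bin {k} ({'peripheral' if k == 1 else 'central' if k == 5 else '...'}): "
          f"normalised intensity {v:.3f}")

profiles = []
for i in range(30):
    p, d, m = simulate_radial_image(128, 50, radial_bias=2.0, noise_sd=0.2, seed=i)
    profiles.append(shell_profile({"probe": p}, d, equal_area_shells(m > 0, 5),
                                  nucleus_id=f"n{i}"))
h, p = shell_trend_test(profiles, "probe")
print(f"\nKruskal-Wallis across shells (30 noisy nuclei): H = {h:.1f}, p = {p:.3g}")
print("a flat profile would give H near 0 and p near 1")
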