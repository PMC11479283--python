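"""Exhaustively search two-band normalized-difference indices for a trait.

For every pair of wavelengths the index (R1 − R2)/(R1 + R2) is correlated
with adaxial hypodermis thickness; the printed best pair should sit near
the wavelengths where the generator ties that trait to the spectrum
(red edge at 700 nm and a SWIR water-band flank near 1441 nm).
"""

import spectraleaf as sl

data = sl.generate_dataset(sl.default_config(), seed=1)

index_map = sl.r2_map(
    data.reflectance,
    data.traits.trait("adaxial_hypodermis_um"),
    trait_name="adaxial_hypodermis_um",
)
pair, r2 = sl.best_pair(index_map)

print(f"channels searched : {index_map.n_channels} "
      f"({index_map.n_channels * (index_map.n_channels - 1) // 2} pairs)")
print(f"best band pair    : {pair.channel_1:g} nm / {pair.channel_2:g} nm")
print(f"best r2           : {r2:.3f}")
print()
print("The r2 is the squared Pearson correlation between the two-band index")
print("and the trait over all 200 leaves; the full matrix can be exported")
print("as a contour-map CSV with spectraleaf.export_contour().")
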