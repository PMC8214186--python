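"""Skin-tone classification from spectrocolorimetry readings.

Computes the individual typology angle (ITA) from CIELAB L* (lightness)
and b* (yellow-blue) for a few representative readings and maps each to
its six-group category; camera-PPG accuracy is typically stratified by
these groups when validating across diverse skin pigmentation.
"""

from pulsefit import ItaMeasurement

readings = [(72.0, 14.0), (65.0, 15.0), (58.0, 17.0),
            (54.0, 20.0), (45.0, 16.0), (38.0, 22.0)]

print("  L*     b*    ITA(deg)  category")
for L, b in readings:
    m = ItaMeasurement.from_lab(L, b)
    print(f"{L:5.1f}  {b:5.1f}  {m.ita_degrees:8.2f}  {m.category}")
print("larger angles (lighter skin) map to the lighter categories;")
print("the cutoff chain is 55 / 41 / 28 / 10 / -30 degrees")
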