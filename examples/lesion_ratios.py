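"""Lesioned-vs-intact striatal concentration ratios.

The unilateral lesion model is characterized biochemically by the ratio
C_lesioned / C_intact per analyte; percent change is 100 * (1 - ratio),
positive for a depletion on the lesioned side.
"""

from sleepfc import lesion_ratio

analytes = {
    # analyte: (lesioned-side mean, intact-side mean, unit)
    "dopamine": (33.2, 67.9, "nmol/g"),
    "GABA": (23.1, 22.5, "umol/g"),
    "glutamate": (41.4, 42.2, "umol/g"),
}

for name, (lesioned, intact, unit) in analytes.items():
    ratio, change = lesion_ratio(lesioned, intact)
    direction = "depletion" if change > 0 else "increase"
    print(f"{name:10s} {lesioned:5.1f} vs {intact:5.1f} {unit}: "
          f"ratio {ratio:.2f}, {abs(round(change))}% {direction}")
# A ~51% dopamine depletion with essentially unchanged glutamate is the
# biochemical signature of a partial unilateral lesion.
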