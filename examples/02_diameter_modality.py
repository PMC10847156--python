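"""Detect when a fibril-diameter distribution becomes bi- and trimodal.

Samples diameters for 21 synthetic postnatal days (the generator switches
from one population to two at day 8 and to three at day 14), fits 1-3
component normal mixtures by EM, scores each against the day's KDE, and
calls the modality of each day as the smallest component count whose
R-squared clears 0.98.
"""

import fibrilmorph as fm
from fibrilmorph.synthetic import sample_mfd, timepoint_mixture

fits, kdes = {}, {}
for day in range(1, 22):
    x = sample_mfd(timepoint_mixture(day), n=2000, seed=500 + day)
    kdes[day] = fm.kde(x)
    fits[day] = {k: fm.fit_mixture(x, k, seed=day * 7 + k, n_restarts=6)
                 for k in (1, 2, 3)}

series = fm.modality_transition(fits, kdes, r2_threshold=0.98)

print("day  modality  R2(k=1)  R2(k=2)  R2(k=3)")
for i, day in enumerate(series.days):
    print(f"{day:>3.0f}  {series.modality[i]:>8d}"
          f"  {series.r2[1][i]:>7.3f}  {series.r2[2][i]:>7.3f}  {series.r2[3][i]:>7.3f}")
print(f"\nfirst bimodal day:  {series.transition_day(2):.0f}")
print(f"first trimodal day: {series.transition_day(3):.0f}")
# A fit with too few components cannot reproduce the extra KDE modes, so
# its R-squared collapses; the day a second (third) population appears is
# the first day k=1 (k=2) drops below the threshold.
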