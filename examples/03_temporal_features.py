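"""Differential fluctuant features (DFFs) on a single rising TG trajectory.

Each year-to-year change (DNF) is weighted by a sigmoid of how close the
later value sits to the indicator's normal limit, and the three weighted
terms are combined with geometric decay favouring recent intervals:
g = b^3 F1 + b^2 F2 + b F3 with b = 0.6 and sigmoid steepness a = 50.
"""

from metsflow import IndicatorSpec, compute_dff, compute_dsf

spec = IndicatorSpec(
    name="TG", units="mmol/L", upper=1.70, inclusive=True, scale_max=2.0
)

rising = [1.0, 1.2, 1.5, 1.9]     # crosses the 1.70 limit in the last year
falling = [1.9, 1.5, 1.2, 1.0]

for label, values in (("rising", rising), ("falling", falling)):
    dff = compute_dff(values, spec)
    print(f"TG {label} {values}: g = {dff.g:+.4f}")
    for term in dff.terms:
        print(f"   {term.interval}: DNF {term.dnf:+.2f}, "
              f"weight S(x)={term.s:.3f} (x={term.x:+.3f}) -> F={term.f:+.4f}")
    dsf = compute_dsf(values[-2], values[-1], spec)
    print(f"   last-interval state change (DSF): {dsf:+d}")

# The rising series gets a large positive g because its recent change
# happens right at the limit (weight ~0.5-1); the same changes far below
# the limit would be damped toward zero.
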