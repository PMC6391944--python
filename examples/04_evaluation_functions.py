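"""The five campaign evaluation functions, side by side.

Shows how the same IR reading scores differently depending on which terms
(conversion, throughput, reagent consumption, energy) a campaign weights,
and why penalty terms move optima off the conversion-maximizing corner.
"""

from flowopt import CAMPAIGNS, IRReading, evaluate, preset

reading = IRReading(p=0.8, s=0.2)  # 80 % apparent conversion

for name in sorted(CAMPAIGNS):
    spec = preset(name)
    campaign = CAMPAIGNS[name]
    score = evaluate(spec, campaign.target_point, reading)
    z = campaign.target_point
    print(f"{name:16s} terms={sorted(spec.terms)}")
    print(f"{'':16s} at ({z.temperature:g} degC, {z.residence_time:g} min, "
          f"{z.equivalents:g} equiv): E = {score:.4f}")
# With identical feedback, multi-term campaigns score far below the
# conversion-only campaign: each active penalty multiplies in a factor
# in (0, 1] that rewards shorter residence times, leaner stoichiometry
# or cooler operation.
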