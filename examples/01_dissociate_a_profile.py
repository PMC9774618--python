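"""Dissociate one decision profile into its underlying tendencies.

A participant answered 6 scenarios in each of the four cells of the
egoistic x altruistic design.  Their acceptance rates alone (especially the
conventional 'altruistic choice' rate p3) cannot tell whether altruistic
choices come from altruism, weak egoism, or a general yes-bias — the three
contrasts below can.
"""

import moralcan as mc

# acceptance rates per cell: p1 = benefits self/harms others, p2 = both,
# p3 = others at own cost, p4 = neither
profile = mc.ProbabilityProfile(4 / 6, 6 / 6, 4 / 6, 2 / 6,
                                n_trials_per_cell=(6, 6, 6, 6))
params = mc.dissociate(profile)

print(f"profile:          p1={profile.p1:.2f} p2={profile.p2:.2f} "
      f"p3={profile.p3:.2f} p4={profile.p4:.2f}")
print(f"altruistic tendency AT = {params.at:+.3f}")
print(f"egoistic tendency   ET = {params.et:+.3f}")
print(f"action preference   OP = {params.op:.3f}")
print(f"altruistic choice   AC = {params.ac:.3f}  (identical to p3)")
print()
print("AT > 0: acceptance rises when the act benefits others;")
print("ET > 0: acceptance rises when the act benefits the self;")
print("OP is the overall probability of acting at all.")
print()

# the map is invertible given the interaction contrast D
d = mc.interaction_term(profile)
back = mc.invert(params, d)
print(f"interaction D = {d:+.3f}; invert(AT, ET, OP, D) returns the profile: "
      f"({back.p1:.2f}, {back.p2:.2f}, {back.p3:.2f}, {back.p4:.2f})")
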