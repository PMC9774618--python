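# moralcan

Process dissociation for **everyday moral decision-making**: a tested Python
pipeline for building, validating and analysing 2×2 (egoistic × altruistic)
scenario batteries.

## The problem

Everyday moral dilemmas force a choice between benefiting others at a
personal cost and benefiting oneself at others' cost ("a neighbour asks for
your last piece of meat during a quarantine").  The traditional single score
— the acceptance rate of the altruistic option — is ambiguous: choosing
altruistically may reflect strong altruistic sensitivity, weak egoistic
sensitivity, or a general tendency to accept any proposed act.

A factorial battery breaks the confound.  Each scene framework exists in
four versions crossing whether the proposed act benefits the **self**
(egoistic / non-egoistic) and whether it benefits **others** (altruistic /
non-altruistic).  With acceptance probabilities p₁…p₄ for the four cells
(p₁ = egoistic & non-altruistic, p₂ = both, p₃ = altruistic &
non-egoistic, p₄ = neither), three orthogonal contrasts dissociate the
processes:

    AT = (p₂ − p₁ + p₃ − p₄) / 2        altruistic tendency   ∈ [−1, 1]
    ET = (p₂ − p₃ + p₁ − p₄) / 2        egoistic tendency     ∈ [−1, 1]
    OP = (p₁ + p₂ + p₃ + p₄) / 4        action preference     ∈ [0, 1]
    AC = p₃                             the conventional altruistic-choice rate

A fourth contrast D = (p₂ + p₄ − p₁ − p₃)/2 (altruism × egoism interaction)
completes the orthogonal basis and makes the map invertible, which the
synthetic-data generator uses to plant known parameter values.

The package is aimed at researchers in moral psychology and behavioural
decision-making who want to (a) validate their own scenario batteries, (b)
compute these parameters from binary survey decisions, and (c) benchmark
the whole analysis chain on synthetic cohorts with known ground truth.

## What is in the box

| module | contents |
|---|---|
| `moralcan.core` | cell structure, probability profiles, the dissociation and its inverse, per-participant estimation |
| `moralcan.validation` | structure-judgment coding (A–D options), one-df chi-square screening against chance, the framework-retention rule |
| `moralcan.simulate` | seeded synthetic cohorts: correlated latent traits, Bernoulli decisions, Likert items with reverse-keying, planted attention-check failures and latency outliers |
| `moralcan.analysis` | exclusions, scale scoring, Cronbach's alpha, Pearson correlation matrix, pooled t tests with Cohen's d, Harman single-factor check, full pipeline orchestration |
| `moralcan.io` / `moralcan.cli` | validated CSV schemas, shipped fixtures, a thin `moralcan` command-line interface |

Shipped reference data: the published validation counts for 13 candidate
scene frameworks (4 cells × 209 raters each) and a scenario bank with the
fully worked public-smoking framework.

## Worked example

Dissociating one participant's acceptance profile (6 scenarios per cell):

```python
>>> import moralcan as mc
>>> profile = mc.ProbabilityProfile(4/6, 6/6, 4/6, 2/6)
>>> params = mc.dissociate(profile)
>>> print(f"AT={params.at:+.3f} ET={params.et:+.3f} OP={params.op:.3f} AC={params.ac:.3f}")
AT=+0.333 ET=+0.333 OP=0.667 AC=0.667
```

This responder is moderately sensitive to both benefit-to-others and
benefit-to-self (AT = ET = +0.33) on top of a general yes-bias (OP = 0.67);
the raw altruistic-choice rate AC = 0.67 alone could not have separated
those readings.

Recovering planted parameters from a simulated cohort
(`python examples/03_simulate_and_recover.py`):

```
       truth   pooled  indiv. mean  indiv. SD
  AT   0.220    0.223        0.223      0.188
  ET   0.310    0.312        0.312      0.181
  OP   0.570    0.571        0.571      0.095
```

Pooled and individual-level means recover the truth to ~0.01; the
individual-level SDs are binomial granularity from 6 binary trials per cell
(predicted in closed form: √(Σₖ pₖ(1−pₖ)/24) ≈ 0.187 for AT/ET).

The other scripts under `examples/` demonstrate framework screening on the
shipped counts (`02`), and the full individual-differences pipeline with
exclusions, reliabilities, correlations and group comparisons (`04`).

The same stages are available from a shell:

```bash
moralcan simulate --seed 42 --out run/
moralcan validate --counts counts.csv --exception relative_2 --out run/
moralcan dissociate --decisions run/decisions.csv --level individual
moralcan analyze --decisions run/decisions.csv --scales run/scales.csv \
                 --demographics run/demographics.csv --out run/
```

## Documentation

The modelling assumptions, generator design, numerical conventions and
known limitations are described in [`docs/methods.md`](docs/methods.md).
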