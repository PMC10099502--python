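# outletchoice

Selection-corrected discrete-choice analysis of where women obtain their
contraceptive method: which structural-quality attributes of a family-planning
outlet (public sector, method variety, signage, stockouts, provider training,
opening hours) pull users past closer alternatives, and how far — in kilometres
— they are willing to travel for each attribute.

The package is written for quantitative researchers working with linked
household–outlet surveys (one row per surveyed woman, one row per audited
outlet, plus a link from each user to the outlet where she obtained her
method). Because such microdata are rarely shareable, the package ships a
synthetic-study generator that emulates the full design — an outlet census in
an outer ring, households in a nested inner ring, selection into method
use/linkage, and outlet choices from a known utility — so every stage of the
pipeline is testable against ground truth.

## The model

Each linked user `i` chooses among the outlets within a fixed straight-line
radius of her home (her choice set, `M_c` alternatives; 3 km for the
Kenya-like preset, 2 km for the Uganda-like preset). Utility is linear in
outlet attributes `z_im` (including distance):

    U_im = z_im' beta_i + eps_im,        eps_im ~ iid Gumbel
    beta_i ~ N(beta, Sigma_beta),        Sigma_beta diagonal

With `Sigma_beta = 0` this is the conditional logit; letting coefficients vary
across women gives the mixed logit, which relaxes the independence of
irrelevant alternatives. The mixing integral is simulated with Halton draws
(maximum simulated likelihood) and the two models are compared by a
likelihood-ratio test.

Only users who were linked to an outlet enter the choice model, and linkage is
not random. A first-stage six-category multinomial logit (no method,
traditional, long-/short-acting unlinked, long-/short-acting linked) on
demographics and supply-environment covariates yields each woman's probability
of her observed linked category; its reciprocal is her inverse-probability
weight (IPW), correcting the choice model for selection on observables.

Coefficients are scale-dependent; the reported metric is willingness to travel

    wtt_k = -beta_k / beta_distance    (km per unit of attribute k),

with delta-method (default) or simulation-based confidence intervals.

## Worked example

```python
from outletchoice import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, preset="kenya_like",
                                n_respondents=4000, n_draws=300, screen=False))
print(report["stages"]["lr_test"])
for row in report["stages"]["wtt"]["table"]:
    print(f"{row['attribute']:>22}: {row['wtt_km']:6.2f} km "
          f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]")
```

Output (seed 1):

```
{'statistic': 11.268352317377717, 'df': 3, 'p_value': 0.010359639932864224}
             n_methods:   0.09 km [0.02, 0.16]
                 open7:   0.36 km [0.14, 0.57]
  stockout_injectables:  -0.05 km [-0.32, 0.22]
      trained_provider:   0.34 km [0.14, 0.55]
            fp_signage:   0.42 km [0.23, 0.61]
             is_public:   1.79 km [1.35, 2.23]
           is_pharmacy:   0.24 km [-0.01, 0.49]
```

The LR test rejects preference homogeneity (p = 0.01): distance aversion,
the taste for method variety, and the public-sector premium vary across women.
The willingness-to-travel column says, for example, that an average user would
accept an extra 1.79 km of travel to reach a public outlet and 0.09 km per
additional contraceptive method on offer — close to the generating truth
ratios (2.0 and 0.15 km) at this sample size (815 linked choosers).

The same pipeline runs from the command line:

```bash
outletchoice generate --preset kenya_like --seed 1 --out study/
outletchoice run --seed 1 --out run1/        # writes wtt.csv, fits, report.json
outletchoice wtt --fit run1/mixedlogit_fit.json --out wtt2.csv
```

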