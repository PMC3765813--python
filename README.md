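# rtcausal

A counterfactual *response-type* calculus for epidemiologic bias analysis
with four binary variables: a confounder `C`, an exposure `E`, a disease
outcome `D`, and a selection (follow-up) indicator `S`, wired as
`C → E`, `C → D`, `E → D`, `E → S`, `D → S`.

`rtcausal` is for methodologists and teachers of causal inference who want
to compute — rather than merely assert — what confounding bias, collider
selection bias, and effect-measure modification look like when the complete
causal truth of a population is written down. The package:

* enumerates the potential-outcome **response types** of each variable
  (4 exposure types `(E_1, E_0)`, 16 disease types `(D_11, D_01, D_10,
  D_00)`, 16 selection types `(S_11, S_01, S_10, S_00)`; 1,024 joint EDS
  types), applies monotonicity and no-additive-interaction restrictions
  (3 × 4 × 4 = 48 admissible types), and evaluates compound (nested)
  potential outcomes such as `D_{c, E_{c'}}` and `S_{E_c, D_{c', E_{c''}}}`;
* maps a fully specified population — a mass function `P_{EiDjSk}` plus
  per-type confounder probabilities `P(C | EiDjSk)` — to the 16 observable
  `(E, D, C, S)` cell frequencies of an observational study
  (`N Σ P(C|type) P(type)` per cell) or of a marginally / stratified
  randomized trial (`N P(E|C) Σ P(C | DjSk) P(DjSk)`), and verifies that the
  trial table is a within-stratum redistribution of the observational one;
* computes associational, standardized, stratum-specific,
  selection-restricted, and causal risk ratios. The causal risk ratio
  `P[D_{e=1}=1] / P[D_{e=0}=1]` comes from g-computation over response
  types; the standardized associational RR is
  `[P_C r(1,1) + P_C̄ r(1,0)] / [P_C r(0,1) + P_C̄ r(0,0)]` with
  `r(e,c) = P(D=1 | E=e, C=c)`;
* audits the exchangeability implication chain
  `E^T ⊥ D^T | C  ⇒  E ⊥ D^T | C  ⇒  E ⊥ (D_{e=1}, D_{e=0}) | C  ⇒
  E ⊥ D_e | C for all e`
  on the exact joint law, quantifies confounding and selection-bias gaps,
  and checks positivity;
* builds **extended causal diagrams** that carry the response types as
  nodes (with latent common causes `U1, U2, U3`), performs intervention
  surgery, enumerates paths, and decides d-separation — reproducing, for
  instance, the seven marginally blocked `E–D^T` paths that conditioning on
  the selection collider `S` opens.

Everything is analytic (expected counts, exact probabilities); a seeded
sampler provides finite-data realizations when you want them.

## Worked example

Consider a population of N = 1,000 in which every individual has response
type E1/D6/S4: always exposed (`E_1 = E_0 = 1`), diseased exactly when the
confounder is present (`D_ce = c`), retained in the study exactly when
exposed-and-diseased (`S_ed = e·d`), with `P(C) = 0.3`:

```python
import rtcausal as rt

pop = rt.PopulationSpec(1000, {(1, 6, 4): 1.0}, {(1, 6, 4): 0.3})

rt.obs_cell_frequencies(pop).cells            # observational study
# (e,d,c,s)=(1, 1, 1, 1) -> 300
# (e,d,c,s)=(1, 0, 0, 0) -> 700

design = rt.DesignSpec("rct_marginal", 0.5)   # randomize E, P(E)=0.5
rt.rct_cell_frequencies(pop, design).cells
# (e,d,c,s)=(1, 1, 1, 1) -> 150
# (e,d,c,s)=(0, 1, 1, 1) -> 150
# (e,d,c,s)=(1, 0, 0, 0) -> 350
# (e,d,c,s)=(0, 0, 0, 0) -> 350
```

Observationally the type splits over exactly two cells by its confounder
value — the 300 with `C = 1` are exposed, diseased, and selected; the 700
with `C = 0` are exposed, healthy, and lost to follow-up. Randomization
redistributes each confounder stratum over the two arms without ever moving
mass across strata.

Bias appears the moment exposure types are correlated with disease types
within confounder strata. On a certified confounded population:

```python
conf = rt.named_fixture("confounded", seed=17)
rt.std_rr(rt.obs_cell_frequencies(conf)).value   # 1.8186
rt.causal_rr(conf).value                         # 1.5244
{v: r.holds for v, r in rt.check_all_conditions(conf).items()}
# {'et_dt_given_c': False, 'e_dt_given_c': False,
#  'full_cond_exch': False, 'cond_exch': False}
```

Standardization over `C` gives 1.82 while the true effect is 1.52 — a 19%
ratio-scale residual confounding that stratified analysis cannot remove,
because conditional exchangeability fails. On a population certified for
response-type independence given `C`, the same two numbers agree to float
precision (both 1.360789 for the shipped `et_dt` fixture, seed 17).

The same machinery is available from a shell:

```bash
rtcausal enumerate --monotone-e --monotone-d --no-int-d --monotone-s --no-int-s
rtcausal fixture --recipe confounded --seed 17 -o pop.yaml
rtcausal measures --population pop.yaml
rtcausal audit --population pop.yaml --seed-sweep 100
rtcausal dsep --graph fig6 --x E --y D_T --given S
rtcausal audit-dag
```

## Layout

| module | contents |
| --- | --- |
| `rtcausal.response_types` | type enumeration, restrictions, compound potential outcomes, consistency mapping |
| `rtcausal.population` | population/design specs, cell frequencies, redistribution audit, sampling |
| `rtcausal.measures` | associational / standardized / causal risk ratios, modification flags |
| `rtcausal.conditions` | exchangeability chain, bias gaps, positivity |
| `rtcausal.dag` | extended diagrams, surgery, path classification, d-separation, claims audit |
| `rtcausal.fixtures` | seeded random populations and certified property-targeted fixtures |
| `rtcausal.io`, `rtcausal.cli` | spec files, canonical JSON, command-line surface |

See `docs/methods.md` for the model, its assumptions, and the numerical
conventions.
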