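# Methods

## The model

We work with four binary variables on a closed population of `N`
individuals: a confounder `C`, an exposure `E` caused by `C`, a disease
outcome `D` caused by `C` and `E`, and a selection indicator `S` caused by
`E` and `D` (a collider; `S = 0` means lost to follow-up). `C` is assumed
not to affect `S` directly, and `C` temporally precedes `E`.

Causation is deterministic at the individual level: each individual carries
a *response type* per caused variable — the full vector of potential
outcomes under every joint setting of its manipulable causes:

* exposure type `(E_1, E_0)` — 4 types;
* disease type `(D_11, D_01, D_10, D_00)`, indexed by `(c, e)` — 16 types;
* selection type `(S_11, S_01, S_10, S_00)`, indexed by `(e, d)` — 16 types.

Types are indexed in descending binary order of the bit vector
(`index = max + 1 − int(bits, 2)`), so index 1 is the all-ones ("doomed")
type and the last index the all-zeros ("immune") type. The joint EDS type
space has 4 × 16 × 16 = 1,024 members.

Two families of a-priori restrictions are supported. *Positive
monotonicity* requires the potential outcome to be non-decreasing in each
cause (componentwise on the setting tuple); it removes E type 3 and D/S
types {3, 5, 7, 9–15}. *No individual-level additive interaction* requires
`D_11 − D_01 − D_10 + D_00 = 0` (likewise for S). The interaction contrast
is our operationalization: combined with monotonicity it retains exactly
D/S types {1, 4, 6, 16}, which is the retention set the restricted joint
enumeration (48 = 3 × 4 × 4 types) requires, so we regard the definition as
forced. All analysis functions work on the unrestricted 1,024-type space;
restrictions are opt-in filters.

*Consistency* links types to data. Observationally, an individual of type
`(i, j, k)` with confounder value `c` shows
`e = E_c`, `d = D_{c,e}`, `s = S_{e,d}`; each type therefore occupies at
most two of the 16 observable `(E, D, C, S)` cells. In a randomized trial
the assigned arm replaces `E_c`, the exposure type becomes irrelevant, and
a `(D type, S type)` pair occupies at most four cells. Compound (nested)
potential outcomes `D_{c, E_{c'}}` and `S_{E_c, D_{c', E_{c''}}}` are
evaluated by direct composition; an entry is *realizable* precisely when
some confounder value produces its setting under consistency (the package
exposes this as a predicate rather than annotating values, since
realizability is metadata, not data).

## Populations, designs, and cell frequencies

A `PopulationSpec` is the complete causal truth: `N`, a mass function over
EDS types, and `P(C=1 | type)` per type. The equivalent conditional
parameterization `{P(C), P(type | C=1), P(type | C=0)}` is accepted and
converted exactly by Bayes' rule. Probability sums are validated to 1e−9
with `math.fsum`; silent renormalization is refused (a wrong sum is a spec
bug, not noise).

Cell frequencies are *expected* real-valued counts `N·P`. For a trial with
`P(E=1 | C=c)` (equal across strata under marginal randomization), cell
`(e, d, c, s)` receives `N · P(E=e|C=c) · Σ P(C=c | DjSk) P(DjSk)` over the
DS pairs whose realization under `(c, e)` is `(d, s)`. The redistribution
audit verifies, pair by pair and stratum by stratum, that these trial
frequencies are exactly the observational stratum masses reweighted by the
assignment probabilities — individuals never cross confounder strata,
because `C` is fixed before exposure is assigned. The identity is algebraic,
so the audit's tolerance (1e−9 on absolute residuals) only absorbs float
summation order.

A seeded sampler (`numpy.random.default_rng`; one generator per call, no
global state) draws i.i.d. individuals for finite-data work; analytic
tables are the reference, sampling the realization.

## Epidemiologic measures

All measures are risk ratios. Associational measures are functionals of a
cell table: `P(D=1|E=1, …) / P(D=1|E=0, …)`, optionally restricted to
`S = 1` and/or a `C` stratum. The standardized RR weights stratum risks by
the total-population confounder prevalence. Causal measures are
functionals of the population: `P[D_e=1]` by g-computation over types
(`Σ_t P_t [P(C|t) D_{1e} + P(C̄|t) D_{0e}]`), with stratum versions
conditioning on `C` and a selection-restricted version that keeps, in each
intervention arm, exactly the individuals that arm would retain
(`S_{e, D_{c,e}} = 1`). A second, independent route computes the causal RR
from response-type sums over the DS marginal — numerator
`Σ_{j: D11=1} P(C|Dj)P(Dj) + Σ_{j: D01=1} P(C̄|Dj)P(Dj)`, denominator the
`D10`/`D00` analogue — with index sets derived from the bit vectors
themselves; the two routes are required to agree to 1e−12 in tests. (Any
printed index list that drops a type whose bit is set — e.g. omitting the
type with `D00 = 1` and all other entries 1 from the `D00` sum — is treated
as a typographical slip; the bits are authoritative.)

A ratio whose denominator risk is zero, or whose conditioning event is
empty, is an *undefined* first-class value with a reason string — never an
exception, never NaN — because degenerate populations (all-immune,
always-exposed, single-stratum) are legitimate inputs.

Effect-measure modification is flagged when the two stratum causal RRs
differ relatively beyond a tolerance (default 1e−9, i.e. exact analytic
inequality); association-measure modification analogously from the stratum
associational RRs. The two flags are computed independently because neither
implies the other.

## Exchangeability conditions and bias gaps

Four conditions are audited on the exact finite joint law of
`(C, E type, D type)` (observed `E` obtained by consistency, or by the
design's assignment law under a trial), ordered strongest first:

1. `E^T ⊥ D^T | C` — response-type independence;
2. `E ⊥ D^T | C`;
3. `E ⊥ (D_{e=1}, D_{e=0}) | C` — full conditional exchangeability;
4. `E ⊥ D_e | C` for each `e` — conditional exchangeability.

Independence is decided by the maximum absolute deviation
`|P(a,b|c) − P(a|c)P(b|c)|` over atoms, with tolerance 1e−12 (everything is
closed-form; no sampling error exists to absorb). A conditional statement
whose conditioning stratum has zero mass is *indeterminate*, not true:
vacuous truth would corrupt the implication audit. The implication chain
1 ⇒ 2 ⇒ 3 ⇒ 4 is asserted over large sweeps of random populations; any
counterexample is a build-failing bug in the checker.

Each inclusion is strict, and the fixture library constructs an exhibit for
each gap:

* **2 without 1** — within the `C=1` stratum the two exposure types that
  map to the same observed exposure carry opposite couplings to the disease
  type, so the type-level dependence cancels at the level of observed `E`.
* **3 without 2** — exposure is coupled only to the half of the D-type bit
  vector that is counterfactual in the current stratum (`(D_01, D_00)`
  within `C=1`, `(D_11, D_10)` within `C=0`), leaving the realized
  potential-outcome pair exposure-independent while the D-type itself is
  not.
* **4 without 3** — the exposed carry perfectly concordant potential-outcome
  pairs (`(1,1)` or `(0,0)`) and the unexposed perfectly discordant ones
  (`(1,0)` or `(0,1)`), each with probability ½: both margins are
  Bernoulli(½) independent of exposure, the pair is maximally dependent.
  This settles, constructively and with all-binary variables, that arm-wise
  exchangeability genuinely does not imply the joint version — while also
  illustrating why the gap is epidemiologically invisible: no marginal
  quantity distinguishes the two populations, and the standardized RR still
  equals the causal RR under condition 4 alone.

The confounding gap is `std_rr − causal_rr` (and their ratio); it vanishes
whenever condition 4 holds. The selection gap compares the `S=1`-restricted
measure of a requested kind with its unrestricted counterpart; its vanishing
is the non-selection-bias condition for that measure. Positivity reports
`P(E=e, C=c)` for the four combinations and flags zeros.

## Extended causal diagrams

The extended diagram adds nodes `E^T, D^T, S^T` whose single outgoing arrow
points to the corresponding observed variable, plus three mutually
independent latent common causes with edges
`U1 → {C, E^T, D^T, S^T}`, `U2 → {E^T, D^T, S^T}`, `U3 → {D^T, S^T}`.
This latent wiring is reconstructed from the documented path inventory of
the diagrams (each latent edge is attested by at least one listed path; no
listed path requires a `U2` or `U3` edge into `C`, so none is present).
Intervention is surgery: marginal randomization removes both arrows into
`E`; stratified randomization removes only `E^T → E`; the observational
stratification scenario is the unmodified graph with `C` in the
conditioning set of the queries — conditioning is always a set argument,
never graph mutation.

The d-separation engine enumerates simple paths in the skeleton
(lexicographically, default cap 8 edges — the graphs have ≤ 10 nodes) and
classifies each by the standard rules (non-collider blocks iff conditioned
on; collider blocks iff neither it nor a descendant is conditioned on).
Tests cross-check every verdict against networkx's independent
reachability-based d-separation criterion, exhaustively over all node pairs
and conditioning sets of size ≤ 2 in every variant. A hard-coded claim
table captures the documented independence statements and path
classifications (randomization separating `E` from all three type nodes;
conditioning on `S` re-connecting `E` and `D^T` through seven listed
collider paths; the two `U1`/`U2` backdoor paths between `E^T` and `D^T`
that conditioning on `C` cannot block), and the audit requires zero
discrepancies. The seven listed selection-bias paths are verified as a
documented list; the engine's full census finds additional `E–D^T` paths
opened by conditioning on `S` (e.g. through `C` or through the collider
`D`'s descendant), which the census reports separately rather than
reinterpreting the documented seven as exhaustive.

## Synthetic populations

The generator draws a sparse support (default 12 types) uniformly from the
admissible types, a Dirichlet(1) mass over the support (uniform on the
simplex — an unbiased default), and i.i.d. uniform `P(C | type)` values;
`N` defaults to 100,000, which only scales expected counts. Bias-targeted
fixtures rejection-sample until the certified gap exceeds 0.05 on the ratio
scale (comfortably above float noise, so certified fixtures cannot flicker);
structural fixtures are built exactly as described above. Every fixture is
certified by the `conditions` module before being returned; failure raises.

What the generator emulates is the *structural* content of the framework:
discrete populations with arbitrary type–confounder dependence. What it
does not emulate: sampling variability (analytic tables are exact;
the sampler exists precisely to add it back), continuous or multiple
confounders, measurement error, and any direct `C → S` effect. Passing
tests therefore demonstrate the algebraic and graphical claims, not
robustness of estimation on finite noisy data.

## Numerical conventions and problem sizes

* Probability sums: `math.fsum`, tolerance 1e−9, no renormalization.
* Independence checks: absolute deviation 1e−12 on the exact joint law.
* Dual-route measure agreement: relative 1e−12.
* Undefined ratios: reason-carrying values, no exceptions.
* RNG: `numpy` generators, one per call, seeded; fixtures spawn attempt
  seeds via `SeedSequence`.
* Sweeps: the implication chain and redistribution identities are audited
  over 1,000 seeded random populations; Monte-Carlo consistency of the
  sampler uses n = 200,000 with a four-binomial-standard-error band —
  sizes at which every check is exact-to-tolerance yet the whole suite
  runs in seconds.

## Known limitations

Binary variables only; one confounder; no direct `C → S` arrow; risk
ratios only (no risk differences or odds ratios); target population is the
total population or a `C` stratum; no twin-network or SWIG semantics for
cross-world queries — the extended diagram intentionally stays in the
single-world factual graph, which is exactly what makes it applicable to
observational studies and trials alike.
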