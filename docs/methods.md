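# Methods

## The two fractional-occupancy models

Both models treat a regulatory element as a set of transcription-factor
binding sites, enumerate every bound/unbound configuration ("state"), assign
each state a statistical weight, and compute expression as the
weight-averaged expression contribution:

```
E = Σ_s W_s E_s / Σ_s W_s
```

**Construct-based quenching model.** A construct is an ordered list of
activator and repressor sites with 1-based bp coordinates. State weights
multiply a binding term per bound site — `A·[act]` for activators (A fixed at
1.0 and excluded from all sensitivity spaces), `R·[rep]` for repressors — and
a homotypic cooperativity per adjacent bound repressor pair: the 5'-most pair
takes `C1`, any further pair `C2` (a single-term mode applies `C1` to every
pair). Adjacency requires consecutive sites with no intervening site of any
role: cooperative binding is a neighbor contact, so an activator between two
repressors breaks the pair. A state's expression contribution is the fraction
of the construct's activators that are bound, each attenuated by
`(1 − Q_b)` for every bound repressor, where the quenching efficiency
`Q_b ∈ [0, 1]` depends on the binned activator-repressor distance. The
default binning is Q1: 0–6 bp, Q2: 7–27, Q3: 28–41, Q4: 42–49, Q5: 50–56,
with the terminal bin Q6 for any repressor 3' of every activator; bins are
fully configurable, and a distance that falls in no bin is an error rather
than a silent extrapolation. The structural consequence this package's
analyses hinge on: quenching efficiencies appear only in the numerator of the
rational expression function, while `R`, `C1`, `C2` appear in numerator and
denominator and can therefore be compensated.

An optional *post-binding* cooperativity mode removes the cooperativity
terms from the denominator only, modeling cooperativity as an event after
binding equilibrium. It exists to demonstrate that moving a parameter out of
the denominator raises its sensitivity; it is off by default.

State enumeration is exact and capped at 20 sites (2^20 states); larger
constructs are rejected, never approximated. A vectorized evaluator
(`FakhouriEvaluator`) precomputes the state tensors per construct so an
objective evaluation over a whole concentration series is a handful of array
operations; tests verify it against an independently coded brute-force loop
to 1e-12 relative.

**Site-count model.** An enhancer is just the triple of Dorsal, Twist and
Snail site counts. A state with i, j, k bound sites of each factor has weight
`C(n_D,i)C(n_T,j)C(n_S,k) · (D[Dl])^i (T[Twi])^j (S[Sna])^k ·
DT^(i·j) · TT^C(j,2) · SS^C(k,2)` — counts with binomial multiplicities are
an exact grouping of the 2^n site-level states because same-factor sites are
interchangeable. Expression is the probability of a state with at least one
bound activator (Dorsal or Twist) and no bound Snail; Snail repression is
absolute. The cooperativity triple (DT, TT, SS) is selected by enhancer
class: (DTr, TTr, SSr) for rho-like, (DTv, TTv, SSv) for vnd-like. The
all-pairs cooperativity exponents and the at-least-one-activator /
no-Snail activation rule are this package's reconstruction — the site-count
formulation carries no arrangement information that could support anything
more detailed.

## Objectives

The construct-panel analyses use RMSE pooled over every
(construct, condition) residual — a single mean, not a mean of per-construct
RMSEs, which preserves the compensation effect whereby an error increase in
one construct can cancel a decrease in another. The profile analyses use the
sample Pearson correlation, pooled across the rho-like and vnd-like profile
records, used raw (higher is better, no sign flip). A constant prediction
vector makes the correlation undefined; it is returned as 0.0 with a warning
so a 100,000-draw census never aborts on a degenerate corner of parameter
space.

## Sensitivity methods

**Local.** The elasticity `(μ/C)(∂C/∂μ)` estimated by central differences
with relative step 1e-4 (absolute floor 1e-6), clipped to the declared range
with one-sided differences at the edges. The coefficient is undefined when
the objective or the parameter value is zero (relative normalization is then
impossible); these are returned as NaN sentinels with warnings, and excluded
from the 0-to-1 scaling maximum.

**Averaged local ("global-local").** |elasticity| averaged over n = 10,000
uniformly sampled points, weighted either uniformly or by the inverse of the
objective (default for error-type objectives: good fits weigh more — the
weighting is a genuinely open choice and changes results, so it is recorded
in every output). Undefined coefficients are dropped and counted; more than
50% undefined aborts with a diagnostic.

**eFAST.** Each parameter in turn is driven at a high frequency
ω_max = min(8·M·k, 512) along the sinusoidal search curve
`x_i(s) = 0.5 + (1/π)·arcsin(sin(ω_i s + φ_i))`, with the complementary
parameters at distinct frequencies 1..k−1 (below ω_max/(2M), so their first
M harmonics never collide with the focus harmonics). With M = 4 harmonics
the curve is sampled at Ns = 2·M·ω_max + 1 points (the Nyquist minimum), and
indices are averaged over Nr = 5 random-phase resamplings. S_i is the
spectral power at the focus frequency's first M harmonics over total power;
S_Ti is one minus the power in the complementary band (below ω_max/2).
These budgets were chosen to hold ±0.03 reproducibility on closed-form test
functions; the studies this emulates report no sampling budget.

**RS-HDMR.** N = 10,000 points uniform on the unit hypercube (mapped to each
parameter's range on its sampling scale), f₀ = sample mean, D = sample
variance. Component functions are expanded in orthonormal shifted Legendre
polynomials (degree 3 first-order, degree 2 per dimension second-order) with
coefficients obtained by Monte-Carlo projection of (f − f₀); squared
coefficient sums over D give S_i and S_ij. The config invariant
N > 10 × (number of coefficients) is enforced. Negative raw estimates
(impossible for these squared-sum estimators, but kept for symmetry with
eFAST) would be clipped for reporting with raw values retained. The reported
per-parameter total is S_i + Σ_j S_ij; third-order terms are not computed.
Monte-Carlo projection inflates each squared coefficient by O(Var(f)/N), so
the summed first+second-order share can slightly exceed 1 at finite N.

## Synthetic data

The generators produce every input the pipeline consumes; the generating
model and the analysis model are the same code path, so at zero noise the
true parameter vector reproduces the data exactly (RMSE 0, correlation 1).

**Reporter panel.** The "original" design is a 12-construct panel with one
Dorsal activator site and one to three Giant repressor sites per construct,
laid out so the quenching-bin representation counts match what is known of
the panel it emulates: Q1 and Q3 in 5 constructs each, Q4 and Q5 in 2 each
(Q2: 3 and Q6: 3 are free choices, recorded in the emitted bin table). The
actual published architectures are not printed anywhere we can consume, so
the arrangements are this package's invention under those count constraints.
The "uniform" design represents every bin in an equal number of
single-repressor constructs; "combinatorial" represents every unordered bin
pair exactly once (15 constructs). Observations pair an activator level
fixed at 1.0 with a normalized repressor gradient (default an 11-point grid
on [0, 1]) and add clipped Gaussian noise (default sd 0.05 of the expression
scale; the emulated data are described only as "noisy", with no noise
model). The default truth is the scale-aware range midpoint; "near-edge"
places every true value at lower + 0.9 × width.

**Ventral-dorsal profiles.** The axis runs ventral (0) to dorsal (1) with
Dorsal `exp(−30x)`, Twist `exp(−45x)` and Snail `exp(−250·max(0, x−0.18))`.
These decays are steeper than real normalized immunofluorescence profiles:
the scaling factors act multiplicatively over [1e8, 1e10], so factor
occupancy only switches within the axis if concentrations traverse that
dynamic range — a property the model demands of its inputs. The rho-like and
vnd-like targets are the site-count model's own output for a chosen
structure pair at a true vector satisfying all three predicted cooperativity
relationships (DTr=50 > DTv=5, TTr=40 > TTv=10, SSr=2 < SSv=20, scaling
factors 1e9). Eight synthetic (rho-like, vnd-like) structure pairs stand in
for the informative enhancer structures, whose real site counts are not
published in consumable form.

What passing tests on these fixtures do *not* show: anything about confocal
imaging noise structure, embryo-to-embryo variability, or the exact index
values of the original analyses, which depend on unpublished measurements.

## Parameter spaces

Quenching efficiencies are sampled on [0, 1], their natural scale. The
repressor scaling factor default is [0.5, 1.5]: R is shared by every
construct in the panel, so its prior width directly sets its share of output
variance, and a window comparable to the fixed activator weight keeps the
analysis in the regime the panel was built to probe (distance-dependent
quenching); with a several-fold R window, R's main effect dominates every
quenching index and the characteristic quenching > scaling > cooperativity
ordering disappears. Homotypic cooperativities span [1, 10]. The site-count
model uses scaling factors in [1e8, 1e10] (linear by default, log10-uniform
by config — the choice changes census composition and is recorded in every
output) and cooperativities in [1, 100].

## The census

100,000 parameter vectors are drawn uniformly; vectors whose pooled Pearson
correlation is strictly greater than 0.981 are kept and classified by three
strict inequalities (DTr > DTv, TTr > TTv, SSr < SSv; ties fail, a
measure-zero event under continuous sampling) into 8 categories from "all
correct" to "all wrong". The Dorsal-Twist predicate can optionally require a
fold margin (DTr > fold·DTv). On the synthetic profiles the acceptance rate
is far higher than the ~0.1% of the original analysis and the category
percentages are near-uniform: the synthetic targets saturate (expression ≈ 0
or 1 over most of the axis), so the correlation constrains mainly the on/off
boundaries — which the scaling factors set — and barely constrains the
cooperativities. That is the cooperativity-insensitivity phenomenon the
census exists to expose, in a more extreme form than the graded real
profiles produce; the plurality of "all correct" sets seen with real data
is not reproduced here.

## Known limitations and open choices

- The exact expression formulas of the emulated studies live in their
  supplements; the state-enumeration forms here preserve the two properties
  the analyses rest on (quenching only in the numerator; cooperativity in
  both), but are not verbatim reconstructions, and only one
  distance-binning scheme ships as a default.
- The averaged-local weighting is an open choice; under both provided
  weightings, the shared scaling factor R has the largest averaged
  elasticity on the default panel (it aggregates residual changes across all
  12 constructs), so this method does not reproduce the
  quenching-above-scaling ordering that the variance-based methods show.
- Problem sizes (10,000 HDMR/averaged-local samples, eFAST budgets from the
  Nyquist minimum, 100,000 census draws, 11 gradient conditions, 60 axis
  positions) are the defaults used throughout the tests and the acceptance
  script.
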