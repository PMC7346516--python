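# Methods

## The release problem

A data holder owns a table of individual health records.  Each record carries
*dimension attributes* `A_1..A_q` — quasi-identifiers such as age, sex and a
region code that an adversary may know from outside sources — plus one
*informative attribute* with a large categorical domain (here: a disease
code) that is the target of later analyses and must stay in raw form.  The
goal is to release record-level microdata under ε-differential privacy: for
any two datasets differing in one record, the probability of any released
output changes by at most a factor e^ε.

Adding Laplace noise to a full contingency table achieves this but injects
noise into *every* cell of the attribute cross-product, which explodes with
dimensionality and with the informative domain size.  The method implemented
here (IPA — informative-attribute preserving anonymization) instead perturbs
the microdata itself with three coordinated operations and never touches the
informative values of real records.

## The mechanism

**Generalization.**  Each dimension attribute has a fixed taxonomy tree
(leaves = raw values, root `*`).  A *node* of the generalization lattice
assigns one level per attribute; all values are replaced by their ancestors
at that level (full-domain generalization).  Records sharing a generalized
tuple form an equivalence class.  Generalization itself spends no budget:
the boundaries are fixed by the taxonomy, not by the data.

**Suppression** (budget `ε_suppression`).  A single noisy threshold
`t + Lap((t−1)/ε_suppression)` is drawn per candidate; classes with at most
that many records are dissolved, their records released with every dimension
value set to `*` (informative value kept).  The threshold's sensitivity is
t−1, which forces t ≥ 2.  Suppression hides which classes exist, so empty
domain classes need no counterfeit mass.

**Counterfeit insertion** (budgets `ε_insertion`, `ε_value`).  Each kept
class's released size is `n + round(Lap(1/ε_insertion))`.  Positive noise
inserts counterfeit records carrying the class's generalized key; negative
noise deletes uniformly chosen real records (the class floors at empty).
Each counterfeit's informative value is drawn by an exponential mechanism
whose score is the class's pre-insertion value frequency,
`count(v)/(n+1)` for values present in the class and
`1/((n+1)(|Inf|−|Inf_i|))` shared uniformly by absent values, with
sensitivity bound ΔS = 1 (scores lie in (0,1)).  Counterfeit values
therefore track the class's real composition without reading any single
record too closely.

**Candidate selection** (budget `ε_candidates`).  One candidate is produced
per lattice node and scored by its information loss

    IL = NCP + EMD + Rate,          u = 3 − IL,

where

* **NCP** — mean normalized certainty penalty per released record and per
  dimension attribute: a label covering `|v|` of `|L|` leaves costs
  `|v|/|L|` (0 for raw values, 1 for `*`).  Dividing by both the record
  count and the attribute count keeps NCP in [0, 1]; a fully suppressed
  dataset scores exactly 1.
* **EMD** — half the L1 distance between the informative-value distributions
  of the original and the released dataset over the shared ordered domain
  (the categorical earth-mover's distance, at most 1).
* **Rate** — the unweighted mean over kept non-empty classes of
  (counterfeits)/(released class size); the suppressed bucket receives no
  counterfeits and is excluded.

Each component moves by at most 1 under a one-record change, so ΔIL = Δu = 3,
and the released dataset is drawn with probability ∝
`exp(ε_candidates · u / (2·3))`.  The total guarantee, by sequential
composition, is `ε_suppression + ε_insertion + ε_value + ε_candidates`.

### Accounting tension

The selection step scores a perturbed candidate for *every* lattice node,
yet the four-term total charges the perturbation budgets once.  This package
implements that accounting as stated; users who prefer to charge every
node's perturbation separately can pass `accounting="strict"`, which divides
the first three budgets by the node count so that the per-node charges
re-compose to the same total.

### Fixed numerical choices

* Laplace draws use the inverse-CDF of exactly one uniform each, so every
  stage consumes a fixed, documented number of variates; one master seed
  per run, with per-stage and per-node child streams derived by hashing, so
  a change in one stage never shifts another's draws.
* The real-valued insertion noise rounds to the nearest integer with ties
  away from zero.
* Counterfeit-value scores use pre-insertion class counts for all counterfeits of a
  class (insertions do not update the histogram mid-class), making the
  inserted set order-independent.
* The noisy suppression threshold is one draw per candidate (the threshold
  is a single protected quantity of sensitivity t−1); a per-class-draw
  variant exists behind `threshold_per_class=True`.
* Negative insertion noise deletes records by default (`mode="symmetric"`),
  preserving the two-sided noisy-count distribution; `mode="clamp"` floors
  deltas at zero but weakens that argument.
* Released rows are sorted (classes by key, rows by informative value,
  suppressed bucket last) so output order leaks nothing about insertion
  order.  Ties in u are resolved only by the exponential sampling itself —
  a deterministic tie-break would break the selection's privacy argument.
* Counterfeit flags never appear in the public output; they are retained in
  a separate audit frame for the data holder only.

## Baselines

*k-anonymization*: deterministic full-domain search returning the
minimum-IL node after suppressing classes smaller than k (a strict
no-suppression mode is available).  No budget is spent — this is the
syntactic baseline the DP method is measured against.

*Noisy contingency table*: the full cross-product of the generalized
domains (informative attribute included, absent combinations included) with
independent `Lap(1/ε)` on every cell, rounded and clamped at zero.  Its loss
is computed from the microdata implied by repeating each cell's rounded
count, with cell excess over the exact count scored as counterfeit mass.
The baseline's node is chosen as the minimum-loss node by exhaustive search
with no budget charged for the choice — a deliberately generous treatment —
and a configurable cell cap guards the combinatorial blow-up (nodes whose
cross-product exceeds the cap are skipped).

## Query evaluation

Utility studies compare filtered group-by counts and group-by means (e.g.
stroke patients per 5-year age band among men) between original and released
data.  On released data a generalized label's count mass is split across
query buckets proportionally to leaf overlap, equality filters match when
the filter value falls inside the label's extent, and means use the label
midpoint as the value surrogate.  On raw data these rules reduce exactly to
the standard answers.  The reconstruction rule is this package's own choice
— the simplest rule consistent with interval semantics — and the gap metric
is the mean absolute bucket difference with missing buckets read as zero.

## Synthetic data

`generate_synthetic` emulates a national claims sample: Age 0–99, Sex,
a 5-digit zip-like region code drawn from 18 region-representative values,
integer length-of-stay 1–30, a surgery flag, and a Disease code from a
50-value domain with Zipf-like frequencies (skew 1.0), optionally associated
with age decade.  Dimension attributes are uniform over their domains.
Defaults: 10,000 records, seed-reproducible.

With 18 observed region codes the Age × Sex × Region cross-product holds
~3,600 cells, giving roughly 3 records per cell at the default size — the
same records-per-class density regime as a multi-million-record national
sample over its full attribute domains.  Drawing region codes uniformly
from all 90,000 5-digit values would instead make every dimension tuple
nearly unique, pushing every lattice node into full suppression — a regime
in which no method comparison is informative.

**What the generator does not reproduce.**  Real claims data are heavily
skewed *in the dimension attributes* (age pyramids, urban concentration,
short-stay dominance), so most real records sit in large equivalence
classes at every node while a long tail of rare combinations makes
k-anonymity expensive.  The generator's uniform dimensions do the opposite:
class sizes are nearly equal, so low lattice nodes are uniformly sparse and
k-anonymity is nearly free.  Consequences for the test suite, measured at
n = 10⁴ on the Age/Sex/Zipcode subset (ε = 1 split 0.1/0.3/0.3/0.3, t = 5,
k = 10):

* The budget trend replicates: mean IL falls from ≈0.63 at ε = 0.5 to
  ≈0.58 at ε = 2 over 20 seeds.
* The method-ordering comparisons do **not** replicate and their acceptance
  tests fail by design rather than being weakened.  With Δu = 3 and
  ε_candidates = 0.3 the selection weights differ by at most e^0.05 across
  the entire lattice, so the released node is nearly uniform over nodes and
  the mean IL (≈0.54) equals the lattice average; the baselines, granted
  free data-dependent minimum-loss node selection, score ≈0.42 (contingency)
  and ≈0.03 (k-anonymity).  On data whose lattice average is low and whose
  k-anonymity cost is high — the real-data regime — the ordering reverses.
  Passing or failing these directional tests therefore speaks to the
  synthetic regime, not to real claims data.

## Problem sizes

Worked-example tests run on the 5- and 7-record reference tables (<1 s).
Distributional checks use 10⁵ draws (3σ tolerances) and 10⁶ draws for the
insertion-stage ratio bound.  Sensitivity enumerations brute-force all
one-record neighbors of random 5–6-record datasets over a 24-cell toy
domain.  Directional replications use 10–20 seeded runs at 10⁴ records on
the three-attribute subset; the full five-dimension schema is exercised at
smaller sizes (its 10⁸-cell bottom cross-product cannot reach the study's
density regime at desk scale).

## Known limitations

* The exponential selection step is extremely weak at practical budgets
  (see above); this is a property of the published mechanism, faithfully
  reproduced, not of this implementation.
* The privacy argument for the four-term total (rather than one scaled by
  the node count) is implemented as stated and exposed as a documented
  accounting choice, not re-proved.
* The contingency baseline is a simplified stand-in for published DP
  histogram methods: generalized cross-product plus per-cell Laplace noise
  with a free node choice.
* Interval taxonomies require aligned, nested band widths that divide the
  domain span; arbitrary irregular hierarchies must be enumerated
  explicitly.
* `ε` may be arbitrarily large (noise-free limits are used in tests);
  zero or negative budgets are rejected.
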