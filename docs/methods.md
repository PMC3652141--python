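# Methods

## The screening model

`nitroscreen` treats CNS candidate triage as three stacked filters plus a
quantitative partitioning estimate.

**Descriptors.** Nine per-compound properties: Log P, topological polar
surface area (PSA, Å²), heavy-atom count, formula weight (Da), H-bond
acceptor count (N + O atoms), H-bond donor count (hydrogens on N or O),
Rule-of-5 violation count, rotatable bonds, and molecular volume (Å³,
optional). When computed from structure, all of them delegate to RDKit:
Ertl fragment-contribution TPSA, Lipinski donor/acceptor conventions, the
default rotatable-bond pattern (acyclic single bonds between non-terminal
heavy atoms, amide C–N excluded; this reproduces 4 for lomustine), and
Crippen atom-contribution Log P. The donor count deliberately counts
*hydrogens*, not heavy atoms: a compound with one OH and one NH has 2
donors, which is the convention the reference descriptor table uses.

The reference 18-agent table was produced with a proprietary Log P and
volume calculator. The Crippen estimate agrees with those Log P values
only to within about ±1 log unit (lomustine: 2.25 vs 2.965), so all
statistics on the reference set use the tabulated Log P, and the computed
path exists for screening *new* structures. Molecular volume has no open
counterpart of the proprietary 3D-fitted group-contribution method, so it
is a pluggable callable and otherwise absent.

**Criteria sets are data.** CNS-A (FW ≤ 400, Log P ≤ 5, donors ≤ 3,
acceptors ≤ 7) and CNS-B (PSA ≤ 90 Å², FW ≤ 450) ship as `CriteriaSet`
objects; users can load others from JSON. Rule-of-5 boundaries are read
literally from the rule's wording: FW violates at ≥ 500 ("less than 500
daltons"), Log P at > 5 ("not greater than 5"), donors at > 5, acceptors
at > 10. A compound is drug-like at ≤ 1 violation.

**Partitioning.** Log BB = −0.0148·PSA + 0.152·Log P + 0.139 with
BB = 10^LogBB. The logarithm base is base-10; this is pinned by the
reference table (10^−0.325 = 0.473). Predictions are computed and stored
at full precision. For display the package follows the reference table's
own convention: Log BB is rounded half-away-from-zero to 3 decimals and
BB is 10 raised to the *rounded* Log BB. That convention is verifiable
from the table itself — for the most lipophilic agent, full precision
gives BB = 0.6626 (→ 0.663) while the printed 0.662 equals 10^(−0.179) —
and with it all 18 published BB values are reproduced exactly. One
published Log BB digit (agent 10, −0.416) is internally inconsistent:
the model gives −0.41664, and the published BB for that row (0.383)
equals 10^(−0.417); the tests treat that cell as a printing erratum with
a 0.001 allowance. Likewise the published rotatable-bond mean (2.3)
contradicts its own min/median/max (4/5/8); the recomputed mean is 5.28
and 2.3 is ignored.

## Statistics layer

* **Summaries** use sample standard deviations (n−1) everywhere — this is
  what reproduces the reference Log P SD of 0.5337 — and the
  mean-of-central-two median for even n.
* **Grubbs' ESD test** (two-sided, default α = 0.05): G = max|xᵢ − x̄|/s,
  compared with G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n)
  quantile of Student's t with n−2 df. The formula matches published
  critical-value tables to < 0.01 at n = 10, 18, 30. Requires n ≥ 3 and
  s > 0.
* **OLS** (statsmodels) refuses rank-deficient designs, naming the
  predictors loading on the null space. On the reference table, FW on
  (Log P, PSA, atoms, rotatable bonds) gives R² = 0.7934.
* **Path coefficients** come from the single-equation path model — every
  listed predictor a direct cause of the response — i.e. OLS on z-scored
  variables. Caveat documented in `PathResult`: with the reference
  table's seven predictors the weights explode (±10³) because PSA,
  acceptor count and donor count are almost perfectly collinear (all
  three separate the same hydroxylated compound); standardized weights
  from such a fit are not interpretable, and only the four-predictor
  model is stable.
* **ANOSIM** uses Clarke's statistic on mid-ranked Euclidean distances,
  R = (r̄_between − r̄_within)/(n(n−1)/4), which is 1 under complete
  separation and lies in [−1, 1]. The permutation p-value includes the
  observed statistic in numerator and denominator, and the RNG seed is a
  required argument. The grouping is a required user input: R depends
  entirely on it, and no canonical grouping exists for the reference set
  (the analysis driver uses hydroxylated-vs-not purely as an
  illustration). Calibration measured under the null (exchangeable data,
  random balanced labels): rejection rate 0.038 at nominal 0.05.
* **Clustering** is agglomerative single linkage on Euclidean distances
  (scipy). By default columns are z-scored first, dropping zero-variance
  columns with a logged notice — on the reference set the all-zero
  Rule-of-5 column. Standardization matters scientifically: raw distances
  are dominated by formula weight (isolating the heaviest compound),
  whereas standardized distances isolate the hydroxylated agent 12, whose
  PSA/donor/acceptor deviations are the chemically meaningful signal.
  Trees export as a merge table or Newick (heights as node depths).

## Synthetic data

`enumerate_analogs` attaches R-group fragments (25 built-in, spanning
cycloalkyl, alkyl, alkenyl, halogenated, hydroxyalkyl, ring and thio
chemistries, each with exactly one attachment point) to the fixed core
`[*:1]NC(=O)N(N=O)CCCl`; the cyclohexyl fragment reconstructs lomustine
exactly. Attachment is C-linked only, matching the reference analogs.

`simulate_descriptor_table` emulates the reference table's statistical
structure without the chemistry stack: Log P ~ N(2.524, 0.5337) truncated
to [1.0, 4.5] (bracketing the observed 1.537–3.924 with margin); PSA
fixed at 61.77 Å² except for a hydroxylated subpopulation at 82.0 Å²
carrying 6 acceptors and 2 donors (the agent-12 signature; default
fraction 1/18, realized as round(fraction·n) records at random positions
so the default gives exactly one per 18); heavy atoms uniform on 12–17
and rotatable bonds on 4–8; FW regenerated from the linear model
−24.859 + 0.9578·LogP − 0.04598·PSA + 19.236·atoms − 3.947·nRot plus
Gaussian noise (default SD 14 Da, roughly the residual scale of that fit
on the reference set) truncated to the 190–315 Da range. Tables are
bit-reproducible per seed. `screening_fixture(n_total, n_pass, seed)`
builds a library in which exactly `n_pass` compounds survive the combined
CNS + Rule-of-5 screen; the failures each violate one sampled criterion
(overweight, overly lipophilic, too polar, or too many donors).

What the simulator does *not* emulate: real R-group chemistry behind the
descriptor values (columns are sampled independently apart from the FW
link and the hydroxylation block, whereas real descriptors co-vary through
structure), measurement error in the descriptors, and any
activity/toxicity dimension. Tests passing on synthetic tables therefore
demonstrate the statistical machinery and the screening logic, not
chemical realism of new libraries.

## Numerical choices and degenerate inputs

* Display rounding is half-away-from-zero via `decimal` (banker's
  rounding would flip several 3-decimal reference values).
* Euclidean distances and OLS run in double precision; oracle tests
  compare against first-principles formulas at 1e−10.
* Empty tables: screening and summarizing refuse them; `bbb_table`
  returns an empty list; report writing refuses empty results rather than
  emitting an empty file.
* Single-linkage ties are resolved by scipy's deterministic merge order;
  on continuous data ties occur with probability 0, and the brute-force
  oracle comparison uses continuous random tables.
* Problem sizes in the test suite: oracle equivalences run at n ≤ 30,
  permutation calibration at 200 repeats × 199 permutations (n = 12),
  clustering-isolation stability at 100 seeded runs of n = 18 — sizes at
  which every check is exact or has negligible Monte-Carlo error.

## Known limitations

* The Log BB model is a two-descriptor linear QSAR fit to neurological
  drugs; it ignores active transport, efflux (P-gp) and metabolism, and
  extrapolates poorly outside PSA ≈ 0–120 Å².
* Computed Log P (Crippen) differs systematically from the proprietary
  calculator behind the reference values; screening verdicts near the
  Log P ≤ 5 boundary may differ between the two paths.
* Path-coefficient output is only as interpretable as the causal diagram
  behind it; the single-equation model is the simplest choice, not a
  validated causal structure.
* ANOSIM's R for the reference set depends entirely on the chosen
  grouping, which is not canonical; reported values should always state
  the grouping and seed.
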