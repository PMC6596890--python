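# Methods

## Model and assumptions

An individual is represented solely by a point on the (K−1)-simplex — the
proportions of their genome assigned to K putative ancestral gene pools by
ADMIXTURE — plus optional age and gender. The dissimilarity between two
individuals is the squared difference sum GD = Σₖ(iₖ−jₖ)², chosen over the
Euclidean norm so that many small component differences (typical of
admixed pairs) accumulate slowly while a single large difference dominates.
GD is bounded by 2, attained by two disjoint single-source profiles.

The match score discretizes similarity for human interpretation: one point
for a joint age-and-gender match (both conditions, one point — this is
what makes the nine-component maximum exactly 10) and one point per
component agreeing within the component tolerance. All comparisons are
inclusive (|Δage| ≤ window, |Δcomponent| ≤ tolerance); the component
comparison carries a 1e-12 guard so that a difference that is exactly the
tolerance in decimal does not fail through binary float representation.
Missing age or gender on either side withholds the demographic point —
the conservative choice, since awarding it would let undocumented
individuals outscore documented mismatches.

The matchers assume the Q rows describe unrelated individuals from one
inference run (a shared K and component order); they do not model
relatedness, batch effects between ADMIXTURE runs, or uncertainty in the
estimated proportions.

## The greedy sweep and the threshold

`pam_simple` is a single pass over the GD matrix in row order: each
surviving row takes its minimum-GD surviving column; ties go to the lowest
column index so the result is deterministic. Greedy pairing is O(n²),
scales to the cohort sizes where exhaustive matching is hopeless
((n−1)!! solutions), and — because each accepted pair is a row minimum —
errs only through "snowball" chains in which one poor assignment forces
the next. An even cohort is always fully paired; an odd one leaves exactly
one individual over.

The score threshold T exists to break those chains. Rejection semantics
matter more than they look. This package refuses the candidate pair but
leaves the rejected row *in the matrix*: it can still be claimed as a
later row's minimum-GD column at an acceptable score, and is unpaired only
if never claimed. Two tempting alternatives fail. Removing the rejected
row immediately strands its nearest neighbour, which then drifts to the
genetically closest *stranger* — and since a systematic perturbation moves
all perturbed individuals in the same direction, those strangers can be
close enough to score above T, manufacturing exactly the misassignments
the threshold should prevent. Removing both members of the rejected
candidate is worse: in removal ablations each unmatchable individual would
drag an innocent, still-matched individual into the unpaired list,
cascading. Under the retained semantics a rejected individual's nearest
neighbour stays put, so neither member of a low-scoring true pair ever
wanders.

`pam_full` trades time for solution quality: for each component c the
cohort is sorted ascending by c (stable sort), and the sweep is re-run
from `full_mode_starts` random rows (uniform over all rows, proceeding
cyclically); the incumbent is replaced only by a *strictly* smaller total
GD, so ties keep the earliest solution and the result is no worse than any
candidate examined, including the first. Every sweep starts from the full
cohort, so individuals unpaired in one pass re-enter the next. Cost is
K × starts sweeps ≈ an order of magnitude over `pam_simple` at the
defaults (9 × 10).

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `threshold` | None | score points | off by default: filtering is a design decision for the analyst; 7 (age/gender + six components) is the workhorse setting in the validation study |
| `age_window` | 5 | years | conventional epidemiological matching width |
| `component_tolerance` | 0.01 | proportion | 1%: at or below the resolution ADMIXTURE proportions are usually reported |
| `full_mode_starts` | 10 | starts/sort | enough restarts that each component ordering is explored from several phases without another order of magnitude of runtime |
| `seed` | None | — | seeds the random starts (`pam_full`) and all baseline randomness |

## The synthetic cohorts

The generator builds the study design the validation rests on: `n_pairs`
admixture vectors drawn i.i.d. from a symmetric Dirichlet(1) over K
components (equivalently, independent positives rescaled to sum to 1),
each copied to a clone partner; ages uniform integers on [18, 80] and
genders equiprobable, copied within each pair so demographics never
confound the genetic signal. Rows interleave the pair members, IDs
`P#####A`/`P#####B`.

Heterogeneity is injected by perturbing the B member of every pair:
component k is scaled by (1−x) for odd-numbered components and (1+x) for
even-numbered ones, then the row is renormalized. The signs alternate
because a uniformly scaled row would be restored exactly by
renormalization; the alternating pattern cannot be. The scaling is
multiplicative — a perturbation *of* x per cent of each component — which
keeps proportions in [0, 1] for x ≤ 0.2 without clipping (clipping is
still applied defensively) and yields a true-pair GD of roughly
x²·Σₖcₖ², growing smoothly with x. With nine components the odd-numbered
set has five members, so the pre-normalization row sum is 1 − x·(c_odd −
c_even), generally not 1; renormalization absorbs the imbalance.

Ablations delete k individuals uniformly at random, marking their
surviving partners partnerless in the truth map; an evaluation counts
such widows as correctly unpaired when left out and misassigned when
paired. The 24-dataset suite is one base cohort × 8 perturbation levels
{0, 2, 5, 8, 11, 14, 17, 20}% × {no removal, remove-1, remove-20},
giving sizes 1000/999/980 at the default 500 pairs. The perturbation grid
is a package choice: it spans the design range [0, 20%] uniformly and
includes the 5% and 11% levels at which the thresholded matcher's
behaviour changes qualitatively.

What the generator does **not** emulate: real cohorts have correlated,
clustered ancestry profiles (not Dirichlet-independent), relatedness,
genotyping and ADMIXTURE estimation error, and no exact clones. Passing
the validation shows the algorithms do what they claim on their own
representation; it is not evidence about accuracy on real genotype data,
where the admixture model itself may misfit. One visible sensitivity: the
fraction of individuals passing threshold 7 at the 11% perturbation
(~30–40% here) depends on the spread of the component distribution, which
the clone-pair design does not pin down.

## Baselines

Race labels are inferred from component roles in the canonical
nine-component model (rule order: African if Sub-Saharan + South Africa
> 50%; else Asian if North East Asia > 10%; else Latino if Native America
> 50%; else White — first match wins, and the thresholds are strict
inequalities). Models 1 and 2 pair uniformly at random within
age-window/gender/label-compatible partners, greedily over a shuffled
order; model 3 collapses the nine components to four macro-ancestry
fractions (African, Asian = NE + SE Asia, Latino, White = remainder) and
runs the greedy GD sweep on those, with no score threshold (thresholds
are calibrated to the nine-component score scale, whose collapsed maximum
is 5). Reported per-pair GD and score always come from the full
nine-component vectors so solutions are comparable across methods. The
PCA baseline projects any per-individual feature matrix onto its top two
principal components, clusters with k-means, and pairs randomly within
clusters; k has no default because nothing in the method selects it.

## Numerical and degenerate-input choices

- Totals are accumulated in double precision; zero-GD checks in tests use
  1e-9…1e-12 absolute tolerances.
- The GD matrix is symmetrized as (D + Dᵀ)/2 after computation so float
  summation order cannot break the symmetry invariants.
- Greedy ties: lowest column index (first `argmin` occurrence); `pam_full`
  incumbent ties: keep the earlier incumbent.
- Q rows whose sum is within 1e-3 of 1 are renormalized on read; further
  off is an error. Admixture vectors are validated to the simplex within
  1e-6 at construction.
- Cohorts of fewer than two individuals raise a dedicated error for every
  pairing operation; mixed K raises a dimension error.
- fam parsing: age ≤ 0 or −9 and genders outside {1, 2} are treated as
  missing, matching common PLINK conventions; the default column layout
  (age in column 4, gender in column 6) follows the Q-companion dialect,
  with `plink_standard` switching to stock PLINK (sex in column 5, no
  age).

## Validation scale

The test suite and `scripts/acceptance.py` run the full 500-pair (1000
individual) design for the headline checks and 5 seeds for the stochastic
ones; property tests use cohorts of 2–60 with a brute-force
perfect-matching enumeration as the optimality oracle at n ≤ 10. The
complete suite runs in well under a minute on one CPU.

## Known limitations

- Greedy matching carries no optimality guarantee; the brute-force oracle
  bounds it from below only at toy sizes. An exact minimum-weight
  non-bipartite matcher is intentionally out of scope as the primary
  algorithm.
- `pam_full` explores only component-sorted orderings; its improvement
  over the single sweep is empirical, not guaranteed per instance.
- The race-label rules and the component-role mapping are specific to the
  canonical nine-component world model; other K require a user-supplied
  role mapping.
- Geographic evaluation assumes a spherical Earth (radius 6371 km).
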