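# Methods

## The process

`pairmhn` models a patient's cancer as a continuous-time Markov chain over
binary genomic events in two coupled lesions. A state is a bit string
`(x1P, x1M, …, xnP, xnM, xseed)`; events accumulate irreversibly, one
transition at a time. The chain has four transition classes:

1. **Shared phase** (`xseed = 0`): the metastasis precursor is still part
   of the primary, so event `i` flips both of its bits at once at the
   classical Mutual-Hazard rate `Θii ∏_{j shared} Θij`. States with
   diverged genotypes and `xseed = 0` are formally part of the bit-string
   space but unreachable; they are excluded from reachable enumeration and
   pinned to zero mass (their rows in dense solves carry a unit diagonal
   so operators stay non-singular).
2. **Seeding**: flips `xseed` at rate `Θss ∏_{j shared} Θsj`. It is the
   last event the two lesions share.
3. **Post-seeding progression**: the primary gains event `i` at a rate
   depending only on its own genotype; the metastasis likewise, times the
   environment effect `Θis`. This conditional independence given the
   seeding state is what all fast paths below exploit.
4. **Observation**: detection of the primary (rate `∏_{j∈PT} ΩPj`, times
   `ΩPs` after seeding) or of the metastasis (only after seeding, rate
   `ΩMs ∏_{j∈MT} ΩMj`) absorbs the system. The wild-type primary
   detection rate is the empty product, exactly 1: all rates are measured
   relative to it, which is the model's identifiability convention for the
   unobservable time scale.

Everything is parameterized on the log scale; "rate exactly zero" is
represented by the floor `LOG_RATE_FLOOR = −30` (`exp(−30) ≈ 9·10⁻¹⁴`)
rather than `−∞`, so every linear operator stays well-posed while the
transition is dynamically irrelevant. Generators use the column
convention `Q[y, x] = rate(x → y)`; dense generator columns sum to zero.

## Likelihood of the five record types

The distribution at first observation is `UP(US−Q)⁻¹p0` and
`UM(US−Q)⁻¹p0` (never an explicit inverse; LU or triangular solves). For
a pair observed primary-first, the state distribution is conditioned on
the observed primary genotype, renormalized, and the metastasis is
propagated with `UM(UM−QM)⁻¹` until its observation; metastasis-first is
the mirror construction; an unrecorded order is the sum of both.
Seeding cannot occur after the first observation: the propagation operator
contains only single-lesion dynamics, so conditional mass still in the
shared phase contributes exactly zero to a later metastasis observation.
The solve is restricted to the seeded subspace, which implements this
limit without inverting a singular operator.

Single-genotype records marginalize the unobserved lesion. A
metastasis-only record sums the order-marginal pair probability over all
primary genotypes; a primary-only record with evidence that no metastasis
exists is scored as the probability that the primary is observed first
with the seeding bit still 0 (the only reading of "sum over the shared
subspace" compatible with the propagation semantics above — pair
probabilities vanish there); with a known-but-unsequenced metastasis it
sums pair probabilities over metastasis genotypes; with unknown status it
adds the last two. These conventions make the primary-only probabilities
sum to exactly 1 over genotypes and evidence, which the tests assert.

Per-sample probabilities below `1e−300` raise an error carrying the
patient id instead of silently underflowing.

## Restricted state spaces and gradients

The dense construction is exponential in `2n+1` and only used as an
oracle (guarded at `n ≤ 4` for the dense extended generator, sparse full
space up to `n = 10`). Production likelihoods run on per-sample
sub-lattices:

- **Paired samples**: events absent from both genotypes are frozen at
  zero. Paths that reach the observed states never leave the sub-lattice;
  pruned events act only through the total exit rates, which are kept in
  the diagonal, so the restriction is exact, at cost `O(2^k + 4^k)` for
  `k` present events.
- **Unpaired samples**: the unobserved lesion is marginalized exactly by
  a reduced chain over (own genotype, seeding). After seeding, the other
  lesion's bits influence neither the tracked lesion's transition rates
  nor its detection rate, and observing the other lesion does not change
  the tracked lesion's law; the only cross-lesion coupling is the
  pre-seeding primary-detection hazard, which halts the system and makes
  a metastasis unobservable. The reduced chain keeps exactly that hazard
  as a kill term. Cost `O(2^k)`.

Both reductions are verified against the dense oracle to `1e−9` (in
practice they agree to machine precision). Every rate in a restricted
stage is a single exponential `exp(a·ξ)` of the flattened parameter
vector with a 0/1 incidence row `a`; the stage operator `D − R` is lower
triangular in lattice order, so likelihoods are forward substitutions and
the gradient of each sample probability comes from one transposed
(adjoint) solve per stage plus an incidence-matrix contraction. Identical
sample configurations in a dataset are grouped and computed once.

## Inference

The objective is the mean log-likelihood minus `λ` times the penalty

    ∑_{i<j} sqrt(θij² + θji² − θij·θji) + ∑_j (|ωPj| + |ωMj|),

one square-root term per unordered event pair (the radicand equals
`(θij − θji/2)² + ¾θji²`, hence nonnegative), which shrinks effect pairs
jointly and promotes symmetric selection. A plain quadratic variant
(`penalty_variant="quadratic"`, same terms without the root) is kept for
comparison but does not produce sparsity. Base rates `θii` and the
scale-setting observation entries `ΩPs`, `ΩMs` are never penalized.
Near zero the gradient uses `ε`-smoothing with `ε = 1e−10`; the reported
penalty value is unsmoothed.

Optimization is gradient ascent with a backtracking Armijo line search
(initial step 0.5, shrink 0.5, growth 1.3, sufficient-decrease constant
`1e−4`), so the accepted-iterate objective trace is non-decreasing by
construction. Default initialization sets all interactions to zero, each
base rate to the logit of the event's marginal frequency (the value that
matches the single-event closed form `Θ/(1+Θ)`), the seeding base rate to
the logit of the fraction of patients with evidence of metastasis, and
`ω = 0`. Convergence is declared when the relative objective improvement
drops below `convergence_tol` (default `1e−7`) or the gradient norm does.

`λ` is chosen by k-fold (default 5) cross-validation: patients are
shuffled with a dedicated seed and assigned whole to folds; the selection
statistic is the mean held-out **unpenalized** log-likelihood (the
penalized value would double-count the prior), and exact ties resolve to
the larger `λ`. Both the statistic and the grid are configuration fields
because neither has a canonical value.

## Synthetic cohorts

The simulator is an exact Gillespie sampler: waiting times by inverse-CDF
exponentials on the summed exit rate, jump identity by one uniform against
the cumulative rate vector. In `until_both_observations` mode the
not-yet-observed lesion continues under its restricted dynamics after the
first observation, mirroring the likelihood's consecutive-observation
semantics; a primary detected before seeding ends the history with the
metastasis forever unobservable. Each run draws from
`SeedSequence(entropy=seed, spawn_key=(run_index,))`, so cohorts are
bit-reproducible across platforms.

`CohortSpec` defaults emulate a large lung-adenocarcinoma clinical cohort:
46.85% primary-only, 43.87% metastasis-only, 9.28% paired records, with
the realized observation order and the latent seeding status at primary
observation recorded (both can be masked to "unknown"). Patients assigned
a metastasis-bearing record type whose history never produced an
observable metastasis are redrawn; their probability mass corresponds to
patients who could never have contributed such a record. Two features of
real data are deliberately **not** emulated: sequencing noise /
panel-coverage differences (genotypes are read off the latent state
exactly) and the clinical selection process that determines which tumor of
a patient gets sequenced. Because record types are assigned exogenously
rather than generated by a model of sequencing choice, the composite
likelihood's implied record-type composition does not exactly match the
generator's mixture; the residual bias shows up as mild shrinkage of
fitted parameters toward configurations favoring observable metastases,
and the recovery experiment quantifies the net effect (Pearson r ≈ 0.9 at
5000 patients). Passing tests therefore demonstrate correctness of the
likelihood, gradients, and estimator under the model's own observation
process, not robustness to assay noise or cohort selection.

The reference ground truth for recovery experiments
(`example_sparse_network`) has four events with base rates between
`e^{−1.5}` and `e^{−0.3}` relative to wild-type detection, five directed
effects of magnitude ≥ 1 with mixed signs — including one promoter of
seeding and one post-seeding suppression — and two mild observation
effects; sparse, strong, mixed-sign networks of this shape are what the
method is designed to detect at realistic cohort sizes.

## Timing reconstructions

The most-likely ordering of a sample's events maximizes, over all
interleavings consistent with the observed genotype(s) and (if known) the
observation order, the product over jumps of
`rate / total exit rate` — the embedded jump chain of the sample's
restricted process, with observation events as competing exits and the
terminal observation factor included. The maximizer is found by dynamic
programming over the restricted sub-lattice (exact; verified bit-equal
against exhaustive path enumeration); ties are broken deterministically by
processing transitions in event-index order and keeping the first
maximum. For paired samples with unrecorded order both orders are
maximized and the winner reported. The default cap of 14 present events
mirrors the practical infeasibility of branched reconstructions for
hypermutated samples (the paired sub-lattice grows as `4^k`).

Relative positions in a linear chain of `L` events (seeding counts,
observations do not) are `(k−1)/(L−1)` for rank `k`, mapping the
initiating event to 0 and the final event to 1; a singleton chain maps to
0. Pre-seeding probabilities are estimated by Monte Carlo as the fraction
of conditioning histories in which the event's occurrence in the relevant
lineage happened in the shared phase; histories without any seeding count
as pre-seeding for primary-tumor conditioning. The exact cross-check
decomposes every history at the seeding jump: a forward solve on the
shared lattice gives the seeding (and pre-seeding-detection) flux per
shared genotype, and triangular absorption solves on the single-lesion
lattices give the detection-genotype distribution from each entry state.

## Numerical choices

- Linear systems: sparse LU on the full space; dense
  `solve_triangular` on restricted stages (they are triangular in lattice
  order by construction). No iterative solvers, no explicit inverses.
- All probabilities accumulate in double precision; restricted solves are
  forward substitutions with strictly positive diagonals.
- Dense-oracle guard: `n ≤ 4` for the extended dense generator
  (`(3·2^{2n+1})²` memory), overridable.
- Problem sizes in the shipped verification suite — 200 models at
  `n ≤ 3` for conservation, 20 models for oracle equivalence, `10⁵`
  Gillespie runs per model for simulator agreement, 5000 patients for
  recovery — were chosen so each property is measured at tight tolerance
  on commodity hardware.

## Known limitations

- One metastasis per patient; no reseeding, no metastasis-to-metastasis
  spread, no subclonal structure (states are consensus profiles).
- The composite likelihood takes the record-type mix as given; cohorts
  whose composition misrepresents the patient population bias the seeding
  parameters (over-representation of metastases inflates the seeding
  rate), a property inherited from the model family.
- Events are irreversible and binary; copy-number dosage and reversions
  are out of scope.
- Paired-sample cost grows as `4^k` in the number of events present, so
  heavily mutated pairs must be capped or excluded.
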