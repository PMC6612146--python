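# Methods

## Problem and model

Given a query MS/MS spectrum and a list of candidate molecules, the task is
to rank the candidates so the true structure comes first. Each candidate is
fragmented in silico by bond disconnection, its fragments are assigned to
the observed peaks, and the candidate receives a consensus score

    S_Fin = ω1·S_MetFrag + ω2·S_Peak + ω3·S_Loss

with non-negative weights summing to one.

The statistical terms rest on a conditional model of fragment annotation.
For a peak with (discretized) mass m explained by a fragment with
fingerprint f̃, the model carries θ_{m,f̃} = P(f̃ | m); assignments of
different peaks are treated as independent, so the spectrum-level
likelihood factorizes into a product over peaks. This deliberately ignores
multi-stage fragmentation (peaks that co-occur because one fragment
fragments further); modelling those dependencies is out of scope.

Fragment equality is fingerprint equality. Two structurally different
fragments with identical fingerprints are the same outcome — a feature,
not a bug: it keeps comparisons constant-time and pools evidence across
near-identical substructures. Neutral losses are modelled the same way:
for peak pairs m_k > m_h whose fragments satisfy f_h ⊂ f_k (atom-index
subset within one candidate) and whose difference f_k ∖ f_h is connected,
the loss mass l = m_k − m_h is annotated with the difference structure.

### Estimation

Maximum likelihood (relative frequency) is reported for diagnostics, but
scoring uses the mean-posterior estimate under a product Dirichlet prior:

    P(f̃ | m) = (N_{m,f̃} + π_{m,f̃}) / Σ_{f̃'} (N_{m,f̃'} + π_{m,f̃'})

where π is α for every real fingerprint and β for the ⊥ outcome ("no
fragment explains this peak"). ⊥ is never observed during training —
training uses only correct candidates, so an unexplained peak carries no
evidence about wrong annotations — hence N_{m,⊥} = 0 and the entire ⊥ mass
comes from β. Losses use separate pseudo counts α_L, β_L. Because all
pseudo counts must be positive and ⊥ is always in the outcome domain, no
conditional probability can reach 1 and the raw score
1/(−Σ log P) is always finite.

The outcome domain is the set of fingerprints observed in training,
extended at query time by the fingerprints of the current query's
candidates. One global fingerprint domain is used in the denominator (not
a per-bin domain); unseen bins and fingerprints are handled as zero-count
lookups, never by mutating the fitted tables — the fitted model is
immutable. Masses outside the binned range are likewise scored as
zero-count rows.

### Discretization

Measured masses cannot be compared exactly, so the m/z axis is cut into
half-open bins [b_i, b_{i+1}) with

    b_{i+1} = b_i + 2·(b_i·mzppm/10⁶ + mzabs)

and every mass is represented by its bin center. Half-open intervals (the
bin definition is otherwise ambiguous at boundaries) and the lower
boundary as the argument of the ppm term are the literal readings adopted
here. One binning, sized from the phase-1 training annotations (peaks and
losses share it, since losses are mass differences on the same axis),
serves the whole model; b0 defaults to the minimum observed annotation
mass minus one bin width.

### Scores

Per candidate: S_RawPeak = 1/(−Σ_k log P(f̃_k|m_k)); S_Peak is S_RawPeak
divided by the per-query maximum so the best candidate scores exactly 1
(all-zero lists normalize to all zeros). S_Loss is defined analogously; a
candidate with no loss assignments receives raw score 0. ⊥ losses at query
time (pairs of annotated peaks whose difference is not a valid loss) are
off by default (`loss_bottom_pairs`), since the training tables contain no
⊥ rows to calibrate them against.

S_MetFrag here is a simplified fragmenter score, not a port of MetFrag's
published one: Σ over explained peaks of rel_intensity^0.6 ·
(mz/precursor_mz)³, discounted multiplicatively by a saturating
broken-bond-energy penalty, total·(1 − λ·E/(1+E)) with λ = 0.2 and E the
summed bond-disconnection energies of the fragments used (bond order as
energy: 1, 1.5, 2, 3). A multiplicative discount was chosen over a
subtractive penalty because a subtraction can exceed the mass-weighted sum
for light-fragment candidates and clamp entire candidate lists to zero.
The term is pluggable; nothing in the statistical model depends on its
absolute values, only on its [0, 1]-after-normalization contract.

## Fragmentation

Breadth-first bond disconnection to depth 2 by default: at each level every
acyclic bond of a fragment is removed and the two components become
children; ring bonds are removed pairwise (a single ring cut does not
disconnect). Duplicate atom sets keep the cheapest generation path.
Fragment masses are computed on the hydrogen-capped neutral fragment (open
valences saturated with H); the synthetic spectra are generated under the
same convention, so training and scoring are mass-consistent. Real spectra
involve hydrogen rearrangements this convention does not model.
Ionization is a ±1.00728 Da proton adjustment (positive/negative mode),
with an explicit adduct-shift override available. Peak assignment picks
the fragment with smallest mass deviation within mzabs + mzppm·mz/10⁶;
exact ties go to the smaller broken-bond energy, so the result is
independent of fragment enumeration order.

## Training procedure

1. **Split.** Unique InChIKey first blocks are shuffled (seeded) and split
   70:30; all spectra of a block stay together, so no molecule leaks
   between phases.
2. **Phase 1 (counts).** Each phase-1 spectrum is assigned to its correct
   candidate's fragments; explained peaks have their m/z *corrected to the
   theoretical fragment mass* before discretization (removing instrument-
   specific mass error from the tables); ⊥ peaks are dropped. Loss
   assignments are computed from the corrected masses. Spectra whose
   precursor is inconsistent with the labelled candidate mass (beyond 3×
   the tolerance) are skipped with a warning.
3. **Phase 2 (optimization).** Each phase-2 spectrum is ranked with its
   correct candidate plus up to 500 decoys (seeded down-sampling). The
   pseudo counts are optimized by grid search over all combinations of
   {0.0025, 0.0005, 0.0001} per axis (3⁴ = 81 sets); weights by 1000
   triples sampled uniformly on the simplex (Dirichlet(1,1,1)), drawn once
   and reused across extension rounds. The objective is the Top1 count.
   If the optimum lies on the border of any axis, that axis is extended by
   ×5 (or ×1/5) per round until the relative Top1 improvement falls below
   1%. Ties resolve to the lexicographically smallest hyper set, then the
   smallest ω1. The evaluation is vectorized over the grid; a test
   verifies it against scoring every combination sequentially through the
   model path.
4. **Finalize.** Counts are recomputed on the *entire* training set
   (phases 1 + 2) with the optimized parameters frozen, enlarging the
   observation domain for query scoring.

Positive and negative mode are trained independently; a model carries one
polarity. With fixed seeds the whole pipeline is bit-reproducible, and the
fitted model round-trips losslessly through its JSON + TSV serialization.

## Fingerprint backends

Four roles, selected by `fingerprint_function`; the model is agnostic to
exact bit semantics — only the induced equivalence classes matter:

| id | construction | length |
|----|--------------|--------|
| `maccs` | RDKit MACCS substructure keys | 167 bits (166 keys + reserved bit 0) |
| `circular` (default) | Morgan radius 2, folded | 1024 bits |
| `path_lingo` | canonical-SMILES q-grams (q = 4), SHA1-hashed | 1024 bits |
| `graph_only` | RDKit path fingerprint on the bond-order-stripped skeleton | 1024 bits |

`graph_only` is blind to bond order by construction (benzene and
cyclohexane collide). The folded length (1024) and q-gram length (4) are
configuration constants; they change collision rates and therefore the
granularity of the learned conditionals.

## Synthetic benchmark

The fixture generator (`fragscore.synth`) makes the full train → score →
rank path runnable with no external data. Default conditions: 30 training
molecules with 3 replicate spectra each, 10 held-out query molecules, 20
mass-matched decoys per query, 5 ppm peak jitter, 10% fragment dropout, 3
noise peaks, exponential intensities, positive mode, top-40 peak filter.

What it emulates, and how:

* Molecules are small connected C/N/O structures (4–12 heavy atoms)
  assembled by joining 2–3 motifs from a fixed alphabet (ethyl/amino/
  ether/branched/ring blocks). The shared alphabet makes fragment
  vocabulary recur across molecules, as substructures recur across real
  metabolites — this is what lets held-out query molecules produce
  fingerprints the model has seen, and it is one half of the benchmark's
  separability guarantee.
* Spectra are the molecules' own depth-2 fragment masses (proton-adjusted,
  jittered), so the correct candidate can explain nearly every true peak
  at tolerance.
* Decoys are drawn from a disjoint molecule pool within ±50 Da of the
  query precursor, but capped so no decoy's fragments can explain more
  than 60% of the query's true peaks — the other half of the separability
  guarantee. Without the cap, near-isobaric toy decoys explain essentially
  all peaks of small molecules and no scoring scheme can separate them.
* Replicate training spectra (3 per molecule) keep the phase-2 set large
  enough (~27 spectra) that the Top1 objective does not saturate into
  massive ties; with ~9 spectra the tie-breaking picks degenerate weight
  triples. Real spectral libraries are similarly replicate-rich.
* Intensities are synthetic draws; the statistical scores never use
  intensity (only the top-40 filter and the fragmenter term do), so a
  simple exponential model suffices.

What passing the benchmark does **not** show: performance on real spectra.
The fixtures have no rearrangement chemistry, no hydrogen shifts, no
adduct or isotope patterns, no realistic intensity structure, and a
candidate space vastly smaller and cleaner than a compound database. The
benchmark validates the machinery (counting, estimation, optimization,
ranking), not chemical realism.

## Numerical and design choices

* Merged replicate spectra: peaks pooled, grouped greedily in ascending
  m/z within 2·(mzabs + mzppm·seed/10⁶) of the group seed, each group
  contributing its plain-mean m/z (not intensity-weighted) and maximum
  intensity; the pass is iterated to a fixpoint so merging is idempotent.
* Top-k peak reduction breaks intensity ties toward lower m/z.
* Rank of the correct candidate counts score ties as better (worst-case
  rank) by default; a mid-rank convention is available
  (`tie_convention="mid"`).
* Candidate lists are cleaned before scoring: disconnected structures and
  non-natural isotopes are dropped; stereoisomers are collapsed by
  InChIKey first block keeping the best-scoring representative.
* ML parameter-recovery checks use 10⁴ sampled assignments per bin row of
  a planted 5×5 conditional distribution; at that size the per-row L1
  error bound of 0.05 holds with a wide margin (expected L1 ≈ 0.016),
  whereas spreading 10⁴ samples across all five rows would make the bound
  a near-coin-flip.
* All randomness flows through numpy Generators seeded from a single user
  seed; derived seeds stay below 2³¹.

## Limitations

* The fragmenter term is a simplified stand-in, not MetFrag's published
  score; absolute consensus values are not comparable to MetFrag's.
* Ionization is modelled as plain (de)protonation; multi-charge ions and
  exotic adducts are out of scope (the adduct shift is configurable).
* The independence assumption ignores fragmentation cascades.
* Hyper-parameter optimization maximizes Top1 only, as a discrete count;
  on small phase-2 sets it ties easily and falls back to deterministic
  tie-breaking.
* Live spectral/compound database retrieval is out of scope; inputs are
  local MGF/MSP files and TSV candidate lists.
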