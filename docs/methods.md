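# Methods

This note documents the models implemented in `codamc`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical choices a user may want to revisit.

## Ground-truth fixtures

The published record constrains the *architecture* of the two ribozymes'
functional regions — two stems (P1, P2) joined by two internal loops into a
lantern, plus a mutation-insensitive stem-loop region (SL2); stem sizes 6
and 5 pairs (LINE-1, one non-canonical A·A closing P1) and 5 and 4 pairs
(OR4K15, one G·U wobble); internal-loop sides of 6 and 5 nt, with the
6-nt loop carrying the conserved C·A cleavage site; the two catalytic
loops identical between the ribozymes except for one tolerant base
(U38 in LINE-1 vs C8 in OR4K15) — but not the full nucleotide sequences.
The shipped fixtures `LINE1_rbz` (46 nt) and `OR4K15_rbz` (47 nt) are
therefore **synthetic stand-ins** designed to satisfy all of those
constraints simultaneously; positions named in the literature that could be
honoured were (e.g. OR4K15's wobble G14·U33, whose singles G14A and U33C
convert it to Watson–Crick and *raise* activity, and its C40-A41 cleavage
site). In the simplified fixtures SL2 is represented as the unpaired
hairpin loop closing P2, kept free of G/U so it cannot form spurious
helices; a real SL2 contains its own short stem. `toy_hairpin` (12 nt,
4-pair stem) exists for enumeration-oracle tests.

## Activity model

Variant activity is multiplicative over independent lesions:

* a disrupted true pair multiplies activity by `delta_pair_break` (0.1);
* a mutated conserved catalytic-loop position by `delta_loop` (0.05);
* a substitution set that leaves a true pair Watson–Crick, wobble, or at
  its planted non-canonical identity pays no penalty (compensatory rescue);
* converting a wobble pair to Watson–Crick multiplies by `wobble_gain`
  (1.6 > 1);
* the product is capped at `activity_cap` (2.0).

The defaults span the printed relative-activity range (≈0.03–1.8) without
saturating the cap. Multiplicativity is itself a modelling decision: it
reproduces exactly the independence baseline that CODA assumes, so any
deviation in synthetic data is attributable to the planted pairs — which is
what makes recovery tests meaningful. Real epistasis is not purely
multiplicative; passing these tests demonstrates correctness of the
inference machinery, not robustness to arbitrary epistatic structure.

The wild-type cleavage probability `p_wt` (0.5) is a free parameter of the
sequencing model (no published value constrains it); a variant cleaves with
probability `min(activity × p_wt, 1)`.

## Library and sequencing simulation

*Doped* libraries mutate every position independently at the doping rate
(default 0.06, the published synthesis rate), alternatives uniform.
*Error-prone* libraries emulate PCR bias: A/U template positions are twice
as mutable as G/C positions and transitions three times as likely as each
transversion (the direction of bias is documented, the magnitudes are not;
2× and 3× are typical Taq figures). The per-position rate is scaled so the
across-position mean equals `doping_rate`.

Default library size is 5×10⁵ molecules (the published template count) and
default sequencing depth 5×10⁶ reads per channel (HiSeq-scale). With a
46-nt region these defaults put the expected read count of every specific
double mutant near 50, which reproduces the >99% double-mutant coverage
regime at the default 20-read filter. In *capture* mode both channels are
exact-depth multinomials (DNA-seq follows library abundance, RNA-seq
follows abundance × cleavage probability × capture efficiency — the
efficiency cancels in RA′). In *cleaved/uncleaved* mode one RNA pool of
`depth_rna` reads is drawn and each variant's reads split binomially by its
cleavage probability, so the total channel is exact-depth and the cleaved
channel is a thinning of it. No read-level artefacts (qualities, PCR
jackpots, barcode collisions, indels) are simulated.

## Activity estimation

RA and RA′ are the exact ratio-of-ratios printed above; the wild-type row
is 1 by construction. Variants are dropped when the denominator channel
has fewer than `min_reads` (default 20, bounding RA noise at roughly ±45%;
the original analysis does not state its filter) or when they carry more
than 3 mutations (the published analysis cutoff). Position profiles are
unweighted means over observed single mutants; positions without singles
are *missing*, never zero. Essential segments are maximal runs of
positions with mean RA below `ra_threshold` (0.5), bridging up to
`max_gap` (2) non-qualifying or missing positions and discarding runs
shorter than `min_len` (5); the gap allowance keeps under-sampled
positions in error-prone libraries from splitting a real segment.

## CODA

The independence model is an RBF-kernel support-vector regression from the
two single-mutant activities to the double-mutant activity. Features are
`(min(RA_i, RA_j), max(RA_i, RA_j), RA_i·RA_j)` — symmetric by
construction, and the product feature lets the regressor reproduce the
analytic product baseline exactly on multiplicative data, making the
deviation scores insensitive to regressor details. With fewer than 50
usable doubles the analytic product is used directly (flagged in the
diagnostics). Training is subsampled to ≤2000 doubles (seeded) to bound
the quadratic kernel cost; residual spread is reported.

Per position pair, D(i,j) is the maximum observed−predicted deviation over
*rescue combos* — substitution pairs whose letters restore Watson–Crick or
wobble complementarity **and** whose constituent singles are both
disruptive (RA < 0.5). The second condition matters: a complementary
double whose singles were never deleterious (e.g. substitutions that pass
through a neutral wobble) is active for reasons unrelated to pairing, and
counting it as rescue produces exactly the high-RA′-double false positives
the original study warns about. Pairs with no rescue combo score half the
maximum deviation over all combos. Deviations are not normalised by a
predicted variance.

The classifier is Gaussian naive Bayes on `(D, n_rescue, min_single_ra)`
with structural prior P(paired) = 2/L (a nested structure has at most L/2
pairs). `n_rescue` counts rescue combos with deviation ≥ 0.25;
`min_single_ra` is the smaller of the two positions' mean single-mutant
activities. The shipped class-conditional parameters were calibrated once
on labelled synthetic datasets (both fixtures, default generator, seeds
101 and 102) and rounded; `calibrate_classifier_params` re-derives them
from any labelled score map. The paired-class sd of D is kept ≥ the
unpaired-class sd, which makes the posterior provably monotone in D.
Pairs with |i−j| < 6 are flagged local (short-range rescue signals are
unreliable).

## CODA+MC

Structures are pseudoknot-free, one pair per position, hairpin loops ≥ 3
nt; paired letters must be Watson–Crick or wobble unless whitelisted. The
energy model is a deliberately simple stacking table — each stacked pair of
pairs contributes −(s₁+s₂)/2 with strengths GC 3.3, AU 2.2, GU 1.4,
non-canonical 0 — rather than a full nearest-neighbour parameter set: the
covariation term dominates the search when data are informative, and an
exact replication of the original energy function is not possible from the
published text (which itself attributes false positives to that
function's imperfection). Loop penalties are omitted for the same reason.

The annealer runs Metropolis moves (add a candidate pair, remove a pair,
slide a helix end) under geometric cooling (T 2.0 → 0.05, factor 0.95, 100
proposals per temperature), scoring `E − w·Σ logit P` with w = 2 (the
published weighting factor) and probabilities clipped to [0.01, 0.99];
local pairs' covariation term is halved. Pairs absent from the probability
map default to the prior 2/L, whose negative logit penalises unsupported
pairs — this is what suppresses spurious helices in the A/C-rich SL2
region. Non-canonical letter pairs become candidates only when their
posterior clears `whitelist_threshold` (0.9): the only route by which a
pair like A6·A41 can enter a model. The best structure visited is
returned; the schedule was sized so that exhaustive enumeration (≤ 16 nt,
same validity rules — the built-in oracle) is matched on toy sequences in
≥ 90% of seeded runs while 25-run ensembles on a 46-nt ribozyme stay in
the seconds range. Ensemble pair frequency is the fraction of final
structures containing the pair; the consensus keeps pairs at frequency ≥
0.8 and repairs conflicts by dropping the lowest-frequency pair.

## Downstream characterisation

The consensus sequence stacks the full sequences of variants with RA ≥ 0.5
(the library is substitution-only, so alignment is positional); each
variant counts once regardless of read depth. The symbol is the most
frequent base, or R/Y when the top two bases are both purines or both
pyrimidines, jointly ≥ 95%, and neither alone is; conservation classes
c95/c98/c100 apply to the top base's fraction and therefore nest.

Element decomposition walks the sequence 5′→3′, emitting each maximal
helix once (at its 5′ arm) and classifying unpaired runs as hairpin loop
(closed by one pair), external (touching an end), or internal-loop side
(everything else, including multiloop segments — adequate for lantern
topologies). Circular-permutation detection compares the reduced cyclic
element lists (hairpin loops collapsed onto their closing stem, external
segments dropped) under rotation, requiring identical kinds and per-element
length differences ≤ `len_tol` (default 1); the smallest matching rotation
offset is returned.

Descriptor matching implements a small RNAbob-like grammar (helices with
length ranges and a mismatch budget, strands with length ranges and IUPAC
constraints) by exhaustive placement; `ts_like_descriptor()` encodes the
two-stem/two-loop lantern and hits both fixtures at their annotated
coordinates.

Kinetics traces are fitted to F = A − B·e^(−k_obs·t) by unweighted least
squares (`scipy.optimize.curve_fit`), optionally after normalising by the
no-divalent-ion control at t = 0. Starting values come from a log-linear
transform of the approach to plateau. Constant traces and amplitudes
indistinguishable from zero return an explicit failure status rather than
an arbitrary rate.

## Problem sizes and determinism

Recovery tests and the acceptance script use the default study conditions:
20 synthetic datasets per ribozyme, 5×10⁵ molecules and 5×10⁶ reads per
channel each, 25 annealing runs per dataset (≈7 s per dataset on one CPU).
Every stochastic step takes an explicit seed and is deterministic given it;
ensemble runs use consecutive child seeds.

## Known limitations

* The activity model is pairwise-multiplicative; higher-order epistasis,
  position-specific noise, and transcription-efficiency artefacts at the 5′
  end are not emulated.
* The energy model has no loop entropies or dangles; with an uninformative
  covariation map its minima are only crude thermodynamic guesses.
* SL2 in the fixtures has no internal stem, so recovery of a third helix
  is never exercised.
* Coordinates printed for the published P2 pair names imply loop sides of
  7 and 6 nt, while the published loop-size discussion says 5 and 6; the
  fixtures follow the element sizes (6/5), shifting P2 by one position
  relative to those pair names.
* Pseudoknots, 3-D modelling, and genome-wide homolog search are out of
  scope.
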