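# Methods

This note documents the modeling choices behind `hardmorph`: what is
computed, which parameters matter, what the synthetic data emulates, and
where the genuinely open design decisions were resolved.

## Complexity indices

Four scalar indices monitor a morph's structural complexity.  They were
chosen to capture complementary facets — information content, functional
density, connectivity, and synthetic difficulty motifs:

- **Bertz**: RDKit's `GraphDescriptors.BertzCT`, a graph-theoretic
  information measure over bonds plus a heteroatom term.
- **Whitlock**: `4·rings + 2·unsaturations + heteroatoms + 2·stereocenters`.
  Aromatic systems are kekulized before counting, so benzene contributes
  three unsaturations and one ring (value 10); a triple bond counts as two
  unsaturations.  The formula predates aromatic-perception conventions and
  kekulization is the reproducible reading.
- **BC**: an additive connectivity index in the Barone–Chanon style:
  3 points per heavy-atom connection of every atom, a flat 3 per
  heteroatom, 6 per ring.  Several additive variants exist in the
  literature; this package fixes the weights above and freezes its own
  golden values.
- **SMCM**: a synthetic-complexity metric assembled from (i) per-atom
  relative Allred–Rochow electronegativities χ(el)/χ(C); (ii) per-bond
  terms — order factor (1 / 1.25 / 2 / 3 for single / aromatic / double /
  triple) times the geometric mean of the endpoint χ values; (iii) one
  point per ring plus one per ring-fusion bond; (iv) two points per
  stereocenter.

Two cross-cutting choices:

- **Unassigned stereocenters count.**  Morphing never writes stereo labels,
  yet stereo-rich skeletons must register as complex; chiral-center counts
  therefore include unassigned potential centers.
- **Absolute scales are irrelevant.**  All thresholds are percentile
  statistics of the same indices on a reference library, so any
  structure-monotone rescaling of an index cancels out of the stop
  decision.  Published variants and toolkit versions of these indices
  differ in absolute value; this package pins golden values from its own
  implementation and documents the formulas instead of chasing any
  particular external version.
- **Normalization.**  Every index is evaluated on the molecule re-derived
  from its canonical SMILES.  Symmetrized smallest-ring perception in the
  toolkit can differ between an edited in-memory molecule and its SMILES
  round-trip; normalizing first makes each index a pure function of the
  structure, which the first-crossing re-scoring guarantee requires.

## Threshold calibration

Reference molecules are binned by molecular weight into eleven half-open
50-Da bins `[i·50, (i+1)·50)` starting at 0, with heavier molecules clamped
into the last bin — drug-like libraries fall almost entirely below 550 Da,
and clamping rejects nothing.  Per (bin, index), three levels are recorded:
the observed maximum and the 99.9% / 99% nearest-rank percentiles (the value
at rank `ceil(q·n)` of the sorted sample).  Nearest-rank reads "99.9% of the
library lies below" as a count statement and avoids interpolation-mode
ambiguity.  Empty bins are flagged and any morph landing in one aborts its
path with a diagnostic rather than guessing.

A structure is *hard* under stop condition (level, k) if **at least k of the
four indices strictly exceed** their (bin, index, level) threshold — strict,
because the thresholds themselves are attained by library members.  The
default condition is (999th permille, k = 1), the best-accuracy cell of the
twelve-configuration grid experiment.

At desk scale a caveat applies: with ~100 molecules per bin the 99.9%
nearest rank coincides with the bin maximum, so the default condition
behaves like "exceed the library's observed extreme", and roughly a quarter
of random walks cross within 30 steps.  With realistic (10⁵–10⁷ molecule)
reference libraries the permille is a genuine interior quantile.

## Morphing

Six operator kinds act on the kekulized molecular graph: add a
singly-bonded atom from the alphabet at any free-valence site; remove an
atom whose deletion keeps the graph connected (non-articulation vertices
only); swap an element where the default valence accommodates the bonded
valence; add a single bond between unbonded free-valence atoms (always a
ring closure, since the graph is connected); remove a ring bond; change a
bond order within the available valence.  The element alphabet defaults to
the drug-like organic subset {C, N, O, S, P, F, Cl, Br, I}.

Sampling is two-stage uniform: first over the operator kinds with at least
one candidate, then over candidates of the chosen kind.  Candidates are
enumerated with cheap valence/connectivity arithmetic; the chosen edit is
verified by full sanitization, and the rare candidate that fails (aromatic
re-perception edge cases) is discarded and redrawn, up to 50 attempts before
the path is declared a dead end.  Paths carry no tabu list — revisits are
possible — and deduplication happens only at library level, by canonical
SMILES.

A walk stops at the **first** morph that satisfies the stop condition
(re-scoring any HIT path must reproduce this: all pre-terminal morphs below,
terminal above).  The step cap is 30.  A start that itself already exceeds
the thresholds is reported as a zero-step hit with a warning but **excluded
from the generated library**: it is a member of the reference distribution,
not a product of morphing, and emitting it would label reference-like
structures as generated negatives.

Starting structures are taken as parsed (largest fragment on request, no
neutralization); whether to desalt or neutralize inputs is left to the
caller.

## Labeled sets

- **Morphing sets**: hard = deduplicated HIT terminals; easy = either the
  corresponding starting structures of crossing paths (grid experiments) or
  an equal-size random sample from a reference library.  Classes are
  trimmed to a common size.
- **Score-threshold sets**: a precomputed synthetic-accessibility score is
  consumed as an input column (the scoring method is a separately published
  model and is not reimplemented here); hard = score > 6, easy sampled from
  score < 4, the ambiguous [4, 6] band excluded entirely.
- **Dense-region sets**: neighbour counts at Tanimoto ≥ 0.6 on 512-bit
  radius-2 Morgan fingerprints, self excluded; ≥ 20 neighbours easy, ≤ 1
  hard.  The 2–19 band is returned (and written) as unlabeled rather than
  silently dropped; the easy class is subsampled to the hard-class size for
  training parity.

## Synthetic library

`fixture_library(n, seed)` grows random valence-tracked molecular graphs
from C/N/O/S/F/Cl (weights 0.58/0.12/0.15/0.05/0.05/0.05, roughly the
element frequencies of drug-like organic molecules), with a 12% chance per
step of a ring closure and 8% of an unsaturation, to a target weight cycling
through the eleven bins; n = 1100 populates every bin with 100 molecules.
It emulates the *coverage* properties the method needs — all weight bins
populated, heteroatom/ring/unsaturation diversity, deterministic for a
seed — but not real chemistry: no aromatic systems are grown, no synthetic
feasibility constraints apply, and its complexity distribution is narrower
than a vendor catalog's.  Passing tests on it demonstrate the machinery
(calibration statistics, first-crossing, classifier separability between
morphs and their starts), not field performance on commercial libraries.

## Classifier and metrics

100-tree scikit-learn random forest on 512-bit fingerprints; other
hyperparameters stay at library defaults and are logged in the report.
Positive class = easy.  Point metrics use the conventional 0.5 probability
threshold; ROC sweeps all score thresholds and the trapezoidal area equals
the Mann–Whitney pair statistic with ties at one half (verified against a
pairwise oracle).  Degenerate denominators yield NaN ("not available"), not
errors.  Because easy examples are sampled from a pool, headline metrics
average five independent samples, each with its own forest; scalar metrics
are averaged, not ROC curves.

## Problem sizes

Experiments in the test suite and the acceptance script run at desk scale,
chosen as the package's own study conditions: 1,100-molecule reference
libraries (100 per bin), 500–1,100 morphing starts, 30-step walks, 100
starts per grid cell, 10,000-value-per-bin synthetic distributions for
calibration oracles.  The pipeline holds out one fifth of the crossing
paths' (start, terminal) pairs as the test split and averages over three
seeds where stability matters.

## Known limitations

- The BC and SMCM contribution tables are this package's documented
  choices within their published families; absolute values are not
  comparable to other software, only orderings and calibrated exceedances.
- Operator semantics ("remove atom" = connectivity-preserving deletion; no
  bond rerouting or atom insertion into a bond) are the simplest reading of
  elementary graph edits; richer operator inventories exist in goal-directed
  morphing tools.  Individual operator kinds can be disabled through the run
  configuration (`operators`), and the element alphabet is configurable.
- Whitlock and SMCM can decrease when an added substituent symmetrizes away
  a potential stereocenter; only BC and the achiral part of Whitlock are
  monotone under atom addition.
- Dense-region labeling on the synthetic library is nearly degenerate
  (few molecules reach 20 neighbours); realistic density structure needs
  real screening collections.
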