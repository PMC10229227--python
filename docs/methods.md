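# Methods

## The data model

The analytical unit is a *snapshot* of an organism, not a species. Four
unit classes are distinguished:

- **semaphoront** — an individual at one ontogenetic stage; carries an
  `ontogenetic_rank` (0-based position in its taxon's developmental series)
  and decay stage 0 or none;
- **semataphont** — an individual after a given amount of post-mortem
  decay; carries `decay_stage ≥ 1` (and the rank of the stage it was
  derived from);
- **fossil_specimen** — an actual or synthetic fossil, stage fields unset;
- **fossil_version** — one of several alternative anatomical
  interpretations of the same fossil under different homology models.

States are binary presence/absence with `?` for unknown, stored internally
as floats with NaN for unknown; this makes pairwise-complete comparisons a
masking exercise. Multistate and polymorphic characters are out of scope
and rejected on input.

Standard NEXUS has no slot for stage metadata, so the canonical metadata
carrier is a sidecar delimited table keyed by `unit_id`; files written by
the package additionally embed the table in a bracketed `UNITMETA` comment
block, which the reader accepts, making the NEXUS round-trip
self-contained and lossless. Gap symbols (`-`) are read as unknown with a
warning. The CSV/TSV carrier puts the metadata columns first, then one
column per character.

### Coding styles

Two treatments of fossil uncertainty are provided: style 1 keeps `?`
(tolerant), style 2 recodes every `?` as absent (strict). Style 2 is
implemented as the mechanical `? → 0` transform of the style-1 matrix —
whether the original strict matrix was mechanically derived or re-scored
by hand is unknowable from the published description, and the mechanical
transform is the reproducible choice. It is idempotent and eliminates all
unknowns.

## Dissimilarity

Gower's coefficient over the comparable character set, i.e. for binary
data the weighted mismatch fraction over characters known in both units.
Unknown-vs-anything pairs contribute to neither numerator nor denominator;
the per-character range term is 1 for 0/1 data. Character weights default
to 1 and only their ratios matter. A pair with an empty comparable set has
no defined distance; the default policy is to raise (ordination needs a
complete matrix), with `na_policy="allow"` recording NaN for exploratory
use and for placement of very incomplete fossils.

## Ordination

**NMDS.** SMACOF-style majorization of Kruskal stress-1. Each iteration
refits the disparities by weighted pool-adjacent-violators regression of
configuration distances on observed dissimilarities and applies a Guttman
transform. Choices that matter:

- *Ties*: Kruskal's primary approach — tied observed dissimilarities may
  receive different fitted values; within a tie block pairs are ordered by
  current configuration distance. Implementations differing in tie
  handling produce slightly different stress values on real data.
- *Disparity normalization*: disparities are rescaled each iteration to a
  fixed sum of squares. Raw stress scales quadratically under uniform
  shrinkage of the configuration, so without this the majorization drifts
  toward total collapse.
- *Starts*: the first start is the PCoA configuration (a standard
  convention that usually lands in the right basin); the remaining
  `n_starts − 1` (default 20 total) draw uniform(−1, 1) coordinates from a
  generator seeded by the user's seed. The lowest-stress start is
  reported, all stresses retained.
- *Convergence*: relative stress decrease below `tol` (default 1e-7) or
  `max_iter` (default 500); an iteration that would increase stress
  (numerical floor) terminates the start.
- *Gauge fixing*: rotation, reflection and scale are gauge freedoms of
  (N)MDS — two runs can legitimately return axis-inverted configurations,
  which is why configurations are normalized: columns centered, rotated to
  the configuration's principal axes, sign fixed so the largest-magnitude
  coordinate on each axis is positive, and scale pinned so configuration
  distances match the observed dissimilarities in sum of squares (exact
  recovery in the Euclidean limit). The reported stress is recomputed from
  the normalized coordinates and equals `kruskal_stress` to 1e-10.

**PCoA.** Double-center −D²/2, eigendecompose, scale eigenvectors by the
square roots of the positive eigenvalues; proportion explained is taken
over positive eigenvalues. Negative eigenvalues (from missing data or
otherwise non-Euclidean distances) are reported, and removed on request by
the **Cailliez correction**: the smallest constant c added to all
off-diagonal dissimilarities making them Euclidean-embeddable, computed as
the largest real eigenvalue of the standard 2n × 2n companion matrix built
from the centered −D²/2 and −D/2 blocks. Tests validate c against an
independent bisection on the embeddability predicate, and the PCoA
coordinates against an independent implementation.

## Morphospace analyses

- **Trajectories** connect one taxon's staged units in stage order; decay
  paths are grouped per (taxon, source ontogenetic rank) since a taxon may
  have several decayed stages (e.g. both a larva and an adult). Segment
  lengths come from either Gower space or ordination coordinates.
- **Convergence profile** C(s): mean pairwise Gower dissimilarity among
  stage-s semataphonts from distinct taxa. Defined in Gower space by
  default so the stem-ward-slippage claim is tested on morphology itself
  rather than on a 2-D projection with its gauge and stress artifacts.
- **Slippage zone**: terminal stage = each taxon's maximum decay stage;
  the zone center is the centroid of terminal units in ordination space,
  or the medoid terminal unit in Gower space (where no centroid exists).
- **Alignment**: least-squares orthogonal Procrustes (rotation plus
  reflection, translation; no scaling by default since normalized NMDS
  configurations already share a scale) estimated on shared units, applied
  to all target units. Reflection is reported — axis inversion between
  runs with and without fossils is expected behavior, not error.
- **Placement**: k nearest extant units per fossil by full Gower
  dissimilarity (not ordination coordinates, to avoid projection
  distortion); ties broken lexicographically by unit id; a fossil with no
  comparable characters against any extant unit is reported UNPLACEABLE
  rather than raising.

### An identifiability caveat worth knowing

When a fossil's decay losses are coded `?` (style 1), those characters
drop out of every comparison, so the fossil is at Gower distance 0 from
its source semataphont *and* from every less-decayed unit of the same
ontogenetic rank — the source taxon is recoverable but the decay *stage*
is not. Only strict recoding (style 2), where absences are taken at face
value, makes the stage identifiable. The placement-recovery tests
therefore run on the style-2 matrix; the contrast between the two styles
is itself one of the analyses the package exposes.

## The synthetic framework generator

The simulator emulates the *structure* of an extant comparative framework,
not any taxon's actual anatomy. Defaults (4 taxa, 71 binary characters, 6
decay stages, 30% shared decay-resistant characters, 30% taxon-private
apomorphies, resistant-last retention) mirror the scale of the
early-vertebrate case study; the checked-in `table1.yaml` configuration
reproduces its full 111-unit census (4 extant taxa expanded into 49
semaphoronts and semataphonts — including separate larval and adult decay
series for the lamprey analogue and two embryonic series for the shark
analogue — plus 62 synthetic fossil units).

Generative assumptions:

- *Decay resistance is a property of the trait*: a character present in
  two taxa is lost at the same stage in both. Per-taxon loss schedules are
  therefore identical up to taxon-specific character occupancy. Under this
  assumption decay can only convert mismatches into matches, which makes
  the per-pair inter-taxon dissimilarity non-increasing in stage — the
  clean resistant-last regime in which stem-ward slippage is provable, not
  merely typical.
- *Retention rules*: `resistant_last` (default) never loses the shared
  characters and loses apomorphies earliest; `labile_last` inverts the
  loss ordering to emulate preservational regimes (e.g. microbially
  mediated mineralization) where decay-prone tissue preserves
  preferentially. No monotone convergence is claimed in that regime, and
  no other preservation-pathway physics is modeled.
- *Ontogeny*: shared and own-apomorphic characters are present at every
  rank; background characters get a random acquisition rank, with a 15%
  chance of being a larval trait lost during life. Extant semataphonts
  score decay losses as real absence (the experimental observer watched
  the trait disappear); fossil derivations score them unknown.
- *Randomness*: one master seed, split into per-character and per-taxon
  streams, so adding a taxon leaves the other taxa's draws unchanged.
  Synthetic fossils are copies of chosen semataphonts with lost characters
  and a configurable fraction of the remaining characters obscured to `?`.

What passing tests on these data do and do not show: they verify the
machinery (distances, ordination, statistics) and the qualitative regime
claims exactly; they do not certify that real decay is nested and
trait-intrinsic, that real characters are independent, or that real
frameworks are as cleanly separated — real extant decay data violate all
three to some degree.

## Tolerances and numerical conventions

- Gower is validated to 1e-12 against a naive per-pair loop.
- PAVA is validated exhaustively against enumerated monotone least squares
  for short sequences and against an independent isotonic-regression
  implementation for longer weighted ones.
- NMDS in the Euclidean limit (distances from 10 planar points) reaches
  stress ≤ 1e-3 and recovers the generating points to RMS ≤ 1e-6 after
  alignment.
- Cailliez-corrected eigenvalues are bounded below by −1e-10 × the largest
  eigenvalue; the constant agrees with the bisection oracle to 1e-6.
- Deterministic outputs: every stochastic step takes an explicit seed, and
  pipeline reruns with the same seed are byte-identical.

Problem sizes in the test suite and acceptance script (111-unit framework,
20 NMDS starts, 50–100 replicate simulations, 100–200 placement trials)
were chosen to exercise the full published census while keeping a complete
run in the minutes range on one core.

## Known limitations

- Binary characters only; no ordered multistate, step matrices or
  molecular data. No alternative cladistic distances (GED/MORD).
- The published 111 × 71 early-vertebrate matrix is third-party data and
  is not redistributed; the stress-reproduction test requires a local copy
  (see README) and otherwise reports the matrix as missing. Reproduction
  of the published stress values to the third decimal is additionally
  limited by the original implementation's unstated start counts and tie
  conventions.
- The slippage zone's published description is visual ("an area of the
  plot"); the centroid/medoid operationalization here is one reasonable
  formalization of it.
- No significance testing (PERMANOVA etc.) — the method is exploratory by
  design — and no plot rendering; ordination scores are exported as tables
  for any plotting tool.
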