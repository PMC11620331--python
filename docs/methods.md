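# Methods

## The collision model

A nick (single-strand break) at genomic position `p` on target strand
`s ∈ {+, −}` meets, in each cell, a replication fork whose direction is
Bernoulli: rightward with probability `f` (the fork directionality,
related to RFD by `RFD = 2f − 1`). The orientation class follows from
(direction, strand): a Crick (−) nick met by a rightward fork lies on
the lagging-strand template (bypass → double-ended break); a Watson (+)
nick met by a rightward fork lies on the leading-strand template
(run-off → single-ended break); both mirror for leftward forks.

Per nicked cell the generator emits blunted break ends as single base
positions:

- leading-strand collision: one end at `p − r` (rightward fork) or
  `p + r` (leftward), with `r` a per-end resection draw;
- lagging-strand collision: two ends at `p − r₁` and `p + r₂` with
  independent draws;
- with probability `converging_prob`, an unrepaired single end gains a
  partner from the converging fork, placed at exactly
  `converging_distance` bp beyond the nick on the far side. The true
  position of a converging fork at the moment of collision is not
  modeled; a fixed distance is the simplest shape that exercises the
  downstream statistics.

Ends left of the nick are recorded on the plus-strand channel, ends to
the right on the minus channel. This identification is a convention:
the asymmetry statistic is positional (left/right of the nick), so any
consistent strand assignment yields identical results; fixing one makes
strand-polarity outputs (e.g. RPA ratios) deterministic.

Resection lengths default to uniform on `(0, L_max]`. Break-mapping
coverage at a population snapshot spreads over per-cell resection
extents, and the estimators below target the *maximum* of that
distribution, which is insensitive to the family; a truncated
exponential is available for sensitivity checks. Background is uniform
Poisson over the main genome (`background_rate` reads/bp, or derived
from a target fraction of signal reads), with no chromatin covariates —
sufficient to stress thresholding, not a model of real background
structure.

Defaults used by the canned scenarios: `f = 0.85` (a strongly but not
perfectly unidirectional locus), 1,000 cells, `L_max = 5` kb, background
at 5% of signal reads, spike-in cell fraction 0.20 at 10,000 cells
sampled. Under these conditions the expected asymmetry of a
leading-strand site is `0.5 − 0.15/(1 + 0.15) ≈ 0.37` and of a
lagging-strand site `≈ −0.04`, inside the empirically reported seDSB
(0.3–0.4) and deDSB (0–0.1) ranges; the simulations are checked against
those ranges, not tuned to them.

## Normalization

RPM multiplies every per-base count by `1e6 / total_mapped_reads`, with
the total carried as track metadata (a library contains reads outside
any displayed window, so it must not be inferred from in-track counts).
Spike-in normalization divides RPM values by
`spikein_locus_reads / total_main_reads`; more spike-in signal therefore
*lowers* normalized values. The direction matters and is asserted in
tests: doubling only the spike-in reads halves the normalized track,
and scaling all raw counts and totals by a common factor leaves the
spike-normalized track exactly unchanged. Normalization is a one-way
state machine (`raw → RPM → spike_normalized`); illegal transitions
raise rather than silently renormalize.

## Peak calling and qualification

The caller is a documented, minimal stand-in: contiguous runs of
combined-strand signal strictly above `min_signal` (default 3), merged
across gaps ≤ `merge_gap`, annotated with summit, max signal, and a
Poisson upper-tail probability against a uniform background rate as the
significance surrogate (default filter p < 0.001). The filters, not the
caller internals, carry the analysis; broad-peak modeling, local-lambda
backgrounds and FDR are deliberately out of scope.

Qualification keeps peaks containing exactly one target site whose
distance to the nearest *other* site (site-to-site, the reading that
matches the rule's subject) strictly exceeds 8,000 bp.

## Asymmetry and classification

`asymmetry = 0.5 − R/(L+R)` over half-open windows `[p−3000, p)` and
`[p, p+3000)`; the nick base belongs to the right window. The statistic
is kept signed (negative when the dominant end lies right of the nick,
as at leftward-fork sites), which makes the mirror antisymmetry
`a(mirror) = −a` testable; classification uses `|a|` with thresholds
0.25 (seDSB) and 0.10 (deDSB) chosen between the reported ranges, both
configurable. `L + R = 0` yields NaN and the site is excluded from
correlation. RPA asymmetry is the plus/minus read ratio over a region;
an empty minus strand is reported as +inf (censored), not an error.

## Resection estimators

**Sliding window** (many shallow sites): signal on one side of the nick
is summed into 50-bp bins outward; background `B` = mean bin signal
over bins fully within 7–9 kb of the nick (same side). A 12-bin window
slides outward; at the first window with ≥ 9 bins strictly below `B`
("more than eight"), the tract endpoint is the outer edge of the
farthest strictly-above-`B` bin in the window — or of the last
above-`B` bin seen before it, or 0 if none. If no window triggers
within `search_limit` (default 50 kb), the limit is returned with an
at-limit flag. Ties with `B` count as neither below nor above; all
boundaries (≥ 9 of 12, strict comparisons, outer-edge reporting) are
configurable and asserted against an independent nested-loop oracle.
When `B` is exactly zero (noise-free simulations) it is replaced by a
tiny positive floor (1e-9) so empty bins still register as below
background; otherwise the strict `<` could never trigger.

The estimator assumes the background window lies **distal to the
tract**. For hyper-resected tracts (tens of kb) the 7–9 kb default sits
inside the signal, making `B` the tract's own density; bin noise then
puts roughly half the bins below `B` and some 12-bin window triggers
far too early. The hyper-resection scenario therefore sets a distal
background range (55–60 kb). Relatedly, the > 8-of-12 rule reacts to
*empty* bins, so per-bin occupancy must stay well above the empty-bin
regime: recovery of a 40-kb tract needs proportionally more events than
a 5-kb tract at the same fidelity (the test suite scales events with
tract length). Estimates are multiples of the bin size, reported at the
outer bin edge (an up-to-50-bp convention choice).

**Unique-site boundary scan** (isolated deep sites): threshold
`τ = mean + k·sd` (default k = 3) of the per-base signal in a distal
flank (default 20–30 kb), replacing a per-site visual threshold with a
reproducible rule; the boundary is the farthest above-`τ` position
reachable without a below-`τ` gap longer than `max_gap` (default
200 bp, tolerating dips inside a peak). An identically-zero flank falls
back to `τ = tau_floor` (default 1).

## RFD and designation

`RFD = (C − W)/(C + W)` per bin (default 1 kb; the appropriate bin size
is data-dependent and configurable), positive = rightward forks, with C
the Crick- and W the Watson-strand fragment count; undefined where a
bin is empty. TrAEL-style chemistries label strands oppositely and may
need a sign flip at import. The nick designation rule is the strand
mirror pair: Crick nick with RFD > 0 → lagging, < 0 → leading; Watson
mirrored; RFD exactly 0 or undefined → unclassified. RFD at a nick is
the value of the containing bin, uninterpolated. The asymmetry–RFD
relationship is summarized by Spearman rank correlation (average-rank
ties); for leading-strand sites |RFD| is paired with |asymmetry|, since
both flip sign with fork direction and the magnitudes carry the
relationship; an exact rank-then-Pearson oracle pins the
implementation. Hidden-Markov segmentation of initiation/termination
zones is explicitly not implemented.

## Deletion and microhomology calling

A read is explained under a single-deletion model: split index `k`
aligns `read[:k]` to `ref[:k]` and `read[k:]` to `ref[k+d:]` with
`d = len(ref) − len(read)`; the smallest `k` with at most `tolerance`
mismatches (default 0) wins, which is exactly VCF-style left alignment
and makes junction coordinates and microhomology length well defined
inside repeats. Reads equal to the reference are intact; reads not
explicable by one deletion are counted unclassified rather than
force-fitted. Junctional microhomology is
`m = max{i : ref[s:s+i] == ref[e:e+i]}`, bounded by the remaining
reference; it may exceed the deletion length inside tandem repeats.
Insertions, substitution clusters and multi-segment events belong to
dedicated editing-outcome tools.

## What the simulator does and does not emulate

It reproduces the *statistical structure* the estimators assume:
strand-asymmetric end placement by collision orientation, resection
spread, fork-directionality mixing, spike-in dilution, uniform
background, and microhomology-biased junctions. It does not model
fragment lengths (a read is one base), replisome or nick-removal
kinetics beyond a cut-efficiency scalar, sister-chromatid dynamics,
chromatin-dependent background, sequencing error, or alignment
artifacts. Passing tests therefore demonstrate correctness of the
statistics under their stated assumptions — not robustness to the full
noise structure of real libraries.

## Reproducibility and problem sizes

Every stochastic routine takes a seed or NumPy `Generator`; a pipeline
run expands one global seed into per-stage substreams, so any stage can
be replayed in isolation and a rerun is byte-identical (asserted via
artifact SHA-256). Simulated genomes are a few hundred kb with 10³–10⁴
events per nick — the scale at which the estimators' sampling error is
comfortably inside the decision thresholds, chosen so the full suite
runs in seconds. Oracle-equivalence suites (sliding-window rule,
microhomology, left alignment) run ≥ 1,000 randomized cases each and
require exact agreement.

## Known limitations

- The bespoke peak caller is not a drop-in for broad-peak callers on
  real data; it exists to carry the documented filters.
- The sliding-window estimator's background placement must be chosen
  with a prior on tract scale (see above); with the 7–9 kb default it
  is reliable for tracts ≲ 6 kb.
- Converging-fork ends at a fixed distance understate the positional
  dispersion of real converging forks.
- Spike-in handling supports a single locus interval; multi-locus
  spike-ins are out of scope.
- The RPA ssDNA model coats resected tracts uniformly; footprint-level
  binding structure is not modeled.
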