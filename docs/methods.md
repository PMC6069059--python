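# Methods

## The model

The package joins two estimators that share one object, the per-person
**location vector** V_i ∈ [0,1]^L over an ordered location space of L
places (a user-supplied gazetteer plus one synthetic entry per household).

**Co-location network.** The tie weight between participants i and j is
the cosine similarity of their location vectors, w_ij ∈ [0,1]. The
interpretation is probabilistic co-presence: two people whose daily visit
probabilities concentrate on the same places have a high chance of
face-to-face encounter. Assumptions worth keeping in mind:

* visits on different days/places are independent (no temporal alignment —
  two Sunday churchgoers and a Sunday/Wednesday pair get the same weight);
* the survey's place *categories* stand in for unknown exact destinations,
  so each report spreads its probability uniformly over every candidate
  place of that category in the reachable ring (a deliberate
  privacy-preserving coarsening; it biases weights toward within-community
  uniformity);
* a tie is *potential* contact, not acquaintance. Centrality, leaders and
  support scores inherit this reading.

**Weighted degree centrality** is DC_i = Σ_{j≠i} w_ij. The self term
(w_ii = 1) is excluded: including it would shift every node by a constant
and give isolates a nonzero score. **Leader ranking** filters a community
to its well-being top decile — by default mental well-being at or above
the (1−d) quantile *and* isolation at or below the d quantile, d = 0.1 —
then sorts by DC (ties: higher MCS, then id). With few participants the
two-sided filter can be empty; `decile=1.0` disables it, and both the
measure and the secondary isolation filter are configurable. The **support
score** is the pairwise SS_ij = w_ij·|HS_i − HS_j|; a node-level aggregate
Σ_j w_ij|HS_i − HS_j| is available separately (`node_support_aggregate`)
for exploratory ranking of "who could help many". "Poor" well-being
defaults to isolation > 50 or a well-being score < 50 (the national-mean
midpoint of these 0–100 standardized scales), and dyads are reported above
SS > 1.0, both configurable.

**Socially weighted KDE.** Each place p carries mass M_p = Σ_i HS_i·V_ip
(expected daily visitation weighted by the visitors' health measure), and
the surface is λ̂(s) = Σ_p k(d_sp)·M_p with the quartic kernel, which
integrates to exactly 1 over its support disk; λ̂ therefore integrates to
Σ_p M_p away from grid edges. HS direction: isolation is used as-is;
mental/physical well-being are inverted (HS = 100 − score) so poor
well-being up-weights. Home places are excluded from the events by default
(`include_home_in_kde=False`): homes carry probability 1 for their
residents and would otherwise dominate every map; the interesting surface
is where isolated people *go*. Home entries are, however, part of the
network vectors by default (`include_home_in_network=True`), which gives
co-resident couples a near-1 tie — intended, since spouses surely meet.

## Geocoding parameters

| parameter | default | units | rationale |
|---|---|---|---|
| travel speed | 800 | m/min | ≈ 48 km/h, rural driving, converts time bins to distance |
| travel bins | (0,10), (11,20), (21,30), (31,40) | min | the survey's fixed vocabulary |
| frequency map | 1, 1/7, 1/30 | day⁻¹ | every day / once a week / once a month |
| home jitter | 0 | m | privacy jitter radius; set > 0 when homes are exact addresses |
| bandwidth τ | data-driven | m | see below; explicit τ always wins and is logged |
| grid cell | τ/20, ≤ 500 cells/axis | m | resolves the kernel while bounding memory |
| hotspot quantile | 0.9 | — | top decile of positive cells |

Reported travel bins are mapped to **contiguous annuli**
[0, 10·v], (10·v, 20·v], ... so every distance belongs to exactly one bin
(the printed bins would leave 1-minute gaps). Reachability is Euclidean by
default; a `reachability` callback on `VectorConfig` accepts precomputed
road-network tables. When several reports put probability on the same
place, daily visit events are treated as independent:
q = 1 − Π(1 − q_r), which keeps every entry in (0,1] (a plain sum could
exceed 1). A report whose ring contains no place of the reported category
is skipped with a structured warning and listed in the run metadata —
an auditable data-quality signal, not an error.

All geometry is planar metres. `geo.lonlat_to_local` projects lon/lat via
a local equirectangular projection about a reference point (sub-1% error
for ≤100 km extents); no geodesic computations are performed.

## Bandwidth

τ = 0.9 · min(SD, √(1/ln 2)·D_m) · n^(−1/5), where SD is the standard
distance of the events about their mass-weighted mean centre, D_m the
mass-weighted median distance to that centre, and n the number of
positive-mass events. This is the familiar geographic-software default;
the min(·) with the median term keeps a few far-flung events (spatial
outliers) from inflating τ. Zero-mass events are dropped before
estimation so empty places don't shape the smoothing. Degenerate inputs
(< 2 distinct locations) raise an error asking for an explicit τ rather
than guessing.

## Numerical choices

* Cosine of an all-zero vector is defined as 0 (no co-location evidence ⇒
  no inferred tie), and zero-weight pairs are not stored but behave as 0.
* Betweenness uses edge length 1 − w (bounded; a certain-contact tie has
  length 0); 1/w is available but unbounded as w → 0.
* Leader/dyad ties break deterministically (score, then id) so outputs are
  stable across runs and platforms.
* Hotspots are 8-connected components of cells ≥ the density quantile of
  positive cells, ranked by peak value; raising the quantile yields nested
  regions.
* The KDE accumulates each event only on the cells within τ (compact
  support), so cells beyond τ of all events are exactly 0 and a naive
  triple-loop evaluation agrees to ~1e-10.
* No KDE boundary correction: the surface integral equals the total mass
  only when events sit ≥ τ inside the grid, which the default grid
  (bounding box padded by τ) guarantees.
* Scores outside [0,100] are rejected, not clipped — clipping would mask
  upstream scoring errors. Missing scores are flagged explicitly and the
  participant is excluded from support-score and density computations with
  a logged warning; they still appear in the network.

## The synthetic generator

`synthetic.simulate` emulates a small rural multi-community survey: 3
communities of 10 couples (60 participants, 30 shared homes) on a ~30 km
triangle, homes within 2.5 km of their community centre, places scattered
within 5 km of the centres, 3–8 reports per participant with categories
weighted toward shopping and eating out, frequencies (0.1, 0.5, 0.4) over
(daily, weekly, monthly), travel bins weighted toward the nearest ring,
and all three scores Normal(50, 10) clipped to [0, 100]. Planted
structure: a hub who reports every category daily (should top the DC
ranking) and an isolated group with isolation ≥ mean + 2 SD sharing a
daily visit that resolves uniquely to one anchor place (the top hotspot
should contain it); rival places of the anchor's category are pushed out
of the community's nearest travel ring to make "resolves uniquely" hold by
construction.

What it does *not* emulate: demographic covariates, workplace activity
(rarely reported in such surveys and deliberately unmodelled), road-network
travel times, seasonal/temporal visit patterns, and reporting error in
categories or bins. Passing the planted-recovery tests therefore shows the
estimators recover structure *under the model's own assumptions* — it does
not validate the co-location→tie inference against observed social
networks, which requires ground-truth contact data.

## Problem sizes

The test suite and the reproduction script run the full chain on 60
participants, ~330 reports, ~73-place location spaces and ~150×150-cell
grids, replicated over 20 seeds — the scale the method targets
(hard-to-reach populations are small by nature); the implementation
handles larger samples, with network construction scaling as O(n²) pairs
and the KDE as O(events · (τ/cell)²).

## Known limitations

* Category-level reporting makes within-community weights relatively
  uniform; with very few place categories the network approaches a blocky
  community structure and DC differences shrink.
* The two-sided leader eligibility filter can reject everyone in small
  communities (documented above; use `decile=1.0` for a pure DC ranking).
* Euclidean rings mis-state reachability where road networks are sparse or
  barrier-ridden; plug in a reachability table for fidelity.
* The support score is symmetric: it flags a *gap*, not a direction; the
  receiver/provider roles come from the poor-well-being rule, not from SS
  itself.
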