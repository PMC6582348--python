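# Methods

## Model and assumptions

The simulator describes a circular genome as a one-dimensional lattice of
60-nt sites.  Only the torsional (twist) component of supercoiling is
modelled; writhe, plectoneme geometry and the topological action of
nucleoid-associated proteins within domains are outside scope (barrier
proteins enter only as fixed domain boundaries).  Supercoils diffuse
instantaneously within a topological domain, so σ is piecewise constant
between the cut points of the circle — fixed barriers plus elongating RNAPs.
Elongation speed is constant (30 nt/s); RNAPs are never stalled by positive
supercoils, which restricts validity to moderately transcribed genes rather
than, say, ribosomal RNA operons.

One Euler step of dt = 2 s applies, in order: (1) stochastic initiation —
each free RNAP can bind an available promoter with probability
min(1, k_on·f(σ_local)·dt), promoters visited in uniformly random order, a
promoter being occluded when its site or the adjacent downstream site carries
an RNAP; (2) elongation by exactly one site per step (dt·speed =
unit length), with movement resolved against start-of-step occupancy so
trailing and head-on RNAPs wait; a newly bound RNAP starts moving the next
step, making the residence time of a gene exactly (length/speed); (3)
twin-domain injection ±Γ/L with Γ = 0.2 per unit length moved; (4)
deterministic, continuous topoisomerase increments k·t(σ)·dt evaluated at the
pre-step σ (explicit Euler; the largest per-step increment, ≈0.005 at 2.5× the
reference gyrase concentration, is small against the sigmoid widths).

### Supercoil bookkeeping

Moving a domain boundary transfers one lattice unit of DNA between the
flanking domains *at the donating domain's density*; binding splits a domain
with both children inheriting σ; termination merges with the length-weighted
average (exact when the two densities are equal, so a split/merge round trip
is bit-exact).  Together with the ±Γ/L injection these rules conserve the
length-weighted mean σ of the circle exactly when no topoisomerase acts —
the discrete analogue of linking-number conservation — and the test suite
verifies it to 10⁻¹² over 10⁴ steps on random genomes.  On a barrier-free
plasmid a single RNAP's positive and negative contributions land in the same
(unique) domain and cancel identically, which is why the freely rotating
plasmid scenario keeps σ constant without any special casing.

## Parameters

| parameter | default | meaning |
|---|---|---|
| dt | 2 s | Euler timestep; dt·speed = one 60-nt site |
| rnap_speed | 30 nt/s | constant elongation speed |
| Γ (gamma) | 0.2 | supercoils injected per unit length transcribed |
| σ_t, ε, m | −0.042, 0.005, 2.5 | promoter opening threshold, width, log-activation |
| topo I σ₀, width | −0.04, 0.012 | activity sigmoid (descending: active on negative σ) |
| gyrase σ₀, width | 0.01, 0.025 | activity sigmoid (ascending; ≈0.40 at σ = 0, ≈0.97 at σ = 0.1) |
| k_basal | 0.001 s⁻¹ | σ rate at the reference concentration |
| reference conc. | 41 nM topo I, 0.1 µM gyrase | in vitro calibration assay |
| in vivo conc. | 0.025 µM topo I, 0.25 µM gyrase | all chromosomal scenarios |
| rnap_pool | 8 | RNAPs available to the 30-kb toy genome |
| initial σ | −0.03 | in vivo scenarios, with ≥30 min burn-in |

Concentration enters linearly relative to the calibration assay; the stated
sigmoid parameters imply ≈0.40 gyrase activity on relaxed DNA (a value often
quoted nearer 30%; the printed parameters are used as-is).  Under this
scaling the enzyme balance of a non-transcribed domain settles at σ ≈ −0.040
in vivo, and at σ ≈ −0.022 after a 5-fold gyrase dilution — matching the
observed post-shock level of ≈ −0.02.  The alternative convention (k_basal at
the in vivo concentrations) was evaluated and rejected: it collapses the
shock response (divergent factor 1.3) and relaxes the genome to σ ≈ −0.004
after the shock.

### Calibrated constants

* Toy-genome basal rates: bisected (log-space, 3 seeds, ±10%) so each active
  gene fires once per 1, 2.5 or 10 min *effectively* (the realised rate
  includes supercoiling feedback and pool competition): k_on = 2.63×10⁻³,
  1.41×10⁻³ and 5.59×10⁻⁴ s⁻¹.  Frozen in `scenarios.CALIBRATED_KON`;
  regenerate with `scripts/calibrate.py`.
* Anchored-plasmid effective curve: the positive-repressed variant keeps the
  sigmoidal form exp(m·U) but moves the threshold to positive σ
  (σ_r = 0.19, ε_r = 0.05, calibrated so the topoI-only plateau represses
  initiation ≈3-fold).  The composite alternative — standard curve times a
  repression sigmoid — cannot reach a factor of 3: the initial rate is
  inflated ~6-fold by the RNAP's own negative wake re-activating the
  standard curve, leaving the no-repression limit of the init/plateau ratio
  at ≈5.9, which any additional descending factor only increases.  A curve
  that is flat at negative σ removes that double-counting and is consistent
  with an effective description of strongly positively supercoiled templates
  where both initiation and elongation are hampered.

## Scenario geometry choices

The 30-kb toy genome places three barriers at 0, 10,020 and 19,980 bp; each
≈10-kb domain carries two 1-kb active genes placed symmetrically with ≈2-kb
margins to the barriers and to the central inactive probe (divergent,
convergent and tandem configurations).  Shock fold-changes proved insensitive
(<2%) to moving the genes 1 kb inward, consistent with orientation — not
position — being the controlling variable.  The divergent tetP/tufB cassette
uses 300-bp-spaced promoters inside one 5-kb domain of a 10-kb circle; the
distance-scan construct holds a 1-kb active gene and a downstream
reversed-curve probe promoter inside a 9-kb domain, at terminator-to-promoter
distances of 0–6 kb.  The default tetP induction sweep ends at k_on =
0.01 s⁻¹: beyond that the shared RNAP pool (8) saturates and the partner
gene's expression turns over, so the documented monotone mutual-activation
regime is the sub-saturation range.

Measurement windows: pre-shock rates over the 30 min before the shock,
post-shock over 30 min starting after a 5-min settling gap; probe rates are
time averages of the recorded instantaneous k_on·f(σ_local); active-gene
rates are event counts.  The anchored-plasmid repression factor compares the
first 10 min against the last 2 h of a 6-h topoI-only phase (the
single-promoter rate is bursty, so 20 replicate seeds are averaged);
recovery is the first time a 5-min sliding mean re-reaches 90% of the initial
rate.  Replicated analyses use ≥20 seeds with 95% bootstrap CIs.

## Topoisomerase recruitment

A ChIP-like activity track is accumulated per lattice site as the integral of
|dσ/dt|·dt of each enzyme.  Aggregated over whole topological domains this
integral is forced toward equality between the two enzymes by stationarity
(each domain's supercoil budget must balance over a steady window), so
orientation preferences are read from the *intergenic* intervals between the
gene pairs: gyrase activity is enriched (~1.06× genome mean) between
convergent genes and topoisomerase I (~1.15×) between divergent ones, with
the small amplitudes expected of this readout.

## Synthetic differential-expression fixtures

The generator builds a circular strand layout from alternating runs of
co-directional genes; every run of length ≥2 contributes exactly one
convergent and one divergent gene, so a circle always carries equal numbers
of the two classes (requested proportions must respect this; odd run counts
are rounded down, keeping realised counts within one of the request).
Responding genes receive p-values ≪ the 0.05 BH-adjusted threshold and a
signed log2 fold-change drawn per class from the planted activation
probability; non-responders get null-like values.  The fixtures emulate the
*statistical* structure of a relaxation-shock DE table — class proportions,
response fraction, activation bias — not read-count noise, library-size
effects or operon structure; passing tests therefore validate the analysis
pipeline and its calibration (5% null rejections, >99% power at the scripted
0.75/0.25 effect), not DE-caller behaviour on real sequencing data.  Gene
classification uses both flanking neighbours; genes in mixed contexts are
"ambiguous" and excluded from the two-class test; operons are not collapsed.

## Known limitations

* The convergent-probe shock factor settles at ≈2.5 rather than below 2: at
  moderate expression the convergent domain is transiently relaxed only about
  a quarter of the time (transcription bursts cluster the relaxed episodes),
  so its mean rate stays close to the idle-balance value whose pre/post ratio
  is itself ≈2.5.  Likewise the stationary mean-σ difference between the
  1-min and 10-min expression settings reaches ≈0.005–0.006 with the default
  pool of 8 RNAPs (the strong setting is partially pool-limited).
* Halving topoisomerase I activity deepens the divergent domains by
  Δσ ≈ −0.024 (three times the convergent shift) but the opening curve
  saturates below σ ≈ −0.06, so the divergent probes gain no measurable
  relative advantage; only the doubled-activity direction (convergent genes
  favoured) is a robust signed effect in this implementation.
* Binding probabilities are capped at min(1, k·dt); very strong promoters
  (k·dt > 1) are outside the intended regime.
* RNAPs occupy a single site with one-site occlusion; head-on collisions make
  both RNAPs wait indefinitely, so gene layouts must keep convergent
  transcribed spans disjoint.
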