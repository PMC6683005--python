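# Methods

## Model and assumptions

The method rests on one biophysical premise: subunits of a stable protein
complex travel through a native column as a single particle and therefore
co-elute, whatever the separation chemistry. Combining two orthogonal
separations (size exclusion, which orders species by hydrodynamic radius,
and ion exchange, which orders them by surface charge) makes chance
co-elution of unrelated proteins unlikely, because two proteins must then
agree on two independent physical axes, in both biological replicates.

Each protein × fraction profile is modelled as a sum of at most four
Gaussian components. A Gaussian is an idealization of a chromatographic
band (no tailing or fronting is modelled); each resolved component is
interpreted as a distinct oligomeric state of the protein. Fractions are
1-based contiguous integers and all peak locations are real-valued
fraction coordinates; a missing or undetected measurement is zero.

## Peak fitting

- **Fittability.** A profile is fitted only if it has two adjacent
  nonzero fractions; otherwise the maximum-intensity fraction is the
  peak (ties break to the earliest fraction, i.e. the largest apparent
  mass on SEC) and the raw profile is retained.
- **Constraints.** Centers μ ∈ [1, F], widths σ ∈ [0.3, F/2] fractions
  (narrower is noise, wider is baseline), amplitudes > 0, and adjacent
  centers ≥ 4 fractions apart (`min_separation`, configurable per
  separation). The separation constraint is enforced as a post-check on
  each converged bounded least-squares solution: a peak count whose best
  fit violates it is inadmissible.
- **Optimization.** Bounded trust-region least squares (scipy `trf`) with
  an analytic Jacobian. Starts: centers at the K highest local maxima of
  a lightly smoothed (σ = 1 fraction) profile, plus seeded jittered
  restarts (`n_starts` = 3 by default); lowest residual sum of squares
  wins. Everything is deterministic given (profile, configuration, seed);
  per-protein seeds are derived from the run seed and a CRC of the
  protein ID so results do not depend on row order.
- **Model selection.** `BIC = n·ln(RSS/n) + 3K·ln(n)` over K = 1…4
  (three free parameters per Gaussian); smallest BIC wins. RSS is floored
  at 1e−300 so an exact fit does not produce −∞.
- **Known limitation.** With an additive, zero-clipped background the
  clipping leaves a positive offset in signal-free regions that extra
  broad components can absorb, and BIC then over-selects K. The intended
  data regime is label-free XIC quantification, whose error is
  multiplicative (roughly constant CV) with a detection floor; the
  recovery guarantees quoted below are stated for that regime. Explicit
  baseline modelling is out of scope.

## Replicate consensus

Peaks from the two biological replicates are matched greedily by
ascending center distance, one-to-one, within a per-column tolerance
(2 fractions SEC, 4 IEX — wider for IEX because it has 65 fractions and a
salt-gradient elution). Matching is symmetric in replicate order; ties
break toward the earlier fraction. A consensus peak averages the two
matched peaks' parameters (the merge rule only affects reported peak
locations — the feature vector keeps both replicates).

A protein is retained only with at least one reproducible peak on *both*
columns. Multi-IEX-peak proteins become one entry per reproducible IEX
peak, suffixed `_peak1`, `_peak2`, … in elution order; every entry of a
protein carries the same SEC component — the earliest-eluting (largest
apparent mass) reproducible one — because that is the species most likely
to act as a complex subunit. Entry feature blocks contain only the
entry's own Gaussian component evaluated on the fraction grid (sibling
components zeroed), which is what makes sibling entries distinguishable
to the clustering; fallback (non-Gaussian) proteins contribute their raw
profiles.

Each of the four blocks (SEC r1, SEC r2, IEX r1, IEX r2) is min–max
scaled to [0, 1] *separately*, then concatenated (206 features at the
default 38 + 65 fractions). Block-wise scaling prevents the longer,
brighter IEX blocks from dominating the distance purely by length or
intensity scale. A constant block maps to zeros so distances stay finite.

## Clustering and cut selection

Profile similarity is squared Euclidean distance, d(x,y) = Σⱼ(xⱼ−yⱼ)².
The default linkage is Ward's criterion, which minimizes the growth of
within-cluster squared distance and therefore pairs naturally with the
metric; average linkage on the squared-Euclidean matrix is available by
configuration. Cluster IDs at a cut of k are numbered 1…k by dendrogram
left-to-right position, so adjacent IDs correspond to adjacent subtrees —
this is what gives the |ΔID| ≤ 2 concordance criterion its meaning.
Cutting uses the merge tree directly (`cut_tree`), so the partition at k
refines the partition at k−1.

The resolution diagnostic computes, at each cut of a sweep (default
20…600 by 10), every cluster's mean member-to-center squared distance
(singletons are exactly 0) and the cross-cluster quartiles. The default
reporting cut is the smallest k whose third quartile has collapsed to
≤ 10% of its value at the smallest cut — the point where the upper
quartile of the distance boxplot "approaches zero" because most clusters
have become tight or singleton. The 10% factor is a design constant of
this package; a fixed cut can be supplied instead (`fixed_k`), mirroring
the published choices of 300 clusters for a ~700-protein cytosol set and
200 for a ~400-protein chloroplast set. A distance exponent of 1
(Euclidean member-to-center) is exposed as a configuration flag because
both conventions appear in the field.

## Benchmarking

- **Intactness** = (max subunits of a known complex in one cluster) /
  (subunits detected in the clustering). The denominator counts detected
  subunits, not the complex's full catalogue.
- **Purity** = (subunits in that best cluster) / (cluster size); ties for
  best cluster break toward the smaller cluster, then the lower ID.
  `_peakN` entries count through their base protein.
- **Compartment mixing**: among clusters with ≥ 2 entries, the percentage
  whose members all share one compartment label; proteins confined to
  different compartments cannot interact, so this bounds the false
  discovery rate of co-elution from above.
- **Pair concordance**: for externally reported interacting pairs,
  observed matches are pairs with |cluster ID difference| ≤ D (default
  D = 2; D = 0 means same cluster). The null draws an independent uniform
  cluster ID in 1…k per protein, n_sim times (default 10,000), and
  reports the fraction of simulations with zero matches, the maximum
  match count, and an empirical p-value. Uniform drawing is the minimal
  reading of a random-ID null; per-pair match probability is
  q = (k + 2Σᵢ₌₁..D (k−i))/k², so the zero-match fraction has closed form
  (1−q)^P for P pairs — used as a cross-check of the simulation.
- **Condition comparison** (e.g. mutant vs wild type): per protein, the
  earliest-eluting reproducible peak per condition, Δfraction and ΔM_app;
  proteins without a reproducible peak in one condition are flagged "not
  detected" there. Shifts are reported descriptively, without a test.
- **Co-IP acceptance**: a pulldown hit is accepted when detected in ≥ 2
  of 3 test replicates and never in the negative control (both thresholds
  configurable).

## Calibration and classification

SEC calibration fits log₁₀(mass in kDa) linearly on peak fraction through
the standards (669–29 kDa by default); the slope must be negative.
Predictions before the first standard are flagged "≥ exclusion limit"
(void-proximal), beyond the last "extrapolated". `M_app` is the
calibrated mass of a peak fraction, `R_app = M_app/M_monomer`, and a
cluster's `M_calc` is the sum of its members' monomer masses assuming 1:1
stoichiometry (unknown masses are excluded and flagged).

Categories are assigned per entry by a first-match cascade, most specific
first; every rule an entry matches is also kept as a secondary flag:

1. singleton clusters by R_app: < 0.5 degraded; 0.5 ≤ R_app < 1.6
   monomeric; ≥ 1.6 homooligomer (the boundary sits at 1.6 exactly on
   the oligomer side);
2. clusters of 2–3 members with entry M_app ≥ 4·M_calc: possible homo-
   or hetero-oligomer with high subunit stoichiometry;
3. multi-peak proteins: an entry with M_app ≥ 4·(its cluster's M_calc) is
   a subcomplex / high stoichiometry; if instead *all* of a protein's
   entries have M_app > 1.4·M_calc, they are partial complex / false
   negatives;
4. clusters of ≥ 2 with |M_calc − mean M_app| ≤ 0.4·mean M_app: putative
   intact complex;
5. clusters with M_calc > 1.4·mean M_app (strict): members with
   R_app ≥ 1.6 are putative complexes clustered with false positives,
   members with R_app < 1.6 likely false-positive monomers;
6. anything else is reported explicitly as unclassified, with a reason.

Cluster-level rules 4–5 compare against the cluster's *average* M_app.
All thresholds are ratios, so the scheme is invariant to a common
rescaling of all masses.

## Synthetic data

The generator emulates the statistical structure of the profiled
experiment, not its biology. Defaults: 200 proteins, 20 planted complexes
with a truncated-geometric size distribution on 2–16 (mean ≈ 4; real
complexes skew small), 38 SEC / 65 IEX fractions, two replicates, peak
widths uniform on 0.8–2.0 fractions, 14% of proteins with a second IEX
peak, 5% contaminants, 2% dropout per matrix, multiplicative lognormal
intensity noise (CV 0.1) with a 10⁻³ relative detection floor, and
lognormal protein abundances (σ = 1) around a 10⁶ intensity scale.
Monomer masses are lognormal around 45 kDa.

A complex's SEC center comes from its summed member mass through the
inverse calibration (the packaged standards span 669–29 kDa over
fractions 6–32); a complex whose mass falls outside the calibrated window
is placed at a uniform random in-range fraction instead. IEX centers are
uniform with the high-salt last third downweighted. Because a complex
elutes as one particle, between-replicate jitter (normal, sd 0.5
fractions, truncated at half the reproducibility tolerance) and peak
width are drawn per *species* — per complex, or per monomeric protein —
with only small per-protein measurement noise (sd 0.15 fractions) on
top; modelling jitter independently per protein would contradict the
co-elution premise the method tests. Contaminants get independent random
centers in every replicate and so fail the reproducibility filter.
Everything is deterministic given the config seed.

What the generator does **not** emulate: peptide-level quantification and
razor-peptide ambiguity, correlated noise between co-eluting abundant
species (ion suppression), asymmetric peak shapes, partial complex
disassembly on the IEX column, and annotation errors. Passing the
end-to-end recovery test therefore demonstrates the pipeline's internal
consistency under the stated noise model, not performance on real
instrument data.

## Problem sizes and numerical choices

The packaged end-to-end check runs the default 200-protein / 20-complex
configuration (~800 profile fits, ~1.5 min); fit-recovery checks use 200
seeded 38-fraction profiles. Tolerances: optimizer ftol/xtol 1e−9 with at
most 200 function evaluations per start; separation post-check slack
1e−9; BIC RSS floor 1e−300. Degenerate inputs: all-zero profiles are
skipped with a log message (fallback requires signal); constant feature
blocks normalize to zeros; zero-variance profiles report an undefined R²
as missing; an empty entry list concatenates to an empty matrix.
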