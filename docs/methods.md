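# Methods

This note records the model, the numerical choices, the simulator design
and the known limits of `tricall`, in enough detail that every default can
be questioned.

## Mixture model and fitting

Each marker is treated independently. The observed contrasts
`c_ij = log2(A/B)` of marker i are modelled as a G-component univariate
normal mixture; cells with non-positive or non-finite signals are missing
and excluded from fitting. Two variance structures are fitted for every
cluster count G ∈ {1..ploidy+1}: shared variance (**E**, 2G free
parameters) and per-cluster variances (**V**, 3G−1). The assumptions are
the usual ones for array genotyping: clusters are approximately Gaussian
in contrast space, cluster order in contrast follows allele dosage, and
samples are independent given the cluster.

**Initialisation.** Each observation is hard-assigned to the nearest
reference contrast mean, giving a crude dosage and an allele-frequency
estimate p̂ = (mean dosage)/ploidy, clipped to [1/(2n), 1−1/(2n)] so
monomorphic-looking markers keep non-degenerate expectations. The g
dosage classes with the largest observed occupancy are retained (ties
broken by Binomial(ploidy, p̂) mass, then by lower dosage); expected class
proportions are the renormalised binomial masses of those classes; block
sizes follow by largest-remainder rounding with a minimum of one
observation per cluster; and the contrast-sorted blocks provide initial
means, variances and weights. Seeding clusters where the data actually
sit (occupancy) rather than where the binomial expects them matters for
markers whose empirical class counts deviate from Hardy–Weinberg.

**MAP-EM.** Cluster means carry a normal prior centred on the initial
block means. The prior precision is fixed for the whole run at
κ/σ̂²_g0, where σ̂²_g0 is the initial within-block variance and κ = 1
(one pseudo-observation at the initialisation scale). Two properties drove
this parameterisation over the alternative of re-scaling the prior by the
*current* cluster variance each iteration:

* the penalised objective (log-likelihood + log prior) is exactly
  non-decreasing, because each M-step is coordinate ascent — weights,
  then unpenalised variance MLEs given the old means, then the penalised
  mean update given the new variances — against a fixed penalty;
* the anchor fades as the data precision n_g/σ²_g grows, so on tight,
  well-populated clusters the converged means are the MLEs. A
  fixed-unit-weight pseudo-observation, by contrast, drags each mean by
  O(1/n_g) towards its initial block mean *regardless of cluster
  tightness*; when an initial block is slightly contaminated this inflates
  the within-cluster variance enough that model selection prefers
  spurious duplicated clusters on nearly noiseless data.

Variances and weights are unpenalised. Defaults: convergence when the
relative change of the penalised objective falls below 1e−6, at most 500
iterations, variance floor 1e−4 contrast units² (prevents density spikes
on duplicated values; a marker whose observations are all identical
converges with the floor variance). A component whose posterior mass
falls below 1e−3 observations marks the fit collapsed; collapsed and
non-converged fits are excluded from model selection. After convergence,
components are relabelled so means ascend. The fit is deterministic: one
start per candidate model, no restarts, so permuting the input order
leaves the result unchanged.

**Scoring.** With logL the observed-data mixture log-likelihood (prior
excluded), BIC = 2·logL − k·log n and ICL = BIC − 2·entropy of the final
responsibilities (0·log 0 := 0). ICL ≤ BIC always, with equality under
hard classification; ICL is preferred because genotype clusters should be
separated, and BIC alone tends to over-fit extra components when cluster
shapes are non-Gaussian.

## Calling, mapping and marker QC

Per cluster count the better variance mode is kept; the overall best ICL
classifies the marker, ties breaking toward fewer clusters. ΔICL is the
ICL gap between the two most likely *cluster counts* (not the top two
models overall — the two variance modes of one count are variants of the
same biological hypothesis). When only one cluster count is feasible,
ΔICL is stored as +∞, so such markers are never removed by a ΔICL filter
alone; they are policed by call rate and by the mapping rule instead.

With all ploidy+1 clusters present, clusters map to dosages by rank
(lowest contrast = all-B). Otherwise each cluster mean maps to the dosage
of the nearest reference mean; if two clusters collide on one reference
dosage the whole locus becomes a no-call. Shipped reference means are
−1.76/0.16/1.94 (diploid) and −1.97/−0.50/0.75/2.14 (triploid);
`GenotypeCallingResults.estimate_reference_means()` recomputes them from
any panel as the per-dosage average fitted means across markers showing
all clusters.

Samples are assigned to their maximum-posterior cluster (ties to the
lower-contrast cluster); uncertainty = 1 − winning posterior; a call is
dropped when uncertainty strictly exceeds 0.15 (an ulp guard keeps
exact-boundary posteriors such as 0.85 from flipping on rounding).
Single-cluster markers have posterior 1 everywhere, hence no
uncertainty-based no-calls — their reliability rests on the reference
mapping. Marker filters follow the published semantics: ΔICL strictly
greater than the threshold, call rate ≥ the threshold (with an ulp
tolerance).

## Pedigree rules and thresholds

Exclusion rules are *derived by enumeration* of parental contributions —
diploids pass one allele each; a triploid's mother passes a chromatid pair
(AA, AB or BB when she is heterozygous, because sister chromatids are
identical only up to crossovers), its father one allele — rather than
hard-coded; the test suite pins the derived tables to the published
12-row diploid and sexed-triploid tables. Unsexed triploid trios use only
configurations excluded under both sex orderings. Duo (offspring ×
candidate) ranking uses the minimal sex-agnostic rule, opposing
homozygotes; mother-specific exclusions add candidate AA with offspring
ABB/BBB and candidate BB with offspring AAA/AAB.

ER = exclusions / mutually-called markers; missing genotypes count in
neither numerator nor denominator, and a duo with no shared called
markers is dropped with a warning. mother.ER uses the same marker set as
ER. Default thresholds mirror the published procedure and are
configurable: markers with triploid ΔICL > 150 and parent marker call
rate ≥ 95% enter assignment; candidates with ER < 0.002 (strict) are
assigned, more than two assignments flag a conflict; an assigned parent
with mother.ER < 0.02 is the mother, ≥ 0.02 the father, and two mothers
or two fathers per offspring flag a conflict. Because the ER threshold
divides an integer exclusion count, its effective resolution is 1/markers:
with ~50k markers it tolerates dozens of error-driven exclusions, with
1000 markers essentially none, so both-parent recall at desk scale is
limited by marker count, not by the rules. The per-offspring
third-lowest-ER diagnostic (the closest non-parent) is reported to guide
re-tuning on other datasets. Duplicate samples are flagged at pairwise
dosage correlation > 0.99 over mutually called markers.

## Maternal recombination profile

At markers with a homozygous father, the offspring dosage minus the known
paternal allele gives the maternal pair; with a heterozygous mother the
pair is informative: heterozygous iff an odd number of effective
crossovers separates locus and centromere. The profile counts, per
marker, heterozygous maternal contributions over informative,
Mendelian-consistent trios; inconsistent trios (impossible maternal
A-count — genotype errors) leave both numerator and denominator and are
tallied separately. Defaults follow the published filtering: ΔICL > 50,
offspring marker call rate ≥ 0.80, parent marker call rate ≥ 0.95, at
least 50 informative trios, markers mapped and sorted by (chromosome,
position). No Hardy–Weinberg assumption is made on the inherited pairs —
the profile is a pure count ratio. A per-mother crossover report
(run-length segmentation of the deduced het/hom states with a minimum run
of 5 informative markers) is available as a deterministic extension; it
is a changepoint summary, not a genetic-map estimate.

## Synthetic data generator

The generator emulates the structure the method assumes: per-marker MAF ~
U(0.05, 0.5); Hardy–Weinberg diploid parents; triploid offspring by
second-polar-body retention; maternal meiosis as a switch-process
half-tetrad model — per chromosome arm a Poisson(1.0) chiasma count with
uniform positions, each chiasma flipping the retained pair's het/hom
state with probability 0.5 independently (no chiasma interference), hom
loci duplicating one randomly chosen maternal haplotype per chromosome;
paternal transmission of one haplotype per chromosome; signals drawn
around the reference means with a common per-marker shift ~ N(0, 0.15),
cluster SDs ~ U(0.08, 0.25) (half the markers with per-cluster SDs, half
shared), an optional "noisy" marker class with cluster SD 0.6, and a
0.5% dosage-level genotype error (a uniformly different dosage,
mimicking miscluster errors; a signal-outlier error mode is also
available). A fixed total signal A+B de-transforms contrast to the
two-channel dialect. All randomness flows from `numpy.random.default_rng`
(PCG64); a seed fully determines every output.

The closed-form het fraction of the meiosis model at centromere distance
d on an arm of length L, y(d) = (1 − exp(−2·rate·switch·d/L))/2, is the
ground truth the recombination module is tested against. It saturates at
1/2; real salmonid chromosomes show strong interference with telomeric
het fractions approaching 1, which this model deliberately does not
reproduce — passing tests show the deduction and counting machinery is
correct, not that the biology of interference is captured. Other known
gaps versus real data: no plate/batch effects, no residual-tetraploidy
("semi-fixed") markers, no DNA-quality gradients between samples, no
linkage in paternal gametes, and cluster shapes exactly Gaussian.

## Study problem sizes and panel-level choices

The acceptance script and tests use desk-scale problem sizes chosen once:
cluster-count recovery on 200 markers × 400 samples with cluster SDs
U(0.05, 0.15) (separation ≥ 8σ, the regime the criterion addresses); the
end-to-end study at 1000 markers, 10 mothers × 10 fathers × 3 offspring,
default noise; the ΔICL sweep on 800 markers × 40 diploid trios with 10%
noisy markers, clean-cluster SDs capped at 0.15 and no dosage errors —
the sweep isolates the filtering trend attributable to overlap-prone
markers, and both uniform dosage errors and rare clean-marker tail
miscalls are threshold-independent channels that would only add Poisson
noise to a pointwise-monotone comparison; recombination recovery on 5
chromosomes × 400 markers × 300 meioses from a single cross (informative
at every marker by construction). Because array genotypes share meioses
across markers, neighbouring markers' het-fraction errors are correlated,
so the CI-coverage fraction varies more between replicates than
independent binomials would suggest.

## Limitations

* Ploidies other than 2 and 3 fit the mixture machinery (the candidate
  set is 2·(ploidy+1)) but the pedigree and recombination modules assume
  diploid parents and second-polar-body triploids; tetraploid × diploid
  crosses would need different exclusion tables and no sex deduction.
* No batch-effect correction and no sex-chromosome-aware calling.
* The ER and mother.ER thresholds are dataset-dependent; the published
  values are defaults, and the third-lowest-ER diagnostic should be
  inspected before trusting them on a new chip or population.
* The caller provides no uncertainty for single-cluster markers, so an
  entirely monomorphic panel cannot be call-rate filtered meaningfully.
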