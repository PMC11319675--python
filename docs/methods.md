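# Methods

## Scope and data model

The package analyses three layers of evidence over a fixed rooted
phylogeny with branch lengths (Newick input; non-ultrametric trees are
used as given, no implicit ultrametricization): per-genome quality and
lifestyle metadata, per-genome KO annotations, and per-genome BGC
predictions. Trees are stored as flat node arrays (tips first, parent
pointers, children lists, per-edge lengths); polytomies are supported
throughout. The QC filter keeps genomes with completeness strictly above
90% and contamination strictly below 5% (both thresholds configurable);
boundary values are excluded on purpose, matching the strict inequality
convention. Upstream tool disagreement (e.g. two different completeness
estimators) is resolved before input: the metadata table carries one
completeness/contamination pair per genome.

Host-clade detection reports every maximal internal node with ≥ 2 tips
whose subtended tips all share one host category; free-living tips never
form clades, singleton host tips are not reported, and maximality makes
the reported clades pairwise disjoint.

## Molecular-function traits

A function definition is an ordered list of steps; each step is a boolean
expression over KO identifiers with `,` (OR, alternative orthologs), `+`
(AND, complex subunits; binds tighter than OR) and parentheses. The
grammar is total: an expression either parses or is rejected with a
position. Completeness is the unweighted fraction of satisfied steps;
binary presence is completeness strictly greater than the threshold, with
two presets: 0.98 ("complete") and 0.50 ("indicative"). Constant trait
columns are removed before enrichment scans (with the removed ids
reported), since a regression on an invariant response is undefined.

The shipped definition file covers headline functions (nitrogen fixation,
photosystem II, Fe–Mn transporter, glucoamylase, chitinase, riboflavin
biosynthesis, chemotaxis, Type I secretion, Sec–SRP, glucogenesis,
zeaxanthin diglucoside) as compact multi-step stubs over real KO
identifiers; the pipeline is correct for any definition set supplied in
the same format. Nitrogenase ortholog panels are mapped separately: the
iron–molybdenum panel (nifH K02588, nifD K02586, nifK K02591, anfG
K00531) and the vanadium panel (vnfD K22896, vnfK K22897, vnfG K22898,
vnfH K22899). K00531 and K22899 are marked *known-absent*: their absence
is systematic in cyanobacteria, so the pathway-detected flag requires all
panel KOs except those.

## BGC grouping

Records are 1-based inclusive GFF3-style intervals. The filter removes
contig-edge records (flagged upstream, or inferred as start = 1 or end =
contig length from a contig-length table) and records shorter than
3000 bp; a record of exactly 3000 bp is retained ("shorter than" removes
strictly). Domain composition is treated as a set; Dice similarity
2|A∩B|/(|A|+|B|) with an edge threshold (default 0.5 = "majority of
domains shared"; the threshold is a free parameter of this artifact and is
exposed as `--edge-threshold`) defines a weighted graph. Pair similarities
are computed through a sparse record×domain incidence product, so the
construction scales with shared-domain pairs rather than all pairs.
Louvain community detection (networkx implementation, seeded; edges
weighted by Dice) partitions the graph; isolated records become singleton
groups so that group sizes always sum to the number of filtered records.
The reported modularity Q is recomputed from its definition independently
of the optimizer. Each group takes the majority predicted class (ties
broken lexicographically; hybrid `+`-joined labels count as their full
label), and only groups containing at least one antiSMASH (or MIBiG)
member survive into the final set. An external reference collection can be
mixed in simply as additional records with an annotation-grade source.

## Phylogenetic logistic regression

Binary traits are modelled as a two-state Markov process along the tree:
one switching rate α (per unit branch length) and branch-specific
stationary frequencies. Tip i's equilibrium is π_i = logit⁻¹(x_i'β); an
internal branch uses the mean equilibrium of the tips it subtends (a
proper, likelihood-coherent interpolation of the tip covariates along the
tree). Transition probability over a branch of length t with equilibrium
π is P(a→b) = (1−e)π(b) + e·δ_ab, e = e^(−αt), and the exact likelihood
is computed by pruning. Lineages that diverge at the root share no path
and therefore carry no covariance: each root-child subtree starts from an
independent stationary draw at its own equilibrium. Two consequences
anchor the model: on a star tree the likelihood factorizes into
independent Bernoulli(π_i) terms — the fit collapses exactly to ordinary
logistic regression — and as α→∞ the same independence limit is reached
on any tree.

Estimation maximizes the Firth-penalized likelihood ℓ(β, α) +
½ log det(X'WX), W = diag(π(1−π)), jointly over (β, log α), which keeps
estimates finite under complete separation (a separation flag is still
reported). The tree is rescaled to unit height internally and log α is
bounded in [−4, 4] on that scale (α is reported back on the original
branch-length scale); optimization is L-BFGS-B followed by a damped-Newton
polish with finite-difference derivatives (gradient tolerance 1e-8, max
200 iterations). Inference reports both a Wald p (finite-difference
Hessian of the penalized objective) and a parametric-bootstrap p
(headline): B = 100 trait simulations under the fitted model along the
tree, refit with α held at its estimate, two-sided
p = (1 + #{|β*−β̂| ≥ |β̂|})/(B+1). Holding α fixed during refits trades a
small amount of bootstrap spread for an order-of-magnitude speedup; the
calibration tests cover the combined procedure. Kernels are JIT-compiled
with numba (a pure-Python fallback computes identical values).

Enrichment scans fit one model per trait column against the lifestyle (or
host-source) factor, with 'free-living' as baseline. Significance is the
uncorrected p < 0.05 rule on the bootstrap p; a Benjamini–Hochberg column
is emitted for transparency but does not drive the flag. Per-trait RNG
streams are derived as crc32(global_seed, trait_id) so parallel or
reordered scans reproduce bit-identically.

## Phylogenetic linear regression (counts)

BGC counts (total and per class) are fit by maximum likelihood under
y ~ N(Xβ, σ²·V_λ), where V is the shared-path covariance from the tree
and V_λ multiplies off-diagonals by λ ∈ [0, 1] (diagonal unchanged). λ is
profiled on a 0.01 grid (Cholesky factors cached per tree) and refined by
bounded scalar optimization (tolerance 1e-6); β and σ² are closed-form
GLS given λ. Estimates stay on the raw count scale. Wald p-values use the
t distribution with n−p degrees of freedom and the unbiased variance
estimate; the parametric bootstrap (B = 100) simulates Gaussian responses
from the fitted model and refits on the λ grid, vectorized across
replicates. Constant count columns (e.g. an all-zero class) are flagged
and excluded from fitting rather than silently dropped.

## D statistic

For a binary trait, nodal values are estimated tips-to-root (each internal
node the arithmetic mean of its children), and the observed d is the sum
over internal nodes of Σ_children |child − node|; polytomies sum over all
children. d is scaled between two simulated expectations with the same
prevalence: D = (d_obs − mean d_Brownian)/(mean d_random − mean
d_Brownian), with 1000 null sets by default. The random null permutes tip
values; the Brownian null simulates a liability (root 0, per-branch
variance = branch length; zero-length branches add none) and thresholds
at the empirical quantile so that exactly round(prevalence·n) tips are 1 —
keeping prevalence identical across observed and null sets makes the d
values directly comparable. p_random is the fraction of permuted d ≤
d_obs; p_brownian the fraction of Brownian d ≥ d_obs.

## Synthetic studies

The generator emulates the statistical structure of a phylum-scale
survey at desk scale. Defaults: a 300-tip Yule tree (pure birth, rate 1,
tips extended to the present, so trees are ultrametric); 8 disjoint
planted host clades of 2–10 tips, categories assigned cyclically from the
ten host categories; 40 functions of 3–5 steps each over a private KO
range, with one function enriched in host-associated genomes (log-odds
+3 on baseline −1.5), one depleted (−3 on +1.5), the rest null with
baselines drawn in logit [−1, 1]; 30 BGC domain archetypes (5–30 domains,
pairwise disjoint, so planted Dice separation is exact), per-genome
archetype prevalence 0.1–0.5 for free-living genomes and scaled down for
host-associated genomes so the expected total-count reduction equals 4
(one archetype instead planted as host-enriched, 0.1 free vs 0.9 host);
2 archetypes never receive antiSMASH backing (exercising the retention
rule); domain dropout 0.05 and gain 0.02 as mild annotation noise; decoy
records violating the length/edge filters at rate 0.05 each; 15 extra
off-tree genomes that fail QC, always including the exact 90.0%/5.0%
boundary cases. Trait presence is translated into KO content exactly
(present = all step KOs; absent = a strict subset of steps), so the truth
table equals the classifier output by construction. An optional Brownian
copula adds phylogenetic correlation to trait presence while preserving
the marginal logistic model (off by default, so regression calibration is
tested in the well-specified independent regime).

What the generator does not emulate: real KEGG-Decoder rule sets,
unbalanced or non-ultrametric empirical trees, correlated traits,
multi-copy BGCs within a genome, and annotation error structure beyond
uniform dropout/gain. Passing tests therefore demonstrate correctness of
the estimators and pipeline plumbing under the planted model, not
robustness to every property of real survey data.

## Numerical choices and problem sizes

Tolerances: Newick round trip 1e-9; modularity recomputation 1e-12;
star-tree logistic vs independent Firth 1e-4; GLS λ refinement 1e-6.
Tie-breaks: consensus class lexicographic; Brownian threshold by liability
rank with index order on ties. Degenerate inputs (constant responses,
empty domain sets, missing labels) raise located errors or are flagged in
scan output, never silently dropped. The test-suite and acceptance-script
study sizes — 100-tip trees with 100–200 replicates for regression
calibration, 50-tip trees with 200 null sets for D-statistic calibration,
and 30–50 end-to-end replicates at the default 300-tip scale — were
chosen to give stable Monte-Carlo estimates at minutes-scale runtime on a
single core.

## Known limitations

Tip-reordering invariance of the logistic fit holds to ~1e-7 (not machine
precision): permuting tips changes floating-point summation order inside
the pruning likelihood, which moves the optimum slightly. The Wald and
bootstrap tests inherit Firth's small-sample conservativeness (empirical
size ~0.02 at nominal 0.05 for n = 100). The logistic model's internal
branch equilibria are subtree means of tip equilibria — a modelling
convention, since covariates exist only at the tips. Louvain is a greedy
heuristic: global modularity optimality is only guaranteed on the small
planted cases where the tests verify it exhaustively.
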