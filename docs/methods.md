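# Methods

This note documents the models, defaults and numerical choices behind
`cranionet`, and what the synthetic study conditions do and do not show.

## Bone-contact networks

A specimen is a labelled, undirected, unweighted graph: nodes are bones
or fused bone units, edges are sutures or articulations. Input matrices
must be square 0/1 CSVs with identical row/column label order; symmetry,
a zero diagonal, uniqueness of labels and (by default) connectivity are
enforced at read time. Disconnected graphs are rejected because the mean
shortest path length L is undefined on them; an `allow_disconnected`
override exists for deliberately degenerate inputs (e.g. the
two-disconnected-cliques modularity fixture).

Laterality is encoded in the label suffix: `_L`/`_R` for the two copies
of a paired bone, `_M` for unpaired midline elements (case-insensitive).
A label without a recognized suffix is treated as midline, which matches
how unpaired elements are usually written in contact matrices. Users
transcribing published supplementary matrices should map their bone
vocabulary onto this convention; only the suffix matters to the code.

Fusion (`fuse_bones`) replaces two bones by one unit whose neighbour set
is the union of the two originals; it models ontogenetic suture closure
and decreases N by exactly 1. `drop_unpaired` deletes all midline
elements, reproducing the deletion experiment used to probe whether
left–right module asymmetry is an artefact of unpaired bones; the result
may legitimately be disconnected, which is reported as a warning, not an
error.

## Network parameters

* D = 2K/(N(N−1)).
* C: mean over all nodes of the local clustering coefficient; nodes of
  degree < 2 contribute 0 and are included in the mean, which keeps C
  defined on trees. A flag (`include_low_degree_in_c=False`) excludes
  them instead.
* L: mean shortest-path length over unordered node pairs (self-pairs
  excluded).
* H: SD of the degree sequence divided by the mean degree. The sample
  (n−1) SD is the default, matching R's `sd` used by the common analysis
  scripts in this literature; `ddof=0` switches to the population SD.
  Although sometimes labelled a "variance" of connectivity, H as defined
  in the methodological sources is this normalized dispersion; the name
  discrepancy is deliberate and documented here.

## Module detection

1. **GTOM.** Order-1 generalized topological overlap:
   t_ij = (shared neighbours + a_ij)/(min(k_i, k_j) + 1 − a_ij), unit
   diagonal. The order is configurable (m-step neighbourhoods); 1 is the
   default because higher orders progressively wash out local structure
   on graphs of only 10–45 nodes. Degree-0 nodes make the denominator
   degenerate and are an error.
2. **Ward.D2** on the dissimilarity 1 − GTOM, implemented via the
   Lance–Williams update with inputs treated as distances (not squared).
   Ties in the minimal merge distance are broken toward the
   lexicographically smallest cluster-index pair, making dendrograms
   bit-reproducible across platforms (verified against scipy's `ward` on
   tie-free inputs).
3. **Q-modules.** Every cut k = 1..N of the dendrogram is scored with
   Newman's modularity Q = Σ_s [l_s/K − (d_s/2K)²]; the cut maximizing Q
   is returned, ties broken toward fewer modules (the more conservative,
   more integrated reading).
4. **S-modules.** Candidate clusters are tested for members having more
   internal than external contacts (one-sided Wilcoxon rank-sum; exact
   permutation null when the larger side has ≤ 25 members — contact
   counts are heavily tied, and the tie-corrected normal approximation
   over-rejects on tiny samples — normal approximation with tie
   correction otherwise; minimum cluster size 3). Two views are
   reported:
   * the **canonical per-specimen count** tests the modules of the
     Q-optimal partition. This follows the description of the test being
     applied to "each module", and behaves correctly in the edge cases: a
     complete graph is a single all-inclusive module with no external
     contacts and has 0 S-modules; two bridged cliques give 2; planted
     modules are counted once each.
   * the **dendrogram-wide p-value map** over all internal clusters (the
     figure-style display, where circles mark p < 0.05/0.01/0.001),
     summarized as the number of innermost significant clusters and the
     total. A purely "maximal significant cluster" count is not useful:
     the union of any two dense modules is itself always significant, so
     that rule collapses nearly every skull to 2.
5. **P** = 1 − Σ (N_s/N)² over the Q-partition.
6. **Asymmetry** counts bone names whose `_L` and `_R` copies receive
   different module ids. On a perfectly mirror-symmetric network with no
   cross-side contacts the dichotomous dendrogram cannot co-assign the
   two sides, so mirrored left/right module twins are expected; the
   complementary check `partition_mirror_consistency` verifies the
   module distribution is identical on the two sides (a well-defined
   left→right module bijection), which is the meaningful symmetry
   statement for the unpaired-bone deletion experiment.

## Morphospace

The nine ordination variables are N, K, D, C, L, H, S-module count,
Q-module count and Q_max; P is excluded. Natural logs are taken first;
variables that can be exactly 0 (C on triangle-free graphs, Q_max on
cliques, S-counts) are offset by ε = 1e−6 with a warning. Gower distance
averages range-normalized absolute differences; a zero-range column
contributes 0 (warned) rather than poisoning the matrix. PCoA is
classical scaling: double-center −½ J D² J, eigendecompose, keep
positive-eigenvalue axes scaled by √λ. Gower distances need not be
Euclidean, so negative eigenvalues can occur; they are dropped by
default and their summed magnitude reported, with Lingoes and Cailliez
corrections available behind a flag. Axis signs are fixed by making each
axis's largest-magnitude coordinate positive.

## Statistics

* Mann–Whitney U is reported on the z scale with tie-corrected variance
  and no continuity correction (the convention of the desktop statistics
  packages this literature uses); |z| is the statistic, the sign is kept
  separately, and a continuity-correction toggle exists.
* Kolmogorov–Smirnov uses the asymptotic two-sample p.
* OLS uses the closed-form slope with a two-sided t-test.
* The ANCOVA compares a two-slope model against a common-slope model;
  F on (1, n₁+n₂−4) df equals the squared t of the group×covariate
  interaction.
* PERMANOVA uses Anderson's pseudo-F on squared distances with raw-label
  permutation and p = (#{F* ≥ F} + 1)/(n_perm + 1); pairwise two-group
  tests multiply p by the number of comparisons (Bonferroni), capped at
  1. 10,000 permutations by default.
* Relative skull size: juveniles as % of the conspecific adult skull-box
  volume; adults as % of the largest sampled adult volume.

## Phylogenetic layer

* `consensus_edges` averages each edge's length over a set of trees
  sharing one (rooted) topology — the temporal consensus of a
  posterior tree sample. Trees are always treated as rooted.
* `split_ontogenetic_tips` turns species tips into juvenile/adult
  cherries with pendant length 1 (birds) or 10 (crocodilians and other
  slow-growing non-birds, reflecting their longer ontogeny). Tip depth
  is preserved by shortening the original pendant edge; if that edge is
  shorter than the cherry length the attachment edge is set to 0 and the
  tree deepens by the difference — only relative depths matter
  downstream.
* **pFDA.** The Brownian covariance V (shared root-to-MRCA depths) is
  λ-scaled (off-diagonals × λ), inverted to the −1/2 power by symmetric
  eigendecomposition with an eigenvalue floor of 1e−10, and used to
  whiten the trait rows; an ordinary LDA is fitted to the whitened
  training rows. λ is selected on a 0–1 grid (step 0.01) by
  leave-one-out training misclassification, ties resolved toward the
  smallest λ (weakest assumed phylogenetic signal). Test taxa are
  whitened jointly with the training taxa through their own tree
  positions before classification. At λ = 0 on a star tree this reduces
  exactly to ordinary LDA. A rank check rejects singular within-group
  covariances with advice to reduce the number of trait axes.
* **BM ASR.** Under Brownian motion the joint likelihood of all node
  values is Gaussian with precision equal to the tree's graph Laplacian
  weighted by 1/branch-length, so the ML internal states solve one
  sparse linear system; the root estimate equals the GLS phylogenetic
  mean (1'V⁻¹x)/(1'V⁻¹1). Verified against R's `ape::ace` (ML) in the
  test suite. Branch lengths must be positive.
* **Juvenile substitution.** adj_i = residual_i + (α + β·s_min) from the
  OLS of trait on relative size — every juvenile slid down the common
  ontogenetic trend to the youngest sampled stage ("hypothetical
  hatchling"). A constant size covariate makes the regression
  inestimable and is an error.
* **Parsimony proxies.** The sample SD of all internal-node values
  (lower = smoother, more parsimonious evolution) and Σ log|value|. The
  log-product is ill-defined for values ≤ 0 — ordination scores are
  routinely negative — so it carries a validity flag and the SD proxy is
  the one to interpret.

## Synthetic study conditions

`SkullTemplate` defaults: 12 bone pairs + 4 midline bones (28 bones,
the scale of a juvenile bird skull; fusion series reach the 10–25 range
of adults), 3 planted modules, p_in = 0.9, p_out = 0.05, and
p_pair_contact = 0.5 — roughly half of paired skull bones (frontals,
parietals, nasals, premaxillae) meet their antimere at a midline suture,
and this cross-side wiring is what lets a planted module span both
sides as a single blob rather than decomposing into left/right halves.
Edges are drawn on the left side and mirrored, so every generated skull
is exactly bilaterally symmetric; connectivity is enforced with
mirror-symmetric bridge edges.

`make_study` builds juvenile/adult pairs per species from one base
skull: the adult applies 8–13 suture closures, the juvenile 0–4, and
relative size tracks closure progress with 5% noise; outgroup taxa keep
0–3 closures (the ancestral, unfused condition). The taxon tree is a
pure-birth clock tree with outgroups on the earliest-diverging tips.

What passing tests on these conditions show: the pipeline's estimators
recover planted structure (modules, ontogenetic slopes, juvenile/adult
separation, smoother substituted reconstructions) when the generating
process matches the model assumptions. What they do not show: robustness
to scoring error in real matrices, to non-Brownian trait evolution, to
unbalanced sampling of ontogenetic stages, or to the anatomical
correlations (shared developmental origins of neighbouring bones) that
real skulls have and the stochastic block structure does not emulate.

## Numerical and reproducibility choices

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the pipeline derives stage seeds from one
  root seed, and rerunning a config reproduces byte-identical CSV/JSON
  outputs (verified by manifest SHA-256 digests). The permutation seed
  affects only PERMANOVA p-values.
* Ward heights are clamped monotone against floating-point jitter;
  Q-cut ties use a 1e−12 tolerance.
* Problem sizes in the shipped test and acceptance runs (e.g. 200
  random graphs ≤ 15 nodes for the parameter oracles, 500 seeds for
  root-recovery bias, 100 seeds for the substitution comparison, 12+5
  taxa in the synthetic cohort) were chosen as the smallest scales at
  which the corresponding statistical statements are stable; all
  generators accept larger sizes.

## Known limitations

* Weighted or directed contact networks are out of scope.
* Overlapping community detection (e.g. OSLOM) is not implemented; the
  dendrogram-based partition cannot express bones belonging to two
  modules.
* PERMANOVA is one-way only; no covariate-adjusted or multi-factor
  designs.
* pFDA assumes an ultrametric tree and a common within-group covariance
  after whitening; λ is a single scalar for all traits.
* The BM ASR uses a single constant rate; OU or multi-rate models are
  not provided.
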