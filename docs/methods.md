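# Methods

`bridgenet` estimates regularised partial-correlation networks over ordinal
survey items, identifies central and bridge variables by expected-influence
centrality, and gates every interpretation on bootstrap stability. This note
records the statistical model, the defaults and why they were chosen, what
the synthetic generator does and does not emulate, and the numerical
decisions a maintainer would want written down.

## Model and pipeline

Respondents answer p items on a 1–5 Likert scale (1 "substantially reduced"
… 5 "substantially increased"). Items belong to one of two declared
communities — lifestyle behaviours or health outcomes — and items worded in
a "less …" direction are reverse coded at load time (x → min+max−x), so
that higher always means healthier. Screening charges each excluded record
to the **first** failing rule in the fixed order blank/incomplete →
duplicate → failed validation question → non-participating country →
missing age/gender, so the per-rule counts partition the excluded set and
`screened = eligible + Σ excluded` holds by construction.

Analysis proceeds in five stages:

1. **Redundancy screening.** For every item pair with |r| ≥ 0.5 the
   back-transformed-average Fisher-z test for two dependent overlapping
   correlations compares the pair's correlation profiles against each third
   item; a pair is flagged when fewer than 25% of those comparisons differ
   at α = 0.01. Connected groups of flagged pairs collapse to a single kept
   item — by default the member with the largest mean |r| to items outside
   the group, ties broken by lowest item id; an explicit keep-list
   overrides. Reduction is one-shot (no iterative re-testing), matching the
   usual practice of removing a redundant block in one pass.
2. **Network estimation.** Pearson correlations on integer scores
   (listwise-complete per network) feed a graphical lasso along 100
   log-spaced penalties from λ_max = max|off-diagonal r| down to
   0.01·λ_max. Each fit is scored with the extended BIC,
   EBIC = −2L + E·log n + 4γ·E·log p with γ = 0.5,
   L = (n/2)(log det K − tr(SK) + p) and E the count of off-diagonal
   entries above 1e−8; the minimiser is kept (ties resolve to the sparser,
   larger-λ fit). The selected precision matrix K becomes edge weights
   w_ij = −K_ij/√(K_ii·K_jj).
3. **Centrality.** Expected influence EI(i) = Σ_j w_ij (signed, one-step)
   within each network; bridge expected influence BEI1(i) = Σ_{j in other
   community} w_ij on the pooled network. Identities Σ EI = 2Σ_{i<j} w_ij
   and EI − BEI1 = within-community strength are asserted in tests.
4. **Stability.** A nonparametric bootstrap (rows resampled with
   replacement, full re-estimation, B = 1000 by default) yields edge-weight
   quantile CIs and per-node replicate centralities. A case-dropping subset
   bootstrap over 10 drop proportions evenly spaced on [0.05, 0.75] yields
   the correlation-stability coefficient: the largest proportion q* such
   that every evaluated q ≤ q* keeps ≥ 95% of replicates correlating ≥ 0.7
   with the full-sample centralities. CS ≤ 0.25 marks a network
   uninterpretable (central/bridge columns become NA); the gate is a strict
   ">". Rounded to two decimals the grid produces the value lattice
   {0.00, 0.05, 0.13, 0.21, 0.28, 0.36, 0.44, 0.52, 0.59, 0.67, 0.75}.
5. **Selection.** Pairwise paired Wilcoxon signed-rank tests on the B
   replicate centralities (zero differences dropped; an all-zero pair
   scores p = 1; exact null for ≤ 25 effective pairs, normal approximation
   with continuity correction above), Holm–Bonferroni adjusted over all
   p(p−1)/2 pairs. The reported top set is the argmax plus every node whose
   adjusted p against the argmax is ≥ 0.05. For the bridge network the
   argmax is restricted to lifestyle nodes, while BEI1 and its tests cover
   all nodes. Applying a paired location test across bootstrap replicates
   is statistically unorthodox (replicates are not independent subjects):
   it detects *sample-level* centrality differences, so in a connected
   network it will flag almost any observed gap as B grows, and it is only
   conservatively calibrated when estimated networks carry no signal (the
   all-zero-difference convention). It is the default because it is the
   procedure this pipeline reproduces; the conventional alternative — the
   empirical CI of the replicate differences excluding zero — is available
   via `centrality_difference_test(..., method="bootstrap_ci")`.

## Key parameters

| parameter | default | rationale |
|---|---|---|
| correlation type | Pearson on 1–5 scores | deterministic, fast; Spearman available; polychoric not implemented |
| n_lambda / min ratio | 100 / 0.01 | conventional EBIC-glasso path resolution |
| EBIC γ | 0.5 | standard sparsity/discovery compromise |
| zero tolerance | 1e−8 | separates solver zeros from small weights in the edge census |
| redundancy α / proportion / corr floor | 0.01 / 0.25 / 0.5 | screening convention; floor restricts candidates to strongly correlated pairs |
| bootstrap B | 1000 | difference tests on 1000 replicate indices |
| drop grid | 10 points, 0.05–0.75 | reproduces the standard CS value lattice |
| CS thresholds | 0.7 corr, 95% prob, gate 0.25 | acceptable > 0.25, preferable > 0.5 |
| planning rule | 3 per edge parameter | n ≥ 3·p(p−1)/2; shortfall warns but does not abort |

## Synthetic data

The generator draws a sparse two-community partial-correlation truth:
within-community edges appear with a configurable density (default 0.2) and
uniform weights (default 0.2–0.5 on the partial-correlation scale), and a
configurable number of cross-community bridge edges (default 3) are placed
uniformly at random unless pinned explicitly. The precision matrix is
I − P; if not positive definite, all weights shrink toward diagonal
dominance (declared zeros stay exactly zero). Latent Gaussian vectors with
the implied correlation structure are discretised through per-item
cutpoints — equal 20% category masses by default, with a shifted "skewed"
preset that mimics the 2.6–3.9 item-mean range typical of real
pandemic-impact surveys. Respondent counts in tests and the acceptance
script (150–2000) sit inside the per-country range such surveys report.

What the generator does **not** emulate: polychoric-scale measurement
error, item-level missingness patterns, sociodemographic confounding,
country-level heterogeneity in thresholds, and acquiescence/social
desirability response styles. Passing recovery tests therefore show the
estimation and inference machinery is correct under a latent-Gaussian
ordinal model — not that any particular real survey meets that model.

## Numerical choices

- **Solver.** `sklearn`'s graphical-lasso coordinate descent, warm-started
  along the descending penalty path, dual-gap tolerance 1e−3 (profiled:
  selection and edge sets are identical to tol 1e−4 on this problem class,
  at ~5× less cost). Penalties whose dense fits are too ill-conditioned for
  the solver (possible in the path tail on near-singular correlation
  matrices) are skipped with a warning; λ = 0 falls back to direct
  inversion. Bootstrap replicates that collapse an item to zero variance
  are redrawn (≤ 10 times, then error); case-dropping subsamples that do
  so count correlation 0, conservatively.
- **EBIC constant.** The +p term in L makes a diagonal K on an identity S
  score exactly 0; constants cancel in selection.
- **Quantiles.** Edge CIs use type-7 (linear-interpolation) empirical
  quantiles so intervals are bit-reproducible.
- **Determinism.** Every stochastic routine takes an integer seed and uses
  an independent `numpy` Generator; re-running a country with the same seed
  reproduces the summary byte-for-byte. Ties (EBIC, keep policy, top-edge
  order, grouping) all break deterministically, lexicographically on ids.
- **Problem sizes.** The test suite and acceptance script run the
  bootstrap-heavy recovery studies with a 30-point penalty path and
  1500–2000 respondents (EBIC selection on a log grid is insensitive to
  path resolution at this scale), keeping a full desk run on one CPU in
  the tens of minutes; point-estimate recovery uses the full 100-point
  default path.

## Limitations

- Pearson correlations on ordinal scores attenuate latent associations
  (a 0.6 latent partial correlation yields roughly 0.45–0.55 observed);
  edge magnitudes are therefore conservative relative to a polychoric
  analysis, though rankings and recovery are robust in the tested regimes.
- No refit of the unpenalised MLE on the selected support: reported
  weights carry lasso shrinkage.
- The redundancy screen tests pairs marginally; heavily overlapping blocks
  with more than ~4 items may need the explicit keep-list.
- Listwise deletion per network means the three networks of one country
  can have different effective n when item-level missingness is present.
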