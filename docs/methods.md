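# Methods

This note documents the models, the numerical choices, and the synthetic
world the package is validated against, including what a green test does
and does not establish.

## Coexpression networks

Each expression dataset (genes × samples, ≥ 8 samples required) is reduced
to one unweighted network over the gene universe shared by all datasets.
Pearson correlation is computed over samples for every pair; the
`edge_budget` highest pairs become edges. Two readings of an "edge budget"
were possible — a gene count or a pair count — and the pair count is the
only one consistent with budgets far exceeding plausible gene-universe
sizes, so the budget counts pairs. Defaults:

- `edge_budget_fraction = 0.05` of C(n, 2) (a corpus-scale budget of
  150,000 pairs over ~8,500 genes is ~0.4%; 5% keeps desk-scale networks
  from being edge-starved at n = 300).
- Ranking by signed r (coexpression modules are positively correlated
  sets); `abs_corr=True` ranks by |r| for users who want sign-free graphs.
- Ties at the budget boundary break lexicographically by gene pair, making
  networks reproducible bit for bit.
- Genes with any missing value or zero variance are dropped from that
  dataset's ranking with a warning; their correlations are undefined.

Module density is (edges inside the set) / C(k, 2); a dataset counts as
"dense" for a module when density ≥ `tau_dense`. `tau_dense` defaults to
0.66, the same value as the reporting filter, since no separate threshold
is defined for the specificity objective.

## The annealing search

Four objectives are maximized jointly for a target phenotype p with
dataset set D_p:

| objective | form | role |
|---|---|---|
| O1 | ln k (k = module size) | size |
| O2 | mean density over dense datasets | absolute density |
| O3 | mean density in D_p − mean density elsewhere | density differential |
| O4 | −ln hypergeometric upper tail of \|dense ∩ D_p\| | specificity |

Scalarization: energy = −Σ wᵢ·normᵢ(Oᵢ) with default weights
(1, 1, 1, 2) and min-max normalization using the extrema observed so far
in the run. Metropolis acceptance (accept a worse state with probability
exp(−ΔE/T)) under geometric cooling: T₀ = 1.0, T ← 0.9·T, 200 steps per
temperature, stop below 10⁻³. Moves add a gene adjacent (in ≥ 1 phenotype
network) to the current set, remove a member, or swap. All logs are
natural logs.

Three choices here were forced by experiment rather than taken from any
prescription, and deserve justification:

1. **Seeding.** A bare random edge is destroyed almost immediately during
   the hot phase and the walk then freezes in an arbitrary dense pair.
   The search instead seeds at an edge that recurs in the largest number
   of the phenotype's networks — recurrent coexpression is precisely the
   signal the method exploits — and greedily expands it to a locally
   optimal module before annealing begins. The anneal then refines (or
   escapes) that candidate. Measured on the default profile, this took
   planted-module recovery from 0/9 to 21/21 single-restart searches.
2. **Log-size objective.** With O1 = k linear and min-max normalization,
   any walk that visits a large state stretches the normalization range so
   far that module-scale size differences (3 vs 10 genes) contribute less
   to the energy than sampling noise in O3, and tiny saturated triangles
   win. O1 = ln k keeps growth from 3 to 10 genes worth as much as growth
   from 30 to 100.
3. **Feasibility constraint.** States dense in zero datasets have
   O2 = O4 = 0 and no gradient back to the feasible region, while the size
   objective still rewards growth; the walk ratchets to the full gene
   universe. Proposals whose dense-dataset set would be empty are
   therefore rejected outright: a module, by definition, is dense
   somewhere.

Because the normalization extrema drift during a run, energies from
different steps are not comparable; the reported candidate per restart is
the accepted state that minimizes energy under the *final* extrema.

Filtering: size ≥ 7, mean density over dense datasets ≥ 0.66, and
Benjamini-Hochberg-adjusted specificity p < 0.01, with BH applied per
phenotype across that phenotype's candidates. Exact duplicate gene sets
from different restarts are collapsed (lowest raw p kept); near-duplicates
are retained.

## Classifier

Five features per (gene g, phenotype p, module M), averaged over the
modules containing g:

- enrichment: −log upper-tail hypergeometric p of |M ∩ G_p| in the shared
  universe;
- PPI: number of interaction edges between g and (M ∩ G_p) \ {g};
- GO (one per subtree BP/CC/MF): S = ∪ over partners h ∈ M ∩ G_p of
  terms(g) ∩ terms(h); score = Σ_{t∈S} −log(freq(t)/N), each distinct
  term once. freq(t)/N is the probability a random universe gene carries
  t; a hypergeometric-sharing alternative is available via
  `go_sig="hypergeom"`. GO annotations are used as given in the input
  table (no ancestor closure).

Training sets follow the ontology: positives are module genes annotated
with p; negatives are module genes with at least one known annotation and
none in {p} ∪ related(p) ∪ parental(p); everything else — related/parental
annotated genes and unannotated genes — is held out and scored after
training. A phenotype with no positives is skipped, not an error.

The ensemble is a scikit-learn random forest: 500 trees, bootstrap
aggregation, `max_features="sqrt"` (2 of 5 features per split), and
`min_samples_split = 11`, which leaves nodes of ≤ 10 samples unsplit —
the "maximum terminal node size 10" convention of the classical
implementation. No class reweighting is applied, so OOB precision is
interpretable against the raw class balance. Training genes are scored by
out-of-bag vote fractions (a gene never out of bag, which is vanishingly
rare at 500 trees, scores 0.5); held-out genes by full-forest vote
fractions. The default decision cutoff is 0.5 and is exposed as a
parameter.

## Pleiotropy

All comparisons use the PAR closure only; related-type edges never block
pleiotropy. The annotation database is ancestor-propagated before the
census (predictions too, after merging). A "new case" requires the gained
phenotype to be incomparable to *every* prior annotation of the gene —
including propagated ancestors, so in a single-rooted ontology new cases
cannot occur (any new term is a descendant of the root the gene already
carries); they require genuinely disjoint branches. The census accepts an
optional phenotype subset (e.g. disease terms only) and an explicit gene
universe for the denominator.

## ChIP concordance

Per phenotype present in both the ChIP collection and the module set:
every module gets an upper-tail hypergeometric enrichment p for TF
targets, computed in the shared expression universe (modules are drawn
from that universe, so it is the only defensible population). When a
phenotype has several ChIP datasets the default pools by per-module
minimum p across TFs (`pooling="tf_min"`); alternatives are a single test
against the target union (`"union"`) or all TF-module pairs as
observations (`"pairs"`). Related modules are those whose discovery
phenotype is the ChIP phenotype or one related-edge away. The one-sided
Mann-Whitney test (related stochastically smaller) uses the exact null
distribution whenever the pooled sample is tie-free and ≤ 60 observations
— the normal approximation is anticonservative at these sizes — and BH
correction runs across phenotypes at FDR 0.05. The display profile bins
p-values and reports per-bin log2 ratios of relative frequencies, with
empty-bin ratios capped at ±10 to stay plottable.

## Synthetic world

The default profile: 300 genes, 12 datasets of 30 samples, 4 leaf
phenotypes under two top-level categories (three datasets per phenotype),
and three 10-gene modules planted in the datasets of PH1–PH3 with
within-module correlation r = 0.9 via the single-factor model
x = √r·z + √(1−r)·ε, whose expected pairwise correlation is exactly r.
Annotation noise: 5% false-positive pairs, 10% false-negative dropout.
PPI density 0.3 within planted modules over a 0.01 background; GO
module-terms shared by 80% of members over uniform background terms; ChIP
target sets covering 80% of a matched module plus random genes. Two
top-level ontology categories (rather than one root) keep disjoint
branches genuinely disjoint, so negative training genes and cross-branch
pleiotropy can exist at all after ancestor propagation.

What the generator does *not* emulate: probe-level artifacts, platform or
batch effects, correlated background structure, ontology depth beyond two
levels, and realistic annotation sparsity. A green recovery test
establishes that the search finds planted blocks of the stated strength
against independent noise — not that it would at corpus scale against
correlated biology.

Two desk-scale consequences are worth knowing. First, recovered modules
usually coincide exactly with planted gene sets, all of whose members are
positively annotated, so the classify stage typically finds no negative
training genes and skips — mirroring the corpus-scale situation where
classifiers could only be trained for a subset of phenotypes. Classifier
behavior is therefore validated on feature-level simulations with planted
separation. Second, with one surviving module per phenotype the
concordance Mann-Whitney test cannot reach significance (minimum p is
1/(m+1)); the powered screen is validated on a dedicated module-collection
simulation (10 related vs 30 unrelated modules).

## Pipeline

Stages run in a fixed dependency order (simulate → discover → classify →
pleiotropy → chip); requesting a stage without its upstream in the same
run is an error. Each stage's seed is derived as
`(master_seed * 1000003 + crc32(stage_name)) mod (2^31 − 1)`, so stages
are independently reproducible. Stage directories are immutable — re-runs
into an existing directory raise rather than overwrite. The manifest
records the configuration snapshot, stage seeds, relative output paths,
and SHA-256 content hashes; no timestamps are written anywhere, so two
runs with the same master seed are byte-identical.

## Known limitations

- The annealing schedule is fixed rather than adaptive; very weak planted
  signal (r ≲ 0.5) at desk scale is often below the edge-budget detection
  floor and will not be recovered.
- BH grouping for module filtering is per phenotype; a global correction
  across phenotypes would be stricter.
- `related_set` is one hop and symmetric; synonymy chains (SY-SY) are not
  closed over.
- The GO score treats term frequencies as independent; no graph-based
  semantic similarity is attempted.
- Restarts run serially; the search is embarrassingly parallel across
  restarts and phenotypes but single-CPU by contract.
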