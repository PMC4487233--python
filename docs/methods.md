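# Methods

Statistical and algorithmic conventions used throughout `famnet`. All
routines are deterministic; anything stochastic (the synthetic generators)
is driven by `numpy.random.default_rng` with explicit per-component
substreams, so a seed fixes every output bit-for-bit.

## Network assembly

Edge lists are read verbatim in the configured dialect (column indices,
comment prefix, skipped header rows, optional organism filter). Merging
canonicalizes symbols case-insensitively (first-seen casing wins), drops
self-loops, deduplicates undirected edges regardless of orientation,
records per-edge provenance as the sorted comma-joined source names, and
removes isolated nodes. The result is a simple undirected `networkx`
graph.

## Family subnetwork

Seed symbols are mapped case-insensitively onto the parent network;
unmapped seeds are reported, and mapping nothing is an error. The family
subnetwork is the induced subgraph on seeds ∪ first neighbors — so
neighbor–neighbor edges are retained — with self-loops and isolates
pruned and an `is_seed` node flag.

## Topology

The degree distribution counts nodes per degree k ≥ 1 (unbinned). The
power-law fit is ordinary least squares of log10(count) on log10(k),
reported as `P(k) = β·k^a` with the coefficient of determination R²; a
zero-variance regression degenerates to R² = 1 with a warning.
Other statistics follow the common network-analyzer conventions:

* **diameter** — maximum finite shortest-path distance (per component);
* **density** — 2E / (N(N−1));
* **centralization** — [N/(N−2)] · (max_k/(N−1) − density);
* **heterogeneity** — population standard deviation of the degree
  sequence divided by its mean;
* **closeness** — component-relative, (n_c − 1)/Σ distances;
* **clustering coefficient** — 2·triangles / (k(k−1)) per node;
* **topological coefficient** — for node n, the mean over partners m
  sharing ≥ 1 neighbor of J(n,m)/k_n, where J(n,m) is the number of
  shared neighbors plus 1 if n and m are adjacent.

## Expression

Matrices are log2-scale, genes × samples, with duplicate probes collapsed
(mean by default, or the maximum-IQR probe). GEO series-matrix files are
parsed directly: `!`-prefixed metadata plus the probe table between the
table markers, with the group label taken from a chosen metadata line.
The fold change of a gene is `log2fc = mean(log2 tumor) − mean(log2
reference)`, reported as magnitude `2^|log2fc|` ≥ 1 plus a direction.
Co-expression uses Pearson correlation (t-transform p-values, n−2 df;
undefined under n < 3 or zero variance). The within-family correlation
matrix is ordered by average-linkage clustering on distance 1 − r, and
pairs with r ≥ 0.8 and Benjamini–Hochberg adjusted p < 0.05 are flagged.

## Enrichment

Over-representation of a query of size n against a term of size K in a
universe of size N with overlap k is the hypergeometric upper tail
P(X ≥ k) (optionally the EASE-style variant with one success removed);
terms with zero overlap are dropped, and BH adjustment is applied across
the reported terms. Two term networks summarize the results: the
enrichment map connects significant terms with overlap coefficient
|A∩B| / min(|A|, |B|) ≥ 0.6, and the kappa network connects terms with
Cohen's κ ≥ 0.3 (computed over the universe membership indicator
vectors) at p < 0.01, labeling each connected component by its most
significant member.

## Sequence family

Pairwise global alignment uses BLOSUM62 with affine gaps (open −10,
extend −0.5; a gap of length L costs open + (L−1)·extend). Percent
identity divides identical columns by the alignment length (a min-length
denominator is available). The family is clustered by average linkage on
a log-damped similarity transform of the identity matrix, with leaf
labels processed in sorted order so input order cannot change the
result. Conserved blocks are maximal runs of ≥ `min_width` alignment
columns whose conservation — modal non-gap residue frequency multiplied
by the non-gap fraction — is ≥ τ (default 0.9).

## Subcellular layers and paths

Localization terms collapse onto seven layers ordered from the
extracellular space to the nucleus: secreted, membrane, cytoplasm, the
three dual `<base>/nucleus` layers, and nucleus. All shortest paths
between two endpoints are read off the BFS predecessor DAG (so every
path's edge count equals the BFS distance), sorted lexicographically,
with a hard enumeration cap that fails loudly. Each geodesic's flow
class compares consecutive layer ranks (duals rank between cytoplasm and
nucleus): monotone toward the nucleus is *inward*, away is *outward*,
otherwise *mixed*; paths touching an unknown layer are *unknown*. The
layered layout places rows by layer order and relaxes x-positions to
neighbor barycenters with per-row respacing and lexicographic
tie-breaking, making it permutation-invariant.

## Synthetic data and validation

The generators plant known parameters — fold changes, correlation-block
strengths (via a shared latent factor with `factor_sd =
noise_sd·sqrt(r/(1−r))`), term memberships, layer frequencies, family
subgroups, and conserved sequence blocks — and the test suite validates
every statistical routine by recovering them, alongside exact
equivalence against brute-force oracles (induced-subgraph extraction,
topology statistics on small random graphs, exhaustive hypergeometric
enumeration, an independent affine-gap alignment dynamic program, and
DFS geodesic enumeration).
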