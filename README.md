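# dimorph

Expression profiling of sexually dimorphic genes in developing avian
gonads.

In birds, males are ZZ and females ZW, and the gonads of the two sexes
diverge rapidly after sex determination: testis genes such as *DMRT1*,
*SOX9* and *AMH* switch on in males, *FOXL2* and *CYP19A1* in females.
Bulk mRNA-seq of embryonic gonads at successive Hamburger–Hamilton stages
(HH27 → HH31 → HH38, plus adult) captures this divergence as per-gene FPKM
trajectories.  `dimorph` implements the full desk-side analysis of such an
experiment, for developmental biologists who have an FPKM matrix and want
candidate sex-differentiation genes out the other end:

1. **TMM normalization** of the FPKM columns (trimmed mean of M-values):
   for sample *k* against a reference *r*, with per-gene proportions
   *p* = FPKM / column total,

   M&#8338; = log₂(p₍ₖ₎/p₍ᵣ₎),  A&#8338; = ½·log₂(p₍ₖ₎·p₍ᵣ₎),

   the doubly trimmed (30 % on M, 5 % on A), precision-weighted mean of M
   gives the scaling factor; factors are rescaled to geometric mean 1.
2. **Sex-bias stratification**: the top 5,000 expressed genes per stage are
   classified by between-sex fold change fc = (max+1)/(min+1) into
   unbiased [1, 1.5), ×1.5–2, ×2–3 and ×3+, summarised separately for
   autosomes and the Z chromosome (incomplete dosage compensation makes
   Z-linked genes ~1.6-fold male-skewed).
3. **Stage-pattern clustering**: genes with ≥ 30 normalized FPKM in at
   least one embryonic sample are quantile-normalized, log₂-transformed
   and z-scored per gene within each sex; the two stage differences
   Δ₁ = z(HH31)−z(HH27) and Δ₂ = z(HH38)−z(HH31) are each split
   up/flat/down by exact one-dimensional 3-means, placing every gene in a
   3×3 grid of nine clusters.  Cluster 2 (up, then flat) is the signature
   of the canonical gonadal sex-differentiation genes.
4. **Candidate selection**: cluster-2 genes with a ≥ 2-fold sex difference
   at HH31.
5. **GO enrichment** of the candidates: one-sided hypergeometric test per
   biological-process term with true-path annotation propagation,
   Benjamini–Hochberg FDR, and a filter keeping terms with FDR < 0.05 and
   is_a depth ≤ 3.

A truth-planting synthetic generator (`dimorph.synthetic`) emulates the
whole experiment — lognormal FPKM noise around planted trajectories in all
nine patterns, planted fold-class genes, a Z dosage excess, planted
cluster-2 candidates and one enriched GO term — so every stage of the
pipeline is testable end to end without sequencing data.

## Worked example

```python
from dimorph.synthetic import SyntheticSpec, generate
from dimorph.normalization import normalize_tmm
from dimorph.clustering import cluster_patterns, select_candidates

data = generate(SyntheticSpec(seed=0))          # 2,242 genes × 8 samples
normalized, factors = normalize_tmm(data.matrix)
patterns = cluster_patterns(normalized)         # filter → QN → z → 3-means
candidates = select_candidates(patterns.assignments, normalized)
print(len(patterns.filtered_genes))
print(candidates.sex.value_counts().to_dict())
```

prints

```
2142
{'male': 52, 'female': 40}
```

— 2,142 of the 2,242 synthetic genes pass the FPKM ≥ 30 filter (100 are
planted below it), and the candidate step recovers exactly the 52 male and
40 female sexually dimorphic cluster-2 genes the generator planted.
Running the enrichment stage on those 92 candidates flags the planted term
(`reproductive structure development`, depth 3) at FDR ≈ 3 × 10⁻⁴.

The same analysis is scriptable from a shell via the `dimorph` CLI
(`synth`, `normalize`, `bias`, `cluster`, `candidates`, `enrich`, and
`run` for the whole pipeline from a YAML config); see `dimorph --help`.

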