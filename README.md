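# phylodiv

Phylogenetic-entropy diversity partitioning for microbial community
data: an OTU-by-sample read-count table on a rooted phylogenetic tree,
partitioned into γ/α/β diversity with per-branch attribution,
permutation significance, and turnover-based ordination.

Designed for environmental microbiology settings — the motivating case
is a drinking-water treatment plant with groundwater, carbon-filter and
post-chlorination compartments — where much of the community is
"microbial dark matter" (candidate phyla without cultured
representatives), so diversity has to be summarized over *lineages* of
a tree rather than a checklist of named taxa.

## The statistic

For a rooted tree *T* with branch lengths *L<sub>i</sub>*, let
*p<sub>i</sub>* be the frequency of observations (reads) descending
from node *i* and *T̄* = Σ<sub>i</sub> *L<sub>i</sub> p<sub>i</sub>*
the mean root-to-observation depth. The phylogenetic Shannon entropy is

> H<sub>p</sub> = −Σ<sub>i</sub> (*L<sub>i</sub>*/*T̄*) *p<sub>i</sub>* ln *p<sub>i</sub>*

and exp(H<sub>p</sub>) is a Hill-number-style *equivalent number of
lineages*: the size of a star tree of equally abundant tips with the
same entropy. Splitting observations into groups *g* with weights
*w<sub>g</sub>* (default 1/G, so unequal sequencing depths do not tilt
the estimate) gives an exactly additive partition
H<sub>γ</sub> = H<sub>α</sub> + H<sub>β</sub>, where H<sub>β</sub> is
the phylogenetic mutual information between lineage and group,

> H<sub>β</sub> = Σ<sub>i</sub> (*L<sub>i</sub>*/*T̄*) Σ<sub>g</sub> *p<sub>ig</sub>* ln ( *p<sub>ig</sub>* / (*p<sub>i</sub>* *w<sub>g</sub>*) ),

a sum of nonnegative per-branch terms that localize *where* on the tree
groups differ. Dividing H<sub>β</sub> by its ceiling
H(G) = −Σ *w<sub>g</sub>* ln *w<sub>g</sub>* gives the **turnover** in
[0, 1]; for two equal-weight groups it is the fraction of observations
on lineages not shared between them. Significance of H<sub>β</sub> is
assessed by re-assigning group labels to individual reads (a
multivariate-hypergeometric split preserving group totals) and
recomputing the statistic.

## Worked example

```python
import phylodiv as pv

data = pv.generate_dwtp_preset(seed=42)          # synthetic 3-compartment dataset
part = pv.partition(data.tree, data.counts, data.grouping)
print(f"D_gamma = {part.d_gamma:.2f} equivalent lineages")
print(f"D_alpha = {part.d_alpha:.2f} equivalent lineages")
print(f"turnover = {part.turnover:.1%} of H(G)")
for g, d in part.group_diversities.items():
    print(f"  {g}: D = {d:.2f}")
print(f"L1372 share of H_beta = {pv.lineage_contribution(part, 'L1372'):.1%}")
print(pv.group_lineage_proportions(part.abundance, 'L1372').round(3).to_dict())
res = pv.permutation_test(data.tree, data.counts, data.grouping,
                          n_permutations=999, seed=0)
print(f"permutation p = {res.p_value:.3f}")
```

prints

```
D_gamma = 10.55 equivalent lineages
D_alpha = 8.34 equivalent lineages
turnover = 21.4% of H(G)
  GW: D = 8.01
  CF: D = 8.00
  CHL: D = 9.07
L1372 share of H_beta = 54.0%
{'GW': 0.04, 'CF': 0.681, 'CHL': 0.582}
permutation p = 0.001
```

The pooled community behaves like ~10.5 equally abundant independent
lineages; an average compartment like ~8.3. About 21% of the maximal
between-compartment information is realized, over half of it carried by
the planted treated-water clade `L1372`, whose per-group observation
shares (4% / 68% / 58% of GW / CF / CHL reads) are recovered from the
sampled counts. The label-permutation test rejects exchangeability at
the smallest attainable p with 999 permutations.

The same analysis is available from the shell:

```bash
phylodiv simulate --preset dwtp --seed 42 --out sim/
phylodiv partition --tree sim/tree.nwk --counts sim/counts.tsv \
    --groups sim/groups.tsv --out out/ --permutations 999 --seed 0
phylodiv pcoa --tree sim/tree.nwk --counts sim/counts.tsv --out out/
phylodiv export-itol --tree sim/tree.nwk --counts sim/counts.tsv \
    --groups sim/groups.tsv --out out/
```

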