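# knockloc

**FDR-controlled, multi-resolution localization of trait-associated genetic
variants with HMM group knockoffs.**

Genome-wide association studies struggle to say *where* causal variants
are: linkage disequilibrium (LD) makes whole neighborhoods of variants
correlate with a trait, and marginal tests cannot tell a causal variant
from its passengers.  `knockloc` instead tests **conditional** hypotheses —
is this *group* of variants associated with the trait given everything else
in the genome? — for contiguous LD blocks at a ladder of nested
resolutions, from broad loci down to single variants, and provably controls
the false discovery rate (FDR) at each resolution.

It is aimed at statistical geneticists who want locus discovery and
fine-mapping in one coherent framework, and at methodologists who want a
compact, fully tested implementation of group knockoffs for hidden Markov
model (HMM) genotype distributions.

## The method in brief

For a partition `G = (G_1, …, G_L)` of the variants, group `g` is null when
`Y ⊥ X_{G_g} | X_{-G_g}`.  The machinery:

1. **Genotype model.** Haplotypes follow a haplotype-cluster HMM (latent
   ancestry clusters, per-site jump probabilities `r`, cluster weights
   `alpha`, emission frequencies `theta`), fitted by EM.
2. **Group knockoffs.** For each haplotype: sample a latent path from
   `P(Z | h)`; sample a knockoff path group-by-group so that the joint law
   of `(X, X̃)` is invariant under swapping any group between the copies
   (cost `O(pK²)` per haplotype, vectorized across the cohort); re-emit
   alleles.  Knockoffs never see the phenotype — they are exact negative
   controls.
3. **Statistics.** A cross-validated sparse regression of `y` on
   `[Z, X, X̃]` (linear or logistic; covariates unpenalized) gives group
   importances `T_g = Σ_{j∈G_g} |β̂_j|` and `T̃_g`, contrasted as
   `W_g = T_g − T̃_g`.
4. **Knockoff filter.** `τ = min{ t : (1 + #{W ≤ −t}) / max(1, #{W ≥ t}) ≤ q }`;
   groups with `W ≥ τ` are reported.  Null sign-symmetry of `W` makes this
   control the FDR at level `q` per resolution.  Local FDR estimates and a
   cross-resolution "simplified count" (keeping only the most specific
   supported finding per locus, flagging unsupported "floating" blocks)
   summarize the output.

A built-in simulator generates the full study design — HMM genotypes with
realistic local LD, causal variants clustered in evenly spaced 0.1-Mb
windows of five with smallest:largest effect ratio 1/19, Gaussian or
liability-threshold (probit) traits — so every statistical claim is
testable end to end without external data.

## Worked example

```python
import numpy as np
from knockloc import simulate as sim
from knockloc.pipeline import run_pipeline

model = sim.synthetic_hmm(seed=0)                  # p=600 variants, K=5
H, X = sim.simulate_genotypes(model, 2000, seed=1) # phased haplotypes + dosages
variants = sim.variant_table(model, X)
spec = sim.place_causal_clusters(variants, seed=2) # 6 clusters x 5 causal SNPs
y = sim.simulate_gaussian_trait(X, spec, seed=3)   # h2 = 0.3

result = run_pipeline(H, y, model.positions, seed=4)
for rr in result.resolutions:
    ds = rr.discoveries
    fdp, n_true, n_false = sim.evaluate_discoveries(ds, spec)
    print(f"resolution ~{ds.resolution_bp/1000:.1f} kb: L={ds.partition.L} groups, "
          f"{ds.n} discoveries ({n_true} true, {n_false} false), FDP={fdp:.2f}")
```

Output:

```
resolution ~25.3 kb: L=44 groups, 0 discoveries (0 true, 0 false), FDP=0.00
resolution ~10.0 kb: L=100 groups, 10 discoveries (10 true, 0 false), FDP=0.00
resolution ~2.0 kb: L=300 groups, 15 discoveries (15 true, 0 false), FDP=0.00
```

Reading this: at the 10-kb resolution the filter reported 10 groups, all of
which contain a truly causal variant (group-level FDP 0); at single-variant
resolution it pinpointed 15 causal SNPs.  The coarse level reported nothing
here — with `q = 0.1` the filter needs at least `1/q = 10` findings to
report anything, and this replicate's coarse statistics fell just short; on
other seeds the coarse level reports ~10–12 loci.  FDR is controlled *on
average* over replicates, which is exactly what the reproduction script
measures.

The same pipeline is available as a CLI over PLINK BED/BIM/FAM and TSV
files:

```bash
knockloc simulate --out-prefix sim --seed 1
knockloc fit-hmm --haplotypes sim.haps.tsv --k 5 --seed 2 --out model.txt
knockloc partition --haplotypes sim.haps.tsv --bim sim.bim --out-prefix part
knockloc knockoffs --haplotypes sim.haps.tsv --model model.txt \
    --partition part.res0.tsv --seed 3 --out-prefix ko0
knockloc stats --genotypes sim --knockoffs ko0 --partition part.res0.tsv \
    --phenotypes sim.pheno.tsv --seed 4 --out stats0.tsv
knockloc filter --stats stats0.tsv --partition part.res0.tsv --q 0.1 \
    --out disc0.tsv
knockloc report --discoveries disc0.tsv --partitions part.res0.tsv \
    --out summary.tsv
```

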