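# motudelim

Species delimitation from DNA barcodes, in one tested toolkit.

Single-locus barcodes (typically COI) are routinely carved into molecular
operational taxonomic units — candidate species — by a zoo of methods that
often disagree: distance-based barcode-gap analyses and automatic
barcode-gap discovery (ABGD), tree-topology statistics (the genealogical
sorting index, Rosenberg's reciprocal-monophyly probability P_AB,
Rodrigo's P(RD)), and the general mixed Yule-coalescent (GMYC) model.
`motudelim` implements all of them behind one consistent interface,
together with a consensus layer that turns each method's +/−/na decisions
over nested species hypotheses into min–max species counts, and a seeded
multispecies-coalescent simulator that makes every stage verifiable
without downloading any data. It is aimed at molecular taxonomists and
methods developers who want these analyses reproducible, scriptable and
cross-checked rather than scattered over web servers and plugins.

## The statistics at the core

* **Barcode gap** — for a focal group, a gap exists when
  `min(inter) > max(intra)`; the gap range is `Δ = min(inter) − max(intra)`.
  Four decision rules (3%, 4%, 10×, 3.2–4.1×) score each group from its
  mean intra, min inter and mean inter K2P distances, with
  `d_K2P = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`.
* **ABGD** — finds the first gap in the ranked distances wider than
  `X·max(P, running mean)`, partitions by single linkage below it, and
  recurses, over a log-spaced series of priors `P`.
* **GSI** — exclusive ancestry of a labeled group on a rooted tree,
  normalized so monophyly scores exactly 1, with a tip-permutation test.
* **Rosenberg's P_AB** — probability of chance reciprocal monophyly,
  `P_AB = 2·C(a+b−2, a−1)·a!(a−1)!·b!(b−1)! / [(a+b)!(a+b−1)!]`.
* **GMYC** — on an ultrametric tree, fits
  `b_i = λ_div k_i^{p_div} + λ_coal Σ_j (n_ij(n_ij−1))^{p_coal}` per
  inter-node interval, profiles the diversification→coalescent transition
  age, and tests it against the one-species null by a likelihood ratio
  (df = 3 for a single threshold).
* **Consensus counting** — exact tiling of a scope by supported,
  pairwise-disjoint hypotheses; nested hypotheses are mutually exclusive
  alternatives, so each method yields a species-count range.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a study-scale dataset (7 species, 82 haplotypes, 655 bp, deep
between-species divergence, shallow within-species variation, one
singleton species) and run the three delimitation routes:

```python
from motudelim.simulate import SimConfig, simulate_dataset
from motudelim.distances import compute_distance_matrix
from motudelim.gap_analysis import overall_gap_analysis, apply_threshold_rules
from motudelim.abgd import AbgdConfig, abgd_partition
from motudelim.gmyc import prepare_ultrametric, fit_gmyc_single

truth, locus = simulate_dataset(SimConfig(seed=1))
D = compute_distance_matrix(locus, model="K2P")

res = overall_gap_analysis(D, truth.group_map(), "sp1")
print(f"sp1: max intra {res.max_intra:.4f}  min inter {res.min_inter:.4f}"
      f"  gap range {res.gap_range:.4f}")

counts = [len(r["primary"]) for r in
          abgd_partition(D, AbgdConfig()).per_prior.values()]
print("ABGD primary group counts over the prior series:", counts)

fit = fit_gmyc_single(prepare_ultrametric(truth.tree, seed=1))
print(f"GMYC: {fit.n_entities} entities, LR = {fit.lr:.1f}, "
      f"p = {fit.p_value:.2e}")
```

prints

```
sp1: max intra 0.0108  min inter 0.1234  gap range 0.1126
ABGD primary group counts over the prior series: [26, 8, 8, 7, 7, 7, 7, 7, 1, 1]
GMYC: 7 entities, LR = 29.1, p = 2.16e-06
```

Species `sp1` shows a clean barcode gap (its deepest within-group
distance, 1.1%, sits far below the closest other group at 12.3%), all
four threshold rules support it, ABGD's primary partition settles on the
true 7 groups across the mid-range priors (the lowest prior oversplits
into haplotype clusters, the highest screens everything as
intraspecific), and GMYC places its transition so that exactly the 7
simulated species emerge, with the mixed model strongly preferred over
the one-species null.

The same analyses run from the shell: `motudelim simulate`, `motudelim
gaps`, `motudelim abgd`, `motudelim treestats`, `motudelim gmyc`, and
`motudelim run-all --config run.cfg` for the whole pipeline with JSON/TSV
outputs and a seed-recording run log.

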