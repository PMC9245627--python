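# hapsmooth

PBWT-based smoothing of phased haplotype panels, and multiway IBD cluster
calling on the smoothed panel.

Phased panels from modern cohorts are `{0,1}`-matrices of M haplotypes by
N variant sites in which haplotypes sharing recent ancestry are identical
over long runs. Exact-matching algorithms built on the positional
Burrows-Wheeler transform (PBWT) find those runs in O(MN) time — but a
single genotyping error (typical rates 0.1–0.5% per genotype) splits an
exact match, and at biobank scale this fragments most long matches and
makes *multiway* shared segments (IBD clusters) nearly undetectable.
`hapsmooth` is for people who run IBD segment or cluster analyses on such
panels: it actively repairs the mismatches first, then matches.

## The model

For haplotype `i` at site `k`, let `B⁻` and `B⁺` be the sets of
haplotypes identical to `i` over the `L` sites to the left and right of a
`g`-site gap around `k`, and `B = B⁻ ∩ B⁺` the **bidirectional block** —
haplotypes plausibly IBD with `i` *through* `k`. Their alleles at `k`
form a reference set `R` for `i`'s allele. The IBD prior declares an
observed allele `b` implausible iff

```
|R| ≥ W   and   AF(b) < ρ
```

(`AF(b)` the in-block frequency of `b`). Smoothing applies this blockwise
along the panel: for every bidirectional block of width ≥ `W` and every
gap site, if `0 < min(#0s, #1s) ≤ |B|·ρ`, the minority alleles are
flipped to the block majority. A bidirectional PBWT scan computes all
blocks in O(MN) time with O(gM) gap state (the reverse block-ID table is
held in memory or spilled to disk). Defaults: `L=20` sites, `W=20`
haplotypes, `g=1` site, `ρ=0.05`.

Cluster calling then reports every maximal match block — a set of
haplotypes identical over an interval, complete for that interval and
unextendable — above a minimum genetic length `Lmin` and width `Wmin`;
running it on the smoothed panel (`ps_cluster`, with `W = Wmin`) is the
error-tolerant cluster caller. Keep `W` below the width of the blocks you
expect: a block needs `W` intact members *besides* sporadic defects, and
a singleton mismatch is only correctable when `|B| ≥ 1/ρ`.

## Worked example

```python
from hapsmooth import (SmootherParams, ClusterParams, generate_copy_group_panel,
                       inject_errors, smooth_panel, ps_cluster, call_clusters,
                       error_correction_report, cluster_power_accuracy)

# 4 planted clusters: 25 exact haplotype copies each, 500 sites
panel, truth = generate_copy_group_panel(n_groups=4, group_width=25, n_sites=500,
                                         segment_spec=(0, 500), seed=7)
noisy, errors = inject_errors(panel, rate=0.002, seed=8)   # 0.2% per genotype-site

smoothed, corrections = smooth_panel(noisy, SmootherParams())
report = error_correction_report(errors.flips, corrections)
print(f"injected errors : {report.n_errors}")
print(f"corrections     : {report.n_corrections}")
print(f"recall          : {report.recall:.2f}   precision: {report.precision:.2f}")

cp = ClusterParams(min_len=400, min_width=25, unit="sites")
plain = cluster_power_accuracy(truth, call_clusters(noisy, cp))
fused = cluster_power_accuracy(truth, ps_cluster(noisy, cp, SmootherParams())[0])
print(f"cluster power   : {plain.power:.2f} unsmoothed -> {fused.power:.2f} smoothed")
```

prints

```
injected errors : 44
corrections     : 39
recall          : 0.89   precision: 1.00
cluster power   : 0.00 unsmoothed -> 0.98 smoothed
```

The five uncorrected errors sit within `L` sites of the panel ends, where
one flank is missing — those are never corrected by design. Unsmoothed,
every planted 25-way cluster is fragmented below the length threshold
(power 0); after smoothing they are recovered essentially in full.

The same pipeline runs from the shell:

```
hapsmooth smooth  --in panel.vcf --out smoothed.vcf --corrections log.tsv
hapsmooth cluster --in panel.vcf --map chr.map --min-len-cm 1.0 --min-width 10 --out clusters.tsv
hapsmooth ibd     --in panel.vcf --map chr.map --min-len-cm 5.0 --out matches.tsv
hapsmooth benchmark --mode coalescent --seed 1 --out report.json
```

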