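# Methods

## Statistical model

A bisulfite experiment reports, for cytosine *i*, a coverage `cov_i` and a
methylated-read count `mc_i`. With per-cytosine methylation probability
`m_i` and non-conversion rate `r` (the probability an unmethylated cytosine
escapes conversion and reads as methylated), a read is methylated with
probability `m_i + (1 − m_i)·r`, so

```
cov_i ~ Poisson(λ),    mc_i | cov_i ~ Binomial(cov_i, m_i + (1 − m_i)·r).
```

This is both the simulator's generative model and the caller's test family:
the null hypothesis at a site is `m_i = 0`, i.e. `mc_i ~ Binomial(cov_i, r)`,
tested one-sided upper-tail because methylation can only inflate the count.
The model assumes independent sites and reads; it ignores overdispersion
from cell-to-cell heterogeneity (a beta-binomial would absorb it) and any
mapping or conversion bias along the genome.

`r` is estimated by pooling all covered cytosines of a contig known to be
unmethylated (the mitochondrial genome in Neurospora-like data):
`r̂ = Σmc / Σcov`, with binomial standard error `√(r̂(1−r̂)/Σcov)`. When no
methylated read is observed on the control, `r̂` is floored at
`1/(Σcov + 1)` — zero observed failures bounds the rate rather than proving
it zero, and a literal `r = 0` would make every `mc > 0` site's p-value
exactly 0. At the other boundary `r = 1` the test is valid but powerless
(p = 1 everywhere), which is the correct behaviour when the control contig
itself looks fully methylated.

## Multiple testing and site status

P-values are Benjamini–Hochberg corrected in one family: all tested sites
of the sample, genome-wide, contexts (CG/CHG/CHH) and strands pooled — no
per-context analysis is made downstream, so splitting families would only
fragment the FDR guarantee. A site is *methylated* iff `q ≤ α` (default
0.05) and `mc > 0`; the `mc > 0` guard is redundant for sane `r̂` but keeps
degenerate non-conversion estimates from labelling zero-signal sites.
Sites with `cov < min_cov` (default 3) are *untested*: a 1–2-read site
cannot reach any useful significance, and calling it unmethylated would be
an assertion the data cannot support.

## DMS and DMR detection

Methylated regions of one strain are obtained by running the two-sample
pipeline against an artificial reference with `cov = 60, mc = 0` at every
cytosine of the genome — the in-silico fully unmethylated sample. For a
between-strain comparison the second strain replaces the artificial
reference. Per site (strand counts summed per position; replicate tables
summed per site before testing), a two-sided Fisher exact test on the 2×2
table of methylated/unmethylated read counts, BH across tested sites, and
`q ≤ α` defines a DMS. The Fisher+BH site test is this package's choice of
a transparent, deterministic two-sample test; permutation-based region
statistics used elsewhere in the literature exercise the same decision
structure but are not reproducible without their exact implementation.

DMSs are chained per contig in one greedy pass: consecutive DMSs at most
`max_gap = 1000` bp apart join a cluster; clusters with at least
`min_dms = 10` members are DMRs. The reported interval spans the first to
the last member DMS (0-based half-open in all outputs); boundaries are not
extended to flanking non-DMS cytosines — a minimal-assumption choice that
affects only edge bases. Duplicate positions collapse before chaining, and
unsorted input is sorted. Greedy chaining on sorted positions is exactly
transitive-closure clustering at distance `max_gap`, which the test suite
verifies against an O(n²) oracle.

## Region statistics

The weighted methylation level of an interval is `Σmc / Σcov` over its
cytosine records, both strands — coverage-weighted, so it satisfies the
pooling identity over disjoint unions and is dominated by well-measured
sites. An interval with `Σcov = 0` is *missing* (NaN), never 0.

Across-region summaries use notched box statistics: median and quartiles by
linear-interpolation quantiles, notch half-width `1.58·IQR/√n` (the McGill
constant; an approximate 95% CI for the median). Two groups whose notches
overlap are read as "not statistically different" — the package deliberately
offers no sharper test for this comparison, because the notch criterion *is*
the inference being reproduced.

Metaplots scale each region to 60 bins: 20 upstream bins of `flank/20` bp
(defaults 1 kb → 50 bp bins), 20 body bins of 5% of the region length
(assignment by position fraction, half-open bins, last bin closed), and 20
downstream bins. Counts are pooled across regions per bin and the bin level
is the pooled weighted fraction (default); an unweighted per-region mean of
bin levels is available via `aggregate="mean"` — with homogeneous regions
the two agree, and pooling was chosen as the default because it extends the
coverage-weighting principle to the profile. Regions shorter than the body
bin count are skipped with a warning; flanks truncated by contig ends simply
contribute fewer sites.

## Synthetic data

The generator emulates what the downstream pipeline sees after alignment —
per-cytosine count tables — not reads; alignment is out of scope, so no
sequencing-error, mapping-bias or repeat-composition model is included.
Defaults describe a desk-scale fungal-style study: two 150 kb nuclear
contigs (GC 0.5), twenty non-overlapping planted domains of 2–5 kb with
levels drawn from 0.6–0.9, a 40 kb fully unmethylated "mitochondria"
contig, Poisson 15× coverage per replicate, two replicates and
`r = 0.005`. Planted domains are kept ≥ 2 kb apart (and off contig ends):
at a separation of exactly 1 kb two distinct truth domains would be merged
by the 1 kb DMS-chaining rule itself, so the generator enforces a margin
comfortably above the merge distance to keep recovery accounting
unambiguous. Cytosines are enumerated on both
strands with contexts CG/CHG/CHH (truncated contexts at contig ends count
as CHH); both strands share the site's `m`.

What passing tests on these data do **not** show about real methylomes:
robustness to overdispersion, to coverage that tracks GC or mappability, to
incomplete conversion that varies along the molecule, or to genetic
polymorphism between compared strains (which produces spurious DMRs in real
comparisons and is explicitly not modelled).

## In-silico digest

The digest module reproduces methylation-sensitive/insensitive isoschizomer
(BfuCI/DpnII, site GATC) Southern logic on a single linear molecule: exact
recognition-site matches (ambiguous bases never match), cut at site start,
and — for the sensitive enzyme — a site is not cut when *any* methylated
cytosine lies within its 4 bp footprint on either strand. Methylation is
binary per molecule; partial digestion of a molecular population is out of
scope. Two invariants follow by construction and are tested: fragment
lengths always sum to the molecule length, and the insensitive enzyme's cut
set is a superset of the sensitive one's, so its fragments refine them.

## Numerical and testing choices

- Binomial tails via `scipy.stats.binom.sf`, BH via statsmodels
  `multipletests`, Fisher via `scipy.stats.fisher_exact` memoised over
  unique 2×2 tables (real tables repeat few distinct count combinations,
  which makes genome-scale Fisher testing cheap).
- Test oracles are independent re-derivations: BH from the step-up
  definition, binomial tails by exact-fraction summation, Fisher by
  exhaustive integer hypergeometric enumeration (with the observed-weight
  tie tolerance bracketed), chaining by an O(n²) scan.
- Statistical assertions on simulated data use binomial standard errors at
  fixed seeds. Single-quantity checks use 3 SE. The 60-bin metaplot check is
  a family of 60 simultaneous comparisons, so the module test uses a
  Šidák-style family-wise 4 SE bound; the end-to-end suite retains the
  per-bin 3 SE check, which a minority of seeds can fail by chance — the
  seeds used are fixed and recorded in the tests.
- End-to-end simulations are sized at tens-to-hundreds of kb and 15–60×
  coverage — large enough that every rate estimate carries thousands of
  informative sites, small enough to run comfortably on a laptop.
- Notched-box comparisons need across-region level variation; fixtures
  plant levels over a range (0.6–0.9) rather than a single constant, since
  a constant level collapses the IQR to counting noise and degenerates the
  notch.

## Known limitations

Binomial (not beta-binomial) site model; Fisher+BH as the DMS test rather
than permutation/RMS statistics; no boundary extension of DMRs beyond
terminal DMSs; no per-context calling; no polymorphism masking between
strains; linear (not circular) molecules in the digest; no population-level
partial digestion.
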