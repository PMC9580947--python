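# rvmgs — sparse Bayesian genomic selection and marker ranking

`rvmgs` predicts quantitative phenotypes from genome-wide biallelic
markers with relevance vector machines (RVMs) and ranks the markers
that drive a trait with a bagged ensemble of sparse Bayesian models.
It is aimed at genomic-selection settings such as biparental crosses,
where genotypes are coded 0/1 by parental origin, traits are
real-valued with occasional missing readings, and the questions are
(a) how well can the trait be predicted from the markers and (b) which
markers matter, and in which direction.

## The model

An RVM is Bayesian linear regression over basis functions
`y(x) = Σ_m w_m ρ_m(x)` with an independent Gaussian prior
`w_m ~ N(0, α_m⁻¹)` per weight.  The precisions **α** and the noise
variance σ² are chosen by maximising the marginal likelihood
(evidence) `p(t | α, σ²) = N(t | 0, σ²I + Φ A⁻¹ Φᵀ)`; iterating the
posterior statistics

    Σ = (σ⁻² ΦᵀΦ + A)⁻¹,   μ = σ⁻² Σ Φᵀ t

with the re-estimates `α_m ← (1 − α_m Σ_mm) / μ_m²` drives most
precisions to infinity.  The few surviving basis functions are the
*relevance vectors*.  Two design matrices give two model families:

* **kernel RVM** — `Φ_ij = K(x_i, x_j)` (linear, polynomial or
  Gaussian kernel): relevance vectors are training individuals; used
  for phenotype prediction.
* **linear-basis RVM** — an intercept column plus the raw markers:
  relevance vectors are *markers*, so the model is an embedded feature
  selector whose signed weights separate trait-increasing from
  trait-decreasing alleles.

For marker ranking, hundreds of linear-basis RVMs are trained on
50–60% subsamples of the individuals; a marker's rank is how many
members kept it as a relevance vector, and markers chosen by at least
half of the ensemble are called *influential*.  See
[docs/methods.md](docs/methods.md) for the update equations, the noise
schedules and the design decisions.

## Worked example

Simulate a 300 × 1,000 biparental cross with ten causal markers (five
trait-increasing, five trait-decreasing, h² = 0.8), then rank markers
with a 100-member ensemble:

```
$ rvmgs simulate --n 300 --m 1000 --k-causal 10 --h2 0.8 --seed 42 --out-prefix ex
simulated 300 x 1000 (k=10, h2=0.8, realized 0.846) -> ex.geno.tsv / .pheno.tsv / .truth.json

$ rvmgs rank --geno ex.geno.tsv --pheno ex.pheno.tsv --trait sim_trait \
             --n-models 100 --base-seed 42 --out-tsv ex.rank.tsv --out-bed ex.rank.bed
ranked 359 of 1000 markers; 11 influential at threshold 0.5; TSV: ex.rank.tsv

$ head -8 ex.rank.tsv
marker_id       chrom   pos     count   rank_fraction   mean_weight     sign    rank_order
chr11:17001     chr11   17001   100     1       -1.002233183    -       1
chr1:43001      chr1    43001   100     1       0.9635673199    +       2
chr5:23001      chr5    23001   100     1       -0.9549955079   -       3
chr8:23001      chr8    23001   100     1       0.9097288274    +       4
chr14:18001     chr14   18001   100     1       0.8885539601    +       5
chr8:59001      chr8    59001   100     1       0.8688147731    +       6
chr1:19001      chr1    19001   100     1       -0.8627568282   -       7
```

Reading the output: `count` is the number of ensemble members that
retained the marker as a relevance vector (all 100 here — these are
unambiguous signals), `mean_weight` is the marker's average effect on
the trait over those members, and `sign` marks the direction; the
simulated effects were ±1 and every one of the ten true causal markers
(recorded in `ex.truth.json`) appears at the top of the ranking with
the correct sign and a weight close to ±1.  About a third of all
markers are ever selected; the rest are reported as having no effect.
The BED file carries the same ranking in 0-based half-open genome
coordinates for browser display.

Other verbs: `rvmgs fit` (single model, saved as a JSON archive),
`rvmgs predict`, and `rvmgs cv` for repeated k-fold cross-validated
model selection over the linear basis, linear kernel and a Gaussian-γ
grid — the protocol used to compare model families per trait.  All of
this is equally available as a library (`rvmgs.fit`,
`rvmgs.fit_ensemble`, `rvmgs.rank_markers`,
`rvmgs.repeated_kfold_cv`, ...).

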