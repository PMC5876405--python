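# parcel

Detection of **ligand-responsive RNA structural elements** — candidate
aptamers and riboswitches — from RNase V1 structure-probing sequencing
data.

RNase V1 cleaves double-stranded RNA, so the number of reads whose first
mapped base lies one nucleotide downstream of a position (its *V1
count*) is a proxy for that position's double-strandedness. When a small
molecule (TPP, FMN, SAM, …) binds an RNA element, the element changes
conformation and its V1 counts shift in the treated libraries only.
`parcel` finds those regions:

1. **Per-position differential test.** V1 counts of one ligand condition
   are compared against the pool of all other conditions with a negative
   binomial exact test (common dispersion φ estimated from replicates by
   conditional maximum likelihood; TMM normalization). Positions below
   the abundance threshold (average normalized counts per sample
   *a* ≤ 1) are not tested.
2. **Score transform.** Tested positions get
   *s<sub>i</sub>* = ln(0.1) − ln(pval<sub>i</sub>) (positive exactly
   when pval < 0.1); abundance-failing positions get a flat −10 penalty.
3. **Maximal segments.** All disjoint maximal-scoring segments of the
   score track are found with the Ruzzo–Tompa algorithm (the single best
   is the Kadane maximal-subarray answer), aggregating evidence over
   contiguous positions, *S* = Σ *s<sub>i</sub>*.
4. **Karlin–Altschul significance.** Under the null the tested p-values
   are ~U(0,1), so segment scores follow an extreme-value law
   *E<sub>v</sub>* = *K* e<sup>−λS</sup>. Both constants are derived
   from first principles: λ = 0.862871 solves 0.1<sup>λ</sup>/(1 − λ) = 1,
   and *K* = *C*\* = 0.0809635 comes from a series of gamma-distribution
   integrals (see `docs/methods.md`).
5. **Final filters.** Reported candidates must pass the E-value cutoff
   (≤ 10), contain a position with absolute fold-change > 2, a position
   with relative abundance above the transcript median + SD, and a
   Bonferroni-corrected p-value < 10. Calls can be classified by region
   with the precedence 5′UTR > CDS/operon > 3′UTR.

The package ships a synthetic-data generator (NB counts with implanted
responsive windows and known ground truth) used by the test suite and
usable for power studies of your own designs.

## Worked example

```python
from parcel import ParcelDetector, SimulationConfig, Window, simulate_counts

cfg = SimulationConfig(
    n_transcripts=3, lengths=300, seed=7, transcript_log_sigma=0.0,
    windows=[Window("tx2", 101, 130, 4.0, "TPP", baseline_mean=20.0)],
)
counts, design, truth = simulate_counts(cfg)

det = ParcelDetector(contrast="TPP").fit(counts, design)
print("dispersion:", round(det.dispersion_, 4))
print("lambda =", round(det.ka_params_.lam, 6), " K =", round(det.ka_params_.K, 7))
print(det.predict()[["transcript", "start", "end", "score",
                     "e_value", "max_abs_log2fc", "called"]].to_string(index=False))
```

prints

```
dispersion: 0.1082
lambda = 0.862871  K = 0.0809635
transcript  start  end      score       e_value  max_abs_log2fc  called
       tx2    101  130 330.922719 7.911362e-126        2.686814    True
```

The estimator recovers the NB dispersion used by the generator (0.1),
derives the extreme-value constants, and calls exactly the implanted
30-nt window on tx2: its aggregate score of 331 over the 30 positions
gives an E-value of ~10⁻¹²⁵ (the expected number of such segments in a
null experiment), and the strongest position changes 2<sup>2.69</sup> ≈
6.4-fold between TPP and the pooled other conditions.

The same stages are available as subcommands of the `parcel` console
script (`count`, `test`, `segments`, `call`, `simulate`, `calibrate`,
`run`); `parcel run --config run.yaml` executes the whole pipeline from
SAM/BAM or TSV counts and writes every intermediate with a provenance
header.

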