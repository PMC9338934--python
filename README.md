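# strsift

Alignment-free screening for short tandem repeat (STR) expansions in
high-throughput sequencing data.

Repeat expansion disorders (Huntington's disease, myotonic dystrophy,
Friedreich's ataxia, fragile X syndrome, ...) are caused by alleles whose
repeat copy number grows far beyond the normal range. In short-read data
an expanded allele leaves a characteristic trace: an excess of reads that
are largely or entirely composed of the repeat motif. `strsift` detects
that trace without any alignment or reference genome, which makes it
equally applicable to WGS, WES and RNA-seq, and fast enough to screen
thousands of samples on one CPU.

## Method

**Per-sample processing.** Every read is compressed with DEFLATE (zlib at
its fastest setting, raw stream) and assigned a complexity ratio

    C = compressed bytes / raw bytes.

Repetitive sequence is more compressible, so reads with C at or below a
read-length-dependent threshold *t_L* are candidate repeat carriers; only
those reach the repeat detector, which finds every *exact maximal
repetition* (run): a substring with minimal period *p*, at least two full
copies, not extensible in either direction. Motifs are collapsed into
canonical classes under cyclic rotation and reverse complementation
(CAG/CTG → AGC, GAA/TTC → AAG), giving 145 classes over motif lengths
3–5 and 501 over lengths 1–6. Thresholds *t_L* ship pre-calibrated for
common read lengths and can be recalibrated by simulation (`strsift
calibrate`) for other lengths, base compositions or error rates.

**Cohort processing.** Each sample is summarised per canonical motif *m*
into a count vector v = (v_1 … v_j), where v_l counts runs of tract
length l, and scored with the information score

    s_m = ( Σ_{i ≤ l ≤ j} v_l · l ) / n

with *n* the library size, *j* the read length and *i* = ⌊0.75·j⌋ by
default, so only tracts spanning at least three quarters of a read —
the signature of an expansion — contribute. Two comparison modes:

* **Screening** (`strsift screen`): one-sided Mann–Whitney U per motif
  (cases > background) with a 10,000-permutation null (exact enumeration
  when feasible) and Benjamini–Hochberg FDR correction across motifs.
* **Outlier detection** (`strsift outliers`): one-versus-many; a sample
  is flagged for a motif when its score strictly exceeds the upper 95%
  BCa-bootstrap confidence bound of the 95th percentile of the score in
  background samples only (percentile-bootstrap fallback on degenerate
  backgrounds).

A simulation subsystem (`strsift simulate`, `strsift.simulate`) generates
background reads under configurable base compositions, reads carrying
(im)pure repeat tracts, synthetic expansion loci, and whole labelled
cohorts, so the entire pipeline can be calibrated and validated without
external data.

## Worked example

Simulate a cohort of 3 expansion carriers (a 150 nt AGC tract) and 21
controls, 2,000 reads of 150 nt each, then run the full workflow:

```sh
strsift simulate --n-cases 3 --n-controls 21 --reads-per-sample 2000 \
    --motif AGC --case-repeat-nt 150 --seed 4 --out-dir cohort
strsift process --in cohort/case_00.fasta --sample-id case_00 \
    --out case_00.profile.tsv
```

```
case_00: 2000 reads, mode length 150 nt, 26 reads with recorded repeats (1.300%)
```

The profile records, per canonical motif, how many runs of each tract
length were seen — here the 25 inserted full-length AGC reads plus one
incidental short repeat:

```
#sample_id      case_00
#library_size   2000
#read_length    150
motif   tract_length    count
AACT    10      1
AGC     150     25
```

After processing every sample and listing the profiles in a manifest
(`sample_id`, `path`, `label`), screening recovers the inserted motif —
U = 63 is the maximal Mann–Whitney statistic for 3 × 21 samples, and the
exact permutation p-value 1/2024 survives FDR correction:

```
$ strsift screen --manifest profiles.tsv --label case --seed 2 --out screen.tsv
motif   n_case  n_control  U     p_raw        p_adjusted   significant
AGC     3       21         63.0  0.000494071  0.000494071  true
```

Outlier detection flags exactly the three carriers: each has information
score s_AGC = 25·150/2000 = 1.875, far above the background bound of 0
(controls carry no long AGC tracts, so the degenerate background takes
the percentile fallback):

```
$ strsift outliers --manifest profiles.tsv --seed 2 --out outliers.tsv
motif   sample_id  score  background_n  upper_bound  method      is_outlier
AGC     case_00    1.875  21            0            percentile  true
AGC     case_01    1.875  21            0            percentile  true
AGC     case_02    1.875  21            0            percentile  true
```

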