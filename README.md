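# cnsv

Channel matrices and profile plots for **large mutational events** in
cancer genomes: allele-specific copy-number segments classified into a
48-channel schema (CNV48) and structural variants into a 32-channel
schema (SV32), producing the channel × sample count matrices that
mutational-signature decomposition methods (e.g. NMF-based extractors)
take as input.

## Who this is for

Cancer-genomics analysts who have per-sample copy-number segmentation
tables (ASCAT, ABSOLUTE, Sequenza, FACETS, Battenberg, PURPLE, or any
generic 5-column format) and/or structural-variant calls in BEDPE, and
need reproducible mutational catalogues of large events plus
per-sample profile and rainfall plots.

## The classification schemas

**CNV48.** Each segment carries integer copy counts for the major
allele *A* and minor allele *B* (*A* ≥ *B* ≥ 0), with total copy number
TCN = *A* + *B*. Segments split into three heterozygosity states —
heterozygous (*A* > 0, *B* > 0), loss of heterozygosity (LOH; *A* > 0,
*B* = 0) and homozygous deletion (*A* = *B* = 0) — then by TCN class
{0, 1, 2, 3–4, 5–8, 9+} and by segment size. Het and LOH use five size
bins (0–100 kb, 100 kb–1 Mb, 1 Mb–10 Mb, 10 Mb–40 Mb, > 40 Mb), homozygous
deletions three (0–100 kb, 100 kb–1 Mb, > 1 Mb). The admissible
combinations are 20 het + 25 LOH + 3 homdel = 48 mutually exclusive
channels, labelled `TCN:state:size` (e.g. `2:LOH:>40Mb` is copy-neutral
LOH of a whole chromosome arm). All size bins are left-open,
right-closed.

**SV32.** Each rearrangement is a deletion, tandem duplication,
inversion, or translocation — taken from an input `svclass` column or
inferred from mate strands (same chromosome: +/+ → del, −/− → tds,
+/− or −/+ → inv; different chromosomes → trans). Events other than
translocations are size-binned (0–10 kb, 10–100 kb, 100 kb–1 Mb,
1 Mb–10 Mb, > 10 Mb) and every event is **clustered** or
**non-clustered**, giving 2 × (3 × 5 + 1) = 32 channels such as
`clustered_del_0-10kb` or `non-clustered_trans`.

**Clustered calls.** For each sample, every breakpoint's
inter-mutational distance (IMD) — distance to the breakpoint
immediately preceding it on the same chromosome — is computed, and each
chromosome's log₁₀(IMD + 1) series is segmented by exact
piecewise-constant fitting (Potts filter): dynamic programming finds
the global minimum of

    Σ_segments  Σ_i (x_i − x̄_segment)²  +  γ · (#segments),    γ = 25 by default.

A segment is clustered when it holds **≥ 10 breakpoints** whose mean
raw IMD is **≤ sample-mean IMD / 10**; an SV is clustered when either
of its breakpoints lies in such a segment.

## Worked example

Generate a synthetic chromothripsis-like sample (12 tightly clustered
events on one chromosome plus 8 dispersed background events — the
generator records every event's intended channel in a `.truth.tsv`
sidecar), then build the SV32 matrix with plots:

```bash
cnsv fixtures --scenario chromothripsis --n 20 --seed 7 --out fx
cnsv matrix-sv --input fx/chromothripsis_n20_s7.bedpe --out out --plot
```

prints

```
wrote out/SV32.matrix.tsv
wrote out/SV32.Sample1.png
wrote out/SV32.Sample1.rainfall.png
```

and the non-zero rows of `out/SV32.matrix.tsv` are

```
MutationType	Sample1
clustered_tds_0-10kb	7
clustered_inv_0-10kb	5
non-clustered_del_1Mb-10Mb	1
non-clustered_del_>10Mb	1
non-clustered_tds_1Mb-10Mb	3
non-clustered_tds_>10Mb	1
non-clustered_inv_>10Mb	2
```

The 12 cluster events (breakpoints ~1 kb apart, far below one tenth of
the sample's mean IMD) come out clustered in their small size bin; the
dispersed background stays non-clustered — exactly the generator's
ground truth. Column sums always equal the number of input events.

Copy-number matrices work the same way from any supported caller
dialect:

```bash
cnsv matrix-cnv --input segments.tsv --dialect ascat --out out --plot
```

Dialect column mappings (tab-separated, header required; a `sample`
column or `--sample-name`):

| dialect | chrom | start | end | major | minor |
|---|---|---|---|---|---|
| generic | chrom | start | end | major_cn | minor_cn |
| ascat | chr | startpos | endpos | nMajor | nMinor |
| absolute | Chromosome | Start | End | Modal_HSCN_1 | Modal_HSCN_2 |
| sequenza | chromosome | start.pos | end.pos | A | B |
| facets | chrom | start | end | tcn.em − lcn.em | lcn.em |
| battenberg | chr | startpos | endpos | nMaj1_A | nMin1_A |
| purple | chromosome | start | end | majorAlleleCopyNumber | minorAlleleCopyNumber |

Fractional copy numbers are rounded half away from zero; coordinates
are 1-based inclusive (BEDPE mate intervals are 0-based half-open and
are collapsed to midpoints). All clustering thresholds (`--gamma`,
`--cluster-factor`, `--min-cluster-bp`) are exposed on `matrix-sv`.

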