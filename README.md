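# vardesk

A Python toolkit re-implementing the computational core of a clinical
cancer-NGS decision-support workflow, for molecular pathology laboratories
and the scientists who curate and report somatic and germline variants from
targeted panels. It covers the path from a caller's VCF to a signed-off
clinical report:

1. **Normalisation** — multi-allelic decomposition, trimming, genomic
   left-alignment and HGVS-style 3'-shifting toward the reportable
   transcript's 3' end (with ins→dup promotion), so every representation of
   the same biological variant maps to one stable key.
2. **Annotation** — batch, per-run annotation through a persistent cache
   keyed by (variant key, source), with workload accounting.
3. **Filter flags** — ten automatic per-assay flags (`pass vaf vrd vad blk
   oor con gmaf pnl sin`) plus a multi-clause user filter-expression engine
   with tumour-stream presets.
4. **QC** — Westgard-style run-yield control limits (mean ± 2 SD of the
   previous ten same-assay runs), amplicon/sample read checks, non-template
   control screening, explicit user sign-off.
5. **Curation** — a persistent knowledge base keyed by normalised HGVS and
   optional disease context, ACMG/AMP evidence combining into five tiers,
   a role-guarded review workflow with a replayable audit trail, and
   free-text search.
6. **Reporting** — merge-field templates rendered to text/HTML with draft
   watermarking and an immutable report archive.
7. **Synthetic fixtures** — a deterministic generator producing complete
   runs (reference, transcripts, replicate-paired VCFs, read-count
   matrices, truth tables), so the whole stack is testable offline.

## The core algorithms

**Indel normalisation.** A variant (chrom, pos, ref, alt) is first trimmed
to its simplest representation (shared suffix, then shared prefix, keeping a
left anchor base). A pure indel inside a repeat tract has many equivalent
placements; left alignment rotates it to the *minimum* genomic position
whose application yields the same edited sequence (the VCF/vt convention),
which defines the canonical `variant_key`. For HGVS display the indel is
instead shifted maximally toward the gene's 3' end — genomic right for
`+` strand transcripts, genomic left for `−` strand — and an insertion whose
sequence equals the adjacent reference run is written as a duplication
(`g.2719_2720del`, `c.153G>A`, `p.(Val600Glu)`-style output).

**Flag thresholds** (strict, boundary values do not fire): VAF < 8 %
somatic / < 15 % germline; total depth < 100; alt depth < 20; population
frequency (GMAF) > 1 %; recurrence in > 35 % of assay samples; variant seen
in only one technical replicate; assay blacklist; outside the region of
interest; inferred-benign consequence. A rule whose input is missing is
reported *unevaluable*, never silently passed.

**Evidence combining.** Curated evidence items (PVS1, PS1–4, PM1–6, PP1–5,
BA1, BS1–4, BP1–7) combine per the published ACMG/AMP rules into
Pathogenic / Likely pathogenic / Unknown pathogenicity / Unlikely
pathogenic / Not pathogenic; contradictory pathogenic and benign
combinations resolve to Unknown.

## Worked example

```bash
vardesk simulate --seed 7 --out demo           # 23 sample VCFs + NTC
vardesk flag --run demo --out demo/flagged.tsv # 69 flagged calls
head -3 demo/flagged.tsv | cut -f1-6
```

```
sample_id  variant_key      gene  hgvs_g           hgvs_c               vaf
NA12878    chr1:2203:G:A    BRAF  chr1:g.2203G>A   TX.BRAF.1:c.153G>A   0.4473
NA12878    chr1:2250:C:T    BRAF  chr1:g.2250C>T   TX.BRAF.1:c.200C>T   0.5086
```

The first call is a synonymous BRAF change — it draws the `con` flag; the
second is a common polymorphism spiked into 80 % of samples, drawing
`gmaf,pnl`. The unpaired NA12878 control has no replicate, so `sin` is
listed as unevaluable rather than passed. Run-level QC against the
simulated ten-run history:

```bash
vardesk qc --run demo --history demo/runhist.tsv
# "total_reads": 1266898, "yield_verdict": "within",
# "bounds": [1175556.0, 1345676.2], "ntc_flagged": {"NTC_1": false}, ...
```

and evidence combining:

```bash
vardesk curate classify --evidence PVS1 --evidence PM2
# Likely pathogenic
```

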