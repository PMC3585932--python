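# pyroclean

Denoising of 454-style pyrosequences of protein-coding (indel-free)
amplicons, such as the 5′ region of the mitochondrial COI barcode.
`pyroclean` corrects homopolymer read errors against an IUPAC-ambiguity
consensus reference and filters PCR error, sequencing error and numt
(nuclear mitochondrial pseudogene) artifacts, recovering both inter- and
intraspecific haplotypes directly — without clustering reads into OTUs.

It is aimed at metabarcoding studies of mixed-species amplicon pools
(demultiplexed FASTA, one file per MID pool) where a taxonomically relevant
reference library exists from which a consensus can be built.

## The method

Protein-coding barcodes like COI are effectively indel-free, so any
insertion or deletion in a pyrosequencing read is diagnostic of a
homopolymer read error and shows up as a frameshift against a reference.
The pipeline anchors each read positionally on a **consensus reference
sequence** written in the IUPAC ambiguity alphabet (e.g. `R` = {A, G}),
built `consambig`-style as the per-column union of states in a reference
alignment. Each read position *bᵢ* is scored by the suffix mismatch count
*mᵢ* — the number of ambiguity-aware mismatches from *bᵢ* to the end of the
read.

1. **Unique-sequence preparation** — forward-primer trimming, length
   filtering (default: drop < 170 nt, truncate at 300 nt) and dereplication
   into count-annotated unique sequences (`>Seq1_2343`).
2. **Consensus construction** — IUPAC union consensus from an aligned
   reference FASTA (or a precomputed consensus is supplied).
3. **Homopolymer correction** — scanning 5′→3′, at each mismatch the
   algorithm tries removing one base of the adjacent homopolymer
   (insertion error) or inserting one base before the mismatch (deletion
   error, filled by homopolymer extension or the consensus symbol), and a
   compensated-indel repair for locally misaligned regions; an edit is kept
   only if the total mismatch count *strictly decreases*. Iterated to a
   fixpoint; counts of colliding corrected sequences are merged.
4. **Consensus filtering** — singletons are excluded, sequences are trimmed
   to 220 nt (the 3′ end denoises poorly for lack of downstream anchors)
   and any sequence > 1 mismatch from the consensus is removed; sequences
   identical up to consistent ambiguity codes are merged.
5. **Frequency filtering** — a sequence ≤ 1% divergent from, and < 10% as
   frequent as, a retained sequence in the same pool is removed
   (PCR/sequencing error and numt proxy).
6. **Artifact flagging** — surviving sequences bearing the signature of an
   uncorrected compensated indel (one contiguous run of ≥ 3 mismatches to a
   higher-count sequence) or a putative numt (low-frequency, low-divergence
   variant of a higher-count sequence) are flagged for manual review
   (`--drop-flagged` removes them).

A bundled simulator generates template communities with known pairwise
divergences, 454-like homopolymer indel and point errors, and linked numts,
with a full truth table — so the whole pipeline is testable without any
external data.

## Worked example

Simulate a 27-species mock community (220 nt templates, pairwise divergence
1–60 nt, 10,000 reads, 0.5 %/run homopolymer indels, 0.1 %/base point
errors, two numts per template at 5 % relative abundance) and denoise it:

```bash
pyroclean simulate --n-reads 10000 --seed 1 -o reads.fasta \
    --templates-out templates.fasta --truth-out truth.tsv
pyroclean run-all reads.fasta --alignment templates.fasta -o out
```

which prints the per-step accounting (percentages are unique-sequence
volume relative to the unique raw reads above the minimum length):

```
                  step  total_reads  unique_reads  pct_of_raw
                   raw        10000          3395         NaN
          step1_unique        10000          3395      100.00
       step3_corrected        10000          2026       59.68
        step4_filtered         7774           127        3.74
step5_cluster_filtered         7252            28        0.82
28 denoised unique sequences -> out
```

Reading it: 10,000 raw reads dereplicate to 3,395 uniques (most error
reads are unique); homopolymer correction collapses 40 % of them back onto
their templates; the consensus filter removes the singleton point-error
cloud; the frequency filter removes error doubles and numts. The 28 final
records in `out/cleaned.fasta` are the 27 true templates (header counts ≈
their read abundance) plus one low-frequency variant that is flagged in
`out/flags.tsv` as a putative numt for manual review — the pipeline reduces
unique-sequence volume to 0.8 % of the raw uniques while losing no true
haplotype.

Every stage is also available as its own subcommand (`prep`, `consensus`,
`correct`, `filter`, `cluster-filter`, `flag`), reading and writing plain
FASTA/TSV, with parameters from flags or a YAML config.

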