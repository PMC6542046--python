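# httguard

Read-based discrimination of **horizontal transposon transfer (HTT)** from
**sequence contamination**, plus the surrounding retrotransposon analytics:
reciprocal best-hit screening of TE libraries against genome sets,
per-species consensus construction, consensus identity matrices,
neighbor-joining trees, and CpG-excluded Kimura-2-parameter repeat
landscapes.

## Who this is for

Anyone who finds the same retroelement family (an RTE-clade non-LTR
element such as BovB, AviRTE or RTE1_Sar) in a parasite genome *and* in
its host's genome and needs to decide whether that is a genuine horizontal
transfer or contamination of one library by the other. Assemblies
misbehave exactly where it matters (repeats, contaminant scaffolds), so
the decision is made on reads: a read pair or a long read comes from one
contiguous molecule, and the *non-repetitive* part of an element-bearing
read tells you which organism the molecule came from.

## The core method

1. **Select** reads that carry the element, by one of three modes:
   long reads whose translation hits the element ORF (`long`), pairs with
   exactly one mate mapping into an annotated element region of the
   reference (`ref`), or — assembly-free — pairs with exactly one mate
   whose best repeat-library hit is the element (`noref`).
2. **Mask** the informative read (the non-element mate, or the whole long
   read) against the full repeat library.
3. **Classify** the masked read against two databases with a shared
   effective search space: *self* (genomes of the focal taxon) and
   *non-self* (genomes of the candidate donor taxon). Hits to the focal
   species' own genome are discarded; the database of the best surviving
   hit (by bitscore) is the verdict.
4. **Summarize**: over assigned reads, a ≥80% *non-self* majority calls
   `contamination`, a ≥80% *self* majority calls
   `endogenous/HTT-consistent`.

Supporting analytics answer the follow-up questions: does the element pass
a reciprocal best-hit screen in enough copies (≥10 loci of ≥100 bp,
E < 1e-10)? Do species consensus sequences place the suspect lineage
*inside* the donor clade on an NJ tree of CpG-excluded K2P distances
(K = −½ ln((1−2p−q)√(1−2q)))? Does the length-weighted landscape of
copy-to-consensus distances show the replication burst expected after a
transfer?

Everything runs end-to-end on synthetic data from the built-in generator
(`httguard.simfixtures`), which plants element families in host/parasite
genome pairs under explicit HTT / contamination / negative scenarios with
per-read truth labels.

## Worked example

Simulate a contamination scenario (the element lives in the donor genome
only; 5% of reads are donor-derived) and run the assembly-free test:

```bash
httguard simulate --scenario contamination --seed 1 --out scratch/contam
httguard contest --mode noref \
    --reads scratch/contam/reads_1.fq --reads scratch/contam/reads_2.fq \
    --rte scratch/contam/rte_consensus.fa \
    --self-db scratch/contam/self_db.fa --nonself-db scratch/contam/nonself_db.fa \
    --own-species recipient --repeat-lib scratch/contam/rte_consensus.fa \
    --out scratch/contam/summary.tsv --per-read scratch/contam/reads.tsv
```

which prints

```
selected=73 self=0 nonself=73 call=contamination
```

73 read pairs had exactly one element-bearing mate; after masking, every
informative mate matched the donor-taxon database better than the focal
taxon's — the element is a contaminant, not a transfer. The same command
on `--scenario htt` data instead classifies ≥95% of informative mates as
*self* (`call=endogenous/HTT-consistent`): the element is flanked by the
recipient's own sequence, as only a genuine genomic insertion can be.
`summary.tsv` carries the counts and fractions, `reads.tsv` the per-read
verdicts with best hit, bitscore and E-value.

The same decision logic applied to a published long-read count — 5309 of
5478 element-bearing long reads hitting the non-self database — gives
`frac_nonself = 0.969, call = contamination`
(`httguard.contest.summarize({"self": 169, "nonself": 5309})`).

## Layout

| module | role |
| --- | --- |
| `httguard.io_formats` | FASTA/FASTQ/BED/SAM/BLAST-tabular I/O, quality masking |
| `httguard.alignkit` | SW/NW alignment, six-frame translation, Karlin–Altschul statistics, seeded database search |
| `httguard.repeatmask` | repeat annotation, merging, filtering, hard/soft masking |
| `httguard.contest` | the contamination test: selection, classification, summary |
| `httguard.httscreen` | reciprocal best-hit TE screening, translated read screening |
| `httguard.consensus_evo` | consensus building, identity matrices, defragmentation, ORFs, NJ trees |
| `httguard.kimura` | CpG-excluded K2P distances and repeat landscapes |
| `httguard.simfixtures` | scenario generator with per-read truth labels |

See `docs/methods.md` for the models, defaults and their rationale.
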