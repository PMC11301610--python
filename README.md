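# iesweave

Detection, assembly and analysis of **internally eliminated sequences
(IESs)** and alternative chromosome breakage sites in ciliate genomes,
from long reads mapped to a somatic reference.

Ciliates carry two kinds of nuclei: a somatic macronucleus (MAC) whose
genome is the usual assembly target, and a germline micronucleus (MIC)
whose genome additionally contains thousands of short interspersed IESs
that are excised during MAC development, typically bounded by short
tandem repeats ("pointers", one copy of which remains in the MAC) — in
many species the dinucleotide `TA`.  When genomic long reads that include
MIC-derived molecules are mapped to a MAC assembly, each unexcised IES
appears as an **insertion** in the alignment, and newly formed chromosome
ends appear as **soft-clipped read tails full of telomeric repeat**.
iesweave turns those alignment signals into annotations, for researchers
studying genome editing, IES retention after gene knockdowns, or partial
germline-genome assembly.

## What it computes

* **milraa** — de novo IES calling. Insertion evidence from the BAM is
  clustered by single linkage on junction distance; clusters with enough
  distinct supporting reads are assembled to a consensus. For accurate
  (CCS-grade) reads the insert sequences themselves are polished and the
  modal junction is used; for noisy subreads the insert **plus ±100 bp of
  flanking read sequence** is extracted, polished to a consensus, and
  realigned to the reference with affine gap scores so the flanks anchor
  the insert and the traceback yields an accurate junction and sequence.
  Insertions are left-normalized (a junction inside a repeat is shifted to
  its leftmost equivalent placement), pointers and TA boundaries are
  annotated, and each call gets a per-site retention score

  ```
  retention = reads with the insert / (reads with + reads without), over spanning reads
  ```

* **milcor** — retention scoring against an existing IES annotation:
  the classic per-site score above, plus a **per-read** score (fraction of
  annotated sites spanned by a read at which the IES is not excised),
  used to bin reads into MIC-like / MAC-like / ambiguous files.

* **miltel** — chromosome breakage sites, from soft clips whose sequence
  is mostly covered by rotations of the telomeric motif (default
  `TTGGGG`) on either strand.

* **simulate / evaluate** — a synthetic-data generator producing paired
  MAC/MIC genomes with planted pointer/TA-structured IESs, noisy long
  reads with their exact true alignments (no external mapper needed), and
  an evaluator that matches calls to the planted truth and reports
  recall, precision and sequence-assembly accuracy.

## Worked example

```sh
iesweave simulate --seed 5 --out-dir sim --n-contigs 1 --contig-len 30000 --n-iess 5
iesweave milraa --bam sim/truth.bam --ref sim/mac.fasta --mode subread \
    --out-gff ies.gff3 --out-fasta ies.fasta --out-clusters clusters.tsv
iesweave evaluate --pred ies.gff3 --pred-fasta ies.fasta \
    --truth sim/ies_truth.tsv --tol 5 --out metrics.json
cat metrics.json
```

prints

```json
{
  "n_truth": 5,
  "n_pred": 5,
  "n_matched": 5,
  "recall": 1.0,
  "precision": 1.0,
  "n_exact_seq": 3,
  "n_seq_1mm1indel": 5
}
```

i.e. all five planted IESs were called within ±5 bp of their true
junctions with no false calls; three insert sequences were reconstructed
base-perfectly and all five to within one mismatch and one indel.  The
GFF3 holds one zero-width junction feature per IES (1-based
`start == end` = first MAC base after the insertion point) with length,
pointer, TA status, support and retention score in the attributes.

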