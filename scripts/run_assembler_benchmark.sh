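#!/usr/bin/env bash
# Full assembler-recovery benchmark harness.
#
# Regenerates the inputs for an external-assembler benchmark: a synthetic
# donor/recipient community, transfers mutated at several divergence
# levels, and error-free paired-end reads from the modified community.
# The assembly and alignment stages require external tools (a metagenome
# assembler such as IDBA_UD or metaSPAdes, and blastn) and their results
# depend on the assembler version and k-mer settings, so they are listed
# here as documented manual steps rather than executed.
#
# Usage: scripts/run_assembler_benchmark.sh [OUTDIR] [SEED]

set -euo pipefail

OUT="${1:-scratch/benchmark}"
SEED="${2:-1}"
LEVELS="0 5 10 15 20 25 30"
FLANK="TAGATGAGTGATTAGTTAGTTA"

mkdir -p "$OUT"

# 1. Synthetic community standing in for the 10 donor + 10 recipient genomes.
hgtsim fixtures --seed "$SEED" --out "$OUT/fixtures"

for LEVEL in $LEVELS; do
    GROUP="$OUT/level_$LEVEL"

    # 2. Mutate the donor genes at this divergence level (ratio 1:0:1:1).
    hgtsim mutate --genes "$OUT/fixtures/donor_genes.fasta" \
        --mutation-level "$LEVEL" --ratio 1:0:1:1 \
        --seed "$SEED" --out "$GROUP/mutated"

    # 3. Insert flanked cassettes into the recipients.
    hgtsim insert --genes "$GROUP/mutated/mutated_genes.fasta" \
        --recipients "$OUT/fixtures/recipients" --flank "$FLANK" \
        --mode uniform --seed "$SEED" --out "$GROUP/inserted"

    # 4. Error-free 2x100 bp pairs, 250 bp insert, even depth.
    hgtsim simulate-reads --community "$GROUP/inserted" \
        --n-pairs 200000 --read-length 100 --insert-size 250 \
        --seed "$SEED" --out "$GROUP/reads"

    cat <<EOF
================================================================
Level $LEVEL% inputs ready under $GROUP.
Manual steps (external tools, version-dependent results):

  # assemble (pick one; sweep k-mer ranges to reproduce the comparison)
  idba_ud  -r <interleaved reads>            -o $GROUP/asm_idba
  metaspades.py -1 $GROUP/reads/reads_R1.fastq \\
                -2 $GROUP/reads/reads_R2.fastq -o $GROUP/asm_spades

  # align transfers to contigs (12-column tabular output)
  makeblastdb -in <contigs.fasta> -dbtype nucl
  blastn -query $GROUP/mutated/mutated_genes.fasta \\
         -db <contigs.fasta> -outfmt 6 > $GROUP/gene_hits.tsv

  # score recovery with the 99%/99%/>1 kb criterion
  hgtsim evaluate \\
      --insertion-report $GROUP/inserted/insertion_report.tsv \\
      --genes $GROUP/mutated/mutated_genes.fasta \\
      --contigs <contigs.fasta> \\
      --recipients $OUT/fixtures/recipients \\
      --gene-hits $GROUP/gene_hits.tsv \\
      --out $GROUP/evaluation
================================================================
EOF
done
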