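# oasm — organelle genome assembly from accurate long reads

`oasm` assembles plant organelle genomes (plastomes and mitogenomes) from
high-accuracy long reads and resolves the assembly graph into primary
circular/linear sequences. The stack:

1. **Syncmer extraction** (`oasm.syncmer`) — reads are homopolymer
   compressed; closed syncmers (k-mers whose first or last s-mer has the
   minimal strand-canonical hash) give a spanning, overlap-guaranteed
   sparse k-mer set (~(k−s+1)/2-fold compression). Distinct syncmers form
   a table with frequencies and run-length consensus; each read becomes a
   vector of ⟨table index, position, orientation⟩ triples.
2. **Sparse de Bruijn graph** (`oasm.kmer_graph`) — Watson–Crick complete
   bidirected graph over syncmer pairs, with per-edge coverage and overlap.
3. **Error correction** (`oasm.error_correct`) — low-frequency syncmers
   mark error blocks; a DFS over the error-trimmed graph scores candidate
   replacement paths with a banded (Ukkonen-style) incremental prefix edit
   distance and applies the best path only when unambiguous.
4. **Graph cleaning and unitigs** (`oasm.assembly_graph`) — coverage
   filtering, tip trimming (<10 kb), bubble popping (<100 kb), maximal
   unambiguous paths with consensus sequences, k-mer-level read mapping,
   and read-triplet-driven disentangling of shared-sequence tangles.
5. **Classification** (`oasm.annotate`) — nhmmscan-style gene hits are
   filtered (e ≤ 1e-6, score ≥ 300) and components labeled progressively,
   with the plastid→mitochondrion transfer rule and new-best-gene gates.
6. **Path resolution** (`oasm.pathfinder`) — EM copy numbers, exhaustive
   canonical path enumeration over the copy-expanded component, longest
   path with a 90% circular preference and read-support tie-breaks;
   plastomes are oriented by Spearman rank correlation against a packaged
   71-gene reference order and rotated to start at psbA; inverted-repeat
   (LSC/IRa/SSC/IRb) structure detection; flip-flop heteroplasmy read
   counts with an exact binomial test. Non-circular first-round primaries
   trigger integer edge-visit optimisation (brute force, or seeded
   simulated annealing for large solution spaces) and a second enumeration.
7. **Simulation** (`oasm.simulate`) — deterministic synthetic genomes
   (exact IRs/DRs, shared segments, gene layouts), HiFi-like reads
   (lognormal 5–25 kb, substitution + homopolymer run-length errors,
   truth-encoding names) and tblout-style hit tables, so the whole pipeline
   is testable offline.

## CLI

```sh
oasm simulate --seed 1 -o sim                    # FASTA/FASTQ/tblout fixtures
oasm assemble reads.fastq -k 1001 -s 31 -c 150 -o asm
oasm classify asm.utg.gfa hits.tbl              # component labels
oasm resolve reads.fastq hits.tbl -c 150 -o out # primary FASTA + structure TSV
```

`resolve` writes `out.primary.fasta` (circular flag in headers) and
`out.structure.tsv` (LSC/IR/SSC coordinates per resolved genome). Useful
flags: `--circular-pref 0.9`, `--sa-seed`, `--max-expanded-nodes`,
`--epsilon`.

## Layout

```
src/oasm/            io_formats, syncmer, kmer_graph, error_correct,
                     assembly_graph, annotate, pathfinder, simulate,
                     pipeline, cli; data/plastid_gene_order.txt
tests/               pytest suite incl. test_acceptance.py (one test per
                     acceptance criterion, with independent oracles)
scripts/acceptance.py
```
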