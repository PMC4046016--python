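# mdmi

Multidimensional mutual-information (2D/3D/4D MI) covariation analysis of
protein multiple sequence alignments, with a structure-based evaluation
battery: top-L contact detection, method-overlap matrices, secondary-structure
period signals, and covariation-graph connectivity/transitivity.

The 2D map is plain pairwise mutual information between alignment columns.
The 3D map replaces each pair score with the conditional MI given a third
column, averaged over every third column, removing ternary indirect coupling;
the 4D map additionally conditions on a fourth column (averaged first over
the fourth, then over the third), removing quaternary interdependencies.
Maps are post-processed with the average-product correction (APC) and a
two-sided z-score product normalization (ZPX2).

## Layout

| module | contents |
| --- | --- |
| `mdmi.msa_io` | FASTA/Stockholm reading, 21-symbol integer encoding, column-to-structure mapping |
| `mdmi.core` | joint entropies of 1–4 columns; 2D/3D/4D covariation map builders |
| `mdmi.corrections` | APC and ZPX2 corrections, standard pipeline |
| `mdmi.mapio` | TSV map interchange (native header format + plain third-party matrices) |
| `mdmi.struct_eval` | PDB centroid contact maps, top-L ranking, true-contact curves, overlap matrices |
| `mdmi.ss_signal` | distance-dependent covariation signal within helices/strands |
| `mdmi.netconn` | covariation graphs, transitivity, shortest indirect paths in structure space |
| `mdmi.synthetic` | synthetic MSAs with planted pair/chain/latent-block dependencies and ground truth |
| `mdmi.cli` | `mdmi` command-line entry point |

## CLI

```sh
mdmi read --format fasta aln.fasta
mdmi simulate --spec spec.json --out aln.fasta --truth truth.tsv
mdmi compute --method 3d --in aln.fasta --out map.tsv
mdmi correct --in map.tsv --out map.zpx2.tsv          # APC + ZPX2
mdmi eval --map map.zpx2.tsv --aln aln.fasta --pdb ref.pdb \
    --chain A --cutoff 8 --minsep 0,6,12,20 --top 0 --out curves.tsv
mdmi overlap --maps a.tsv --maps b.tsv --top 250 --out overlap.tsv
mdmi ss-signal --map map.zpx2.tsv --aln aln.fasta --pdb ref.pdb \
    --type helix --out signal.tsv
mdmi network --map map.zpx2.tsv --aln aln.fasta --pdb ref.pdb \
    --mode transitivity --out transitivity.tsv
```

Map files are tab-separated L×L matrices with a `#` metadata header; plain
whitespace/CSV matrices from third-party covariation tools are read as
`external` maps. Every file-producing run writes a
`<output>.manifest.json` recording parameters, input hashes and the package
version.

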