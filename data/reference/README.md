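# Reference sequences (user-supplied)

Exact reproduction of the published gene/protein parameters for the
*Acidithiobacillus ferrooxidans* ATCC 23270 sHSP genes requires the
public genome sequence (GenBank accession NC_011761, loci Afe_1009,
Afe_1437, Afe_2172), which is not redistributed with this package.

To enable the reference-sequence checks, place here:

- `shsp_cds.fasta` — the three annotated CDS nucleotide sequences
  (start through stop codon), FASTA ids `Afe_1009`, `Afe_1437`, `Afe_2172`.
- `shsp_proteins.fasta` — the three protein sequences, same ids.

For example, with Entrez Direct and the coordinates from the NC_011761
annotation:

```sh
efetch -db nuccore -id NC_011761.1 -format fasta_cds_na > cds_all.fna
seqkit grep -nr -p "Afe_1009|Afe_1437|Afe_2172" cds_all.fna > shsp_cds.fasta
```

Tests that depend on these files fail with an explanatory message when
the files are absent; everything else in the package runs on synthetic
data.
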