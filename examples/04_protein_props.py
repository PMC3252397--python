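"""Protein characterization: length, molecular weight, theoretical pI,
and pairwise identity/similarity.

Runs on small demonstration peptides; point `read_fasta` at your own
protein FASTA for real sequences.
"""

from shspkit import characterize, pairwise_identity_similarity
from shspkit.proteins import properties_table

demo = {
    "acidic_rich": "MDEDEDSAEELLKEAGITQDEFEEIVGDDAEYAE",
    "basic_rich": "MKKRLKQAARKGLKHKQRSVKRALKKTGSKKRLA",
    "mixed": "MSLIRWQPFREFDSLQSEIDRIFDDAIASTGGSR",
}
props = [characterize(name, seq) for name, seq in demo.items()]
print(properties_table(props).to_string(index=False))
# mw_da: average-mass molecular weight (residues + one water);
# pi: pH of zero net charge under the Bjellqvist pKa set.

r = pairwise_identity_similarity(demo["acidic_rich"], demo["mixed"],
                                 "acidic_rich", "mixed")
print(f"\n{r.locus_a} vs {r.locus_b}: identity {r.identity_pct:.0f}%, "
      f"similarity {r.similarity_pct:.0f}% over {r.alignment_length} columns")
# identity = identical alignment columns; similarity also counts
# positive-scoring (conservative) BLOSUM62 substitutions.
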