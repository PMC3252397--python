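"""GC chi-square screen for horizontally acquired genes.

Simulates one AT-rich gene (40% GC) and one typical gene against the
59% coding-gene background of *A. ferrooxidans* and also recomputes the
significance pattern implied by the published per-gene GC percentages.
"""

from shspkit import hgt_screen
from shspkit.composition import composition_table, gc_chi_square
from shspkit.published import CDS_LENGTH_NT, GC_PERCENT, GENOME_AVG_GC
from shspkit.simulate import simulate_gene

genes = [
    simulate_gene(450, 0.40, seed=7, locus="foreign_like"),
    simulate_gene(450, 0.59, seed=8, locus="native_like"),
]
print(composition_table(hgt_screen(genes)).to_string(index=False))
# hgt_flag is True when the gene's GC differs from the genomic background
# at alpha = 0.01 (Pearson chi-square, 1 df).

print("\npattern from the published GC percentages:")
for locus, gc_pct in GC_PERCENT.items():
    n = CDS_LENGTH_NT[locus]
    chi2, p = gc_chi_square(round(gc_pct / 100 * n), n, GENOME_AVG_GC)
    print(f"  {locus}: GC {gc_pct:.2f}% over {n} nt -> p = {p:.2e} "
          f"({'candidate HGT' if p < 0.01 else 'background-like'})")
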