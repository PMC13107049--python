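"""Enumerate the copy-number tag library and size the panel-selection space.

Each cell population is barcoded by a triple (c_C, c_G, c_R) of tandem
11th-strand repeat counts for the cyan/green/red split FPs.  With levels
{0,1,2,4,8} and at most 12 total repeats, 96 distinct non-null barcodes
exist — and choosing the best 20 of them is a search over ~2x10^20 subsets,
which is why panel selection uses random sampling rather than enumeration.
"""

from fpbarcode import tags

lib = tags.enumerate_tag_library(levels=(0, 1, 2, 4, 8), max_total=12)
print(f"library size: {len(lib)} tags")
print(f"first/last:   {lib[0].tag_id} ... {lib[-1].tag_id}")

n_subsets = tags.subset_count(96, 20)
print(f"20-of-96 subsets: {tags.format_scientific(n_subsets, 1)} ({n_subsets})")

print(f"binary 5-color capacity: {tags.binary_label_capacity(5)} combinations")
# 96 intensity barcodes from 3 colors vs. 31 on/off states from 5 colors:
# intensity modulation beats adding fluorophores.
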