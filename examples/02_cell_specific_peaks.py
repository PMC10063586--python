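"""Derive cell-type-specific peaks with the "half or less" sharing rule.

Peaks from all cell types are merged into consensus units; a unit is
cell-type-specific iff it appears in at most half of the cell types
(inclusive at exactly half), and is then emitted into the specific set of
every member cell type.
"""

from cellrisk import annotation, synthio

genome = synthio.generate_genome(synthio.GenomeConfig(n_variants=2000), seed=1)
peaks, truth_table = synthio.generate_annotations(
    genome,
    synthio.AnnotationConfig(n_cell_types=6, n_background_peaks=400, sharing="mixed"),
    seed=2,
)

specific = annotation.derive_cell_specific_peaks(list(peaks.values()), 0.5)
print("sharing histogram of consensus units:")
print(truth_table["count"].value_counts().sort_index().to_string())
for cell in sorted(specific):
    print(f"{cell}: {len(peaks[cell])} raw peaks -> {len(specific[cell])} specific")
# Units shared by 1-3 of the 6 cell types survive the filter; units in 4+
# cell types are excluded everywhere.
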