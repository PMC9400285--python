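# Template KIR gene region BED (chrom, start, end, gene), 0-based half-open.
# ILLUSTRATIVE PLACEHOLDER COORDINATES ONLY — replace with coordinates
# matched to your reference build before genotyping real data.  The KIR
# locus lies on chromosome 19q13.4; gene boundaries differ between builds
# and between KIR haplotypes.
chr19	54724000	54737000	KIR3DL3
chr19	54738000	54753000	KIR2DL3
chr19	54754000	54769000	KIR2DL1
chr19	54770000	54784000	KIR2DL4
chr19	54785000	54800000	KIR3DL1
chr19	54801000	54816000	KIR2DS4
chr19	54817000	54832000	KIR3DL2
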