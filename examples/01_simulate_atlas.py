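"""Generate the default synthetic chickpea-like atlas and write it to disk.

The bundle contains a random-base genome with planted gene models, a
32-tissue / 94-sample FPKM matrix, a motif library, variants, QTL intervals
and the machine-readable ground truth behind all of them.
"""

import sys

from ciceratlas import synthetic

outdir = sys.argv[1] if len(sys.argv) > 1 else "scratch/atlas"
bundle = synthetic.generate_atlas(synthetic.AtlasSpec(seed=1))
paths = synthetic.write_atlas(bundle, outdir)

print(f"transcripts:        {len(bundle.annotation)}")
print(f"  protein-coding:   {len(bundle.annotation.pcgs)}")
print(f"  lncRNAs:          {len(bundle.annotation.lncrnas)}")
print(f"samples:            {bundle.atlas.matrix.shape[1]} over {len(bundle.atlas.tissues)} tissues")
print(f"motifs / variants / QTLs: {len(bundle.motifs)} / {len(bundle.variants)} / {len(bundle.qtls)}")
print("files written to:", outdir)
# The counts above are the planted study design; the truth_*.tsv files in the
# output directory record which transcript plays which role.
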