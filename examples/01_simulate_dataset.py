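"""Generate an RRBS-like dataset with planted DMRs and inspect it.

Simulates the emulated study design — 5 sire families, each with a control
arm (sons sired before the father's heat exposure) and a heat arm — and
writes bismark-coverage count files, BED annotation tracks, a design table
and the planted-truth BED.
"""

from pathlib import Path
from tempfile import mkdtemp

from dmrcall import SimulationParams, generate_dataset

outdir = Path(mkdtemp(prefix="dmrcall_example_"))
params = SimulationParams(seed=42)
dataset = generate_dataset(params, outdir)

n_cpgs = sum(len(p) for p in dataset.landscape.positions.values())
n_island = sum(m.sum() for m in dataset.landscape.island_mask.values())
print(f"wrote {len(dataset.tables)} samples to {outdir}")
print(f"{n_cpgs} CpGs ({n_island} inside CpG islands), "
      f"{len(dataset.annotation['CDS'])} genes, "
      f"{len(dataset.annotation['CGI'])} CpG islands")
print(f"{len(dataset.truth)} planted DMRs "
      f"(effect {params.planted_effect:+.2f} methylation-ratio shift in the heat arm):")
for t in dataset.truth[:5]:
    print(f"  {t.chrom}:{t.start}-{t.end}  {t.n_cpgs} CpGs  {t.direction}")
print("...")
# Each count file is one sample's per-CpG methylated/unmethylated reads; the
# planted intervals are where the heat arm's methylation was shifted, i.e.
# what the pipeline should rediscover without being told.
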