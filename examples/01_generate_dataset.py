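"""Simulate a texture-analyzer stress-relaxation experiment on tomatoes.

Draws a small fruit population (3 per size class x probe position, with the
published between-fruit parameter spread), simulates one compression trace
per fruit (1 mm at 1 mm/s, 60 s hold, 20 Hz, 0.49 N contact trigger) and
writes the dataset as CSV files.
"""

import tempfile
from pathlib import Path

import fruitrelax as fr

noise = fr.NoiseSpec(seed=0)  # 0.5% force noise, full parameter spread
population = fr.sample_population(n_per_group=3, noise=noise, family="mixed")
traces = [fr.generate_force_trace(s, fr.CompressionProtocol(), noise) for s in population]

outdir = Path(tempfile.mkdtemp(prefix="fruitrelax_"))
fr.write_dataset(population, traces, outdir)

print(f"{len(population)} fruit, {len(traces)} traces written to {outdir}")
first = population[0]
trace = traces[0]
n_relax = int((trace.stages == "relaxation").sum())
print(f"example fruit {first.id}: R = {first.radius_mm:.1f} mm, "
      f"ground truth = {first.true_params}")
print(f"its trace has {len(trace.times)} samples, {n_relax} in the 60 s hold "
      f"(20 Hz x 60 s), peak force {trace.forces.max():.2f} N")
# The peak force of a few newtons is what a texture analyzer reads when a
# ripe tomato is compressed by 1 mm; the hold block is the part the
# relaxation models are fitted to.
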