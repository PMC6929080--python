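"""Tune pipeline parameters by differential evolution on a tiny phantom set.

A deliberately small run (3 images, population 6, 2 generations) that shows
the optimiser's mechanics: the best fitness (mean curve MAE in px, plus a
100 px penalty per failed image) can only go down across generations.
A real calibration would use a larger set, population and generation count.
"""

from octlens.config import PipelineConfig
from octlens.optimize import config_fitness, pipeline_bounds, run_de
from octlens.phantom import generate_dataset

dataset = generate_dataset(3, base_seed=12)
best, history = run_de(config_fitness(dataset), pipeline_bounds(),
                       n=6, max_gen=2, seed=12)
config = PipelineConfig.from_vector(best)
print("best fitness per generation (px):",
      [round(h, 2) for h in history])
print(f"selected parameters: median {config.median_k}, "
      f"Canny {config.canny_low:.0f}/{config.canny_high:.0f}, "
      f"snake alpha/beta {config.snake_alpha:.0f}/{config.snake_beta:.0f}")
# The history is non-increasing by construction: a candidate configuration
# only replaces its predecessor when it segments the set at least as well.
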