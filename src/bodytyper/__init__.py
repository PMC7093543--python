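"""bodytyper: body-shape stratification of anthropometric cohorts.

From raw multi-measure body-scanner tables to meta-measures, body types,
aging trajectories and health associations, with a synthetic-cohort
generator for fully reproducible runs.
"""

__version__ = "0.1.0"

from .cohort import Cohort, MeasureMatrix
from .config import (ArchetypeSpec, BlockSpec, ConfigError, GeneratorConfig,
                     LinkRule, PipelineConfig)
from .synthetic import (generate_activity, generate_cohort, generate_health,
                        plant_block_structure, simulate)

__all__ = [
    "Cohort", "MeasureMatrix", "ArchetypeSpec", "BlockSpec", "ConfigError",
    "GeneratorConfig", "LinkRule", "PipelineConfig", "generate_activity",
    "generate_cohort", "generate_health", "plant_block_structure", "simulate",
    "run_pipeline", "__version__",
]


def run_pipeline(config, out_dir=None):
    """Execute the full analysis pipeline (see :mod:`bodytyper.pipeline`)."""
    from .pipeline import run_pipeline as _run
    return _run(config, out_dir)
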