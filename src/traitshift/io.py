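"""One import surface for every file format the pipeline touches.

Grids are ESRI ASCII (plus a YAML stack manifest), occurrences and traits
are CSV, phylogenies are Newick, scenarios and configs are YAML.  The
functions live next to the objects they serialise; this module gathers
them for callers that only do I/O.
"""

from .config import PipelineConfig
from .grids import (read_grid, read_scenario, read_stack, write_grid,
                    write_scenario, write_stack)
from .phylo import read_tree
from .synthetic import read_occurrences, write_occurrences
from .traits import read_traits, write_traits

__all__ = [
    "read_grid", "write_grid", "read_stack", "write_stack",
    "read_scenario", "write_scenario", "read_tree",
    "read_occurrences", "write_occurrences",
    "read_traits", "write_traits", "PipelineConfig",
]
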