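"""Shared configuration for the numbered analysis drivers.

One fixed seed and one run directory so the drivers compose into a single
reproducible analysis.  The planted up:down proportion is set to 0.9 here
(regulation in chronically exposed cohorts is dominated by up-regulation);
the library default remains symmetric.
"""

from pathlib import Path

from radprot import RunConfig

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"

CONFIG = RunConfig(seed=11, up_fraction=0.9)
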