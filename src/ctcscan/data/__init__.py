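"""Bundled reference spot-count tables from z-stack / step calibration scans.

Four per-cell FISH spot-count tables recorded while calibrating the
acquisition on patient material carrying ALK-, ROS1- and ERG-rearranged
tumors: three tables sweep the z-stack count (5-30 at a 0.6-um step) and one
sweeps the step (0.5-0.8 um at 30 stacks).  ``n.i.`` marks cells whose
spots were uncountable (non-optimal DAPI focus).  A handful of source cells
were typographically garbled in print; the transcriptions here follow the
bold-row-maximum convention of the source tables.
"""

from __future__ import annotations

from importlib import resources

from ctcscan.fafish import SpotCountTable
from ctcscan.io import read_fish_table_csv

REFERENCE_TABLES = {
    "zstacks_alk": "table_zstacks_alk.csv",
    "zstacks_ros1": "table_zstacks_ros1.csv",
    "zstacks_erg": "table_zstacks_erg.csv",
    "step_alk": "table_step_alk.csv",
}


def load_reference_table(key: str) -> SpotCountTable:
    """Load one bundled calibration table by key.

    Keys: ``zstacks_alk``, ``zstacks_ros1``, ``zstacks_erg`` (columns are
    z-stack counts 5..30) and ``step_alk`` (columns are steps 0.5..0.8 um).
    """
    try:
        fname = REFERENCE_TABLES[key]
    except KeyError:
        raise KeyError(f"unknown reference table {key!r}; options: {sorted(REFERENCE_TABLES)}")
    with resources.as_file(resources.files(__package__) / fname) as p:
        return read_fish_table_csv(p)
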