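"""Unit bridge between per-cell molecule counts and molar concentrations.

The kinetic model works in mol/L while all measurements (qRT-PCR, plasmid
copy number) come in molecules per cell.  The two are linked by the volume
of a single cell, ``CELL_VOLUME_L`` (default 1e-15 L, a typical E. coli
cytoplasmic volume).  The volume is a configuration knob: every function
accepts an explicit ``volume_l`` so that analyses can record the value they
used.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol
CELL_VOLUME_L = 1.0e-15   # default single-cell volume, litres


def molecules_to_molar(n_molecules: float, volume_l: float = CELL_VOLUME_L) -> float:
    """Convert a per-cell molecule count to a molar concentration."""
    if volume_l <= 0:
        raise ValueError(f"cell volume must be positive, got {volume_l}")
    return n_molecules / (AVOGADRO * volume_l)


def molar_to_molecules(conc_m: float, volume_l: float = CELL_VOLUME_L) -> float:
    """Convert a molar concentration to a per-cell molecule count."""
    if volume_l <= 0:
        raise ValueError(f"cell volume must be positive, got {volume_l}")
    return conc_m * AVOGADRO * volume_l
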