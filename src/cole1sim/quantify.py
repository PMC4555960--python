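"""Absolute quantification: qRT-PCR calibration lines, copy number from
plasmid mass, and replicate statistics.

CT values from a 10-fold standard dilution series are regressed on
log10(template molecules) to give a calibration line (slope approximately
-3.32 at 100% PCR efficiency); sample CTs are inverted through the line and
divided by the cell count to give molecules per cell.  Plasmid copy number
is alternatively computed from a measured plasmid mass, the plasmid size
and the cell titer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .units import AVOGADRO

#: average mass of one double-stranded base pair, g/mol
BASE_PAIR_MASS_G_PER_MOL = 650.0


@dataclass(frozen=True)
class CalibrationLine:
    """Linear CT = slope * log10(molecules) + intercept.

    A working standard has a negative slope (more template, earlier CT);
    ``dilution_range`` is the number of decades spanned by the standards.
    """

    slope: float
    intercept: float
    r_squared: float
    dilution_range: float

    @property
    def efficiency(self) -> float:
        """PCR amplification efficiency implied by the slope (1.0 = 100%)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def ct_for(self, molecules: float) -> float:
        if molecules <= 0:
            raise ValueError("molecule count must be positive")
        return self.slope * math.log10(molecules) + self.intercept

    def molecules_for(self, ct: float) -> float:
        return 10.0 ** ((ct - self.intercept) / self.slope)


def fit_calibration(molecule_counts, ct_values) -> CalibrationLine:
    """Least-squares calibration line of CT on log10(molecules).

    Requires >= 2 distinct positive dilution points.  A non-negative fitted
    slope indicates a degenerate standard series and raises a warning flag
    (the line is still returned).
    """
    m = np.asarray(molecule_counts, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if m.shape != ct.shape or m.ndim != 1:
        raise ValueError("molecule counts and CT values must be 1-D, equal length")
    if np.any(m <= 0):
        raise ValueError("molecule counts must be strictly positive")
    logm = np.log10(m)
    if len(np.unique(logm)) < 2:
        raise ValueError("need at least two distinct dilution points")
    res = stats.linregress(logm, ct)
    if res.slope >= 0:
        warnings.warn("calibration slope is non-negative: degenerate standard",
                      RuntimeWarning, stacklevel=2)
    return CalibrationLine(float(res.slope), float(res.intercept),
                           float(res.rvalue ** 2),
                           float(logm.max() - logm.min()))


def molecules_from_ct(ct: float, line: CalibrationLine, cell_count: float,
                      warn_extrapolation: bool = True) -> float:
    """Molecules per cell implied by a sample CT.

    Inverts the calibration line and divides by the cell count.  CT values
    outside the calibrated CT window are still converted, with an
    extrapolation warning.
    """
    if cell_count <= 0:
        raise ValueError(f"cell count must be positive, got {cell_count}")
    if warn_extrapolation and line.slope < 0:
        ct_hi = line.intercept  # CT at one molecule
        ct_lo = line.intercept + line.slope * line.dilution_range * 1.5
        if not (ct_lo <= ct <= ct_hi):
            warnings.warn(f"CT {ct} outside calibrated range", RuntimeWarning,
                          stacklevel=2)
    return line.molecules_for(ct) / cell_count


def pcn_from_mass(mass_ng: float, plasmid_size_bp: float, purity_ratio: float,
                  cell_count: float,
                  bp_mass: float = BASE_PAIR_MASS_G_PER_MOL) -> float:
    """Plasmid copy number from an isolated plasmid mass.

    (mass in g x purity) / (size_bp x 650 g/mol/bp) gives moles of plasmid;
    times Avogadro's number and divided by the cell titer gives
    molecules per cell.
    """
    if mass_ng <= 0 or plasmid_size_bp <= 0 or cell_count <= 0:
        raise ValueError("mass, plasmid size and cell count must be positive")
    if not (0.0 < purity_ratio <= 1.0):
        raise ValueError(f"purity ratio must be in (0, 1], got {purity_ratio}")
    moles = mass_ng * 1e-9 * purity_ratio / (plasmid_size_bp * bp_mass)
    return moles * AVOGADRO / cell_count


def quantify_samples(samples, lines: dict, average: str = "ct"):
    """Per-sample absolute quantification from a plate export.

    ``samples`` is a DataFrame with columns sample, target, ct, cell_count
    (one row per technical replicate); ``lines`` maps target name to its
    CalibrationLine.  Technical replicates are averaged on the CT scale
    before inversion (``average="ct"``); ``average="molecules"`` instead
    inverts each CT and averages in molecule space (a geometric-mean-like
    alternative).  Returns a DataFrame sample x target -> molecules/cell.
    """
    import pandas as pd
    if average not in ("ct", "molecules"):
        raise ValueError("average must be 'ct' or 'molecules'")
    rows = []
    for (sample, target), grp in samples.groupby(["sample", "target"]):
        line = lines[target]
        cells = float(grp["cell_count"].iloc[0])
        if average == "ct":
            value = molecules_from_ct(float(grp["ct"].mean()), line, cells,
                                      warn_extrapolation=False)
        else:
            value = float(np.mean([
                molecules_from_ct(ct, line, cells, warn_extrapolation=False)
                for ct in grp["ct"]]))
        rows.append({"sample": sample, "target": target,
                     "molecules_per_cell": value})
    return pd.DataFrame(rows)


def replicate_table(per_sample, group_cols=("time_point", "target")):
    """Collapse biological replicates to mean +/- SD (population formula).

    ``per_sample`` must carry the grouping columns and a
    ``molecules_per_cell`` column; the output mirrors the layout of the
    per-timepoint concentration tables (one row per group).
    """
    import pandas as pd
    rows = []
    for keys, grp in per_sample.groupby(list(group_cols)):
        m, sd = mean_sd(grp["molecules_per_cell"].to_numpy())
        row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        row.update({"mean": m, "sd": sd, "n": len(grp)})
        rows.append(row)
    return pd.DataFrame(rows)


def mean_sd(values) -> tuple[float, float]:
    """Replicate mean and population standard deviation (divisor N).

    With a single replicate the SD is undefined and returned as NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one replicate")
    m = float(v.mean())
    if v.size == 1:
        return m, float("nan")
    return m, float(np.sqrt(np.mean((v - m) ** 2)))
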