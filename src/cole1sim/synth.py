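"""Synthetic study generator.

Produces every raw input the measurement pipeline consumes — OD600 growth
curves, qRT-PCR standard dilution series and sample plates, plasmid-mass /
cell-titer records — from a known ground truth, so the whole pipeline
(growth fitting, absolute quantification, model calibration, simulation)
can be exercised and checked end to end without any laboratory data.

Noise models: multiplicative log-normal for OD readings and plasmid masses
(strictly positive quantities), additive Gaussian for CT values.  All
randomness flows from the single ``seed`` in the configuration.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import CalibrationLine, BASE_PAIR_MASS_G_PER_MOL
from .units import AVOGADRO


@dataclass
class SyntheticStudyConfig:
    """Ground truth and noise levels for one synthetic cultivation study.

    The defaults emulate the structure of the measured study: three
    biological replicates per harvest point, exponential growth described
    by a polynomial in time, more free RNAI than RNAII at every time point,
    and copy-number scatter that can reach a large fraction of the mean.
    """

    seed: int
    #: polynomial coefficients (descending) of true ln(OD/OD0) vs t [h]
    true_mu_poly: tuple[float, ...] = (0.0, -0.004, 0.3, 0.0)
    harvest_times_h: dict = field(default_factory=lambda: {
        "T1": 5.25, "T2": 8.25, "T3": 10.5})
    true_pcn: dict = field(default_factory=lambda: {
        "T1": 46.0, "T2": 48.0, "T3": 46.0})
    true_rna: dict = field(default_factory=lambda: {
        "T1": {"RNAI": 34.0, "RNAII": 3.0},
        "T2": {"RNAI": 17.0, "RNAII": 1.0},
        "T3": {"RNAI": 6.0, "RNAII": 0.44}})
    plasmid_size_bp: int = 7896
    replicates: int = 3
    od_timestep_h: float = 0.25
    od_sigma: float = 0.02            # log-normal sigma on OD readings
    ct_sigma: float = 0.2             # Gaussian sigma on CT values
    mass_cv: float = 0.3              # log-normal CV on plasmid masses
    cal_slope: float = -3.32          # CT per decade, ~100% PCR efficiency
    cal_intercept: float = 38.0
    dilution_decades: int = 6
    standard_top_molecules: float = 2e8
    #: cells per quantified extract; keeps sample totals inside the
    #: calibrated standard range (samples are diluted into range in practice)
    cell_count: float = 1e6

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.dilution_decades < 4:
            raise ValueError("need at least 4 dilution decades")
        for tp, v in self.true_pcn.items():
            if v <= 0:
                raise ValueError(f"true PCN must be positive at {tp}")

    def rng(self, stream: str) -> np.random.Generator:
        # stable stream id (builtin hash() is salted per process)
        stream_id = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng([self.seed, stream_id])

    def true_log_od(self, t: float) -> float:
        return float(np.polyval(self.true_mu_poly, t))

    def true_mu(self, t: float) -> float:
        return float(np.polyval(np.polyder(np.poly1d(self.true_mu_poly)), t))

    @property
    def true_line(self) -> CalibrationLine:
        return CalibrationLine(self.cal_slope, self.cal_intercept, 1.0,
                               float(self.dilution_decades))


def generate_od_series(config: SyntheticStudyConfig) -> pd.DataFrame:
    """OD600 readings on a regular grid with replicate scatter.

    OD(t) = OD0 * exp(true log-growth) with multiplicative log-normal
    noise; the returned table carries one row per (time, replicate) and the
    min/max replicate envelope per time point.
    """
    rng = config.rng("od")
    t_max = max(config.harvest_times_h.values())
    times = np.arange(0.0, t_max + config.od_timestep_h / 2,
                      config.od_timestep_h)
    od0 = 0.05
    rows = []
    for t in times:
        clean = od0 * math.exp(config.true_log_od(t))
        reps = clean * np.exp(rng.normal(0.0, config.od_sigma,
                                         config.replicates))
        for j, od in enumerate(reps, start=1):
            rows.append({"time_h": t, "replicate": j, "od600": od})
    df = pd.DataFrame(rows)
    env = df.groupby("time_h")["od600"].agg(["min", "max"]).rename(
        columns={"min": "od_min", "max": "od_max"})
    return df.merge(env, on="time_h")


def generate_qpcr_study(config: SyntheticStudyConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standard-curve and sample plates for RNAI and RNAII.

    Standards follow a 10-fold dilution series read through the true
    calibration line; sample CTs are implied by the true per-cell RNA
    counts and the cell count.  Gaussian CT noise throughout.
    """
    rng = config.rng("qpcr")
    line = config.true_line
    standards = []
    for target in ("RNAI", "RNAII"):
        for d in range(config.dilution_decades + 1):
            molecules = config.standard_top_molecules / 10 ** d
            for rep in range(1, config.replicates + 1):
                ct = line.ct_for(molecules) + rng.normal(0.0, config.ct_sigma)
                standards.append({"target": target, "dilution": d,
                                  "molecules": molecules, "replicate": rep,
                                  "ct": ct})
    samples = []
    for tp, rna in config.true_rna.items():
        for target, per_cell in rna.items():
            total = per_cell * config.cell_count
            for rep in range(1, config.replicates + 1):
                ct = line.ct_for(total) + rng.normal(0.0, config.ct_sigma)
                samples.append({"sample": f"{tp}_rep{rep}", "time_point": tp,
                                "target": target, "replicate": rep,
                                "ct": ct, "cell_count": config.cell_count})
    return pd.DataFrame(standards), pd.DataFrame(samples)


def generate_pcn_records(config: SyntheticStudyConfig) -> pd.DataFrame:
    """Plasmid-mass / cell-titer records consistent with the true PCN.

    The clean isolated mass is back-computed from the true copy number,
    plasmid size and cell count; log-normal mass noise (CV ``mass_cv``)
    and per-record purity ratios in (0.7, 1] are applied.
    """
    rng = config.rng("mass")
    sigma = math.sqrt(math.log(1.0 + config.mass_cv ** 2))
    rows = []
    for tp, pcn in config.true_pcn.items():
        for rep in range(1, config.replicates + 1):
            purity = rng.uniform(0.7, 1.0)
            clean_ng = (pcn * config.cell_count / AVOGADRO
                        * config.plasmid_size_bp * BASE_PAIR_MASS_G_PER_MOL
                        / purity * 1e9)
            mass = clean_ng * math.exp(rng.normal(-0.5 * sigma ** 2, sigma))
            rows.append({"time_point": tp, "replicate": rep,
                         "mass_ng": mass, "purity_ratio": purity,
                         "cell_count": config.cell_count,
                         "plasmid_size_bp": config.plasmid_size_bp})
    return pd.DataFrame(rows)


def write_study(config: SyntheticStudyConfig, outdir) -> dict:
    """Write od.csv, standards.csv, samples.csv, pcn.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    od = generate_od_series(config)
    standards, samples = generate_qpcr_study(config)
    pcn = generate_pcn_records(config)
    od.to_csv(outdir / "od.csv", index=False)
    standards.to_csv(outdir / "standards.csv", index=False)
    samples.to_csv(outdir / "samples.csv", index=False)
    pcn.to_csv(outdir / "pcn.csv", index=False)
    truth = {
        "seed": config.seed,
        "true_mu_poly": list(config.true_mu_poly),
        "harvest_times_h": config.harvest_times_h,
        "true_mu": {tp: config.true_mu(t)
                    for tp, t in config.harvest_times_h.items()},
        "true_pcn": config.true_pcn,
        "true_rna": config.true_rna,
        "calibration": {"slope": config.cal_slope,
                        "intercept": config.cal_intercept},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
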