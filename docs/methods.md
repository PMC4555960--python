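# Methods

## The model

The replication-control circuit is a deterministic, well-mixed mass-action
network of 15 species: free pDNA and five origin-engaged plasmid states
(short hybrid `pDNA·RNAII-s`, elongated hybrid `pDNA·RNAII-lo`, cleaved
primer `pDNA·RNAII-primer`, tRNA-shielded hybrid `pDNA·RNAII·tRNA`, and the
RNAI-bound kissing/stable complexes `pDNA·RNAII·RNAI-u`,
`pDNA·RNAII·RNAI-st`, plus the Rom-bound intermediate on the low-copy
plasmid), the free pools RNAI, RNAII, Rom and uncharged tRNA, the free
RNAI·RNAII duplex, the free RNAII·tRNA complex, and a bookkeeping counter
of completed replication events (`replicated_pDNA`, excluded from the
copy-number readout and from dilution).

Every reaction is elementary mass action with a single rate constant
k1…k26; the full mapping lives in `src/cole1sim/data/network.yaml` and is
deliberately data, not code, so it can be revised without touching the
solver.  The high-copy network is the low-copy network minus the five
Rom-dependent reactions (Rom binding/release/conversion, Rom
synthesis/degradation — the constants with no high-copy value) and minus
the two Rom-containing species.

Replication proceeds through

    pDNA  --k17-->  pDNA·RNAII-s  --k5-->  pDNA·RNAII-lo
          --k8-->  pDNA·RNAII-primer  --k7-->  2 pDNA

with three competing fates for the RNAI-sensitive short hybrid: abortive
turnover (k6), RNAI capture into the kissing complex (k3, reversible via
k4), and tRNA shielding (k14) into a state that matures to the primer
regardless of RNAI (k16).  Captured complexes either revert (k4), decay
abortively releasing the plasmid and an RNAI·RNAII duplex (k12), or mature
into the stable complex (k10, or via Rom: k1/k2/k13), which decays slowly
(k26) back to free pDNA plus duplex.  RNAI and Rom are transcribed from
free plasmid copies (k18, k20), uncharged tRNA is synthesized at a constant
rate (k24, the only zeroth-order constant) and removed by
degradation/recharging (k19); free RNAI, RNAII and the duplex degrade with
k22, k21 and k11; free RNAI and RNAII anneal in solution (k25), and the
RNAII·tRNA complex can hybridize with a plasmid origin (k9).

## Units and the cell-volume bridge

The solver works in mol/L and minutes; measurements are molecules per cell.
They are linked by a single-cell volume **V = 1·10⁻¹⁵ L** (typical
*E. coli*), exposed as `cole1sim.units.CELL_VOLUME_L` and accepted
explicitly by every conversion so analyses can record the value used.
Growth rates are h⁻¹ and divided by 60 inside the ODE.

## The growth-dilution term

The canonical single-equation form carries −(μ/60)[S] for every species
(`dilution="all"`), and that mode is what the dilution-limit analyses and
tests use.  The *study protocol*, however, follows one cell from birth to
just before its next division: the run starts from **half** the measured
pre-division copy number, so the halving at division already accounts for
the plasmid pool's dilution, and applying the continuous term to
plasmid-bearing species as well would count division twice.
`simulate_generation` therefore defaults to `dilution="plasmid_exempt"`
(diffusible species diluted, plasmid-bearing species not); with the full
term the measured behaviour of the high-copy strain — in particular the
near-linear production under the predictive scenarios — cannot be
reproduced.  Both modes are first-class arguments on `ReactionNetwork.rhs`
and the simulation entry points.

## Reconstructing the reaction ↔ constant mapping

The published constants come with units and provenance but not with an
explicit reaction list, so the assignment of k-indices to reactions had to
be reconstructed.  Several structural constraints pin it down surprisingly
tightly once the models are required to reproduce the measured behaviour of
*both* strains after calibrating only k3/k4/k26 at T2:

- **Transcription initiation must be slow (k17 = 0.25 min⁻¹).**  Every run
  starts with the entire plasmid pool free and the RNAI pool at its small
  measured value, far below the model's quasi-steady level.  A fast
  initiation constant floods the origin states before RNAI accumulates and
  produces a large replication burst in the first minutes; the reference
  trajectories are nearly linear in time (starvation production is almost
  exactly one tenth of the modified-tRNA production, as exact time-dilation
  of the rescaled mass-action system requires for linear trajectories), so
  such a burst cannot be present.  0.25 min⁻¹ — roughly one RNAII per
  plasmid every four minutes — is also the scale reported for RNAII
  initiation in vivo.
- **Elongation out of the RNAI-sensitive window is fast (k5 = 12 min⁻¹).**
  The tRNA shield competes with elongation for the short hybrid at rate
  k14·[tRNA]ss ≈ 4.1 min⁻¹ (with [tRNA]ss = k24/k19), so the
  modified-tRNA/normal production ratio is ≈ 1 + 4.1/k_elong; the observed
  ratio ≈ 1.5 requires k_elong ≈ 12.  The remaining 4.3-min⁻¹ constants
  become RNase H cleavage (k8) and abortive hybrid turnover (k6).
- **k19 is the tRNA-removal constant and k22 the RNAI-degradation
  constant.**  The table's own footnote derives k19 (with k24) from a
  polymerase transcription rate, tying it to the tRNA cycle; the 0.35-min⁻¹
  family (k21/k22/k26, ≈ 2-min RNA half-life) covers RNAII, RNAI and
  complex decay.  The tRNA steady pool k24/k19 this implies is what sets
  the shield strength above.
- **The fitted k26 is the stable-complex decay.**  Of the three calibrated
  constants it is the only one that controls how long a plasmid stays
  sequestered after RNAI capture; assigning it the inert duplex instead
  leaves the calibration one effective degree of freedom short.
- **RNAI/Rom transcription is first order in the free pDNA pool** (the
  plain mass-action reading of a plasmid-catalyzed synthesis).  A
  `gene_dosage` flag in the network table switches any synthesis to the
  summed concentration of all plasmid-bearing species instead; with the
  free-pool form the model's RNAI level stays closer to the measured scale
  and its equilibration transient is shorter.
- **k14 is applied as a second-order constant** (M⁻¹min⁻¹) although the
  source table prints first-order units for it: its own footnote equates
  its kinetics with the bimolecular RNAI·RNAII association, and 1.8·10⁵ is
  the literature value for tRNA–RNA association.  This is the only unit
  reinterpretation in the final mapping.

Alternatives that were implemented and rejected during model development:
RNAII supply limited per cell rather than per plasmid (cannot reach the
measured high-copy replication flux, and the T2 calibration rails k3 at its
bounds), transcription proportional to total plasmid dosage (overstates the
RNAI pool and lengthens the equilibration transient), and a fast initiation
constant (replication burst, see above).

## Calibration of k3, k4, k26

The objective is the squared difference between the simulated
end-of-generation copy number at T2 (under normal nutrients, see below)
and the measured T2 value — a single scalar residual for three constants,
so the problem is deliberately treated as under-determined: a bounded
(×/÷10 around the published values) Nelder–Mead search on log-parameters is
restarted from 16 log-normally perturbed starts (σ = 0.5, first start
unperturbed; fixed seed), the best near-optimal point is reported, and
`profile_objective` sweeps each constant across its full bounded range so
flat directions are visible instead of hidden.  In practice k3 is the
identifiable direction; the k26 profile is essentially flat.  T1 and T3 are
never fitted — they are the validation set.

## Simulation protocol and scenarios

Initial state: measured free RNAI and RNAII, pDNA at half the measured
copy number, every other pool zero.  μ is held constant at the
harvest-time value; the duration is the tabulated generation time of the
harvest point (150/138/147 min for the low-copy strain, 136/162/347 min for
the high-copy strain).  Note the tabulated 347 min at the last high-copy
point is used as printed even though ln 2/μ at μ = 0.090 h⁻¹ would give
≈ 462 min; the discrepancy is inherited from the source tables, not
resolved here.

Nutrient scenarios rescale constants multiplicatively:

| scenario        | k24 factor | global k factor | μ factor |
|-----------------|-----------:|----------------:|---------:|
| `normal`        |       0.01 |               1 |        1 |
| `starvation`    |          1 |             0.1 |      0.1 |
| `modified_trna` |          1 |               1 |        1 |

Under normal supply only ~1% of tRNA is uncharged, hence the 0.01 on the
tRNA synthesis constant; this factor is also applied in the calibration
and validation runs.  Starvation slows every reaction and growth tenfold
while uncharged tRNA is fully available.  The starvation run uses the
unscaled generation time (347 min) so all three scenarios are compared
over the same wall-clock window; a dilated duration ln 2/(0.1 μ) can be
passed explicitly instead.

## Numerical choices

LSODA with rtol 1·10⁻⁸ and atol 1·10⁻¹² M; trajectories are clipped at
zero only when written out, never inside the right-hand side; integration
aborts if any concentration undershoots beyond −10⁻⁸ of the state scale.
Tighter tolerances can be passed where analytic limits are being verified
(the dilution closed form holds to < 10⁻⁶ relative error at rtol 10⁻¹¹).
Copy numbers are rounded to integers for report tables only; CSVs keep the
raw floats.  Calibration and batch runs evaluate trajectories on coarse
output grids (8 points) since only the endpoint enters the objective; the
ODE systems themselves are 13–15 species and integrate in tens of
milliseconds.

## The synthetic-data generator

`cole1sim.synth` emulates the *structure* of the measured study: three
biological replicates at three exponential-phase harvest points; OD₆₀₀
readings from a polynomial log-growth truth with multiplicative log-normal
noise (σ = 0.02) and a min/max replicate envelope; qRT-PCR standards on a
10-fold dilution series (6–7 decades) read through a true calibration line
of slope −3.32 (≈100% PCR efficiency) with Gaussian CT noise (σ = 0.2);
sample CTs implied by the true per-cell RNA counts and a cell count chosen
so samples fall inside the calibrated range; and plasmid-mass records
back-computed from the true copy number with log-normal noise (CV = 0.3)
and purity ratios in (0.7, 1].  Default truths mirror the low-copy strain
(PCN ≈ 46–48, RNAI > RNAII at every point).  All randomness derives from
one mandatory seed via named, process-stable sub-streams.

What it does **not** emulate: amplification chemistry (CT values are exact
line reads plus noise — no efficiency drift, primer-dimer or plateau
effects), lag/stationary growth phases, densitometric gel analysis (purity
ratios are drawn, not imaged), or biological correlation between RNA and
PCN scatter.  Passing the closure tests therefore demonstrates that the
pipeline's arithmetic and calibration are consistent end to end, not that
it is robust to every real-data pathology.

## Known limitations

- The reaction ↔ constant mapping is a reconstruction constrained by the
  published constants, the described mechanism and the measured/simulated
  copy numbers; other assignments reproducing the same observables may
  exist.  The mapping is editable data (`network.yaml`) for exactly this
  reason.
- The model's internal free-RNAI pool at quasi-steady state exceeds the
  measured free-RNAI counts (tens of thousands versus hundreds per cell at
  high copy); only the copy-number observables are validated.
- Single-generation scope: one cell, constant μ, daughters not followed.
  Multi-generation simulation works mechanically (chain runs, halving the
  final state) but is unvalidated.
- The k3/k4/k26 calibration is intentionally under-determined; reported
  point estimates are representatives of a near-optimal set (see the
  profiles), not uniquely identified constants.
- No stochastic (SSA) or spatial effects; at ~46 plasmids per cell
  copy-number noise is not negligible in reality.
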