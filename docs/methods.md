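# Model and methods

## Overview

`blastosim` grows a mouse blastocyst in silico from a single cell using
four developmental rules on top of a soft-particle mechanics model. Cells
are unit circles (2D; unit spheres in the 3D validation mode); all lengths
are in cell radii. Gene expression is collapsed into four discrete states:
undetermined ICM (Nanog+Gata6 coexpressing), trophectoderm (TE), epiblast
(EPI, Nanog-high, FGF4-secreting), and primitive endoderm (PrE, Gata6-high,
weakly adhesive). A biological TE cell is represented by two circles
(TE cells are about twice the size of ICM cells), which also realizes the
reported 2x TE proliferation rate under uniform per-circle division.

## Mechanics

Pairs interact through

    V(d) = exp(-d) - S exp(-d / beta),    beta = 5,

repulsive below and attractive above the zero-force distance
d* = -ln(S/beta)/(1 - 1/beta) (2.65 for S = 0.6). The attraction factor S
encodes adhesion biology:

| pair | S | range |
|---|---|---|
| any pair before lineages exist | 0.6 | 5 radii, all pairs |
| TE-TE | polar factor, up to 1.4 | < 2.5 radii, true nearest neighbors |
| TE-ICM | 0.6 (0.4 if the ICM cell is PrE, from E3.5) | <= 5 radii, true nearest neighbors |
| ICM-ICM | 0.6 (0.4 for any pair involving PrE, from E3.5) | global (no cutoff) |

The TE-TE factor depends on the polarity unit vectors e1, e2 and the unit
separation u:

    S = -1.4 (e1 x u) . (e2 x (-u)) = 1.4 [e1.e2 - (e1.u)(e2.u)],

maximal (+1.4) for parallel polarities perpendicular to the separation (the
tight-junction sheet configuration), zero when a polarity lies along the
separation, negative for antiparallel polarities. Because S depends on the
separation *direction*, the exact force on a TE pair carries a tangential
component; `total_force` returns the full gradient of the energy, verified
against central differences to 1e-6. The tangential term matters: it is
what keeps the TE a single-file sheet; dropping it (the quasi-static
central-force approximation, available as `polar_tangential_force=False`)
lets TE cells stack into multi-row rafts and no cavity forms.

Motion is overdamped Euler: per step, `x += dt * F + xi` with additive
Gaussian noise of sd 1e-3 per coordinate, and TE polarity angles follow
`alpha += dt * 0.1 * sum_j sin(alpha_j - alpha_i) + xi_p` (noise sd
pi * 1e-3) over in-range TE pairs — damped alignment of the tight-junction
axes. In 3D the alignment generalizes to the tangent-projected update
`e_i += dt * 0.1 * sum_j (e_j - (e_i.e_j) e_i)` with renormalization.

### Nearest-neighbor interaction filtering

Pairs involving a TE cell interact only when they are *true nearest
neighbors*: the halfway point of the segment must not be strictly closer to
any third cell (the same construction the 3D mode uses to separate nearest
from next-nearest neighbors; ties are kept). This is essential, not
cosmetic. If every pair within the 5-radius range interacted, the summed
attraction of all ICM cells in range would pull the TE shell onto the ICM
with a net force two orders of magnitude above the noise; the shell jams
against the ICM, tears, and unrolls into a flat sheet in essentially every
replicate. With the filter, a TE cell feels only its contact layer, the
shell floats at the pair equilibrium, and proliferation-driven expansion
opens the cavity. The pre-polarity morula, by contrast, uses the plain
5-radius truncation for all pairs: the long-range attraction compacts it
into a round disc, which is exactly what the surface rule needs (below).
Specified ICM cells attract globally (protrusion-mediated contact), which
keeps the ICM a single cluster on one side of the cavity and lets PrE
progenitors sort outward. All three range conventions are configurable
(`morula_interaction`, `icm_interaction`, `te_icm_filtered`).

## The clock and the schedule

Growth is exponential with unit division rate per circle. To the 16-cell
stage, cleavage divisions run as synchronous rounds, each advancing the
clock by ln 2 (so the 16-cell stage is t = ln 16 = "E3.0"). Afterwards a
random circle divides per event and the clock advances by 1/N (the expected
waiting time). The daughter is inserted at the midpoint between mother and
nearest neighbor (center of the 3 nearest neighbors in 3D) with a small
jitter, inheriting the mother's fate (and, for TE, polarity); the system
then relaxes toward mechanical equilibrium before the next event.

The rules are scheduled as follows:

- **Rule 1** fires when the biological count first reaches 16 (for
  unperturbed embryos, exactly E3.0). Surface cells — fewer than 5 nearest
  neighbors on the true-nearest-neighbor graph — become TE with radially
  outward polarity and are expanded to two circles placed +-0.8 radii along
  the local tangent; inner cells become undetermined ICM.
- **Rules 2-4** run at *absolute* times: FGF/ERK competence spans
  [E3.0, E4.0] (fate draws at ICM divisions; fates freeze afterwards),
  differential adhesion switches on at E3.5, and apoptosis plus endpoint
  classification happen at E4.5. One stage unit (the simulated E3.0->E3.5
  interval) is 0.715 clock units, calibrated once so the unperturbed
  ensemble ends near 132 biological cells (ln(132/16)/3 plus a small
  finite-population correction).

This split — polarity by cell count, signaling by absolute time — is what
produces scaling: halving an embryo at the 2-, 4-, or 8-cell stage delays
the 16-cell stage by exactly one cleavage round, so the embryo ends one
doubling smaller (~66 cells) with unchanged proportions, while aggregates
of two embryos reach 16 cells a round early and end at ~264. In the
clamped FGF modes (depletion/excess) the clamp also converts cells still
undetermined when the window closes, since a clamped extracellular signal
acts on non-dividing cells too.

## Endpoint classification

A snapshot is classified by, in order: ICM composition (no PrE -> EPI-only;
no EPI/undetermined -> PrE-only), shell and cavity geometry, deep PrE, and
the PrE seal. The shell test rasterizes the plane at 0.5 radii, draws discs
of radius 1.25 (half the TE contact distance) around TE circles, and
flood-fills from outside: the shell is intact iff no ICM cell is reachable
from the outside. The cavity is the interior point with the largest
clearance from any cell center; it must admit an empty disc of three cell
areas (clearance >= 1 + sqrt 3) and lie >= 2 radii from the ICM centroid
(one-sidedness). A PrE cell with more than 3 non-PrE ICM neighbors is
"deep" (the apoptosis criterion; TE neighbors do not count); any deep PrE
at the endpoint is a PrE-in-EPI error. Every EPI (or undetermined) cell
must be screened from the cavity: the segment from the cell to the cavity
center must pass within 1 radius of a PrE cell; otherwise the replicate is
an EPI-in-PrE error. Double PrE layers count as success as long as they
seal. Failing shell/cavity/one-sidedness is reported as NO_TE (no
blastocyst formed). Undetermined cells remaining at E4.5 are counted with
the EPI (they are Nanog-coexpressing). Thresholds are declared conventions;
the classifier is deterministic and invariant under rigid motions up to
grid resolution.

## The lattice model

Rule 2 alone, on a fixed periodic grid of ICM cells (no division, no
mechanics): asynchronous single-site updates set a site to PrE with
probability equal to the high-FGF4 fraction of its 8-neighborhood (Moore;
von Neumann available). Local amplification with neighbor-mediated
inhibition drives the PrE/ICM ratio to 1/2 independent of lattice size —
the proportioning mechanism of the full model in isolation.

## Parameters

| name | default | meaning |
|---|---|---|
| `S_default` / `S_pre` / `S_neutral_adhesion` | 0.6 / 0.4 / 0.5 | attraction factors (dimensionless) |
| `beta` | 5 | attraction range of V (radii) |
| `polar_prefactor` | 1.4 | TE-TE polar attraction scale |
| `global_cutoff`, `te_icm_cutoff` | 5 | interaction truncation (radii) |
| `te_te_cutoff` | 2.5 | TE-TE contact range (radii) |
| `dt` | 0.1 | Euler step |
| `relax_steps` / `relax_tol` | 200 / 1e-3 | relaxation cap per event; early stop when max dt*F falls below tol |
| `noise_sd_position` / `noise_sd_angle` | 1e-3 / pi*1e-3 | additive noise per step |
| `polarity_mobility` | 0.1 | polarity slower than positions |
| `stage_unit` | 0.715 | E3.0->E3.5 on the division clock (calibrated once to the ~132-cell endpoint) |
| `fgf_undetermined_weight` | 1.0 | 0.5 in the half-FGF4-from-undetermined variant |
| `epi_apoptosis_fraction` | 0.0 | 0.2 in the EPI-apoptosis variant |

The noise level is the model's stability edge: with the polar prefactor
raised from 1.4 to 1.5 the TE over-repels when new cells are inserted, and
below ~1.3 the shell cannot hold together — the regression scenario is
reproducible by setting `polar_prefactor` accordingly.

## Problem sizes and runtime

Desk-scale ensembles use 50 replicates per condition (between one and four
minutes per condition on one CPU; a wild-type replicate grows ~220
division events to ~200 circles). The published experiments used 200
replicates; `n_replicates` scales freely. The doublet-aggregation check
runs 8-12 replicates (embryos are twice the size and ~7x the cost) and the
FGF-delay comparison 30-50; the lattice model runs 1e5 updates in seconds.
Replicates are seeded independently from a master seed (numpy
`SeedSequence`), so ensembles are reproducible bit-for-bit and independent
of execution order.

## What the model does and does not capture

The generator *is* the study system here — there is no external data. The
simulations reproduce: the blastocyst topology (TE shell, cavity, one-sided
ICM, PrE between EPI and cavity), ~79-90% wild-type success, lineage
proportions (ICM/total ~0.39, EPI/ICM ~0.44-0.50 with the large
replicate-to-replicate spread that uniform stochastic division implies),
exact 1/2x and 2x size scaling under halving/aggregation with preserved
proportions, single-lineage ICMs under FGF clamping, unsorted
salt-and-pepper endpoints under neutralized adhesion, and size-independent
PrE/ICM proportioning on the lattice. Known limitations:

- No osmotic cavity mechanics: the cavity is purely an emergent cell-free
  region; shell expansion is proliferation-driven.
- PrE apico-basal polarity is not modeled, so PrE cells cluster more than
  observed under FGF excess, and the sorted PrE typically *envelops* the
  EPI (a two-layer seal) rather than forming a single cavity-facing layer.
  A consequence is that this implementation almost never leaves a PrE cell
  trapped deep in the EPI core at the endpoint: the mispositioned-PrE
  incidence (and hence the apoptosis load and the success-rate deficit it
  causes elsewhere) is near zero here, lower than reported equilibrium
  values for this class of model, and the halved-embryo success rate is
  correspondingly higher (~0.8 vs ~0.6).
- Fates are discrete; Nanog/Gata6 levels and FGF4 diffusion are collapsed
  into the neighbor-counting rule.
- The 2D classifier's geometric thresholds are conventions; the 3D mode is
  validated qualitatively (shell connectivity, enclosure, cavity size)
  rather than classified into the five error types.
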