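# blastosim

Rule-based, off-lattice simulation of mouse preimplantation development.

Early mouse embryos build a blastocyst — an outer trophectoderm (TE) shell
around a fluid-filled cavity, with the inner cell mass (ICM) clustered to
one side and split into epiblast (EPI) and primitive endoderm (PrE) — with
remarkable robustness: embryos halved or aggregated before compaction still
produce correctly proportioned blastocysts. `blastosim` asks how much of
this self-organization follows from four cell-level rules acting on soft,
physically interacting cells:

1. **Develop polarity, if surface cell.** At the 16-cell stage, cells with
   fewer than 5 nearest neighbors become TE, with polarity pointing
   radially outward. Each TE cell is represented by two unit circles and
   divides at twice the ICM rate.
2. **Switch fate, if surrounded by too many cells of the same type.** From
   E3.0 to E4.0, at every ICM division mother and daughter convert to PrE
   with probability `P(PrE) = (# high-FGF4 neighbors) / (# ICM neighbors)`
   (EPI and undetermined cells count as high FGF4), else to EPI — a
   discrete Turing-like lateral-inhibition mechanism.
3. **Less adhesion, if PrE progenitor.** From E3.5, the attraction factor of
   every pair involving a PrE cell drops from `S = 0.6` to `S = 0.4`
   (differential adhesion drives sorting).
4. **Die, if in a wrong position.** At E4.5, PrE cells surrounded by more
   than 3 non-PrE ICM cells undergo apoptosis.

Cells are unit circles (spheres in the 3D validation mode) moving by
overdamped dynamics `dx/dt = -dV/dx + eta` under the pair potential

```
V(d) = exp(-d) - S exp(-d / beta),          beta = 5
S    = -1.4 (e1 x r12) . (e2 x r21)         for TE-TE pairs,
```

where `e1, e2` are the TE polarity unit vectors and `r12` the unit
separation; polarity angles follow damped alignment dynamics
`dalpha/dt = -0.1 dV_p/dalpha + eta_p` with `V_p = -cos(alpha_i - alpha_j)`.
Interactions of TE cells are restricted to true nearest neighbors
(halfway-point criterion); specified ICM cells attract each other globally.
Growth is by cell division (synchronous cleavage rounds to the 16-cell
stage, then random single divisions with relaxation to mechanical
equilibrium in between). Each endpoint is classified as a successful
blastocyst or one of five error types (no TE shell, EPI-only, PrE-only,
EPI stuck in the PrE layer, PrE buried in the EPI core), and the package
scripts every published perturbation: rule deletions, FGF4
depletion/excess/delay, embryo halving, and aggregation of 2-3 embryos.

## Worked example

```python
from blastosim import make_spec, run_ensemble

spec = make_spec("wild_type", n_replicates=50, seed=11)
stats = run_ensemble(spec)["stats"]
print(f"success      {stats['frac_success']:.2f}")
print(f"cells        {stats['mean_total_cells']:.1f} +- {stats['sd_total_cells']:.1f}")
print(f"ICM/total    {stats['mean_icm_total']:.2f} +- {stats['sd_icm_total']:.2f}")
print(f"EPI/ICM      {stats['mean_epi_icm']:.2f} +- {stats['sd_epi_icm']:.2f}")
```

prints (seed 11):

```
success      0.88
cells        132.9 +- 8.1
ICM/total    0.40 +- 0.10
EPI/ICM      0.48 +- 0.11
```

i.e. ~88% of replicates end as a correctly organized blastocyst of ~133
cells, with ~38% of cells in the ICM of which about half are epiblast —
and the rest fail, mostly because the TE shell breaks or the PrE layer
does not seal the epiblast from the cavity. The same interface runs every
perturbation (`make_spec("drule3")`, `make_spec("halve")`,
`make_spec("aggregate2")`, ...), and halved embryos come out at ~66 cells
with unchanged proportions because the FGF/ERK competence window is fixed
in absolute time while growth is exponential.

The same functionality is available from a shell:

```bash
blastosim run --experiment wild_type --n 50 --seed 11 --out out/
blastosim turing --size 10 --updates 100000 --seed 1
blastosim render out/traj --out frames/
```

## Layout

- `blastosim.state` / `blastosim.params` — cells, embryos, outcomes, model
  constants, stage schedule, rule switches
- `blastosim.potentials` / `blastosim._kernels` / `blastosim.dynamics` —
  pair interactions (exact gradients) and the overdamped integrator
- `blastosim.neighbors` — contact graphs and the halfway-point true
  nearest-neighbor algorithm
- `blastosim.lifecycle` — the four rules and cell division
- `blastosim.classifier` — endpoint classification and 2D<->3D count scaling
- `blastosim.experiments` — growth engine, perturbations, ensembles
- `blastosim.turing` — the lateral-inhibition lattice model
- `blastosim.io` / `blastosim.cli` — trajectories, manifests, rendering,
  3D validation, command line

See `docs/methods.md` for the model description, parameter table, and the
design choices behind the implementation.
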