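"""Scripted in-silico experiments: wild type, rule deletions, FGF modulation
and delay, embryo halving, aggregation, and batch ensembles.

Growth proceeds in two phases.  Up to the 16-cell stage the cleavage
divisions are synchronous rounds, each advancing the clock by ln 2 (so the
population grows as e^t with every cell dividing at unit rate, and the
16-cell stage falls at t = ln 16 = E3.0 for unperturbed embryos).  Once the
biological count reaches 16 the polarity rule fires and growth switches to
sequential random single divisions: one circle is picked uniformly at random
and the clock advances by 1/N per event (the expected waiting time at unit
per-circle rate).  Uniform circle selection makes a biological TE cell - two
circles - divide at twice the ICM rate.  Rules 2-4 fire at absolute times
E3.0/E3.5/E4.5, which is what makes halved and aggregated embryos scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .classifier import classify, ensemble_stats
from .dynamics import IntegratorState, NumericalInstabilityError, relax
from .lifecycle import (apply_rule1_polarity, apply_rule2_fate,
                        apply_rule3_adhesion, apply_rule4_apoptosis,
                        deep_pre_indices, divide_cell, select_divider)
from .neighbors import NeighborGraph
from .params import ModelParams, RuleConfig, StageSchedule
from .potentials import OverlapError
from .state import Embryo, Lineage, Outcome

__all__ = ["ExperimentSpec", "run_replicate", "run_ensemble", "run_wild_type",
           "halve_embryo", "aggregate_embryos", "run_condition_suite",
           "EXPERIMENTS", "make_spec"]

LN2 = math.log(2.0)
_ICM_LINEAGES = (int(Lineage.UNDETERMINED_ICM), int(Lineage.EPI), int(Lineage.PRE))


@dataclass
class ExperimentSpec:
    """One named experimental condition."""

    name: str = "wild_type"
    rule_config: RuleConfig = field(default_factory=RuleConfig)
    manipulation: tuple | None = None  # ("halve", stage) | ("aggregate", k, stage)
    n_replicates: int = 200
    seed: int = 0
    params: ModelParams = field(default_factory=ModelParams)
    schedule: StageSchedule | None = None
    spatial_bisection: bool = False  # halving: split by position, not at random

    def __post_init__(self) -> None:
        if self.schedule is None:
            self.schedule = StageSchedule(stage_unit=self.params.stage_unit)
        if self.rule_config.rule2_mode == "delayed" and self.schedule.fgf_delay == 0:
            # 24-hour signalling block: competence opens at E3.5 instead of E3.0
            self.schedule = replace(self.schedule,
                                    fgf_delay=self.schedule.stage_unit)
        if self.manipulation is not None:
            stage = self.manipulation[-1]
            if stage not in (2, 4, 8):
                raise ValueError("manipulation stage must be 2, 4 or 8 cells")
        self.schedule.validate()


def halve_embryo(embryo: Embryo, spatial: bool = False) -> Embryo:
    """Remove half the cells (floor half retained for odd counts).

    By default the removed half is random; with ``spatial`` the embryo is
    bisected by position along a random axis.  Stage triggers are left
    untouched, mimicking blastomere-removal experiments.
    """
    n = embryo.n
    keep = n - n // 2 if n % 2 else n // 2
    if spatial:
        axis = embryo.rng.normal(size=embryo.dim)
        proj = embryo.positions @ axis
        order = np.argsort(proj)
        drop = order[keep:]
    else:
        drop = embryo.rng.choice(n, size=n - keep, replace=False)
    embryo.remove_cells(drop)
    return embryo


def aggregate_embryos(embryos: list[Embryo], gap: float = 1.0) -> Embryo:
    """Merge 2 or 3 same-stage embryos into one (pre-compaction aggregate).

    Centroids are placed one embryo diameter apart (in a line for two, on a
    triangle for three); the merged embryo keeps the first embryo's clock,
    parameters, and RNG.
    """
    if not 2 <= len(embryos) <= 3:
        raise ValueError("can aggregate 2 or 3 embryos")
    t0 = embryos[0].t
    if any(abs(e.t - t0) > 1e-9 or e.n != embryos[0].n for e in embryos):
        raise ValueError("embryos must be at the same stage")
    radii = [np.linalg.norm(e.positions - e.positions.mean(axis=0),
                            axis=1).max() + 1.0 for e in embryos]
    k = len(embryos)
    merged = embryos[0]
    if k == 2:
        offsets = [np.zeros(merged.dim)]
        off = np.zeros(merged.dim)
        off[0] = radii[0] + radii[1] + gap
        offsets.append(off)
    else:
        side = max(radii[i] + radii[j] + gap
                   for i in range(k) for j in range(i + 1, k))
        tri = np.array([[0.0, 0.0], [side, 0.0], [side / 2, side * math.sqrt(3) / 2]])
        offsets = [np.zeros(merged.dim) for _ in range(k)]
        for i in range(k):
            offsets[i][:2] = tri[i]
    for e, off in zip(embryos, offsets):
        center = e.positions.mean(axis=0)
        if e is merged:
            merged.pos[:merged.n] += off - center
        else:
            for i in range(e.n):
                merged.add_cell(e.pos[i] + off - center, Lineage(int(e.lin[i])),
                                polarity=e.pol[i], pair_id=int(e.pair[i]))
    return merged


def _mother_graph(embryo: Embryo, mother: int) -> NeighborGraph:
    """Rule-2 neighborhood of the dividing cell (pre-division)."""
    from .neighbors import rule_neighbor_graph

    return rule_neighbor_graph(embryo)


def _cleavage_round(embryo: Embryo, integrator: IntegratorState) -> None:
    """One synchronous round: every cell divides once, relaxing in between."""
    order = embryo.rng.permutation(embryo.n)
    for i in order:
        divide_cell(embryo, int(i))
        relax(embryo, integrator=integrator)
    embryo.t += LN2


def _grow_rounds_to(embryo: Embryo, count: int,
                    integrator: IntegratorState) -> None:
    while embryo.n < count:
        _cleavage_round(embryo, integrator)


def run_replicate(spec: ExperimentSpec, seed, record=None,
                  dim: int = 2) -> Outcome:
    """Run one replicate from a single cell to the E4.5 endpoint.

    ``record``, if given, is called with the embryo after every event (for
    trajectory capture).  Returns the classified :class:`Outcome` (in 3D a
    qualitative shell/cavity assessment stands in for the 2D classifier).
    """
    params = spec.params
    rc = spec.rule_config
    sched = spec.schedule
    rng = np.random.default_rng(seed)
    integrator = IntegratorState.from_params(params, rng=rng)

    def new_embryo(r):
        e = Embryo(params, dim=dim, rng=r)
        e.add_cell(np.zeros(dim), Lineage.UNDETERMINED_ICM)
        return e

    embryo = new_embryo(rng)

    # --- cleavage phase (synchronous rounds) -----------------------------
    if spec.manipulation and spec.manipulation[0] == "aggregate":
        _, k, stage = spec.manipulation
        others = [new_embryo(rng) for _ in range(k - 1)]
        _grow_rounds_to(embryo, stage, integrator)
        for o in others:
            o.t = 0.0
            _grow_rounds_to(o, stage, integrator)
        embryo = aggregate_embryos([embryo] + others)
        relax(embryo, n_steps=5 * params.relax_steps, integrator=integrator)
    elif spec.manipulation and spec.manipulation[0] == "halve":
        stage = spec.manipulation[1]
        _grow_rounds_to(embryo, stage, integrator)
        halve_embryo(embryo, spatial=spec.spatial_bisection)
        relax(embryo, integrator=integrator)

    _grow_rounds_to(embryo, sched.rule1_cell_count, integrator)

    # --- polarity (Rule 1) ------------------------------------------------
    if rc.rule1_enabled:
        apply_rule1_polarity(embryo)
        relax(embryo, n_steps=5 * params.relax_steps, integrator=integrator)
    embryo.rule1_done = True
    if record is not None:
        record(embryo)

    # --- sequential growth to the endpoint -------------------------------
    t_end = sched.t_e45
    rule2_start = sched.rule2_start
    rule2_closed = False

    def close_rule2_window():
        # clamped FGF levels act on every ICM cell, not only dividing ones:
        # when competence ends, cells still undetermined follow the clamp
        target = {"no_fgf": Lineage.EPI, "excess_fgf": Lineage.PRE}.get(rc.rule2_mode)
        if target is not None:
            for idx in np.flatnonzero(
                    embryo.lineages == int(Lineage.UNDETERMINED_ICM)):
                embryo.set_lineage(int(idx), target)

    while True:
        n = embryo.n
        dt_event = 1.0 / n
        if embryo.t + dt_event > t_end:
            break
        embryo.t += dt_event
        if not embryo.rule3_active and embryo.t >= sched.t_e35:
            apply_rule3_adhesion(embryo, rc)
        if not rule2_closed and embryo.t > sched.rule2_end:
            close_rule2_window()
            rule2_closed = True
        mother = select_divider(embryo)
        rule2_applies = (rc.rule2_mode not in ("off",)
                         and int(embryo.lin[mother]) in _ICM_LINEAGES
                         and rule2_start <= embryo.t <= sched.rule2_end)
        graph = _mother_graph(embryo, mother) if rule2_applies else None
        daughter = divide_cell(embryo, mother)
        if rule2_applies:
            apply_rule2_fate(embryo, mother, daughter, rc, graph=graph)
        relax(embryo, integrator=integrator)
        if record is not None:
            record(embryo)

    # --- endpoint: apoptosis and classification --------------------------
    if not rule2_closed:
        close_rule2_window()
    deep_before = len(deep_pre_indices(embryo)) > 0
    if rc.rule4_enabled:
        apply_rule4_apoptosis(embryo, rc)
        relax(embryo, integrator=integrator)
    if record is not None:
        record(embryo)
    if dim == 3:
        from .io import shell_diagnostics_3d
        from .state import OutcomeCategory, biological_counts

        diag = shell_diagnostics_3d(embryo)
        counts, fractions = biological_counts(embryo)
        ok = diag["shell_intact"] and diag["cavity_clearance"] > 1.5
        outcome = Outcome(
            category=OutcomeCategory.SUCCESS if ok else OutcomeCategory.NO_TE,
            counts=counts, fractions=fractions,
            apoptosis_count=embryo.apoptosis_count)
    else:
        outcome = classify(embryo)
    outcome.deep_pre_before_apoptosis = deep_before
    return outcome


def run_ensemble(spec: ExperimentSpec, progress: bool = False) -> dict:
    """Run ``spec.n_replicates`` independent replicates and summarize.

    Replicates use seeds spawned from the master seed and are independent,
    so the summary does not depend on execution order.  Integrator failures
    are recorded per replicate, not fatal to the ensemble.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    outcomes: list[Outcome | None] = []
    failures = 0
    for i, child in enumerate(children):
        try:
            outcomes.append(run_replicate(spec, child))
        except (NumericalInstabilityError, OverlapError):
            outcomes.append(None)
            failures += 1
        if progress and (i + 1) % 10 == 0:
            print(f"  {spec.name}: {i + 1}/{spec.n_replicates}", flush=True)
    stats = ensemble_stats([o for o in outcomes if o is not None])
    stats["numerical_failures"] = failures
    stats["condition"] = spec.name
    return {"spec": spec, "outcomes": outcomes, "stats": stats}


def run_wild_type(spec: ExperimentSpec | None = None, **kw) -> dict:
    if spec is None:
        spec = make_spec("wild_type", **kw)
    return run_ensemble(spec)


def run_condition_suite(specs: list[ExperimentSpec], progress: bool = False):
    """Run several conditions and tabulate the category fractions."""
    import pandas as pd

    if not specs:
        raise ValueError("need at least one condition")
    rows = []
    results = {}
    for spec in specs:
        res = run_ensemble(spec, progress=progress)
        results[spec.name] = res
        rows.append(res["stats"])
    table = pd.DataFrame(rows).set_index("condition")
    return table, results


#: Named experiment registry (Fig 3b/4/5 conditions and published variants).
EXPERIMENTS: dict[str, dict] = {
    "wild_type": {},
    "drule1": {"rule_config": dict(rule1_enabled=False)},
    "drule2_low": {"rule_config": dict(rule2_mode="no_fgf")},
    "drule2_high": {"rule_config": dict(rule2_mode="excess_fgf")},
    "drule2_delay": {"rule_config": dict(rule2_mode="delayed")},
    "drule3": {"rule_config": dict(rule3_mode="neutralized")},
    "drule4": {"rule_config": dict(rule4_enabled=False)},
    "halve": {"manipulation": ("halve", 8)},
    "halve2": {"manipulation": ("halve", 2)},
    "halve4": {"manipulation": ("halve", 4)},
    "aggregate2": {"manipulation": ("aggregate", 2, 8)},
    "aggregate3": {"manipulation": ("aggregate", 3, 8)},
    "epi_apoptosis": {"rule_config": dict(epi_apoptosis_fraction=0.2)},
    "half_fgf_undetermined": {"rule_config": dict(fgf_undetermined_weight=0.5)},
    "halve_drule4": {"manipulation": ("halve", 8),
                     "rule_config": dict(rule4_enabled=False)},
}


def make_spec(name: str, n_replicates: int = 200, seed: int = 0,
              params: ModelParams | None = None) -> ExperimentSpec:
    """Build the :class:`ExperimentSpec` for a named condition."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; "
                       f"choose from {sorted(EXPERIMENTS)}")
    entry = EXPERIMENTS[name]
    rc_kw = dict(entry.get("rule_config", {}))
    params = params if params is not None else ModelParams()
    rc = RuleConfig(**rc_kw)
    if rc.epi_apoptosis_fraction == 0.0:
        rc.epi_apoptosis_fraction = params.epi_apoptosis_fraction
    if rc.fgf_undetermined_weight == 1.0:
        rc.fgf_undetermined_weight = params.fgf_undetermined_weight
    return ExperimentSpec(name=name, rule_config=rc,
                          manipulation=entry.get("manipulation"),
                          n_replicates=n_replicates, seed=seed, params=params)
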