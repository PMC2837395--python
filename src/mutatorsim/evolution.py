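"""Population dynamics: chemostat growth, stress protocols, and controls.

Discrete-time agent-based dynamics.  Per time step, every cell (in order):
expression-level fluctuation, death with probability d, division with
probability b (the mother is replaced by two independently mutated
daughters; lethal daughters are discarded).  When the population exceeds
the carrying capacity, excess organisms are culled uniformly at random —
a chemostat regime in which faster growth buys faster random drift.

Stress protocols change exactly one global parameter at t_apply:
heat shock raises T, stationary phase drops the base growth rate
threefold, starvation drops the optimal production level tenfold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cell as cm
from .cell import Cell, CellEnv, FitnessParams, Genome, is_mutator

__all__ = [
    "StressProtocol",
    "StressError",
    "ExtinctionError",
    "Population",
    "Trajectory",
    "apply_stress",
    "run_evolution",
    "run_competition",
    "run_constant_fitness",
]

EVENT_COLUMNS = [
    "t", "kind", "gene", "lineage_id", "mutator_before", "mutator_after", "detail",
]

SERIES_COLUMNS = [
    "t", "N", "mean_b", "mean_m", "mutator_freq",
    "mean_C1", "mean_C2", "mean_C3", "mean_C4",
    "mean_pnat1", "mean_pnat2", "mean_pnat3", "mean_pnat4",
    "mean_pint23", "mean_pint44",
]


class StressError(ValueError):
    """Unknown stress kind, or a protocol applied twice."""


class ExtinctionError(RuntimeError):
    """The population died out (reported in run metadata, not raised by runs)."""


@dataclass(frozen=True)
class StressProtocol:
    kind: str  # heat_shock | stationary_phase | starvation
    t_apply: int = 20_000
    heat_T: float = 1.00
    b0_factor: float = 1.0 / 3.0
    C0_factor: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("heat_shock", "stationary_phase", "starvation"):
            raise StressError(f"unknown stress kind {self.kind!r}")


def apply_stress(params: FitnessParams, protocol: StressProtocol) -> FitnessParams:
    """Return parameters with exactly one stress change applied."""
    if getattr(params, "_stressed", False):
        raise StressError("stress protocol already applied")
    if protocol.kind == "heat_shock":
        new = dataclasses.replace(params, T=protocol.heat_T)
    elif protocol.kind == "stationary_phase":
        new = dataclasses.replace(params, b0=params.b0 * protocol.b0_factor)
    else:  # starvation
        new = dataclasses.replace(params, C0=params.C0 * protocol.C0_factor)
    object.__setattr__(new, "_stressed", True)
    return new


@dataclass
class Trajectory:
    """Time series of population summaries plus the event log."""

    series: pd.DataFrame
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)


class Population:
    """A finite population of cells under chemostat dynamics."""

    def __init__(
        self,
        cells: list[Cell],
        params: FitnessParams,
        env: CellEnv,
        cap: int = 5000,
        rng: np.random.Generator | None = None,
        record_every: int = 25,
    ):
        self.cells = cells
        self.params = params
        self.env = env
        self.cap = int(cap)
        self.rng = rng if rng is not None else np.random.default_rng()
        self.t = 0
        self.record_every = int(record_every)
        self._events: list[tuple] = []
        self._series: list[tuple] = []
        self._id = max((c.lineage_id for c in cells), default=0)
        self.record()

    # -- bookkeeping -------------------------------------------------------

    def next_id(self) -> int:
        self._id += 1
        return self._id

    def log(self, kind: str, gene: int = -1, lineage_id: int = -1,
            before: bool | None = None, after: bool | None = None,
            detail: str = "") -> None:
        self._events.append((self.t, kind, gene, lineage_id, before, after, detail))

    @property
    def size(self) -> int:
        return len(self.cells)

    def mutator_frequency(self) -> float:
        if not self.cells:
            raise ExtinctionError("empty population has no mutator frequency")
        thr = self.params.mutator_threshold
        return sum(c.m > thr for c in self.cells) / len(self.cells)

    def record(self) -> None:
        cells = self.cells
        n = len(cells)
        if n == 0:
            self._series.append((self.t, 0) + (np.nan,) * (len(SERIES_COLUMNS) - 2))
            return
        thr = self.params.mutator_threshold
        mean = lambda xs: float(np.mean(xs))
        row = (
            self.t, n,
            mean([c.b for c in cells]),
            mean([c.m for c in cells]),
            sum(c.m > thr for c in cells) / n,
            *(mean([c.C[i] for c in cells]) for i in range(4)),
            *(mean([c.proteins[i].p_nat for c in cells]) for i in range(4)),
            mean([c.itab.p_int[1, 2] for c in cells]),
            mean([c.itab.p_int[3, 3] for c in cells]),
        )
        self._series.append(row)

    # -- dynamics ----------------------------------------------------------

    def step(self) -> None:
        """One time step: fluctuate → die → divide → cull.

        Random draws are batched per step (one array per decision kind)
        rather than per cell; the per-cell operations are identical to the
        single-cell primitives in :mod:`mutatorsim.cell`.
        """
        if not self.cells:
            raise ExtinctionError("cannot step an extinct population")
        params, env, rng = self.params, self.env, self.rng
        cells = self.cells
        n = len(cells)

        # 1. epigenetic expression fluctuations
        if params.r > 0 or any(c.r_override for c in cells):
            r_arr = np.array(
                [params.r if c.r_override is None else c.r_override for c in cells]
            )
            hits = rng.random((n, cm.N_GENES)) < r_arr[:, None]
            if hits.any():
                cells = list(cells)
                for i in np.flatnonzero(hits.any(axis=1)):
                    c = cells[i]
                    c2, changes = cm.apply_fluctuations(c, hits[i], params, rng)
                    before, after = is_mutator(c, params), is_mutator(c2, params)
                    for gene, _old, _new in changes:
                        self.log("SS", gene, c.lineage_id, before, after)
                    cells[i] = c2
            self.cells = cells

        # 2. deaths
        u = rng.random(n)
        survivors = [c for c, ui in zip(self.cells, u) if ui >= params.d]

        # 3. divisions: mothers replaced by two independently mutated daughters
        u = rng.random(len(survivors))
        b_arr = np.array([c.b for c in survivors])
        divide = u < b_arr
        next_gen: list[Cell] = [c for c, dv in zip(survivors, divide) if not dv]
        mothers = [c for c, dv in zip(survivors, divide) if dv]
        if mothers:
            m_arr = np.array([c.m for c in mothers])
            counts = rng.poisson(np.repeat(m_arr, 2 * cm.N_GENES)).reshape(
                len(mothers), 2, cm.N_GENES
            )
            for k, c in enumerate(mothers):
                for half in range(2):
                    d, events = cm.make_daughter(
                        c, counts[k, half], env, params, rng, self.next_id
                    )
                    if d is not None:
                        next_gen.append(d)
                    for ev in events:
                        self.log(ev["kind"], ev["gene"], ev["lineage_id"],
                                 ev.get("mutator_before"), ev.get("mutator_after"),
                                 ev["detail"])

        # 4. chemostat culling
        if len(next_gen) > self.cap:
            keep = self.rng.choice(len(next_gen), size=self.cap, replace=False)
            keep.sort()
            next_gen = [next_gen[i] for i in keep]
        self.cells = next_gen

        self.t += 1
        if self.t % self.record_every == 0:
            self.record()

    def apply_protocol(self, protocol: StressProtocol) -> None:
        """Apply the stress at the current step and refresh every phenotype.

        Cells whose mutator status flips purely because of the parameter
        change are logged as Env events.
        """
        self.params = apply_stress(self.params, protocol)
        if protocol.kind == "heat_shock":
            self.env = self.env.at_temperature(self.params.T)
            refresh = lambda c: cm.at_temperature(c, self.env, self.params)
        else:
            refresh = lambda c: cm.refresh(c, self.params)
        new_cells = []
        for c in self.cells:
            c2 = refresh(c)
            before, after = is_mutator(c, self.params), is_mutator(c2, self.params)
            if before != after:
                self.log("Env", -1, c.lineage_id, before, after)
            new_cells.append(c2)
        self.cells = new_cells
        self.log("Env", -1, -1, None, None, f"protocol={protocol.kind}")

    def run(self, t_max: int, protocol: StressProtocol | None = None) -> Trajectory:
        extinct_at = None
        while self.t < t_max:
            if protocol is not None and self.t == protocol.t_apply:
                self.apply_protocol(protocol)
            try:
                self.step()
            except ExtinctionError:
                extinct_at = self.t
                break
            if not self.cells:
                extinct_at = self.t
                break
        return self.trajectory(extinct_at)

    def trajectory(self, extinct_at: int | None = None) -> Trajectory:
        series = pd.DataFrame(self._series, columns=SERIES_COLUMNS)
        events = pd.DataFrame(self._events, columns=EVENT_COLUMNS)
        meta = {"t_final": self.t, "extinct_at": extinct_at, "cap": self.cap}
        return Trajectory(series, events, meta)


# ---------------------------------------------------------------------------
# run drivers
# ---------------------------------------------------------------------------

def _structure_set(config, seed):
    from .lattice import enumerate_compact_conformations, sample_structure_set

    if config.structure_source == "limit":
        return enumerate_compact_conformations(limit=config.n_structures)
    full = enumerate_compact_conformations()
    if config.n_structures >= full.count:
        return full
    return sample_structure_set(full, config.n_structures, seed)


def build_seed(config, rng_design, conf_set=None):
    """Design (or load) the seed genome and calibrate G_ref and b0.

    Calibration makes the seed exactly wild-type (m = m_min) and balances
    its birth rate against the death rate (b = d), as the initial
    condition of every evolutionary run.
    """
    from .design import DesignConfig, design_seed_genome
    from .lattice import load_mj_energy_model

    if conf_set is None:
        conf_set = _structure_set(config, int(rng_design.integers(2**31)))
    em = load_mj_energy_model(config.T)
    env = CellEnv(conf_set, em, config.k_convention)
    params = config.fitness_params()

    if config.seed_genes is not None:
        genome = Genome(tuple(config.seed_genes))
    else:
        dcfg = DesignConfig(
            p_nat_threshold=config.design_p_nat,
            p_int_threshold=config.design_p_int,
        )
        genome, _ = design_seed_genome(conf_set, em, dcfg, rng_design)

    C = np.asarray(config.initial_concentrations(), dtype=np.float64)
    seed_cell, reason = cm.develop(genome, C, env, params)
    if seed_cell is None:
        raise RuntimeError(f"seed genome not viable: {reason}")
    if config.calibrate_G_ref:
        params = dataclasses.replace(params, G_ref=seed_cell.G44)
    if config.calibrate_b0 and params.constant_b is None:
        params = dataclasses.replace(
            params, b0=params.d / (seed_cell.G1 * seed_cell.G23)
        )
    seed_cell, reason = cm.develop(genome, C, env, params)
    assert seed_cell is not None
    return seed_cell, params, env


def run_evolution(config) -> Trajectory:
    """Run one full evolutionary simulation from a designed seed."""
    ss = np.random.SeedSequence(config.master_seed)
    s_struct, s_design, s_dyn = ss.spawn(3)
    conf_set = _structure_set(config, int(np.random.default_rng(s_struct).integers(2**31)))
    seed_cell, params, env = build_seed(
        config, np.random.default_rng(s_design), conf_set
    )
    cells = [cm.clone(seed_cell, i + 1) for i in range(config.seed_pop)]
    pop = Population(
        cells, params, env, cap=config.cap,
        rng=np.random.default_rng(s_dyn), record_every=config.record_every,
    )
    protocol = config.protocol_obj()
    traj = pop.run(config.t_max, protocol)
    traj.meta.update({"master_seed": config.master_seed,
                      "protocol": config.protocol,
                      "b0": params.b0, "G_ref": params.G_ref})
    return traj


def run_competition(config, n_replicates: int = 1, r_high: float = 0.01):
    """Competition between fluctuation-capable (r=r_high) and frozen (r=0)
    lineages seeded 50/50 from the same genome.

    Returns a DataFrame indexed by t with the per-replicate and mean
    fractional population of the fluctuating lineage.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    traces = []
    for rep in range(n_replicates):
        ss = np.random.SeedSequence((config.master_seed, rep))
        s_struct, s_design, s_dyn = ss.spawn(3)
        conf_set = _structure_set(config, int(np.random.default_rng(s_struct).integers(2**31)))
        seed_cell, params, env = build_seed(
            config, np.random.default_rng(s_design), conf_set
        )
        half = config.seed_pop
        cells = []
        for i in range(half):
            c = cm.clone(seed_cell, i + 1)
            cells.append(dataclasses.replace(c, label=0, r_override=r_high))
        for i in range(half):
            c = cm.clone(seed_cell, half + i + 1)
            cells.append(dataclasses.replace(c, label=1, r_override=0.0))
        pop = Population(cells, params, env, cap=config.cap,
                         rng=np.random.default_rng(s_dyn),
                         record_every=config.record_every)
        ts, fracs = [0], [0.5]
        while pop.t < config.t_max and pop.cells:
            try:
                pop.step()
            except ExtinctionError:
                break
            if pop.t % config.record_every == 0:
                n0 = sum(c.label == 0 for c in pop.cells)
                ts.append(pop.t)
                fracs.append(n0 / len(pop.cells))
        traces.append(pd.Series(fracs, index=ts, name=f"rep{rep}"))
    out = pd.concat(traces, axis=1)
    out["mean_fraction"] = out.mean(axis=1)
    out.index.name = "t"
    return out


def run_constant_fitness(
    b_values,
    config,
    n_replicates: int = 1,
    sample_every: int = 25,
    window: int = 2000,
):
    """Drift control: fitness fixed to b, mutation machinery intact.

    For each constant birth probability the mutator frequency is sampled
    every ``sample_every`` steps over the last ``window`` steps and
    ensemble-averaged over replicates.  Returns a DataFrame with columns
    (b, mean_mutator_freq, n_samples).
    """
    b_values = list(b_values)
    if any(not 0 < b <= 1 for b in b_values):
        raise ValueError("constant fitness values must lie in (0, 1]")
    rows = []
    for b in b_values:
        samples = []
        for rep in range(n_replicates):
            cfgb = dataclasses.replace(config, constant_b=float(b))
            ss = np.random.SeedSequence((config.master_seed, int(b * 10**6), rep))
            s_struct, s_design, s_dyn = ss.spawn(3)
            conf_set = _structure_set(cfgb, int(np.random.default_rng(s_struct).integers(2**31)))
            seed_cell, params, env = build_seed(
                cfgb, np.random.default_rng(s_design), conf_set
            )
            pop = Population([cm.clone(seed_cell, i + 1) for i in range(cfgb.seed_pop)],
                             params, env, cap=cfgb.cap,
                             rng=np.random.default_rng(s_dyn),
                             record_every=cfgb.record_every)
            t_start = cfgb.t_max - window
            while pop.t < cfgb.t_max and pop.cells:
                try:
                    pop.step()
                except ExtinctionError:
                    break
                if pop.t > t_start and pop.t % sample_every == 0:
                    samples.append(pop.mutator_frequency())
        rows.append((b, float(np.mean(samples)) if samples else np.nan, len(samples)))
    return pd.DataFrame(rows, columns=["b", "mean_mutator_freq", "n_samples"])
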