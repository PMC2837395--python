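"""Measurements on finished runs: mutator waves, their causes, landscapes.

The cause taxonomy follows the model's three routes into (or out of) the
mutator phenotype: an environmental change (Env — the stress itself flips
cells with no genomic or expression change), a mutation in the MMR gene
(Mut), and epigenetic stochastic switching of the MMR expression level
(SS).  Population-level transitions are mutator-frequency crossings of
0.5 with hysteresis: a crossing only counts if the frequency previously
sat below 0.25 (for a rise) or above 0.75 (for a fall), which suppresses
chatter around the threshold.  Flips driven through the equilibrium by
changes in *other* genes fall into an explicit "unattributed" column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cell as cm
from .cell import Cell, CellEnv, FitnessParams
from .evolution import Population, Trajectory

__all__ = [
    "mutator_frequency",
    "classify_transitions",
    "fitness_class",
    "LandscapeHistogram",
    "local_fitness_landscape",
]

FITNESS_CLASSES = (0.33, 0.62, 1.0)
CAUSES = ("Env", "Mut", "SS", "unattributed")


def mutator_frequency(pop) -> float:
    """Fraction of cells whose mutation rate exceeds the mutator threshold."""
    if isinstance(pop, Population):
        return pop.mutator_frequency()
    cells = list(pop)
    if not cells:
        raise ValueError("empty population has no mutator frequency")
    return sum(c.m > 0.01 for c in cells) / len(cells)


def fitness_class(mean_b: float) -> float:
    """Nearest of the three post-adaptation fitness classes."""
    if not 0 < mean_b <= 1:
        raise ValueError("mean_b must be in (0, 1]")
    return min(FITNESS_CLASSES, key=lambda c: abs(c - mean_b))


def _flip_cause(row) -> str:
    if row.kind == "Env":
        return "Env"
    if row.kind == "Mut" and row.gene == 3:
        return "Mut"
    if row.kind == "SS" and row.gene == 3:
        return "SS"
    return "unattributed"


def classify_transitions(
    traj: Trajectory,
    low: float = 0.25,
    high: float = 0.75,
) -> pd.DataFrame:
    """Count population-level mutator transitions by direction and cause.

    A transition into mutators (M) is a crossing of freq = 0.5 from an
    armed low state (freq previously < ``low``); a transition back (W)
    requires a previously armed high state (> ``high``).  The cause is
    the majority proximal cause among the per-cell flips logged in the
    window since arming, with precedence Env > Mut > SS on ties.

    Pure function of the trajectory: same input, same table.
    """
    series = traj.series
    events = traj.events
    freq = series["mutator_freq"].to_numpy()
    times = series["t"].to_numpy()

    counts = {("M", c): 0 for c in CAUSES}
    counts.update({("W", c): 0 for c in CAUSES})
    transitions = []

    side = "low" if freq[0] <= 0.5 else "high"
    armed = (freq[0] < low) if side == "low" else (freq[0] > high)
    armed_t = times[0]
    for k in range(1, len(freq)):
        f, t = freq[k], times[k]
        if side == "low":
            if f < low:
                armed, armed_t = True, t
            elif f > 0.5 and armed:
                transitions.append(("M", armed_t, t))
                side, armed = "high", False
        else:
            if f > high:
                armed, armed_t = True, t
            elif f < 0.5 and armed:
                transitions.append(("W", armed_t, t))
                side, armed = "low", False

    flips = events[
        events["mutator_before"].notna()
        & events["mutator_after"].notna()
        & (events["mutator_before"] != events["mutator_after"])
    ]
    for direction, t0, t1 in transitions:
        to_mut = direction == "M"
        # closed on the left so that flips logged exactly at the arming
        # record (e.g. the stress step itself) belong to this window
        window = flips[
            (flips["t"] >= t0) & (flips["t"] <= t1)
            & (flips["mutator_after"] == to_mut)
        ]
        if len(window) == 0:
            counts[(direction, "unattributed")] += 1
            continue
        tally = window.apply(_flip_cause, axis=1).value_counts()
        best = max(CAUSES, key=lambda c: (tally.get(c, 0), -CAUSES.index(c)))
        counts[(direction, best)] += 1

    out = pd.DataFrame(
        [
            {"direction": d, **{c: counts[(d, c)] for c in CAUSES}}
            for d in ("M", "W")
        ]
    ).set_index("direction")
    out["total"] = out.sum(axis=1)
    return out


@dataclass(frozen=True)
class LandscapeHistogram:
    """Histogram of relative fitness changes x = (b_mut - b)/b per mutation.

    Lethal mutants (stop codon or destabilised protein) are assigned
    x = -1, a complete loss of fitness, and land in the first bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    x: np.ndarray
    n_lethal: int

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def local_fitness_landscape(
    cell: Cell,
    env: CellEnv,
    params: FitnessParams,
    rng: np.random.Generator,
    n_mutants: int = 1000,
    bins=None,
) -> LandscapeHistogram:
    """Probe the local fitness landscape with single non-synonymous
    point mutations.

    Each of ``n_mutants`` independent substitutions is applied to a fresh
    copy of the genome; candidates that leave the protein sequence
    unchanged are rejected and redrawn.  Birth rate is recomputed with
    total concentrations held fixed.
    """
    if n_mutants < 1:
        raise ValueError("n_mutants must be >= 1")
    nt = "ACGT"
    xs = np.empty(n_mutants)
    n_lethal = 0
    b0 = cell.b
    if b0 <= 0:
        raise ValueError("reference cell has zero birth rate")
    for k in range(n_mutants):
        while True:
            gene = int(rng.integers(4))
            pos = int(rng.integers(cm.GENE_LENGTH))
            old_gene = cell.genome.genes[gene]
            choices = [c for c in nt if c != old_gene[pos]]
            new_gene = (
                old_gene[:pos] + choices[int(rng.integers(3))] + old_gene[pos + 1:]
            )
            new_aa = cm.translate(new_gene)
            if new_aa is None:  # nonsense mutation: non-synonymous, lethal
                break
            if new_aa != cell.proteins[gene].aa_seq:
                break
        if new_aa is None:
            xs[k] = -1.0
            n_lethal += 1
            continue
        genome = cell.genome.with_gene(gene, new_gene)
        mutant, _reason = cm._develop_daughter(cell, genome, [gene], env, params, -1)
        if mutant is None:
            xs[k] = -1.0
            n_lethal += 1
        else:
            xs[k] = (mutant.b - b0) / b0
    if bins is None:
        top = max(1.0, float(xs.max()))
        bins = np.linspace(-1.0, top, 51)
    bins = np.asarray(bins, dtype=float)
    # clip so every sampled mutant lands in a bin (counts sum to n_mutants)
    counts, edges = np.histogram(np.clip(xs, bins[0], bins[-1]), bins=bins)
    return LandscapeHistogram(edges, counts, xs, n_lethal)
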