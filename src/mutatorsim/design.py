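"""Monte-Carlo design of seed sequences.

Seed genomes are built by simulated annealing in sequence space: random
residue substitutions accepted by a Metropolis criterion on the design
objective.  Genes 1–3 only need a stable fold (p_nat above a threshold in
a randomly chosen target conformation); gene 4 additionally needs a strong
self-interaction, since its product functions as an MMR homodimer.
Interactions between RCG products are deliberately left undesigned — the
simulated populations must discover them by evolution.

Designed proteins are back-translated to 81-nt genes with uniformly random
synonymous codons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import AA_TO_CODONS, Genome
from .lattice import (
    AA_ALPHABET,
    ConformationSet,
    EnergyModel,
    _conf_energies,
    binding_mode_energies,
    fold,
)
from scipy.special import logsumexp

__all__ = ["DesignConfig", "DesignError", "DesignResult",
           "design_stable_gene", "design_homodimer_gene", "design_seed_genome"]


class DesignError(RuntimeError):
    """Design failed to reach its thresholds within the step budget."""


@dataclass(frozen=True)
class DesignConfig:
    """Thresholds and annealing schedule for sequence design.

    p_nat_threshold defaults to the lethality threshold plus a safety
    margin so that seed cells are robust to early drift.
    """

    p_nat_threshold: float = 0.7
    p_int_threshold: float = 0.4
    max_steps: int = 30_000
    beta_start: float = 2.0
    beta_end: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.p_nat_threshold < 1:
            raise ValueError("p_nat_threshold must be in (0, 1)")
        if not 0 < self.p_int_threshold < 1:
            raise ValueError("p_int_threshold must be in (0, 1)")


@dataclass(frozen=True)
class DesignResult:
    gene: str
    aa_seq: str
    structure_index: int
    p_nat: float
    p_int: float | None
    steps: int


def _p_target(seq_idx: np.ndarray, target: int, conf_set: ConformationSet,
              em: EnergyModel) -> tuple[float, float, bool]:
    """(log p_target, E_target, is_unique_minimum) for one sequence."""
    e = _conf_energies(conf_set.contact_maps, seq_idx, em.contact_energy)
    et = e[target]
    log_p = -et / em.temperature - logsumexp(-e / em.temperature)
    order = np.argsort(e, kind="stable")
    unique = bool(order[0] == target and e[order[1]] > et)
    return float(log_p), float(et), unique


def back_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Random synonymous codon choice for each residue."""
    parts = []
    for a in aa_seq:
        codons = AA_TO_CODONS[a]
        parts.append(codons[int(rng.integers(len(codons)))])
    return "".join(parts)


def _random_seq(rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 20, size=27).astype(np.int8)


def _seq_str(seq_idx: np.ndarray) -> str:
    return "".join(AA_ALPHABET[i] for i in seq_idx)


def design_stable_gene(
    structure_index: int,
    conf_set: ConformationSet,
    em: EnergyModel,
    cfg: DesignConfig,
    rng: np.random.Generator,
) -> DesignResult:
    """Design a gene whose product folds stably into the given structure.

    Metropolis walk on log p_nat(target) with a linear annealing schedule;
    stops as soon as the target is the unique native state with p_nat at
    or above the threshold.
    """
    if not 0 <= structure_index < conf_set.count:
        raise ValueError("structure_index outside the conformation set")
    seq = _random_seq(rng)
    log_p, _, unique = _p_target(seq, structure_index, conf_set, em)
    log_thr = np.log(cfg.p_nat_threshold)
    for step in range(cfg.max_steps):
        if unique and log_p >= log_thr:
            aa = _seq_str(seq)
            return DesignResult(back_translate(aa, rng), aa, structure_index,
                                float(np.exp(log_p)), None, step)
        beta = cfg.beta_start + (cfg.beta_end - cfg.beta_start) * step / cfg.max_steps
        pos = int(rng.integers(27))
        old = seq[pos]
        seq[pos] = int(rng.integers(20))
        new_log_p, _, new_unique = _p_target(seq, structure_index, conf_set, em)
        if new_log_p >= log_p or rng.random() < np.exp(beta * (new_log_p - log_p)):
            log_p, unique = new_log_p, new_unique
        else:
            seq[pos] = old
    raise DesignError(
        f"stable design did not reach p_nat {cfg.p_nat_threshold} "
        f"in {cfg.max_steps} steps (got {np.exp(log_p):.3f})"
    )


def design_homodimer_gene(
    structure_index: int,
    conf_set: ConformationSet,
    em: EnergyModel,
    cfg: DesignConfig,
    rng: np.random.Generator,
) -> DesignResult:
    """Design a stable protein that also forms a strong homodimer.

    Stage 1 is plain stability design; stage 2 anneals the homodimer
    native-mode probability p_int(self, self) while rejecting any move
    that drops stability below threshold or changes the native state.
    """
    base = design_stable_gene(structure_index, conf_set, em, cfg, rng)
    state = fold(base.aa_seq, conf_set, em)
    seq = state.seq_idx.copy()
    log_thr = np.log(cfg.p_nat_threshold)

    def homodimer_log_p(seq_idx: np.ndarray) -> float:
        s = fold(_seq_str(seq_idx), conf_set, em)
        if s.native_index != structure_index:
            return -np.inf
        e = binding_mode_energies(s, s, conf_set, em)
        return float(-e.min() / em.temperature
                     - logsumexp(-e / em.temperature))

    log_p_nat, _, unique = _p_target(seq, structure_index, conf_set, em)
    log_p_int = homodimer_log_p(seq)
    log_int_thr = np.log(cfg.p_int_threshold)
    for step in range(cfg.max_steps):
        if log_p_int >= log_int_thr and unique and log_p_nat >= log_thr:
            aa = _seq_str(seq)
            return DesignResult(back_translate(aa, rng), aa, structure_index,
                                float(np.exp(log_p_nat)),
                                float(np.exp(log_p_int)), base.steps + step)
        beta = cfg.beta_start + (cfg.beta_end - cfg.beta_start) * step / cfg.max_steps
        pos = int(rng.integers(27))
        old = seq[pos]
        seq[pos] = int(rng.integers(20))
        new_log_nat, _, new_unique = _p_target(seq, structure_index, conf_set, em)
        if not new_unique or new_log_nat < log_thr:
            seq[pos] = old
            continue
        new_log_int = homodimer_log_p(seq)
        if new_log_int >= log_p_int or rng.random() < np.exp(beta * (new_log_int - log_p_int)):
            log_p_nat, unique, log_p_int = new_log_nat, new_unique, new_log_int
        else:
            seq[pos] = old
    raise DesignError(
        f"homodimer design did not reach p_int {cfg.p_int_threshold} "
        f"in {cfg.max_steps} steps (got {np.exp(log_p_int):.3f})"
    )


def design_seed_genome(
    conf_set: ConformationSet,
    em: EnergyModel,
    cfg: DesignConfig,
    rng: np.random.Generator,
) -> tuple[Genome, list[DesignResult]]:
    """Design a full 4-gene seed genome.

    Native structures are drawn uniformly at random from the conformation
    set; genes 1–3 get stable designs, gene 4 a stable strong homodimer.
    """
    targets = rng.integers(0, conf_set.count, size=4)
    results = [
        design_stable_gene(int(targets[i]), conf_set, em, cfg, rng)
        for i in range(3)
    ]
    results.append(design_homodimer_gene(int(targets[3]), conf_set, em, cfg, rng))
    genome = Genome(tuple(r.gene for r in results))
    return genome, results
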