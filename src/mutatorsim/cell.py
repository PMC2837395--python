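"""The genotype→phenotype map of one model cell.

A cell carries four 81-nt genes.  Genes 1–3 are replication-controlling
genes (RCGs): protein 1 functions as a free monomer, proteins 2 and 3 as a
heterodimer, and together they set the birth probability b.  Gene 4 models
the mismatch-repair (MMR) system: the concentration of functional MMR
homodimers G44 linearly suppresses the per-gene mutation rate m.

Phenotype construction: translate each gene with the standard genetic code,
fold the 27-mers over the conformation set, dock every protein pair over the
144 rigid modes, feed the binding constants into the law-of-mass-action
solver, and read the functional concentrations G1, G23 and G44 off the
equilibrium.  An in-frame stop codon, or any protein falling below the
stability threshold theta_nat, makes the phenotype lethal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .equilibrium import (
    EquilibriumState,
    functional_mmr_concentration,
    functional_rcg_concentrations,
    solve_lma,
)
from .lattice import (
    ConformationSet,
    EnergyModel,
    InteractionTable,
    ProteinState,
    build_interaction_table,
    fold,
)

__all__ = [
    "GENE_LENGTH",
    "N_GENES",
    "Genome",
    "FitnessParams",
    "CellEnv",
    "Cell",
    "SequenceError",
    "translate",
    "develop",
    "clone",
    "with_concentrations",
    "at_temperature",
    "birth_rate",
    "mutation_rate",
    "is_mutator",
    "fluctuate_concentrations",
    "mutate_genome",
    "replicate",
]

GENE_LENGTH = 81
N_GENES = 4
_NT = "ACGT"
_NT_SET = frozenset(_NT)

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)


class SequenceError(ValueError):
    """A gene fails the nucleotide alphabet/length contract."""


def translate(gene: str) -> str | None:
    """Translate an 81-nt gene to a 27-mer; ``None`` flags an in-frame stop."""
    if len(gene) != GENE_LENGTH:
        raise SequenceError(f"gene length {len(gene)} != {GENE_LENGTH}")
    if not _NT_SET.issuperset(gene):
        raise SequenceError("gene contains letters outside ACGT")
    aa = []
    for k in range(0, GENE_LENGTH, 3):
        res = CODON_TO_AA[gene[k : k + 3]]
        if res == "*":
            return None
        aa.append(res)
    return "".join(aa)


@dataclass(frozen=True)
class Genome:
    """Four nucleotide genes of 81 nt each."""

    genes: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.genes) != N_GENES:
            raise SequenceError(f"genome must carry {N_GENES} genes")
        for g in self.genes:
            if len(g) != GENE_LENGTH or not _NT_SET.issuperset(g):
                raise SequenceError("each gene must be 81 nt over ACGT")

    def with_gene(self, idx: int, gene: str) -> "Genome":
        genes = list(self.genes)
        genes[idx] = gene
        return Genome(tuple(genes))


@dataclass(frozen=True)
class FitnessParams:
    """Global physiology parameters.

    b0 : base growth rate (calibrated per seed genome so that the initial
        birth probability equals the death rate d).
    C0 : optimal total protein concentration; sigma : overproduction
        penalty coefficient.
    theta_nat : stability threshold below which a protein is lethally
        misfolded.
    m_min / m_max : wild-type and maximal per-gene mutation rates; G_ref
        the functional-MMR concentration at which m == m_min.
    r : per-gene probability per step of an expression-level fluctuation,
        with multiplicative Gaussian magnitude fluct_sd.
    T : environmental temperature in contact-potential units.
    constant_b : if set, birth probability is fixed to this value (drift
        control experiments) instead of being computed from the genotype.
    """

    b0: float = 707.445
    C0: float = 0.4
    sigma: float = 100.0
    d: float = 0.005
    theta_nat: float = 0.6
    m_min: float = 1e-4
    m_max: float = 0.1
    G_ref: float = 1.0
    r: float = 0.01
    T: float = 0.85
    fluct_sd: float = 0.1
    conc_floor: float = 1e-6
    mutator_threshold: float = 0.01
    lma_rel_tol: float = 1e-3
    constant_b: float | None = None

    def __post_init__(self) -> None:
        if not (self.m_min < self.mutator_threshold < self.m_max):
            raise ValueError("need m_min < mutator threshold < m_max")
        if self.T <= 0 or self.C0 <= 0 or self.G_ref <= 0:
            raise ValueError("T, C0 and G_ref must be positive")
        if not 0 <= self.r <= 1:
            raise ValueError("fluctuation rate r must be in [0, 1]")


@dataclass(frozen=True)
class CellEnv:
    """Shared structural machinery: conformations, potential, conventions."""

    conf_set: ConformationSet
    em: EnergyModel
    k_convention: str = "min"

    def at_temperature(self, T: float) -> "CellEnv":
        return CellEnv(self.conf_set, self.em.at_temperature(T), self.k_convention)


@dataclass(frozen=True, slots=True)
class Cell:
    """One organism: genome, expression levels, and derived phenotype."""

    genome: Genome
    C: np.ndarray
    proteins: tuple[ProteinState, ...]
    itab: InteractionTable
    eq: EquilibriumState
    G1: float
    G23: float
    G44: float
    b: float
    m: float
    lineage_id: int = 0
    parent_id: int = -1
    label: int = 0
    r_override: float | None = None


def birth_rate_from(G1: float, G23: float, total_C: float, params: FitnessParams) -> float:
    """Birth probability: b0·G1·G23 damped by the overproduction penalty."""
    if params.constant_b is not None:
        return float(params.constant_b)
    b = params.b0 * G1 * G23 / (1.0 + params.sigma * (total_C - params.C0) ** 2)
    return float(min(max(b, 0.0), 1.0))


def mutation_rate(G44: float, params: FitnessParams) -> float:
    """Per-gene mutation rate, linear in the functional MMR concentration.

    m = m_min at G44 >= G_ref (fully functional repair) rising linearly to
    m_max at G44 = 0 (no repair).
    """
    if G44 < 0:
        raise ValueError("G44 must be non-negative")
    deficit = max(0.0, 1.0 - G44 / params.G_ref)
    return params.m_min + (params.m_max - params.m_min) * deficit


def is_mutator(cell: Cell, params: FitnessParams | None = None) -> bool:
    thr = params.mutator_threshold if params is not None else 0.01
    return cell.m > thr


def birth_rate(cell: Cell, params: FitnessParams) -> float:
    """Recompute the birth probability from the cell's current equilibrium."""
    return birth_rate_from(cell.G1, cell.G23, float(cell.C.sum()), params)


def _phenotype(
    proteins: tuple[ProteinState, ...],
    itab: InteractionTable,
    C: np.ndarray,
    params: FitnessParams,
) -> tuple[EquilibriumState, float, float, float, float, float]:
    eq = solve_lma(C, itab.K, rel_tol=params.lma_rel_tol)
    p_nat = [p.p_nat for p in proteins]
    g1, g23 = functional_rcg_concentrations(
        eq, p_nat[0], p_nat[1], p_nat[2], itab.p_int[1, 2]
    )
    g44 = functional_mmr_concentration(eq, itab.p_int[3, 3], p_nat[3])
    b = birth_rate_from(g1, g23, float(C.sum()), params)
    m = mutation_rate(g44, params)
    return eq, g1, g23, g44, b, m


def develop(
    genome: Genome,
    C: np.ndarray,
    env: CellEnv,
    params: FitnessParams,
    lineage_id: int = 0,
    parent_id: int = -1,
    label: int = 0,
    r_override: float | None = None,
    check_viability: bool = True,
) -> tuple[Cell | None, str | None]:
    """Build a cell's full phenotype from scratch.

    Returns ``(cell, None)`` or ``(None, reason)`` when the phenotype is
    lethal (in-frame stop, or any protein with p_nat < theta_nat).
    """
    aa_seqs = []
    for i, gene in enumerate(genome.genes):
        aa = translate(gene)
        if aa is None:
            return None, f"stop codon in gene {i}"
        aa_seqs.append(aa)
    proteins = tuple(fold(aa, env.conf_set, env.em) for aa in aa_seqs)
    if check_viability:
        for i, p in enumerate(proteins):
            if p.p_nat < params.theta_nat:
                return None, f"unstable protein {i} (p_nat={p.p_nat:.3f})"
    itab = build_interaction_table(proteins, env.conf_set, env.em, env.k_convention)
    C = np.asarray(C, dtype=np.float64).copy()
    eq, g1, g23, g44, b, m = _phenotype(proteins, itab, C, params)
    return (
        Cell(genome, C, proteins, itab, eq, g1, g23, g44, b, m,
             lineage_id, parent_id, label, r_override),
        None,
    )


def clone(cell: Cell, lineage_id: int) -> Cell:
    """Identical daughter sharing every immutable phenotype component."""
    return Cell(
        cell.genome, cell.C, cell.proteins, cell.itab, cell.eq,
        cell.G1, cell.G23, cell.G44, cell.b, cell.m,
        lineage_id, cell.lineage_id, cell.label, cell.r_override,
    )


def with_concentrations(cell: Cell, C: np.ndarray, params: FitnessParams) -> Cell:
    """Re-equilibrate after an expression-level change (genome unchanged)."""
    C = np.asarray(C, dtype=np.float64)
    eq, g1, g23, g44, b, m = _phenotype(cell.proteins, cell.itab, C, params)
    return Cell(
        cell.genome, C.copy(), cell.proteins, cell.itab, eq, g1, g23, g44, b, m,
        cell.lineage_id, cell.parent_id, cell.label, cell.r_override,
    )


def refresh(cell: Cell, params: FitnessParams) -> Cell:
    """Recompute b and m under new global parameters (same T)."""
    eq, g1, g23, g44, b, m = _phenotype(cell.proteins, cell.itab, cell.C, params)
    return Cell(
        cell.genome, cell.C, cell.proteins, cell.itab, eq, g1, g23, g44, b, m,
        cell.lineage_id, cell.parent_id, cell.label, cell.r_override,
    )


def at_temperature(cell: Cell, env: CellEnv, params: FitnessParams) -> Cell:
    """Re-evaluate the whole phenotype at the environment's temperature.

    Energy spectra are temperature independent, so no refolding/redocking
    is needed — only the Boltzmann weights and binding constants change.
    """
    T = env.em.temperature
    proteins = tuple(p.at_temperature(T) for p in cell.proteins)
    itab = cell.itab.at_temperature(T)
    eq, g1, g23, g44, b, m = _phenotype(proteins, itab, cell.C, params)
    return Cell(
        cell.genome, cell.C, proteins, itab, eq, g1, g23, g44, b, m,
        cell.lineage_id, cell.parent_id, cell.label, cell.r_override,
    )


def fluctuate_concentrations(
    cell: Cell,
    params: FitnessParams,
    rng: np.random.Generator,
) -> tuple[Cell, list[tuple[int, float, float]]]:
    """Epigenetic expression noise: per gene, with probability r rescale
    C_i by (1 + eta), eta ~ Normal(0, fluct_sd), floored at conc_floor.

    Returns the updated cell and a list of (gene, old, new) changes.
    """
    r = params.r if cell.r_override is None else cell.r_override
    if r == 0.0:
        return cell, []
    hits = rng.random(N_GENES) < r
    return apply_fluctuations(cell, hits, params, rng)


def apply_fluctuations(
    cell: Cell,
    hits: np.ndarray,
    params: FitnessParams,
    rng: np.random.Generator,
) -> tuple[Cell, list[tuple[int, float, float]]]:
    """Fluctuate the genes flagged in ``hits`` (bool per gene)."""
    if not hits.any():
        return cell, []
    C = cell.C.copy()
    events = []
    for i in np.flatnonzero(hits):
        old = C[i]
        C[i] = max(old * (1.0 + rng.normal(0.0, params.fluct_sd)), params.conc_floor)
        events.append((int(i), float(old), float(C[i])))
    return with_concentrations(cell, C, params), events


def mutate_genome(
    genome: Genome, m: float, rng: np.random.Generator
) -> tuple[Genome, list[int]]:
    """Apply Poisson(m) single-nucleotide substitutions per gene.

    Returns the mutated genome and the list of affected gene indices
    (with multiplicity one per substitution).
    """
    n_subs = rng.poisson(m, N_GENES)
    return mutate_genome_counts(genome, n_subs, rng)


def mutate_genome_counts(
    genome: Genome, n_subs: np.ndarray, rng: np.random.Generator
) -> tuple[Genome, list[int]]:
    """Apply a given number of substitutions per gene at uniform positions."""
    if not n_subs.any():
        return genome, []
    genes = list(genome.genes)
    touched: list[int] = []
    for i in np.flatnonzero(n_subs):
        g = list(genes[i])
        for _ in range(n_subs[i]):
            pos = int(rng.integers(GENE_LENGTH))
            choices = [c for c in _NT if c != g[pos]]
            g[pos] = choices[int(rng.integers(3))]
            touched.append(int(i))
        genes[i] = "".join(g)
    return Genome(tuple(genes)), touched


def _develop_daughter(
    mother: Cell,
    genome: Genome,
    touched: list[int],
    env: CellEnv,
    params: FitnessParams,
    lineage_id: int,
) -> tuple[Cell | None, str | None]:
    """Incremental phenotype update: refold only mutated genes."""
    proteins = list(mother.proteins)
    for i in sorted(set(touched)):
        aa = translate(genome.genes[i])
        if aa is None:
            return None, f"stop codon in gene {i}"
        if aa == proteins[i].aa_seq:  # synonymous
            continue
        proteins[i] = fold(aa, env.conf_set, env.em)
        if proteins[i].p_nat < params.theta_nat:
            return None, f"unstable protein {i} (p_nat={proteins[i].p_nat:.3f})"
    proteins_t = tuple(proteins)
    itab = mother.itab
    for i in sorted(set(touched)):
        if proteins_t[i] is not mother.proteins[i]:
            itab = itab.replace_protein(i, proteins_t, env.conf_set, env.em)
    if itab is mother.itab:  # all substitutions synonymous
        return clone_with_genome(mother, genome, lineage_id), None
    eq, g1, g23, g44, b, m = _phenotype(proteins_t, itab, mother.C, params)
    return (
        Cell(genome, mother.C, proteins_t, itab, eq, g1, g23, g44, b, m,
             lineage_id, mother.lineage_id, mother.label, mother.r_override),
        None,
    )


def clone_with_genome(cell: Cell, genome: Genome, lineage_id: int) -> Cell:
    return Cell(
        genome, cell.C, cell.proteins, cell.itab, cell.eq,
        cell.G1, cell.G23, cell.G44, cell.b, cell.m,
        lineage_id, cell.lineage_id, cell.label, cell.r_override,
    )


def replicate(
    cell: Cell,
    params: FitnessParams,
    env: CellEnv,
    rng: np.random.Generator,
    next_id,
) -> tuple[list[Cell], list[dict]]:
    """Divide into two daughters, each independently mutated at rate m.

    Daughters inherit the mother's expression levels epigenetically.
    Lethal daughters (stop codon or destabilised protein) are discarded
    and reported as events.  ``next_id`` is a callable yielding fresh
    lineage ids.
    """
    daughters: list[Cell] = []
    events: list[dict] = []
    for _ in range(2):
        d, evs = make_daughter(
            cell, rng.poisson(cell.m, N_GENES), env, params, rng, next_id
        )
        if d is not None:
            daughters.append(d)
        events.extend(evs)
    return daughters, events


def make_daughter(
    cell: Cell,
    n_subs: np.ndarray,
    env: CellEnv,
    params: FitnessParams,
    rng: np.random.Generator,
    next_id,
) -> tuple[Cell | None, list[dict]]:
    """One daughter with the given per-gene substitution counts."""
    genome, touched = mutate_genome_counts(cell.genome, n_subs, rng)
    if not touched:
        return clone(cell, next_id()), []
    d, reason = _develop_daughter(cell, genome, touched, env, params, next_id())
    if d is None:
        return None, [{"kind": "lethal", "gene": -1, "detail": reason,
                       "lineage_id": cell.lineage_id}]
    events = [
        {
            "kind": "Mut", "gene": g, "detail": "",
            "lineage_id": d.lineage_id,
            "mutator_before": is_mutator(cell, params),
            "mutator_after": is_mutator(d, params),
        }
        for g in touched
    ]
    return d, events
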