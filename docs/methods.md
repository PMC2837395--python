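# Methods

`mutatorsim` is an agent-based, multiscale simulator in which the fitness
and the mutation rate of every model cell are *derived* from its genome
through explicit protein biophysics, rather than assumed.  This note
records the model, its tunable parameters, the numerical choices, and what
the desk-scale tests do and do not establish.

## The cell model

Each organism carries four genes of 81 nucleotides.  Translation uses the
standard genetic code; an in-frame stop codon makes the phenotype lethal
(a truncated 27-mer cannot fill the cube).  Each 27-residue protein folds
on the 3×3×3 cubic lattice.

**Conformation space.**  The maximally compact conformations are the
Hamiltonian self-avoiding chains that fill the 3×3×3 cube.  Exhaustive
backtracking finds 4,960,608 directed chains; reducing by the 48-element
cubic point group (rotations and reflections, chain direction retained)
leaves exactly **103,346** symmetry-distinct conformations.  Chain
*reversal* is deliberately not identified: doing so would halve the count
to 51,704 and break the canonical figure (reducing by the 24 proper
rotations plus reversal gives the same 103,346 — the two conventions
coincide in count; we use the rotation+reflection form).  Every
conformation carries exactly 28 non-bonded nearest-neighbour contacts
(54 cube edges − 26 chain bonds).  Enumeration is canonical-lexicographic:
a chain is stored only if no symmetry image of its cell sequence is
lexicographically smaller, so the output order is deterministic and
sorted, and a truncated enumeration (`limit=n`) is a well-defined
deterministic fixture.  Full-scale runs use a uniform random subsample of
10,000 structures (the published operating point); the "evenly
distributed" subset of the original work may have used stratification —
plain uniform sampling is provided and this is a known open point.

**Energetics.**  Conformational energy is the sum of Miyazawa–Jernigan
pairwise contact energies over the 28 contacts; the shipped table is a
transcription of the 1996 upper-triangular e_ij matrix (file
`data/mj1996_contact_energies.txt`, version-tagged).  Individual entries
transcribed from the literature may deviate in the last digit; all model
behaviour rests on the broad hydrophobicity structure of the table, not
on exact entries.  Temperature T is in the same dimensionless units
(defaults 0.85, heat shock 1.00).

**Folding stability.**  P_nat is the Boltzmann weight of the
minimum-energy conformation within the structure set,
P_nat = exp(−E0/T)/Σ_c exp(−E_c/T), computed with log-sum-exp.  Energy
ties break to the lowest conformation index; designed sequences are
required to have a strict minimum.  A protein with P_nat below the
lethality threshold θ_nat (default 0.6, the conventional stability cut in
this model family; the source value is not printed) is lethally
misfolded.  Lethality is enforced on newly developed daughter phenotypes:
cells are not retroactively killed when the environment changes, but all
of their offspring are checked at birth.

**Docking.**  Two rigid compact proteins dock face-to-face: 6 faces × 6
faces × 4 in-plane rotations = **144 modes** (reflections are not extra
modes).  Mode geometry is constructed from the 24 proper cube rotations;
each mode pairs the nine 3×3 surface sites across the interface, and the
interface energy is the sum of contact energies between the residues the
two native conformations place at facing sites.  P_int is the Boltzmann
probability of the minimum-energy mode among the 144.

**Binding constants.**  The source's binding-constant expression is not
printed; we adopt K_ij = exp(−E_int_min/T) in a unit
reference-concentration convention — the minimal reading of "computed
from the lowest binding energy" — with a mode-summed alternative
K_ij = Σ_modes exp(−E_mode/T) available behind the `k_convention`
switch (`"min"` default, `"mode_sum"`).  Because the base growth rate b0
is calibrated per seed genome (below), the overall scale of K is absorbed
and only relative changes matter.

**Law of mass action.**  Free monomer concentrations solve
F_i = C_i/(1 + 2 K_ii F_i + Σ_{j≠i} K_ij F_j), F_ij = K_ij F_i F_j.
The factor 2 on the homodimer term is forced by mass conservation
(C_i = F_i + 2F_ii + Σ_{j≠i}F_ij), which is asserted in tests to within
10× the solver tolerance.  The solver iterates plainly, stopping when
every F_i changes by less than 0.1% of its new value (the published
stopping rule; `rel_tol` configurable); if the plain map oscillates —
which it always does for large K — it switches to 0.5-damped iteration,
which is strongly contracting exactly in that stiff limit.  Near
titration-degenerate instances (huge K with nearly balancing totals)
both maps slow down; a damped-Newton polish on the bounded
parameterisation F_i = C_i/(1+e^{z_i}) then finishes the solve.  The
fixed point of this monomer–dimer system is unique, and the iteration and
the Newton route are cross-checked against each other and against the
closed-form quadratic solutions on random instances.

**Functional concentrations and fitness.**  Protein 1 functions as a
folded free monomer, proteins 2+3 as a folded native-mode heterodimer,
protein 4 (the mismatch-repair prototype) as a folded native-mode
homodimer:

    G1  = F_1 · P_nat(1)
    G23 = F_23 · P_int(2,3) · P_nat(2) · P_nat(3)
    G44 = F_44 · P_int(4,4) · P_nat(4)²

The G1/G23 products mirror the explicit G44 structure; whether the
source's fitness numerator carries the P_nat factors of proteins 2 and 3
is not printed, and the homodimer analogy is adopted.  Birth probability:

    b = b0 · G1 · G23 / (1 + σ (ΣC_i − C0)²),  clamped to [0, 1]

with σ = 100 and C0 = 0.4: overproduction is metabolically penalised.
Mutation rate is linear in functional repair capacity:

    m = m_min + (m_max − m_min) · max(0, 1 − G44/G_ref)

with m_min = 10⁻⁴ (wild type), m_max = 0.1 (configurable; "two to three
orders of magnitude" above wild type), and G_ref calibrated to the seed
cell's G44 so the seed is exactly wild-type.  A mutator is a cell with
m > 0.01 (strict inequality).

**Expression noise.**  Per step and per gene, with probability r
(default 0.01) the total concentration is rescaled by (1+η),
η ~ N(0, 0.1); concentrations are floored at 10⁻⁶ (the LMA needs C ≥ 0
and negative draws are not otherwise addressed).  C_i are inherited by
both daughters — heritable epigenetic state, the "stochastic switching"
(SS) channel.

## Population dynamics

Discrete time.  Per step and per cell, in this fixed order: fluctuate
expression → die with probability d = 0.005 → divide with probability b
(the mother is replaced by two daughters, each independently acquiring
Poisson(m) substitutions per gene; both daughters mutate — the source's
plural reading); finally, if the population exceeds the cap (5000 at full
scale) the excess is culled uniformly at random (chemostat).  The
within-step order is a choice the source does not pin down; an
order-sensitivity check at the level of equilibrium statistics showed no
qualitative dependence.  Runs start from `seed_pop` (500) identical
designed cells with equal concentrations C0/4 per gene; b0 is calibrated
per seed genome so the initial b equals d (707.445 is the published
instance of this calibration, not a universal constant).

Stress protocols change exactly one parameter at t_apply (20,000 at full
scale): heat shock T 0.85→1.00; stationary phase b0→b0/3 (707.445→
235.815 in the published instance); starvation C0 0.4→0.04.  On stress,
every phenotype is re-evaluated (energy spectra are
temperature-independent, so re-evaluation at a new T needs no refolding)
and cells whose mutator status flips with no genomic or expression change
are logged as Env events.

**Event log and transition classification.**  Every genome change (Mut,
with gene index), expression change (SS, with gene index), and
stress-driven flip (Env) is logged with the cell's mutator status before
and after.  A population-level transition is a mutator-frequency crossing
of 0.5 armed by hysteresis (the frequency must previously have been
< 0.25, or > 0.75 for the downward direction) — the crossing rule is not
defined in the source and hysteresis suppresses chatter.  Each transition
is attributed to the majority proximal cause among the individual flips
in the window since arming (Env > Mut > SS on ties); flips that ride on
changes in *other* genes through the shared equilibrium go to an explicit
"unattributed" column rather than being forced into the three categories.

## Sequence design

Seeds are designed by Metropolis annealing in sequence space (random
single-residue substitutions; objective log P_nat of a uniformly randomly
chosen target conformation; linear inverse-temperature ramp).  Gene 4 is
designed in two stages: stability first, then homodimer P_int annealed
subject to the stability constraint.  Defaults: P_nat ≥ 0.7 (lethality
threshold + 0.1 margin, since the source's seed stability is not
printed), homodimer P_int ≥ 0.4.  RCG–RCG interactions are left
undesigned, so seed fitness is poor and the first adaptation phase is
genuine.  Back-translation draws uniformly random synonymous codons.

## Scaled-down test world

The full operating point (cap 5000, 10,000 structures, 25,000 steps, 100
replicates) is hours-to-days of CPU; the shipped `configs/*_full.yaml`
reproduce it unchanged.  The test suite runs the same physics smaller:

- structure sets of 200–1000 conformations built by truncated canonical
  enumeration (deterministic, corner-biased — adequate because only the
  *relative* Boltzmann structure matters at fixed set);
- populations capped at 150–300, runs of 3,000–6,000 steps, ≥10
  replicates where ensembles are compared;
- the fluctuation-sweep comparison starts from unequal,
  post-adaptation-like concentrations (0.125, 0.125, 0.125, 0.025 —
  RCGs up, MMR down, summing to C0), mirroring the published sweep setup;
- stress is applied at t = 4000, after the initial adaptation completes
  and the first mutator wave recedes at this scale.

Green desk-scale tests establish the *mechanisms* — no adaptation or
mutator fixation without expression noise; drift purging mutators faster
at higher constant fitness; Env-modal mutator waves under heat shock and
SS-modal waves under starvation — not the published percentages, which
are ensemble quantities at 100×25,000-step scale.  Small populations also
carry a real extinction risk in the critical (b = d) founding phase that
the full-scale system does not; ensemble tests skip pre-stress
extinctions.

## Known limitations

- Mean-field LMA ignores crowding and small-copy-number effects.
- The MMR prototype is a homodimer; the real mutS dimer-of-dimers
  equilibrium is out of scope.
- No horizontal gene transfer, indels, recombination, or regulatory
  mutations; no higher-order complexes.
- The contact-energy table is a literature transcription (see above).
- Landscape histograms place lethal mutants at x = −1 (complete fitness
  loss) rather than excluding them; configurable via explicit bins.
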