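"""Lattice-protein thermodynamics on the 3x3x3 cube.

This module owns the structural layer of the model cell: exhaustive
enumeration of maximally compact 27-mer conformations (Hamiltonian chains
filling the 3x3x3 cube, reduced by the 48-element cubic point group to the
canonical 103,346), the 144 rigid face-to-face docking modes between two
compact proteins, and the Boltzmann thermodynamics built on a pairwise
residue contact potential: folding stability P_nat and dimer binding
(minimum interface energy, native-mode probability P_int, binding constant
K).

Energies are dimensionless (contact-potential units); temperature T is
expressed in the same units.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import logsumexp

__all__ = [
    "AA_ALPHABET",
    "N_COMPACT_CONFORMATIONS",
    "N_DOCKING_MODES",
    "EnergyModel",
    "ConformationSet",
    "ProteinState",
    "DockingMode",
    "InteractionTable",
    "enumerate_compact_conformations",
    "sample_structure_set",
    "fold",
    "enumerate_docking_modes",
    "bind",
    "build_interaction_table",
    "load_mj_energy_model",
]

#: Residue order used for integer encoding throughout the package.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: Exact count of symmetry-distinct compact 27-mer conformations.
N_COMPACT_CONFORMATIONS = 103_346
#: Exact count of rigid docking modes between two compact proteins (6*6*4).
N_DOCKING_MODES = 144

_N_SITES = 27
_N_CONTACTS = 28  # 54 cube edges minus 26 chain bonds


class AlphabetError(ValueError):
    """A sequence contains a letter outside the 20-residue alphabet."""


class SizeError(ValueError):
    """A requested subset size is out of range."""


# ---------------------------------------------------------------------------
# cube geometry
# ---------------------------------------------------------------------------

def _site_coords() -> np.ndarray:
    return np.array(
        [(i // 9, (i // 3) % 3, i % 3) for i in range(_N_SITES)], dtype=np.int64
    )


_COORDS = _site_coords()
_CELL_OF = {tuple(c): i for i, c in enumerate(_COORDS)}


def _neighbour_table() -> tuple[np.ndarray, np.ndarray]:
    nbrs = np.full((_N_SITES, 6), -1, dtype=np.int64)
    cnt = np.zeros(_N_SITES, dtype=np.int64)
    for i in range(_N_SITES):
        x, y, z = _COORDS[i]
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            t = (x + d[0], y + d[1], z + d[2])
            if all(0 <= v < 3 for v in t):
                nbrs[i, cnt[i]] = _CELL_OF[t]
                cnt[i] += 1
        # ascending neighbours make the DFS emit chains in lexicographic
        # order, so canonical representatives come out sorted
        nbrs[i, : cnt[i]] = np.sort(nbrs[i, : cnt[i]])
    return nbrs, cnt


_NBRS, _NCNT = _neighbour_table()
_ADJACENT = np.zeros((_N_SITES, _N_SITES), dtype=np.bool_)
for _i in range(_N_SITES):
    for _k in range(_NCNT[_i]):
        _ADJACENT[_i, _NBRS[_i, _k]] = True


def _symmetry_permutations() -> np.ndarray:
    """The 48 cell permutations induced by cube rotations and reflections."""
    perms = []
    for axes in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            p = np.empty(_N_SITES, dtype=np.int64)
            for i in range(_N_SITES):
                c = _COORDS[i] - 1
                t = tuple(signs[k] * c[axes[k]] + 1 for k in range(3))
                p[i] = _CELL_OF[t]
            perms.append(p)
    return np.array(perms)


_SYM_PERMS = _symmetry_permutations()


# ---------------------------------------------------------------------------
# enumeration kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _enumerate_kernel(nbrs, ncnt, perms, out):  # pragma: no cover - numba
    """Backtracking over directed Hamiltonian chains; store canonical reps.

    A chain is canonical when no point-group image of its cell sequence is
    lexicographically smaller.  DFS visits cell sequences in lexicographic
    order, so canonical representatives are produced sorted and the search
    may stop early once ``out`` is full.
    """
    limit = out.shape[0]
    found = 0
    path = np.empty(27, dtype=np.int64)
    used = np.zeros(27, dtype=np.bool_)
    pos = np.empty(28, dtype=np.int64)
    for start in range(27):
        path[0] = start
        used[start] = True
        depth = 0
        pos[0] = 0
        while depth >= 0:
            if depth == 26:
                canonical = True
                for g in range(perms.shape[0]):
                    cmp = 0
                    for t in range(27):
                        q = perms[g, path[t]]
                        if q < path[t]:
                            cmp = -1
                            break
                        elif q > path[t]:
                            cmp = 1
                            break
                    if cmp == -1:
                        canonical = False
                        break
                if canonical:
                    for t in range(27):
                        out[found, t] = path[t]
                    found += 1
                    if found == limit:
                        return found
                used[path[depth]] = False
                depth -= 1
                continue
            cur = path[depth]
            advanced = False
            k = pos[depth]
            while k < ncnt[cur]:
                nxt = nbrs[cur, k]
                k += 1
                if not used[nxt]:
                    pos[depth] = k
                    depth += 1
                    path[depth] = nxt
                    used[nxt] = True
                    pos[depth] = 0
                    advanced = True
                    break
            if not advanced:
                used[cur] = False
                depth -= 1
        used[:] = False
    return found


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyModel:
    """Pairwise residue contact potential plus environmental temperature.

    ``contact_energy`` is indexed by :data:`AA_ALPHABET` order on both axes.
    """

    contact_energy: np.ndarray
    temperature: float
    version: str = "custom"

    def __post_init__(self) -> None:
        e = np.asarray(self.contact_energy, dtype=np.float64)
        if e.shape != (20, 20):
            raise ValueError("contact_energy must be 20x20")
        if not np.allclose(e, e.T):
            raise ValueError("contact_energy must be symmetric")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "contact_energy", e)

    def at_temperature(self, temperature: float) -> "EnergyModel":
        return EnergyModel(self.contact_energy, temperature, self.version)


def load_mj_energy_model(temperature: float = 0.85) -> EnergyModel:
    """Load the shipped Miyazawa–Jernigan style contact table.

    The file stores the matrix in its original residue order; it is
    re-indexed here to :data:`AA_ALPHABET` order.
    """
    ref = importlib.resources.files("mutatorsim.data").joinpath(
        "mj1996_contact_energies.txt"
    )
    lines = ref.read_text().splitlines()
    header = [ln for ln in lines if ln.startswith("#")]
    order = header[-1][1:].split()
    version = "unknown"
    for ln in header:
        if "version:" in ln:
            version = ln.split("version:")[1].strip()
    rows = [ln for ln in lines if ln and not ln.startswith("#")]
    raw = np.array([[float(v) for v in ln.split()] for ln in rows])
    perm = [order.index(a) for a in AA_ALPHABET]
    table = raw[np.ix_(perm, perm)]
    return EnergyModel(table, temperature, version=version)


def encode_sequence(aa_seq: str) -> np.ndarray:
    """Encode a 27-residue sequence as int8 indices into AA_ALPHABET."""
    try:
        return np.array([_AA_INDEX[a] for a in aa_seq], dtype=np.int8)
    except KeyError as exc:  # invalid residue letter
        raise AlphabetError(f"invalid residue {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# conformation set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConformationSet:
    """Symmetry-distinct compact conformations as chains plus contact maps.

    ``paths[c, t]`` is the cube cell occupied by residue ``t`` of
    conformation ``c``; ``contact_maps[c]`` lists the 28 non-bonded
    nearest-neighbour residue pairs (i < j, j > i+1); ``occupants[c, s]``
    inverts ``paths``: the residue position sitting at cell ``s``.
    ``indices`` records provenance into the full canonical enumeration.
    """

    paths: np.ndarray
    contact_maps: np.ndarray
    occupants: np.ndarray
    indices: np.ndarray

    @property
    def count(self) -> int:
        return self.paths.shape[0]

    def __len__(self) -> int:
        return self.count

    def subset(self, idx: np.ndarray) -> "ConformationSet":
        idx = np.asarray(idx)
        return ConformationSet(
            self.paths[idx],
            self.contact_maps[idx],
            self.occupants[idx],
            self.indices[idx],
        )

    @staticmethod
    def from_paths(paths: np.ndarray, indices: np.ndarray | None = None) -> "ConformationSet":
        paths = np.ascontiguousarray(paths, dtype=np.int8)
        n = paths.shape[0]
        occupants = np.empty_like(paths)
        occupants[np.arange(n)[:, None], paths.astype(np.intp)] = np.arange(
            _N_SITES, dtype=np.int8
        )
        # candidate non-bonded residue pairs (i < j, j > i + 1)
        pi, pj = np.triu_indices(_N_SITES, k=2)
        contact = _ADJACENT[
            paths[:, pi].astype(np.intp), paths[:, pj].astype(np.intp)
        ]
        counts = contact.sum(axis=1)
        if not np.all(counts == _N_CONTACTS):
            bad = int(np.flatnonzero(counts != _N_CONTACTS)[0])
            raise ValueError(
                f"conformation {bad} has {int(counts[bad])} contacts, expected 28"
            )
        rows, cols = np.nonzero(contact)
        cmaps = np.empty((n, _N_CONTACTS, 2), dtype=np.int8)
        cmaps[:, :, 0] = pi[cols].reshape(n, _N_CONTACTS)
        cmaps[:, :, 1] = pj[cols].reshape(n, _N_CONTACTS)
        if indices is None:
            indices = np.arange(n, dtype=np.int64)
        return ConformationSet(paths, cmaps, occupants, np.asarray(indices, dtype=np.int64))


def enumerate_compact_conformations(limit: int | None = None) -> ConformationSet:
    """Enumerate canonical compact conformations in deterministic order.

    With ``limit`` the search stops after the first ``limit`` canonical
    chains (the lexicographically smallest representatives), which makes
    small deterministic structure sets cheap to build for tests and
    scaled-down simulations.  Without it the full canonical set of
    103,346 conformations is returned (≈30 s of compiled backtracking).
    """
    cap = N_COMPACT_CONFORMATIONS if limit is None else int(limit)
    if not 1 <= cap <= N_COMPACT_CONFORMATIONS:
        raise SizeError(f"limit must be in [1, {N_COMPACT_CONFORMATIONS}]")
    out = np.empty((cap, _N_SITES), dtype=np.int8)
    found = _enumerate_kernel(_NBRS, _NCNT, _SYM_PERMS, out)
    return ConformationSet.from_paths(out[:found])


def count_compact_conformations() -> int:
    """Full enumeration, returning only the canonical count."""
    return enumerate_compact_conformations().count


def sample_structure_set(full: ConformationSet, n: int, rng_seed: int) -> ConformationSet:
    """Uniform random subset without replacement; deterministic in the seed."""
    if not 1 <= n <= full.count:
        raise SizeError(f"subset size {n} out of range [1, {full.count}]")
    rng = np.random.default_rng(rng_seed)
    idx = np.sort(rng.choice(full.count, size=n, replace=False))
    return full.subset(idx)


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

@njit(cache=True)
def _conf_energies(contact_maps, seq_idx, table):  # pragma: no cover - numba
    n = contact_maps.shape[0]
    out = np.empty(n, dtype=np.float64)
    for c in range(n):
        e = 0.0
        for k in range(contact_maps.shape[1]):
            a = seq_idx[contact_maps[c, k, 0]]
            b = seq_idx[contact_maps[c, k, 1]]
            e += table[a, b]
        out[c] = e
    return out


@dataclass(frozen=True)
class ProteinState:
    """A folded 27-mer: sequence, native conformation, and stability.

    ``energies`` keeps the per-conformation energy spectrum so that P_nat
    can be re-evaluated instantly at a new temperature (the spectrum itself
    is temperature independent).
    """

    aa_seq: str
    seq_idx: np.ndarray = field(repr=False)
    energies: np.ndarray = field(repr=False)
    native_index: int
    E0: float
    p_nat: float
    temperature: float

    def at_temperature(self, temperature: float) -> "ProteinState":
        p = _p_native(self.energies, self.E0, temperature)
        return ProteinState(
            self.aa_seq, self.seq_idx, self.energies,
            self.native_index, self.E0, p, temperature,
        )


def _p_native(energies: np.ndarray, e0: float, temperature: float) -> float:
    log_z = logsumexp(-energies / temperature)
    return float(np.exp(-e0 / temperature - log_z))


def fold(aa_seq: str, conf_set: ConformationSet, em: EnergyModel) -> ProteinState:
    """Fold a sequence over a conformation set.

    The native state is the minimum-energy conformation (ties broken to the
    lowest index); P_nat is its Boltzmann weight within the set.
    """
    if len(aa_seq) != _N_SITES:
        raise ValueError("sequence must have 27 residues")
    seq_idx = encode_sequence(aa_seq)
    energies = _conf_energies(conf_set.contact_maps, seq_idx, em.contact_energy)
    native = int(np.argmin(energies))
    e0 = float(energies[native])
    return ProteinState(
        aa_seq, seq_idx, energies, native, e0,
        _p_native(energies, e0, em.temperature), em.temperature,
    )


# ---------------------------------------------------------------------------
# docking geometry
# ---------------------------------------------------------------------------

_FACE_NORMALS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)


def _proper_rotations() -> list[np.ndarray]:
    rots = []
    for axes in itertools.permutations(range(3)):
        m = np.zeros((3, 3), dtype=np.int64)
        for k in range(3):
            m[k, axes[k]] = 1
        for signs in itertools.product((1, -1), repeat=3):
            r = np.diag(signs) @ m
            if round(np.linalg.det(r)) == 1:
                rots.append(r)
    return rots


_ROTATIONS = _proper_rotations()


@dataclass(frozen=True)
class DockingMode:
    """One rigid face-to-face docking arrangement of two compact proteins.

    ``interface_pairs[k] = (cell_i, cell_j)`` gives the 9 touching cube
    cells, in each protein's own frame, across the interface.
    """

    face_i: int
    face_j: int
    rotation: int
    interface_pairs: np.ndarray


def _build_docking_modes() -> list[DockingMode]:
    modes: list[DockingMode] = []
    centre = np.array([1, 1, 1])
    for fi in range(6):
        n_i = _FACE_NORMALS[fi]
        # 3x3 sites on this face of cube i, deterministic order
        face_sites = [
            s for s in range(_N_SITES)
            if np.dot(_COORDS[s] - centre, n_i) == 1
        ]
        for fj in range(6):
            n_j = _FACE_NORMALS[fj]
            k = 0
            for rot in _ROTATIONS:
                if not np.array_equal(rot @ n_j, -n_i):
                    continue
                # cube j sits adjacent to face fi of cube i
                centre_j = centre + 3 * n_i
                pairs = np.empty((9, 2), dtype=np.int8)
                for t, s in enumerate(face_sites):
                    w = _COORDS[s] + n_i  # facing world position
                    u = rot.T @ (w - centre_j) + centre
                    pairs[t, 0] = s
                    pairs[t, 1] = _CELL_OF[tuple(int(v) for v in u)]
                modes.append(DockingMode(fi, fj, k, pairs))
                k += 1
            assert k == 4
    assert len(modes) == N_DOCKING_MODES
    return modes


_DOCKING_MODES: list[DockingMode] | None = None
_MODE_PAIRS: np.ndarray | None = None


def enumerate_docking_modes() -> list[DockingMode]:
    """The 144 rigid docking modes (6 faces x 6 faces x 4 rotations)."""
    global _DOCKING_MODES
    if _DOCKING_MODES is None:
        _DOCKING_MODES = _build_docking_modes()
    return _DOCKING_MODES


def _mode_pairs() -> np.ndarray:
    global _MODE_PAIRS
    if _MODE_PAIRS is None:
        _MODE_PAIRS = np.stack([m.interface_pairs for m in enumerate_docking_modes()])
    return _MODE_PAIRS


# ---------------------------------------------------------------------------
# binding
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mode_energies(mode_pairs, occ_i, occ_j, seq_i, seq_j, table):  # pragma: no cover
    n = mode_pairs.shape[0]
    out = np.empty(n, dtype=np.float64)
    for m in range(n):
        e = 0.0
        for k in range(mode_pairs.shape[1]):
            ri = seq_i[occ_i[mode_pairs[m, k, 0]]]
            rj = seq_j[occ_j[mode_pairs[m, k, 1]]]
            e += table[ri, rj]
        out[m] = e
    return out


def binding_mode_energies(
    state_i: ProteinState,
    state_j: ProteinState,
    conf_set: ConformationSet,
    em: EnergyModel,
) -> np.ndarray:
    """Interface energies of all 144 docking modes for two folded proteins."""
    occ_i = conf_set.occupants[state_i.native_index]
    occ_j = conf_set.occupants[state_j.native_index]
    return _mode_energies(
        _mode_pairs(), occ_i, occ_j, state_i.seq_idx, state_j.seq_idx,
        em.contact_energy,
    )


def _binding_thermo(
    energies: np.ndarray, temperature: float, k_convention: str
) -> tuple[float, float, float]:
    e_min = float(energies.min())
    log_z = logsumexp(-energies / temperature)
    p_int = float(np.exp(-e_min / temperature - log_z))
    if k_convention == "min":
        k = float(np.exp(-e_min / temperature))
    elif k_convention == "mode_sum":
        k = float(np.exp(log_z))
    else:
        raise ValueError(f"unknown binding-constant convention {k_convention!r}")
    return e_min, p_int, k


def bind(
    state_i: ProteinState,
    state_j: ProteinState,
    conf_set: ConformationSet,
    em: EnergyModel,
    k_convention: str = "min",
) -> tuple[float, float, float]:
    """Dock two folded proteins over all 144 modes.

    Returns ``(E_int_min, p_int, K)``: the minimum interface energy, the
    Boltzmann probability of the minimum-energy (native) mode, and the
    binding constant.  The default convention takes K = exp(-E_int_min/T)
    in a unit reference-concentration convention; ``mode_sum`` uses the
    full mode partition function instead.
    """
    e = binding_mode_energies(state_i, state_j, conf_set, em)
    return _binding_thermo(e, em.temperature, k_convention)


@dataclass(frozen=True)
class InteractionTable:
    """All pairwise binding thermodynamics for a cell's four proteins.

    ``mode_energies[i, j]`` keeps the 144-mode spectrum so the table can be
    re-evaluated at a new temperature without re-docking.
    """

    E_int: np.ndarray
    p_int: np.ndarray
    K: np.ndarray
    mode_energies: np.ndarray = field(repr=False)
    k_convention: str = "min"

    def at_temperature(self, temperature: float) -> "InteractionTable":
        n = self.E_int.shape[0]
        e_int = np.empty_like(self.E_int)
        p_int = np.empty_like(self.p_int)
        kmat = np.empty_like(self.K)
        for i in range(n):
            for j in range(i, n):
                e, p, k = _binding_thermo(
                    self.mode_energies[i, j], temperature, self.k_convention
                )
                e_int[i, j] = e_int[j, i] = e
                p_int[i, j] = p_int[j, i] = p
                kmat[i, j] = kmat[j, i] = k
        return InteractionTable(e_int, p_int, kmat, self.mode_energies, self.k_convention)

    def replace_protein(
        self,
        idx: int,
        states: tuple[ProteinState, ...],
        conf_set: ConformationSet,
        em: EnergyModel,
    ) -> "InteractionTable":
        """Recompute only the row/column touching protein ``idx``."""
        e_int = self.E_int.copy()
        p_int = self.p_int.copy()
        kmat = self.K.copy()
        mode_e = self.mode_energies.copy()
        for j in range(len(states)):
            a, b = min(idx, j), max(idx, j)
            spec = binding_mode_energies(states[a], states[b], conf_set, em)
            mode_e[a, b] = mode_e[b, a] = spec
            e, p, k = _binding_thermo(spec, em.temperature, self.k_convention)
            e_int[a, b] = e_int[b, a] = e
            p_int[a, b] = p_int[b, a] = p
            kmat[a, b] = kmat[b, a] = k
        return InteractionTable(e_int, p_int, kmat, mode_e, self.k_convention)


def build_interaction_table(
    states: tuple[ProteinState, ...],
    conf_set: ConformationSet,
    em: EnergyModel,
    k_convention: str = "min",
) -> InteractionTable:
    n = len(states)
    e_int = np.empty((n, n))
    p_int = np.empty((n, n))
    kmat = np.empty((n, n))
    mode_e = np.empty((n, n, N_DOCKING_MODES))
    for i in range(n):
        for j in range(i, n):
            spec = binding_mode_energies(states[i], states[j], conf_set, em)
            mode_e[i, j] = mode_e[j, i] = spec
            e, p, k = _binding_thermo(spec, em.temperature, k_convention)
            e_int[i, j] = e_int[j, i] = e
            p_int[i, j] = p_int[j, i] = p
            kmat[i, j] = kmat[j, i] = k
    return InteractionTable(e_int, p_int, kmat, mode_e, k_convention)
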