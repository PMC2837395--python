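"""Persistence: trajectories, genomes, the conformation cache, fixtures."""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cell import Genome
from .evolution import EVENT_COLUMNS, SERIES_COLUMNS, Trajectory

__all__ = [
    "FormatError",
    "write_trajectory",
    "read_trajectory",
    "write_genome_fasta",
    "read_genome_fasta",
    "cached_full_enumeration",
    "make_fixture",
]

SCHEMA_VERSION = 1


class FormatError(RuntimeError):
    """Trajectory on disk is truncated or from an incompatible schema."""


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a directory of CSV tables plus metadata.

    Row counts are recorded so that truncation is detectable on read.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips float64 exactly through text
    traj.series.to_csv(path / "series.csv", index=False, float_format="%.17g")
    traj.events.to_csv(path / "events.csv", index=False, float_format="%.17g")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n_series_rows": int(len(traj.series)),
        "n_event_rows": int(len(traj.events)),
        "meta": _jsonable(traj.meta),
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    try:
        with open(path / "meta.json") as fh:
            meta = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"unreadable trajectory metadata: {exc}") from exc
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"schema version {meta.get('schema_version')} != {SCHEMA_VERSION}"
        )
    series = pd.read_csv(path / "series.csv", float_precision="round_trip")
    events = pd.read_csv(path / "events.csv", float_precision="round_trip")
    if list(series.columns) != SERIES_COLUMNS or list(events.columns) != EVENT_COLUMNS:
        raise FormatError("unexpected trajectory column schema")
    if len(series) != meta["n_series_rows"] or len(events) != meta["n_event_rows"]:
        raise FormatError("trajectory tables are truncated")
    return Trajectory(series, events, meta["meta"])


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: Genome, path, annotations: dict | None = None) -> None:
    """Four records per cell; the gene index lives in the record id."""
    ann = annotations or {}
    records = []
    for i, gene in enumerate(genome.genes):
        desc = " ".join(f"{k}={v}" for k, v in ann.items())
        records.append(SeqRecord(Seq(gene), id=f"gene{i + 1}", description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path) -> Genome:
    records = sorted(SeqIO.parse(str(path), "fasta"), key=lambda r: r.id)
    if len(records) != 4:
        raise FormatError(f"expected 4 gene records, found {len(records)}")
    return Genome(tuple(str(r.seq) for r in records))


# ---------------------------------------------------------------------------
# conformation cache
# ---------------------------------------------------------------------------

def _cache_dir() -> Path:
    base = os.environ.get("MUTATORSIM_CACHE", None)
    if base:
        return Path(base)
    return Path.home() / ".cache" / "mutatorsim"


def cached_full_enumeration():
    """Full canonical enumeration, memoised on disk.

    The cache key hashes the enumeration convention so a stale cache is
    regenerated rather than silently reused.
    """
    from . import lattice

    key = hashlib.sha256(
        f"v{SCHEMA_VERSION}:48sym:lex:{lattice.N_COMPACT_CONFORMATIONS}".encode()
    ).hexdigest()[:12]
    path = _cache_dir() / f"conformations_{key}.npz"
    if path.exists():
        try:
            paths = np.load(path)["paths"]
            if paths.shape == (lattice.N_COMPACT_CONFORMATIONS, 27):
                return lattice.ConformationSet.from_paths(paths)
        except Exception:
            pass  # fall through and regenerate
    cs = lattice.enumerate_compact_conformations()
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, paths=cs.paths)
    return cs


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, rng_seed: int = 0):
    """Deterministic small objects for tests and examples.

    kinds: tiny_structure_set (200 conformations), toy_cell,
    toy_population, constructed_event_log.
    """
    from . import cell as cm
    from .config import RunConfig
    from .design import DesignConfig, design_seed_genome
    from .evolution import Population
    from .lattice import enumerate_compact_conformations, load_mj_energy_model

    rng = np.random.default_rng(rng_seed)
    if kind == "tiny_structure_set":
        return enumerate_compact_conformations(limit=200)
    if kind in ("toy_cell", "toy_population"):
        conf_set = enumerate_compact_conformations(limit=200)
        em = load_mj_energy_model(0.85)
        env = cm.CellEnv(conf_set, em)
        genome, _ = design_seed_genome(conf_set, em, DesignConfig(), rng)
        params = RunConfig().fitness_params()
        seed, reason = cm.develop(genome, np.full(4, 0.1), env, params)
        assert seed is not None, reason
        import dataclasses

        params = dataclasses.replace(
            params, G_ref=seed.G44, b0=params.d / (seed.G1 * seed.G23)
        )
        seed, _ = cm.develop(genome, np.full(4, 0.1), env, params)
        if kind == "toy_cell":
            return seed, params, env
        cells = [cm.clone(seed, i + 1) for i in range(50)]
        return Population(cells, params, env, cap=100,
                          rng=np.random.default_rng(rng_seed), record_every=5)
    if kind == "constructed_event_log":
        # a log whose transition causes are known by construction:
        # one stress-driven (Env) M-wave, one mutational W-wave
        series = pd.DataFrame({
            "t": [0, 10, 20, 30, 40, 50, 60],
            "mutator_freq": [0.0, 0.1, 0.8, 0.9, 0.6, 0.2, 0.1],
        })
        events = pd.DataFrame([
            (15, "Env", -1, 1, False, True, ""),
            (15, "Env", -1, 2, False, True, ""),
            (45, "Mut", 3, 1, True, False, ""),
            (45, "Mut", 3, 2, True, False, ""),
            (48, "SS", 3, 3, True, False, ""),
        ], columns=EVENT_COLUMNS)
        return Trajectory(series, events, {"constructed": True})
    raise ValueError(f"unknown fixture kind {kind!r}")
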