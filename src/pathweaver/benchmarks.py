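"""Published benchmark transitions: registry, retrieval and measurements.

Five crystallographic open/closed pairs are commonly used to exercise
conformational pathway samplers: calmodulin (1CLL/1CTR and 2F3Y/1CFD),
adenylate kinase (1AKE/4AKE), cyanovirin-N (2EZM/1L5E) and the E. coli
ribose-binding protein (2DRI/1URP).  This module knows how to fetch the
entries from the PDB, load them through the coarse-grained parser and
compute the standard comparisons (initial CA-lRMSD, residue counts, full
pathway runs).  The structures themselves are not distributed with the
package; :func:`ensure_benchmark_files` downloads them on first use into a
local cache directory.
"""

from __future__ import annotations

import pathlib
import urllib.request

from .kinematics import Conformation, lrmsd
from .search import PathResult, SearchConfig, run_search
from .structure import Structure, pair_residues, read_structure

__all__ = [
    "BENCHMARK_PAIRS",
    "BenchmarkUnavailable",
    "default_cache_dir",
    "ensure_benchmark_files",
    "load_benchmark_structure",
    "initial_lrmsd",
    "residue_count",
    "run_benchmark_search",
]

PDB_DOWNLOAD_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"

# name -> (start_id, start_chain, goal_id, goal_chain)
BENCHMARK_PAIRS: dict[str, tuple[str, str, str, str]] = {
    "calmodulin_open_closed": ("1CLL", "A", "1CTR", "A"),
    "calmodulin_apo_iq": ("2F3Y", "A", "1CFD", "A"),
    "adenylate_kinase": ("1AKE", "A", "4AKE", "A"),
    "cyanovirin_n": ("2EZM", "A", "1L5E", "A"),
    "ribose_binding_protein": ("2DRI", "A", "1URP", "A"),
}


class BenchmarkUnavailable(RuntimeError):
    """Raised when a benchmark structure is neither cached nor fetchable."""


def default_cache_dir() -> pathlib.Path:
    return pathlib.Path(__file__).resolve().parents[2] / "benchmarks" / "pdb"


def ensure_benchmark_files(
    pdb_ids, cache_dir: pathlib.Path | None = None, timeout: float = 60.0
) -> dict[str, pathlib.Path]:
    """Return ``{pdb_id: path}`` for the requested entries, downloading any
    that are missing from the cache directory.

    Raises :class:`BenchmarkUnavailable` with a precise message when an
    entry cannot be obtained (e.g. no network access).
    """
    cache_dir = cache_dir or default_cache_dir()
    cache_dir.mkdir(parents=True, exist_ok=True)
    out = {}
    for pdb_id in pdb_ids:
        path = cache_dir / f"{pdb_id.upper()}.pdb"
        if not path.exists():
            url = PDB_DOWNLOAD_URL.format(pdb_id=pdb_id.upper())
            try:
                with urllib.request.urlopen(url, timeout=timeout) as resp:
                    path.write_bytes(resp.read())
            except Exception as exc:
                raise BenchmarkUnavailable(
                    f"benchmark structure {pdb_id} is not cached at {path} and could "
                    f"not be downloaded from {url}: {exc}. Place the PDB file there "
                    "manually to run the published-benchmark comparisons."
                ) from exc
        out[pdb_id] = path
    return out


def load_benchmark_structure(
    pdb_id: str, chain_id: str, cache_dir: pathlib.Path | None = None
) -> Structure:
    path = ensure_benchmark_files([pdb_id], cache_dir)[pdb_id]
    return read_structure(path.read_text(), chain_id)


def initial_lrmsd(pair_name: str, cache_dir: pathlib.Path | None = None) -> float:
    """CA-lRMSD between the start and goal structures of a registered pair."""
    start_id, start_chain, goal_id, goal_chain = BENCHMARK_PAIRS[pair_name]
    start = load_benchmark_structure(start_id, start_chain, cache_dir)
    goal = load_benchmark_structure(goal_id, goal_chain, cache_dir)
    pairing = pair_residues(start, goal)
    return lrmsd(start, goal, pairing)


def residue_count(pdb_id: str, chain_id: str = "A", cache_dir: pathlib.Path | None = None) -> int:
    """Number of complete residues the coarse-grained parser retains."""
    return load_benchmark_structure(pdb_id, chain_id, cache_dir).n_residues


def run_benchmark_search(
    pair_name: str,
    config: SearchConfig | None = None,
    reverse: bool = False,
    cache_dir: pathlib.Path | None = None,
) -> PathResult:
    """Run the full pathway search on a registered benchmark pair."""
    start_id, start_chain, goal_id, goal_chain = BENCHMARK_PAIRS[pair_name]
    if reverse:
        start_id, start_chain, goal_id, goal_chain = goal_id, goal_chain, start_id, start_chain
    start = Conformation(load_benchmark_structure(start_id, start_chain, cache_dir))
    goal = Conformation(load_benchmark_structure(goal_id, goal_chain, cache_dir))
    return run_search(start, goal, config or SearchConfig())
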