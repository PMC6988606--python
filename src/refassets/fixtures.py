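"""Seeded synthetic data and in-process harness helpers.

Everything here derives solely from its seed and parameters — no clock,
no hostname — so reruns are byte-identical.  The random source is
Python's :class:`random.Random` (the Mersenne Twister, MT19937), a
named, widely implemented PRNG.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Dict, List, Tuple

from .build import BuildRequest, build_asset
from .config import GenomeConfig, init_config, list_local, write_config
from .exceptions import RefAssetsError
from .registry import AssetRegistryPath
from .server import ArchiveEntry, AssetServer, serve

_ALPHABET = "ACGTN"


def generate_fasta(
    n_records: int,
    length_range: Tuple[int, int],
    line_width: int = 60,
    seed: int = 0,
) -> str:
    """Deterministic synthetic FASTA text with records ``chr1..chrN``."""
    lo, hi = length_range
    if n_records < 1:
        raise RefAssetsError(f"n_records must be >= 1, got {n_records}")
    if lo < 1 or hi < lo:
        raise RefAssetsError(f"invalid length range: ({lo}, {hi})")
    if line_width < 1:
        raise RefAssetsError(f"line width must be >= 1, got {line_width}")
    rng = random.Random(seed)
    chunks: List[str] = []
    for i in range(1, n_records + 1):
        length = rng.randint(lo, hi)
        seq = "".join(rng.choice(_ALPHABET) for _ in range(length))
        chunks.append(f">chr{i}")
        for start in range(0, length, line_width):
            chunks.append(seq[start : start + line_width])
    return "\n".join(chunks) + "\n"


def write_fasta(
    path: Path,
    n_records: int,
    length_range: Tuple[int, int],
    line_width: int = 60,
    seed: int = 0,
) -> Path:
    path.write_text(
        generate_fasta(n_records, length_range, line_width, seed), encoding="utf-8"
    )
    return path


def make_populated_config(
    tmp_root: Path,
    n_genomes: int = 1,
    n_assets: int = 1,
    seed: int = 0,
) -> Tuple[Path, Dict[str, List[str]]]:
    """Build fasta assets for synthetic genomes; return (config path, listing).

    Each genome gets a built ``fasta`` asset under the default tag;
    ``n_assets`` beyond 1 adds further builds of the same asset under
    tags ``v2, v3, ...``.  The returned listing is the ground truth for
    ``list_local`` assertions.
    """
    tmp_root = Path(tmp_root)
    config_path = tmp_root / "config.yaml"
    config = init_config(config_path, tmp_root / "genomes")
    expected: Dict[str, List[str]] = {}
    rng = random.Random(seed)
    for g in range(1, n_genomes + 1):
        genome = f"genome{g}"
        fasta_in = tmp_root / f"{genome}.fa"
        write_fasta(fasta_in, n_records=2, length_range=(50, 120), seed=rng.randrange(2**31))
        tags = ["default"] + [f"v{j}" for j in range(2, n_assets + 1)]
        for tag in tags:
            build_asset(
                config,
                BuildRequest(
                    AssetRegistryPath(genome, "fasta", tag),
                    files={"fasta": str(fasta_in)},
                ),
            )
        expected[genome] = sorted(f"fasta:{t}" for t in tags)
    write_config(config, config_path)
    assert list_local(config) == expected
    return config_path, expected


def ephemeral_server(
    entries: List[ArchiveEntry], config: GenomeConfig
) -> AssetServer:
    """In-process archive server on an OS-assigned port.

    Returns a started :class:`AssetServer`; call ``.stop()`` (or use it
    as a context manager) to release the port.
    """
    return serve(entries, config, host="127.0.0.1", port=0)
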