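from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict

import pytest

from refassets import BuildRequest, build_asset, init_config, load_config, write_config
from refassets.fixtures import ephemeral_server, write_fasta
from refassets.registry import AssetRegistryPath
from refassets.server import archive_assets


def snapshot_tree(root: Path) -> Dict[str, str]:
    """Relative path → content hash for every file under *root*."""
    out = {}
    for p in sorted(Path(root).rglob("*")):
        if p.is_file():
            out[p.relative_to(root).as_posix()] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    return out


@pytest.fixture
def fresh_config(tmp_path):
    """An initialized, empty configuration."""
    return init_config(tmp_path / "config.yaml", tmp_path / "genomes")


@pytest.fixture
def fasta_input(tmp_path):
    return write_fasta(
        tmp_path / "input.fa", n_records=2, length_range=(40, 90), seed=11
    )


@pytest.fixture
def built_config(fresh_config, fasta_input):
    """Config with hg38/fasta:default built from a synthetic genome."""
    build_asset(
        fresh_config,
        BuildRequest(
            AssetRegistryPath("hg38", "fasta"), files={"fasta": str(fasta_input)}
        ),
    )
    write_config(fresh_config)
    return fresh_config


@pytest.fixture
def served(built_config):
    """(server, entries, config) for an archived built_config."""
    entries = archive_assets(built_config)
    server = ephemeral_server(entries, built_config)
    yield server, entries, built_config
    server.stop()
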