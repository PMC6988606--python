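"""Asset identity and traceability: content digests, build logs, recipe text.

Digest construction (documented bit-exactly so other implementations can
reproduce it):

1. Enumerate every regular file under the asset directory, recursively.
   Paths are taken relative to the asset directory and normalized to
   forward slashes.  Files whose basename starts with ``_build_log`` are
   excluded, so the digest can itself be recorded inside the log.
2. Hash each file's raw bytes with SHA-256 (streamed; no newline or
   encoding normalization — assets are binary-opaque).
3. Sort the (relative path, file hex digest) pairs by relative path and
   feed them into a fresh SHA-256 as ``<path>\\0<hexdigest>\\n`` encoded
   as UTF-8.

The asset digest is the final hex digest.  An empty directory therefore
hashes the empty byte sequence:
``e3b0c44298fc1c149afbf4c8996fb92427ae41e4649b934ca495991b7852b855``.
The digest depends only on relative paths and contents — never on the
absolute location, the name of the asset directory itself, timestamps,
or the order the filesystem enumerates entries in.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import yaml

from .exceptions import RefAssetsError

#: Fixed name of the provenance record inside an asset directory.
BUILD_LOG_NAME = "_build_log.yaml"

#: Prefix of files excluded from digest computation.
_LOG_PREFIX = "_build_log"

#: Number of hex characters shown in human-facing short digests.
SHORT_DIGEST_LEN = 32

_CHUNK = 1 << 20


class AssetDigest(str):
    """Lowercase hex SHA-256 digest of an asset directory's contents."""

    @property
    def short(self) -> str:
        return self[:SHORT_DIGEST_LEN]


def compute_file_digest(path: os.PathLike | str) -> str:
    """SHA-256 of a single file's bytes, streamed."""
    h = hashlib.sha256()
    try:
        with open(path, "rb") as fh:
            while chunk := fh.read(_CHUNK):
                h.update(chunk)
    except OSError as exc:
        raise RefAssetsError(f"cannot read file for digest: {path}: {exc}") from exc
    return h.hexdigest()


def compute_asset_digest(asset_dir: os.PathLike | str) -> AssetDigest:
    """Digest of an asset directory per the canonical construction above.

    Raises
    ------
    RefAssetsError
        If the directory does not exist or a file is unreadable (the
        error names the file).
    """
    root = Path(asset_dir)
    if not root.is_dir():
        raise RefAssetsError(f"not a directory: {asset_dir}")
    pairs: List[Tuple[str, str]] = []
    for dirpath, dirnames, filenames in os.walk(root):
        dirnames.sort()
        for name in filenames:
            if name.startswith(_LOG_PREFIX):
                continue
            full = Path(dirpath) / name
            rel = full.relative_to(root).as_posix()
            pairs.append((rel, compute_file_digest(full)))
    pairs.sort()
    h = hashlib.sha256()
    for rel, digest in pairs:
        h.update(f"{rel}\0{digest}\n".encode("utf-8"))
    return AssetDigest(h.hexdigest())


@dataclass
class BuildLog:
    """Provenance record written alongside every built asset."""

    registry_path: str
    recipe_name: str
    recipe_version: str
    inputs: List[Tuple[str, str, str]] = field(default_factory=list)
    software_versions: Dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    asset_digest: str = ""

    def to_dict(self) -> dict:
        return {
            "registry_path": self.registry_path,
            "recipe_name": self.recipe_name,
            "recipe_version": self.recipe_version,
            "inputs": [
                {"name": n, "path": p, "digest": d} for (n, p, d) in self.inputs
            ],
            "software_versions": dict(self.software_versions),
            "started": self.started,
            "finished": self.finished,
            "asset_digest": self.asset_digest,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BuildLog":
        return cls(
            registry_path=data["registry_path"],
            recipe_name=data["recipe_name"],
            recipe_version=data["recipe_version"],
            inputs=[
                (i["name"], i["path"], i["digest"]) for i in data.get("inputs", [])
            ],
            software_versions=dict(data.get("software_versions", {})),
            started=data.get("started", ""),
            finished=data.get("finished", ""),
            asset_digest=data.get("asset_digest", ""),
        )


def write_build_log(asset_dir: os.PathLike | str, log: BuildLog) -> Path:
    """Write *log* as YAML under the digest-excluded name; return its path."""
    path = Path(asset_dir) / BUILD_LOG_NAME
    path.write_text(
        yaml.safe_dump(log.to_dict(), sort_keys=True, default_flow_style=False),
        encoding="utf-8",
    )
    return path


def read_build_log(asset_dir: os.PathLike | str) -> BuildLog:
    path = Path(asset_dir) / BUILD_LOG_NAME
    if not path.is_file():
        raise RefAssetsError(f"no provenance: build log not found in {asset_dir}")
    return BuildLog.from_dict(yaml.safe_load(path.read_text(encoding="utf-8")))


def serialize_recipe(recipe) -> str:
    """Deterministic, key-sorted YAML rendering of a recipe.

    Equal recipes serialize byte-identically; any declared difference
    (including descriptions) changes the output.
    """
    return yaml.safe_dump(
        recipe.to_dict(), sort_keys=True, default_flow_style=False
    )
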