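"""HTTP client: discover remote assets and pull them with verification.

Servers are tried in configured order; the first to respond wins.  A
pull streams the tarball to a temporary file, checks its bytes against
the advertised archive digest, unpacks into a temporary directory,
recomputes the asset digest against the advertised one, and only then
moves the tree into ``{genome_folder}/{genome}/{asset}/{tag}/`` and
registers it.  Any failure removes the temporaries, leaving both the
genome folder and the configuration untouched.
"""

from __future__ import annotations

import hashlib
import shutil
import tarfile
import tempfile
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import requests

from .config import (
    GenomeConfig,
    TagEntry,
    register_tag_entry,
)
from .exceptions import IntegrityError, MissingEntryError, NetworkError, RefAssetsError
from .provenance import BUILD_LOG_NAME, compute_asset_digest
from .registry import AssetRegistryPath

_TIMEOUT = 30.0
_CHUNK = 1 << 16


def list_remote(servers: List[str], timeout: float = _TIMEOUT) -> Dict[str, List[str]]:
    """Union of remote listings; first-listed server wins on genome conflicts.

    Per-server failures are tolerated as long as at least one server
    responds; if all fail a :class:`NetworkError` lists every attempt.
    """
    if not servers:
        raise NetworkError("no genome servers configured")
    result: Dict[str, List[str]] = {}
    failures: List[str] = []
    any_success = False
    for server in servers:
        url = server.rstrip("/") + "/v2/assets"
        try:
            resp = requests.get(url, timeout=timeout)
            resp.raise_for_status()
            listing = resp.json()
        except (requests.RequestException, ValueError) as exc:
            failures.append(f"{url}: {exc}")
            continue
        any_success = True
        for genome, assets in listing.items():
            result.setdefault(genome, list(assets))
    if not any_success:
        raise NetworkError(
            "all genome servers unreachable: " + "; ".join(failures)
        )
    return result


def _fetch_attributes(
    servers: List[str], p: AssetRegistryPath, timeout: float
) -> Tuple[str, dict]:
    """First server that has the asset wins; returns (server, attributes)."""
    not_found: Optional[Tuple[str, str]] = None  # (level, message)
    failures: List[str] = []
    for server in servers:
        base = server.rstrip("/")
        url = f"{base}/v2/asset/{p.genome}/{p.asset}/attributes"
        try:
            resp = requests.get(url, params={"tag": p.tag}, timeout=timeout)
        except requests.RequestException as exc:
            failures.append(f"{url}: {exc}")
            continue
        if resp.status_code == 404:
            try:
                detail = resp.json()
            except ValueError:
                detail = {}
            not_found = (
                detail.get("level", "asset"),
                detail.get("detail", f"not found remotely: {p}"),
            )
            continue
        try:
            resp.raise_for_status()
            return base, resp.json()
        except (requests.RequestException, ValueError) as exc:
            failures.append(f"{url}: {exc}")
    if not_found is not None:
        raise MissingEntryError(
            f"asset not available on any configured server: {not_found[1]}",
            not_found[0],
        )
    raise NetworkError("all genome servers unreachable: " + "; ".join(failures))


def _download_verified(
    url: str, dest: Path, expected_digest: str, timeout: float
) -> None:
    h = hashlib.sha256()
    with requests.get(url, stream=True, timeout=timeout) as resp:
        resp.raise_for_status()
        with open(dest, "wb") as fh:
            for chunk in resp.iter_content(_CHUNK):
                h.update(chunk)
                fh.write(chunk)
    if h.hexdigest() != expected_digest:
        raise IntegrityError(
            f"archive digest mismatch for {url}: expected {expected_digest}, "
            f"got {h.hexdigest()}"
        )


def pull_asset(
    config: GenomeConfig,
    path: AssetRegistryPath,
    force: bool = False,
    timeout: float = _TIMEOUT,
) -> Tuple[GenomeConfig, TagEntry]:
    """Download, verify, unpack, and register a remote asset.

    Refuses to replace an existing local tag without *force* — including
    the case where local and remote digests differ.
    """
    try:
        config.get_tag_entry(path)
    except MissingEntryError:
        pass
    else:
        if not force:
            raise RefAssetsError(
                f"tag already exists locally: {path.genome}/{path.asset}:"
                f"{path.tag} (pass force to replace)"
            )

    server, attrs = _fetch_attributes(config.genome_servers, path, timeout)
    archive_url = (
        f"{server}/v2/asset/{path.genome}/{path.asset}/archive?tag={path.tag}"
    )

    folder = Path(config.genome_folder)
    folder.mkdir(parents=True, exist_ok=True)
    tmp_tar = None
    tmp_dir = None
    try:
        fd = tempfile.NamedTemporaryFile(
            dir=folder, suffix=".tgz.part", delete=False
        )
        fd.close()
        tmp_tar = Path(fd.name)
        _download_verified(archive_url, tmp_tar, attrs["archive_digest"], timeout)

        tmp_dir = Path(tempfile.mkdtemp(dir=folder, prefix=".pulling."))
        with tarfile.open(tmp_tar, "r:gz") as tar:
            tar.extractall(tmp_dir, filter="data")

        digest = str(compute_asset_digest(tmp_dir))
        if digest != attrs["asset_digest"]:
            raise IntegrityError(
                f"unpacked asset digest mismatch for {path}: expected "
                f"{attrs['asset_digest']}, got {digest}"
            )

        final_dir = folder / path.genome / path.asset / path.tag
        final_dir.parent.mkdir(parents=True, exist_ok=True)
        if final_dir.exists():
            shutil.rmtree(final_dir)
        tmp_dir.replace(final_dir)
        tmp_dir = None
    finally:
        if tmp_tar is not None and tmp_tar.exists():
            tmp_tar.unlink()
        if tmp_dir is not None and tmp_dir.exists():
            shutil.rmtree(tmp_dir, ignore_errors=True)
            # prune any directories created for a failed unpack
            for d in (folder / path.genome / path.asset, folder / path.genome):
                if d.is_dir() and not any(d.iterdir()):
                    d.rmdir()

    entry = TagEntry(
        asset_path=f"{path.genome}/{path.asset}/{path.tag}",
        seek_keys=dict(attrs.get("seek_keys", {})),
        asset_digest=attrs["asset_digest"],
        build_log=(
            BUILD_LOG_NAME if BUILD_LOG_NAME in attrs.get("contents", []) else None
        ),
    )
    register_tag_entry(config, path, entry, force=force)
    return config, entry
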