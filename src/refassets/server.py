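"""Archive preparation and the HTTP API that serves archived assets.

``archive_assets`` compresses every (asset, tag) of a genome folder into
an individual gzip tarball and records integrity metadata (tarball
digest, size, content listing, asset digest) in a manifest written
beside the configuration file.  Re-archiving is idempotent: entries
whose asset digest is unchanged are skipped.

``serve`` exposes the manifest over a small read-only HTTP service.
All endpoints live under the ``/v2`` prefix (unprefixed paths
redirect); the service also publishes an OpenAPI 3.0 document at
``/v2/openapi.json`` describing every endpoint.  The implementation is
standard-library ``http.server`` so the service runs with no extra
runtime dependencies.
"""

from __future__ import annotations

import json
import tarfile
import threading
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Dict, List, Optional
from urllib.parse import parse_qs, urlsplit

import yaml

from . import __version__
from .config import GenomeConfig, seek
from .exceptions import RefAssetsError
from .provenance import BUILD_LOG_NAME, compute_file_digest, serialize_recipe
from .registry import AssetRegistryPath

ARCHIVE_DIR_NAME = "archive"
MANIFEST_NAME = "archive_manifest.yaml"

API_PREFIX = "/v2"

#: Metadata endpoints under ``/v2/asset/{genome}/{asset}/``.
ASSET_ENDPOINTS = ("archive", "digest", "recipe", "log", "attributes")


@dataclass
class ArchiveEntry:
    """Server-side record for one archived (asset, tag)."""

    registry_path: str
    archive_path: str  # relative to the archive root
    archive_digest: str
    archive_size: int
    contents: List[str] = field(default_factory=list)
    asset_digest: str = ""

    def to_dict(self) -> dict:
        return {
            "registry_path": self.registry_path,
            "archive_path": self.archive_path,
            "archive_digest": self.archive_digest,
            "archive_size": self.archive_size,
            "contents": list(self.contents),
            "asset_digest": self.asset_digest,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchiveEntry":
        return cls(
            registry_path=d["registry_path"],
            archive_path=d["archive_path"],
            archive_digest=d["archive_digest"],
            archive_size=int(d["archive_size"]),
            contents=list(d.get("contents", [])),
            asset_digest=d.get("asset_digest", ""),
        )


def manifest_path_for(config: GenomeConfig) -> Path:
    if not config.path:
        raise RefAssetsError("configuration has no file path; cannot place manifest")
    return Path(config.path).parent / MANIFEST_NAME


def archive_root_for(config: GenomeConfig) -> Path:
    if not config.path:
        raise RefAssetsError("configuration has no file path; cannot place archives")
    return Path(config.path).parent / ARCHIVE_DIR_NAME


def load_manifest(path: Path) -> List[ArchiveEntry]:
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    return [ArchiveEntry.from_dict(e) for e in data.get("entries", [])]


def write_manifest(path: Path, entries: List[ArchiveEntry]) -> None:
    data = {"entries": [e.to_dict() for e in entries]}
    path.write_text(
        yaml.safe_dump(data, sort_keys=True, default_flow_style=False),
        encoding="utf-8",
    )


def _make_tarball(asset_dir: Path, tarball: Path) -> List[str]:
    """Archive the contents of *asset_dir* (no leading path components)."""
    contents = sorted(
        p.relative_to(asset_dir).as_posix()
        for p in asset_dir.rglob("*")
        if p.is_file()
    )
    tarball.parent.mkdir(parents=True, exist_ok=True)
    with tarfile.open(tarball, "w:gz") as tar:
        for rel in contents:
            tar.add(asset_dir / rel, arcname=rel)
    return contents


def archive_assets(config: GenomeConfig) -> List[ArchiveEntry]:
    """Create one gzip tarball per (asset, tag); return the full manifest.

    Idempotent: an existing archive whose recorded asset digest matches
    the config's current digest is left untouched.
    """
    if not any(g.assets for g in config.genomes.values()):
        raise RefAssetsError("nothing to archive: configuration lists no assets")
    root = archive_root_for(config)
    manifest_file = manifest_path_for(config)
    previous = {
        e.registry_path: e
        for e in (load_manifest(manifest_file) if manifest_file.is_file() else [])
    }
    entries: List[ArchiveEntry] = []
    for gname, genome in sorted(config.genomes.items()):
        for aname, asset in sorted(genome.assets.items()):
            for tag, tag_entry in sorted(asset.tags.items()):
                registry_path = f"{gname}/{aname}:{tag}"
                asset_dir = Path(tag_entry.asset_path)
                if not asset_dir.is_absolute():
                    asset_dir = Path(config.genome_folder) / asset_dir
                if not asset_dir.is_dir():
                    raise RefAssetsError(
                        f"asset files missing on disk for {registry_path}: "
                        f"{asset_dir}"
                    )
                rel_tarball = f"{gname}/{aname}__{tag}.tgz"
                tarball = root / rel_tarball
                prior = previous.get(registry_path)
                if (
                    prior is not None
                    and prior.asset_digest == tag_entry.asset_digest
                    and (root / prior.archive_path).is_file()
                ):
                    entries.append(prior)
                    continue
                contents = _make_tarball(asset_dir, tarball)
                entries.append(
                    ArchiveEntry(
                        registry_path=registry_path,
                        archive_path=rel_tarball,
                        archive_digest=compute_file_digest(tarball),
                        archive_size=tarball.stat().st_size,
                        contents=contents,
                        asset_digest=tag_entry.asset_digest,
                    )
                )
    write_manifest(manifest_file, entries)
    return entries


# -- HTTP service --------------------------------------------------------


def _openapi_document() -> dict:
    """Machine-readable API schema covering every served endpoint."""
    tag_param = {
        "name": "tag",
        "in": "query",
        "required": False,
        "schema": {"type": "string"},
        "description": "Asset tag; defaults to the asset's default tag.",
    }
    path_params = [
        {
            "name": name,
            "in": "path",
            "required": True,
            "schema": {"type": "string"},
        }
        for name in ("genome", "asset")
    ]
    def op(summary, content_type, schema):
        return {
            "get": {
                "summary": summary,
                "parameters": path_params + [tag_param],
                "responses": {
                    "200": {
                        "description": "OK",
                        "content": {content_type: {"schema": schema}},
                    },
                    "404": {"description": "Unknown genome, asset, or tag"},
                },
            }
        }

    json_obj = {"type": "object"}
    text = {"type": "string"}
    binary = {"type": "string", "format": "binary"}
    return {
        "openapi": "3.0.2",
        "info": {
            "title": "refassets archive server",
            "version": __version__,
            "description": "Read-only API serving archived genome assets "
            "and their integrity metadata.",
        },
        "paths": {
            "/v2/genomes": {
                "get": {
                    "summary": "List available genomes",
                    "responses": {
                        "200": {
                            "description": "OK",
                            "content": {
                                "application/json": {
                                    "schema": {
                                        "type": "array",
                                        "items": {"type": "string"},
                                    }
                                }
                            },
                        }
                    },
                }
            },
            "/v2/assets": {
                "get": {
                    "summary": "Map each genome to its available asset:tag entries",
                    "responses": {
                        "200": {
                            "description": "OK",
                            "content": {"application/json": {"schema": json_obj}},
                        }
                    },
                }
            },
            "/v2/asset/{genome}/{asset}/archive": op(
                "Download the asset tarball", "application/octet-stream", binary
            ),
            "/v2/asset/{genome}/{asset}/digest": op(
                "Asset content digest", "application/json", json_obj
            ),
            "/v2/asset/{genome}/{asset}/recipe": op(
                "Canonical recipe text", "text/plain", text
            ),
            "/v2/asset/{genome}/{asset}/log": op(
                "Build provenance log", "text/plain", text
            ),
            "/v2/asset/{genome}/{asset}/attributes": op(
                "Archive size, digests, contents and seek keys",
                "application/json",
                json_obj,
            ),
        },
    }


class _NotFound(Exception):
    def __init__(self, message: str, level: str):
        super().__init__(message)
        self.level = level


class _Handler(BaseHTTPRequestHandler):
    server_version = f"refassets/{__version__}"

    # injected by serve(): entries, by_path, config, archive_root
    def log_message(self, *args) -> None:  # silence request logging
        pass

    def _send_json(self, obj, status: int = 200) -> None:
        body = json.dumps(obj).encode("utf-8")
        self.send_response(status)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def _send_text(self, text: str, status: int = 200) -> None:
        body = text.encode("utf-8")
        self.send_response(status)
        self.send_header("Content-Type", "text/plain; charset=utf-8")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def _send_bytes(self, data: bytes) -> None:
        self.send_response(200)
        self.send_header("Content-Type", "application/octet-stream")
        self.send_header("Content-Length", str(len(data)))
        self.end_headers()
        self.wfile.write(data)

    def _redirect(self, location: str) -> None:
        self.send_response(307)
        self.send_header("Location", location)
        self.send_header("Content-Length", "0")
        self.end_headers()

    # lookup helpers ----------------------------------------------------

    def _resolve(self, genome: str, asset: str, tag: Optional[str]):
        srv = self.server
        genomes = {e.registry_path.split("/")[0] for e in srv.entries}
        if genome not in genomes:
            raise _NotFound(f"genome not found: {genome}", "genome")
        asset_names = {
            e.registry_path.split("/")[1].split(":")[0]
            for e in srv.entries
            if e.registry_path.startswith(genome + "/")
        }
        if asset not in asset_names:
            raise _NotFound(f"asset not found: {genome}/{asset}", "asset")
        if tag is None:
            asset_entry = (
                srv.config.genomes.get(genome, None)
                and srv.config.genomes[genome].assets.get(asset)
            )
            tag = asset_entry.default_tag if asset_entry else "default"
        key = f"{genome}/{asset}:{tag}"
        if key not in srv.by_path:
            raise _NotFound(f"tag not found: {key}", "tag")
        return srv.by_path[key], tag

    def do_GET(self) -> None:  # noqa: N802 (http.server API)
        parts = urlsplit(self.path)
        path = parts.path.rstrip("/") or "/"
        query = parse_qs(parts.query)
        tag = query.get("tag", [None])[0]
        try:
            if not path.startswith(API_PREFIX):
                target = API_PREFIX + path + (f"?{parts.query}" if parts.query else "")
                self._redirect(target)
                return
            route = path[len(API_PREFIX):]
            if route == "/openapi.json":
                self._send_json(_openapi_document())
            elif route == "/genomes":
                genomes = sorted(
                    {e.registry_path.split("/")[0] for e in self.server.entries}
                )
                self._send_json(genomes)
            elif route == "/assets":
                mapping: Dict[str, List[str]] = {}
                for e in self.server.entries:
                    g, rest = e.registry_path.split("/", 1)
                    mapping.setdefault(g, []).append(rest)
                self._send_json({g: sorted(v) for g, v in mapping.items()})
            elif route.startswith("/asset/"):
                segments = route.split("/")[2:]
                if len(segments) != 3 or segments[2] not in ASSET_ENDPOINTS:
                    self._send_json({"detail": "unknown endpoint"}, 404)
                    return
                genome, asset, endpoint = segments
                entry, resolved_tag = self._resolve(genome, asset, tag)
                self._dispatch_asset(endpoint, genome, asset, resolved_tag, entry)
            else:
                self._send_json({"detail": "unknown endpoint"}, 404)
        except _NotFound as exc:
            self._send_json({"detail": str(exc), "level": exc.level}, 404)
        except BrokenPipeError:
            pass

    def _dispatch_asset(
        self, endpoint: str, genome: str, asset: str, tag: str, entry: ArchiveEntry
    ) -> None:
        srv = self.server
        if endpoint == "archive":
            data = (srv.archive_root / entry.archive_path).read_bytes()
            self._send_bytes(data)
        elif endpoint == "digest":
            self._send_json({"asset_digest": entry.asset_digest})
        elif endpoint == "recipe":
            from .build import get_recipe  # late import: avoids cycle

            try:
                recipe = get_recipe(asset)
            except RefAssetsError as exc:
                raise _NotFound(str(exc), "recipe") from exc
            self._send_text(serialize_recipe(recipe))
        elif endpoint == "log":
            rp = AssetRegistryPath(genome, asset, tag, seek_key="dir")
            log_file = Path(seek(srv.config, rp)) / BUILD_LOG_NAME
            if not log_file.is_file():
                raise _NotFound(
                    f"no build log for {genome}/{asset}:{tag}", "log"
                )
            self._send_text(log_file.read_text(encoding="utf-8"))
        elif endpoint == "attributes":
            asset_entry = srv.config.genomes[genome].assets[asset]
            tag_entry = asset_entry.tags[tag]
            self._send_json(
                {
                    "registry_path": entry.registry_path,
                    "tag": tag,
                    "default_tag": asset_entry.default_tag,
                    "archive_digest": entry.archive_digest,
                    "archive_size": entry.archive_size,
                    "contents": entry.contents,
                    "asset_digest": entry.asset_digest,
                    "seek_keys": dict(tag_entry.seek_keys),
                }
            )


class AssetServer:
    """An in-process, thread-backed instance of the archive API."""

    def __init__(
        self,
        entries: List[ArchiveEntry],
        config: GenomeConfig,
        host: str = "127.0.0.1",
        port: int = 0,
    ):
        self._httpd = ThreadingHTTPServer((host, port), _Handler)
        self._httpd.entries = entries
        self._httpd.by_path = {e.registry_path: e for e in entries}
        self._httpd.config = config
        self._httpd.archive_root = archive_root_for(config)
        self._thread: Optional[threading.Thread] = None
        self._stopped = False

    @property
    def base_url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}"

    def start(self) -> "AssetServer":
        self._thread = threading.Thread(
            target=self._httpd.serve_forever, daemon=True
        )
        self._thread.start()
        return self

    def stop(self) -> None:
        if self._stopped:
            return
        self._stopped = True
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    def __enter__(self) -> "AssetServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


def serve(
    entries: List[ArchiveEntry],
    config: GenomeConfig,
    host: str = "127.0.0.1",
    port: int = 0,
) -> AssetServer:
    """Start serving *entries*; returns a started :class:`AssetServer`."""
    return AssetServer(entries, config, host=host, port=port).start()
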