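"""Genome configuration file: create, read, mutate, persist.

The configuration file is a YAML document tracking the genome folder
location, an ordered list of remote server URLs, and every locally
registered asset with its paths and content digest:

.. code-block:: yaml

    config_version: "1.0"
    genome_folder: /abs/path/genomes
    genome_servers:
      - http://localhost:8000
    genomes:
      hg38:
        assets:
          fasta:
            default_tag: default
            tags:
              default:
                asset_path: hg38/fasta/default
                seek_keys:
                  dir: .
                  fasta: hg38.fa
                asset_digest: <hex>
                build_log: _build_log.yaml

Writes are atomic (rename-into-place) and the canonical serialization is
key-sorted, so ``write(load(f))`` is byte-identical for any canonically
formatted file.  All cross-process mutations go through
:func:`locked_update`, which holds an exclusive advisory lock on a
sidecar ``<config>.lock`` file; readers are lock-free.
"""

from __future__ import annotations

import os
import shutil
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional

import yaml
from filelock import FileLock

from .exceptions import (
    ConfigError,
    ConfigVersionError,
    MissingEntryError,
    RefAssetsError,
)
from .registry import AssetRegistryPath
from .provenance import BUILD_LOG_NAME, compute_asset_digest

CONFIG_VERSION = "1.0"

#: Environment variable consulted when no explicit config path is given.
CONFIG_ENV_VAR = "REFASSETS"

#: Reserved seek key addressing the asset directory itself.
DIR_SEEK_KEY = "dir"

_TAG_KEYS = {"asset_path", "seek_keys", "asset_digest", "build_log"}


@dataclass
class TagEntry:
    """One tagged version of one asset."""

    asset_path: str
    seek_keys: Dict[str, str] = field(default_factory=dict)
    asset_digest: str = ""
    build_log: Optional[str] = None

    def __post_init__(self) -> None:
        self.seek_keys.setdefault(DIR_SEEK_KEY, ".")

    def to_dict(self) -> dict:
        d = {
            "asset_path": self.asset_path,
            "seek_keys": dict(self.seek_keys),
            "asset_digest": self.asset_digest,
        }
        if self.build_log is not None:
            d["build_log"] = self.build_log
        return d


@dataclass
class AssetEntry:
    default_tag: str
    tags: Dict[str, TagEntry] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "default_tag": self.default_tag,
            "tags": {t: e.to_dict() for t, e in self.tags.items()},
        }


@dataclass
class GenomeEntry:
    assets: Dict[str, AssetEntry] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"assets": {a: e.to_dict() for a, e in self.assets.items()}}


@dataclass
class GenomeConfig:
    """In-memory mirror of the genome configuration file."""

    genome_folder: str
    genome_servers: List[str] = field(default_factory=list)
    genomes: Dict[str, GenomeEntry] = field(default_factory=dict)
    config_version: str = CONFIG_VERSION
    #: Path the config was loaded from / written to; not serialized.
    path: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "config_version": self.config_version,
            "genome_folder": self.genome_folder,
            "genome_servers": list(self.genome_servers),
            "genomes": {g: e.to_dict() for g, e in self.genomes.items()},
        }

    # -- lookups ---------------------------------------------------------

    def get_tag_entry(self, p: AssetRegistryPath) -> TagEntry:
        """Resolve *p* to its TagEntry, erroring at the first absent level."""
        genome = self.genomes.get(p.genome)
        if genome is None:
            raise MissingEntryError(f"genome not found: {p.genome}", "genome")
        asset = genome.assets.get(p.asset)
        if asset is None:
            raise MissingEntryError(
                f"asset not found: {p.genome}/{p.asset}", "asset"
            )
        tag = asset.tags.get(p.tag)
        if tag is None:
            raise MissingEntryError(
                f"tag not found: {p.genome}/{p.asset}:{p.tag}", "tag"
            )
        return tag


def _canonical_dump(data: dict) -> str:
    return yaml.safe_dump(
        data, sort_keys=True, indent=2, default_flow_style=False, allow_unicode=True
    )


def _parse_tag_entry(tag_name: str, raw: object, errors: List[str]) -> TagEntry:
    if not isinstance(raw, dict):
        errors.append(f"tags.{tag_name}: expected mapping")
        return TagEntry(asset_path="")
    unknown = set(raw) - _TAG_KEYS
    if unknown:
        errors.append(f"tags.{tag_name}: unknown keys {sorted(unknown)}")
    for key in ("asset_path", "seek_keys", "asset_digest"):
        if key not in raw:
            errors.append(f"tags.{tag_name}: missing key {key!r}")
    return TagEntry(
        asset_path=str(raw.get("asset_path", "")),
        seek_keys=dict(raw.get("seek_keys") or {}),
        asset_digest=str(raw.get("asset_digest", "")),
        build_log=raw.get("build_log"),
    )


def config_from_dict(data: object, path: Optional[str] = None) -> GenomeConfig:
    """Validate and materialize a parsed YAML document.

    Raises :class:`ConfigError` listing every offending key, or
    :class:`ConfigVersionError` for an unsupported major version.
    """
    if not isinstance(data, dict):
        raise ConfigError("configuration file is not a YAML mapping")
    errors: List[str] = []
    for key in ("config_version", "genome_folder", "genome_servers", "genomes"):
        if key not in data:
            errors.append(f"missing key {key!r}")
    if errors:
        raise ConfigError("malformed configuration: " + "; ".join(errors))
    version = str(data["config_version"])
    if version.split(".")[0] != CONFIG_VERSION.split(".")[0]:
        raise ConfigVersionError(
            f"unsupported config_version {version!r}; this build understands "
            f"major version {CONFIG_VERSION.split('.')[0]}"
        )
    servers = data["genome_servers"]
    if not isinstance(servers, list):
        errors.append("genome_servers: expected list")
        servers = []
    genomes_raw = data["genomes"]
    if genomes_raw is None:
        genomes_raw = {}
    if not isinstance(genomes_raw, dict):
        errors.append("genomes: expected mapping")
        genomes_raw = {}
    genomes: Dict[str, GenomeEntry] = {}
    for gname, graw in genomes_raw.items():
        if not isinstance(graw, dict) or "assets" not in graw:
            errors.append(f"genomes.{gname}: missing key 'assets'")
            continue
        assets: Dict[str, AssetEntry] = {}
        for aname, araw in (graw["assets"] or {}).items():
            if not isinstance(araw, dict) or "tags" not in araw:
                errors.append(f"genomes.{gname}.assets.{aname}: missing key 'tags'")
                continue
            tags = {
                t: _parse_tag_entry(t, traw, errors)
                for t, traw in (araw["tags"] or {}).items()
            }
            default_tag = araw.get("default_tag")
            if default_tag not in tags:
                errors.append(
                    f"genomes.{gname}.assets.{aname}: default_tag "
                    f"{default_tag!r} not among tags"
                )
                continue
            assets[aname] = AssetEntry(default_tag=default_tag, tags=tags)
        genomes[gname] = GenomeEntry(assets=assets)
    if errors:
        raise ConfigError("malformed configuration: " + "; ".join(errors))
    return GenomeConfig(
        genome_folder=str(data["genome_folder"]),
        genome_servers=[str(s) for s in servers],
        genomes=genomes,
        config_version=version,
        path=path,
    )


def resolve_config_location(
    explicit: Optional[str] = None, environment: Optional[Mapping[str, str]] = None
) -> str:
    """Decide which configuration file to use.

    An explicit argument wins; otherwise the ``REFASSETS`` environment
    variable; otherwise an actionable error naming both mechanisms.
    """
    if explicit:
        return explicit
    env = os.environ if environment is None else environment
    from_env = env.get(CONFIG_ENV_VAR)
    if from_env:
        return from_env
    raise ConfigError(
        "no configuration file specified: pass one with -c/--config or set "
        f"the {CONFIG_ENV_VAR} environment variable"
    )


def init_config(
    target_path: os.PathLike | str,
    genome_folder: os.PathLike | str,
    servers: Optional[List[str]] = None,
) -> GenomeConfig:
    """Create an empty configuration file at *target_path*.

    Refuses to overwrite an existing non-empty file.  The genome folder
    is created if absent and recorded as an absolute path.
    """
    target = Path(target_path)
    if target.exists() and target.stat().st_size > 0:
        raise ConfigError(
            f"refusing to overwrite existing configuration file: {target}"
        )
    folder = Path(genome_folder).absolute()
    folder.mkdir(parents=True, exist_ok=True)
    config = GenomeConfig(
        genome_folder=str(folder),
        genome_servers=list(servers or []),
        path=str(target),
    )
    target.parent.mkdir(parents=True, exist_ok=True)
    write_config(config, target)
    return config


def load_config(path: os.PathLike | str) -> GenomeConfig:
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"configuration file not found: {p}")
    try:
        data = yaml.safe_load(p.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"configuration file is not valid YAML: {p}: {exc}") from exc
    return config_from_dict(data, path=str(p))


def write_config(config: GenomeConfig, path: Optional[os.PathLike | str] = None) -> None:
    """Atomically persist *config* (write temp sibling, rename into place)."""
    target = Path(path) if path is not None else Path(config.path or "")
    if not str(target):
        raise ConfigError("no path to write configuration to")
    text = _canonical_dump(config.to_dict())
    fd, tmp = tempfile.mkstemp(
        dir=str(target.parent) or ".", prefix=target.name, suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, target)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    config.path = str(target)


def _lock_for(path: os.PathLike | str) -> FileLock:
    return FileLock(str(path) + ".lock")


@contextmanager
def locked_update(path: os.PathLike | str) -> Iterator[GenomeConfig]:
    """Load-modify-write a configuration file under an exclusive lock.

    Yields the freshly loaded config; on clean exit the (possibly
    mutated) config is written back atomically.  On exception nothing is
    written.
    """
    with _lock_for(path):
        config = load_config(path)
        yield config
        write_config(config, path)


# -- operations ----------------------------------------------------------


def list_local(config: GenomeConfig) -> Dict[str, List[str]]:
    """Mapping genome → sorted list of ``asset:tag``, each tag exactly once."""
    out: Dict[str, List[str]] = {}
    for gname, genome in config.genomes.items():
        entries = [
            f"{aname}:{tag}"
            for aname, asset in genome.assets.items()
            for tag in asset.tags
        ]
        out[gname] = sorted(entries)
    return out


def _is_within(child: Path, parent: Path) -> bool:
    try:
        child.absolute().relative_to(parent.absolute())
        return True
    except ValueError:
        return False


def add_asset(
    config: GenomeConfig,
    path: AssetRegistryPath,
    local_dir: os.PathLike | str,
    seek_keys: Optional[Mapping[str, str]] = None,
    force: bool = False,
) -> GenomeConfig:
    """Register an already-built directory as an asset.

    Directories inside the genome folder are recorded by relative path;
    anything else is recorded by absolute path without copying.  The
    content digest is computed at registration time.
    """
    src = Path(local_dir)
    if not src.is_dir() or not any(src.iterdir()):
        raise RefAssetsError(f"asset directory missing or empty: {src}")
    folder = Path(config.genome_folder)
    if _is_within(src, folder):
        asset_path = src.absolute().relative_to(folder.absolute()).as_posix()
    else:
        asset_path = str(src.absolute())
    keys = dict(seek_keys or {})
    keys.setdefault(DIR_SEEK_KEY, ".")
    for key, rel in keys.items():
        if key != DIR_SEEK_KEY and not (src / rel).exists():
            raise RefAssetsError(
                f"seek key {key!r} points to nonexistent file {rel!r} in {src}"
            )
    entry = TagEntry(
        asset_path=asset_path,
        seek_keys=keys,
        asset_digest=str(compute_asset_digest(src)),
        build_log=BUILD_LOG_NAME if (src / BUILD_LOG_NAME).is_file() else None,
    )
    register_tag_entry(config, path, entry, force=force)
    return config


def register_tag_entry(
    config: GenomeConfig,
    path: AssetRegistryPath,
    entry: TagEntry,
    force: bool = False,
) -> None:
    """Insert *entry* at *path*, refusing to clobber without *force*."""
    genome = config.genomes.setdefault(path.genome, GenomeEntry())
    asset = genome.assets.get(path.asset)
    if asset is None:
        asset = AssetEntry(default_tag=path.tag)
        genome.assets[path.asset] = asset
    if path.tag in asset.tags and not force:
        raise RefAssetsError(
            f"tag already exists: {path.genome}/{path.asset}:{path.tag} "
            "(pass force to overwrite)"
        )
    asset.tags[path.tag] = entry


def remove_asset(config: GenomeConfig, path: AssetRegistryPath) -> GenomeConfig:
    """Deregister a tag and delete its files if they live in the genome folder.

    Files referenced by another remaining tag (aliases) or located
    outside the genome folder are left untouched.  Empty asset/genome
    directories are pruned so a build followed by a remove restores the
    genome folder exactly.
    """
    entry = config.get_tag_entry(path)  # raises at the right level
    genome = config.genomes[path.genome]
    asset = genome.assets[path.asset]
    del asset.tags[path.tag]

    still_referenced = any(
        t.asset_path == entry.asset_path
        for g in config.genomes.values()
        for a in g.assets.values()
        for t in a.tags.values()
    )
    folder = Path(config.genome_folder)
    target = Path(entry.asset_path)
    if not target.is_absolute():
        target = folder / target
    if not still_referenced and _is_within(target, folder) and target.exists():
        shutil.rmtree(target)
        parent = target.parent
        while _is_within(parent, folder) and parent != folder.absolute():
            if any(parent.iterdir()):
                break
            parent.rmdir()
            parent = parent.parent

    if not asset.tags:
        del genome.assets[path.asset]
    elif asset.default_tag == path.tag:
        asset.default_tag = sorted(asset.tags)[0]
    if not genome.assets:
        del config.genomes[path.genome]
    return config


def tag_asset(
    config: GenomeConfig,
    path: AssetRegistryPath,
    new_tag: str,
    force: bool = False,
) -> GenomeConfig:
    """Alias an existing tag under *new_tag* — no files are copied."""
    entry = config.get_tag_entry(path)
    if new_tag == path.tag:
        raise RefAssetsError(f"new tag must differ from source tag {path.tag!r}")
    asset = config.genomes[path.genome].assets[path.asset]
    if new_tag in asset.tags and not force:
        raise RefAssetsError(
            f"tag already exists: {path.genome}/{path.asset}:{new_tag}"
        )
    asset.tags[new_tag] = TagEntry(
        asset_path=entry.asset_path,
        seek_keys=dict(entry.seek_keys),
        asset_digest=entry.asset_digest,
        build_log=entry.build_log,
    )
    return config


def seek(config: GenomeConfig, path: AssetRegistryPath) -> str:
    """Absolute file path for a registry path; pure lookup, no filesystem I/O.

    With an explicit seek key the path of that key is returned.  Without
    one, the seek key named like the asset wins if present (recipes
    declare their primary output under the recipe's own name), otherwise
    the reserved ``dir`` key — i.e. the asset directory.
    """
    entry = config.get_tag_entry(path)
    if path.seek_key is not None:
        if path.seek_key not in entry.seek_keys:
            raise MissingEntryError(
                f"seek key not found: {path.genome}/{path.asset}."
                f"{path.seek_key}:{path.tag} (known: "
                f"{', '.join(sorted(entry.seek_keys))})",
                "seek_key",
            )
        key = path.seek_key
    elif path.asset in entry.seek_keys:
        key = path.asset
    else:
        key = DIR_SEEK_KEY
    base = Path(entry.asset_path)
    if not base.is_absolute():
        base = Path(config.genome_folder) / base
    rel = entry.seek_keys[key]
    resolved = base if rel in (".", "") else base / rel
    return os.path.normpath(str(resolved))
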