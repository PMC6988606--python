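"""Recipe framework and the build engine.

Recipes are declared in a packaged YAML manifest (``recipes.yaml``) so
new declarative recipes can be added without code changes.  Exactly one
recipe (``fasta``) carries an internal, fully implemented procedure; the
aligner-index recipes are command templates describing how locally
installed tools would be invoked, validated at load time but never
executed unless the caller explicitly allows it.

Builds are atomic: outputs are materialized in a hidden temporary
sibling directory and renamed into ``{genome_folder}/{genome}/{asset}/
{tag}/`` only after the procedure, digest, and provenance log all
succeed.  A failed build leaves the genome folder exactly as it was.
"""

from __future__ import annotations

import gzip
import os
import shutil
import string
import subprocess
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import yaml

from . import __version__
from .config import DIR_SEEK_KEY, GenomeConfig, TagEntry, register_tag_entry, seek
from .exceptions import BuildError, MissingEntryError, RecipeError
from .provenance import (
    BuildLog,
    compute_asset_digest,
    compute_file_digest,
    write_build_log,
)
from .registry import AssetRegistryPath

_CONTEXT_PLACEHOLDERS = {"genome", "asset_dir", "tag"}


@dataclass(frozen=True)
class RecipeInput:
    name: str
    description: str = ""


@dataclass(frozen=True)
class RecipeParam:
    name: str
    default: Optional[str] = None
    description: str = ""


@dataclass(frozen=True)
class Recipe:
    """Declarative description of how to build one asset kind."""

    name: str
    version: str
    description: str
    procedure: str  # "internal" | "command_template"
    required_files: Tuple[RecipeInput, ...] = ()
    required_assets: Tuple[str, ...] = ()
    required_params: Tuple[RecipeParam, ...] = ()
    outputs: Mapping[str, str] = field(default_factory=dict)
    default_seek_key: str = ""
    command_template: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "version": self.version,
            "description": self.description,
            "procedure": self.procedure,
            "required_files": [
                {"name": f.name, "description": f.description}
                for f in self.required_files
            ],
            "required_assets": list(self.required_assets),
            "required_params": [
                {"name": p.name, "default": p.default, "description": p.description}
                for p in self.required_params
            ],
            "outputs": dict(self.outputs),
            "default_seek_key": self.default_seek_key,
        }
        if self.command_template is not None:
            d["command_template"] = self.command_template
        return d


@dataclass
class BuildRequest:
    """User-supplied inputs for one build invocation."""

    registry_path: AssetRegistryPath
    files: Dict[str, str] = field(default_factory=dict)
    params: Dict[str, str] = field(default_factory=dict)


def _placeholders(template: str) -> set:
    return {
        name
        for _, name, _, _ in string.Formatter().parse(template)
        if name is not None
    }


def _validate_recipe(recipe: Recipe) -> None:
    if recipe.default_seek_key not in recipe.outputs:
        raise RecipeError(
            f"recipe {recipe.name!r}: default_seek_key "
            f"{recipe.default_seek_key!r} not among outputs"
        )
    declared = (
        {f.name for f in recipe.required_files}
        | {p.name for p in recipe.required_params}
        | set(recipe.required_assets)
        | _CONTEXT_PLACEHOLDERS
    )
    templates = list(recipe.outputs.values())
    if recipe.command_template is not None:
        templates.append(recipe.command_template)
    for template in templates:
        undeclared = _placeholders(template) - declared
        if undeclared:
            raise RecipeError(
                f"recipe {recipe.name!r}: template references undeclared "
                f"placeholders {sorted(undeclared)}"
            )
    if recipe.procedure == "command_template" and recipe.command_template is None:
        raise RecipeError(f"recipe {recipe.name!r}: missing command_template")
    if recipe.procedure == "internal" and recipe.name not in INTERNAL_PROCEDURES:
        raise RecipeError(f"recipe {recipe.name!r}: no internal procedure")


def _recipe_from_dict(name: str, raw: dict) -> Recipe:
    return Recipe(
        name=name,
        version=str(raw.get("version", "0")),
        description=str(raw.get("description", "")).strip(),
        procedure=raw["procedure"],
        required_files=tuple(
            RecipeInput(f["name"], f.get("description", ""))
            for f in raw.get("required_files") or []
        ),
        required_assets=tuple(raw.get("required_assets") or []),
        required_params=tuple(
            RecipeParam(p["name"], p.get("default"), p.get("description", ""))
            for p in raw.get("required_params") or []
        ),
        outputs=dict(raw.get("outputs") or {}),
        default_seek_key=str(raw.get("default_seek_key", "")),
        command_template=raw.get("command_template"),
    )


def _load_recipes() -> Dict[str, Recipe]:
    from importlib.resources import files

    text = files("refassets").joinpath("recipes.yaml").read_text(encoding="utf-8")
    raw = yaml.safe_load(text)["recipes"]
    recipes = {}
    for name, entry in raw.items():
        recipe = _recipe_from_dict(name, entry)
        _validate_recipe(recipe)
        recipes[name] = recipe
    return recipes


_RECIPES: Optional[Dict[str, Recipe]] = None


def recipe_registry() -> Dict[str, Recipe]:
    global _RECIPES
    if _RECIPES is None:
        _RECIPES = _load_recipes()
    return _RECIPES


def get_recipe(name: str) -> Recipe:
    recipes = recipe_registry()
    if name not in recipes:
        raise RecipeError(
            f"no recipe named {name!r}; known recipes: "
            + ", ".join(sorted(recipes))
        )
    return recipes[name]


def _requirements_summary(recipe: Recipe) -> str:
    parts = []
    if recipe.required_files:
        parts.append("files: " + ", ".join(f.name for f in recipe.required_files))
    if recipe.required_assets:
        parts.append("assets: " + ", ".join(recipe.required_assets))
    if recipe.required_params:
        parts.append(
            "params: "
            + ", ".join(
                f"{p.name}={p.default}" if p.default is not None else p.name
                for p in recipe.required_params
            )
        )
    return "; ".join(parts) or "no requirements"


def list_recipes() -> List[Tuple[str, str]]:
    """All buildable asset kinds with a one-line requirements summary."""
    return [
        (name, _requirements_summary(recipe))
        for name, recipe in sorted(recipe_registry().items())
    ]


def describe_requirements(recipe_name: str) -> Dict[str, list]:
    """Structured requirements of one recipe: files, assets, params."""
    recipe = get_recipe(recipe_name)
    return {
        "files": [
            {"name": f.name, "description": f.description}
            for f in recipe.required_files
        ],
        "assets": list(recipe.required_assets),
        "params": [
            {"name": p.name, "default": p.default, "description": p.description}
            for p in recipe.required_params
        ],
    }


def render_command(
    recipe: Recipe,
    request: BuildRequest,
    resolved_paths: Mapping[str, str],
) -> str:
    """Substitute all placeholders of a command-template recipe.

    *resolved_paths* supplies context names plus prerequisite-asset
    paths; file inputs and (defaulted) params come from *request*.
    """
    if recipe.procedure != "command_template" or recipe.command_template is None:
        raise RecipeError(f"recipe {recipe.name!r} has no command template")
    mapping: Dict[str, str] = {}
    for p in recipe.required_params:
        if p.default is not None:
            mapping[p.name] = p.default
    mapping.update({k: str(v) for k, v in request.files.items()})
    mapping.update({k: str(v) for k, v in request.params.items()})
    mapping.update({k: str(v) for k, v in resolved_paths.items()})
    try:
        return recipe.command_template.format(**mapping)
    except KeyError as exc:
        raise RecipeError(
            f"unresolved placeholder {exc.args[0]!r} in recipe {recipe.name!r}"
        ) from exc


# -- fasta procedure -----------------------------------------------------


def _is_gzipped(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _open_sequence(path: Path):
    return gzip.open(path, "rb") if _is_gzipped(path) else open(path, "rb")


def _write_fai_and_sizes(
    fasta_path: Path, fai_path: Path, sizes_path: Path
) -> None:
    """Index an uncompressed FASTA file.

    The FAI dialect is the 5-column tab-separated one: sequence name,
    length in bases, byte offset of the first base, bases per full line,
    bytes per full line (terminator included).  chrom sizes rows are
    ``name<TAB>length`` in input order.
    """
    records: List[Tuple[str, int, int, int, int]] = []
    seen = set()
    name: Optional[str] = None
    offset = 0
    length = 0
    seq_start = 0
    linebases = 0
    linewidth = 0
    last_line_full = True

    def flush() -> None:
        if name is None:
            return
        if length == 0:
            raise BuildError(f"empty sequence record {name!r} in {fasta_path}")
        records.append((name, length, seq_start, linebases, linewidth))

    with open(fasta_path, "rb") as fh:
        for line in fh:
            stripped = line.rstrip(b"\r\n")
            if stripped.startswith(b">"):
                flush()
                name = stripped[1:].split()[0].decode() if stripped[1:].split() else ""
                if not name:
                    raise BuildError(f"unnamed sequence record in {fasta_path}")
                if name in seen:
                    raise BuildError(
                        f"duplicate sequence name {name!r} in {fasta_path}"
                    )
                seen.add(name)
                offset += len(line)
                seq_start = offset
                length = 0
                linebases = 0
                linewidth = 0
                last_line_full = True
                continue
            if name is None:
                raise BuildError(
                    f"not a FASTA file (data before first header): {fasta_path}"
                )
            nbases = len(stripped)
            if nbases == 0:
                raise BuildError(
                    f"blank line inside record {name!r} in {fasta_path}"
                )
            if linebases == 0:
                linebases, linewidth = nbases, len(line)
            else:
                if not last_line_full:
                    raise BuildError(
                        f"ragged line lengths in record {name!r} in {fasta_path}: "
                        "only the final line of a record may be short"
                    )
                if nbases > linebases:
                    raise BuildError(
                        f"ragged line lengths in record {name!r} in {fasta_path}"
                    )
            last_line_full = nbases == linebases
            length += nbases
            offset += len(line)
        flush()
    if not records:
        raise BuildError(f"no sequence records in {fasta_path}")
    with open(fai_path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write("{}\t{}\t{}\t{}\t{}\n".format(*rec))
    with open(sizes_path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec[0]}\t{rec[1]}\n")


def build_fasta(
    input_fasta: os.PathLike | str,
    output_dir: os.PathLike | str,
    base_name: Optional[str] = None,
) -> Dict[str, str]:
    """Materialize the fasta asset: uncompressed sequence, FAI, chrom sizes.

    The sequence output is a byte-exact (decompressed) copy of the
    input, so line structure is preserved.  Returns the mapping
    ``{fasta, fai, chrom_sizes}`` → produced file path.
    """
    src = Path(input_fasta)
    if not src.is_file():
        raise BuildError(f"input FASTA not found: {src}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = base_name or src.name.removesuffix(".gz").rsplit(".", 1)[0] or "genome"
    fasta_path = out / f"{base}.fa"
    fai_path = out / f"{base}.fa.fai"
    sizes_path = out / f"{base}.chrom.sizes"
    with _open_sequence(src) as rfh, open(fasta_path, "wb") as wfh:
        shutil.copyfileobj(rfh, wfh)
    if fasta_path.stat().st_size == 0:
        fasta_path.unlink()
        raise BuildError(f"empty FASTA input: {src}")
    try:
        _write_fai_and_sizes(fasta_path, fai_path, sizes_path)
    except BuildError:
        for p in (fasta_path, fai_path, sizes_path):
            p.unlink(missing_ok=True)
        raise
    return {
        "fasta": str(fasta_path),
        "fai": str(fai_path),
        "chrom_sizes": str(sizes_path),
    }


def _run_fasta_procedure(
    recipe: Recipe,
    request: BuildRequest,
    tmp_dir: Path,
    context: Dict[str, str],
) -> None:
    build_fasta(
        request.files["fasta"], tmp_dir, base_name=context["genome"]
    )


INTERNAL_PROCEDURES = {"fasta": _run_fasta_procedure}


# -- build engine --------------------------------------------------------


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def build_asset(
    config: GenomeConfig,
    request: BuildRequest,
    force: bool = False,
    allow_execution: bool = False,
) -> Tuple[GenomeConfig, TagEntry]:
    """Build the asset named by the request's registry path and register it.

    All validation happens before anything is written.  On any failure
    the temporary build directory and any directories created for it are
    removed, so the genome folder and config are left untouched.
    """
    rp = request.registry_path
    recipe = get_recipe(rp.asset)

    try:
        config.get_tag_entry(rp)
    except MissingEntryError:
        pass
    else:
        if not force:
            raise BuildError(
                f"tag already exists: {rp.genome}/{rp.asset}:{rp.tag} "
                "(pass force to rebuild)"
            )

    for f in recipe.required_files:
        if f.name not in request.files:
            raise BuildError(
                f"missing required input file {f.name!r} for recipe "
                f"{recipe.name!r} (pass --files {f.name}=PATH)"
            )
        if not Path(request.files[f.name]).is_file():
            raise BuildError(
                f"required input file {f.name!r} does not exist: "
                f"{request.files[f.name]}"
            )
    params = {
        p.name: p.default for p in recipe.required_params if p.default is not None
    }
    params.update(request.params)
    for p in recipe.required_params:
        if p.name not in params:
            raise BuildError(
                f"missing required parameter {p.name!r} for recipe {recipe.name!r}"
            )

    asset_paths: Dict[str, str] = {}
    for aname in recipe.required_assets:
        try:
            asset_paths[aname] = seek(
                config, AssetRegistryPath(rp.genome, aname)
            )
        except MissingEntryError as exc:
            raise BuildError(
                f"recipe {recipe.name!r} requires asset {rp.genome}/{aname}; "
                "build or pull it first"
            ) from exc

    folder = Path(config.genome_folder)
    final_dir = folder / rp.genome / rp.asset / rp.tag
    if final_dir.exists() and not force:
        raise BuildError(f"asset directory already exists: {final_dir}")

    context = {
        "genome": rp.genome,
        "tag": rp.tag,
        "asset_dir": str(final_dir),
    }
    rendered_outputs = {
        key: template.format(**{**params, **asset_paths, **context})
        for key, template in recipe.outputs.items()
    }

    parent = final_dir.parent
    created: List[Path] = []
    probe = parent
    while not probe.exists():
        created.append(probe)
        probe = probe.parent
    parent.mkdir(parents=True, exist_ok=True)
    tmp_dir = parent / f".{rp.tag}.building.{os.getpid()}"

    started = _now()
    try:
        tmp_dir.mkdir()
        if recipe.procedure == "internal":
            context_tmp = dict(context, asset_dir=str(tmp_dir))
            INTERNAL_PROCEDURES[recipe.name](recipe, request, tmp_dir, context_tmp)
        else:
            if not allow_execution:
                raise BuildError(
                    f"recipe {recipe.name!r} requires running external software; "
                    "external execution not supported in this environment "
                    "(pass allow_execution to override)"
                )
            command = render_command(
                recipe,
                BuildRequest(rp, dict(request.files), params),
                {**asset_paths, **dict(context, asset_dir=str(tmp_dir))},
            )
            proc = subprocess.run(
                command, shell=True, capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise BuildError(
                    f"build command failed (exit {proc.returncode}): {command}\n"
                    f"{proc.stderr}"
                )

        produced = {
            p.relative_to(tmp_dir).as_posix()
            for p in tmp_dir.rglob("*")
            if p.is_file()
        }
        expected = set(rendered_outputs.values())
        if recipe.procedure == "internal":
            # internal recipes produce exactly their declared outputs
            if produced != expected:
                raise BuildError(
                    f"recipe {recipe.name!r} output mismatch: produced "
                    f"{sorted(produced)}, declared {sorted(expected)}"
                )
        else:
            # index outputs may be file prefixes, so check by prefix
            for rel in expected:
                if not any(p.startswith(rel) for p in produced):
                    raise BuildError(f"declared output missing after build: {rel}")

        digest = compute_asset_digest(tmp_dir)
        log = BuildLog(
            registry_path=f"{rp.genome}/{rp.asset}:{rp.tag}",
            recipe_name=recipe.name,
            recipe_version=recipe.version,
            inputs=[
                (name, str(Path(p).absolute()), compute_file_digest(p))
                for name, p in sorted(request.files.items())
            ],
            software_versions={
                "refassets": __version__,
                "python": sys.version.split()[0],
            },
            started=started,
            finished=_now(),
            asset_digest=str(digest),
        )
        log_path = write_build_log(tmp_dir, log)

        if final_dir.exists():
            shutil.rmtree(final_dir)
        os.replace(tmp_dir, final_dir)
    except BaseException:
        if tmp_dir.exists():
            shutil.rmtree(tmp_dir, ignore_errors=True)
        for d in created:
            if d.exists() and not any(d.iterdir()):
                d.rmdir()
        raise

    entry = TagEntry(
        asset_path=f"{rp.genome}/{rp.asset}/{rp.tag}",
        seek_keys={**rendered_outputs, DIR_SEEK_KEY: "."},
        asset_digest=str(digest),
        build_log=log_path.name,
    )
    register_tag_entry(config, rp, entry, force=force)
    return config, entry
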