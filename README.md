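# refassets

A reference-genome asset manager. `refassets` organizes genome-associated
resources ("assets" — sequence files, index bundles, annotation sets) under a
standard on-disk layout, tracks them in a human- and machine-readable YAML
configuration file, and addresses every asset with a portable registry path:

```
{genome}/{asset}[.{seek_key}][:{tag}]
```

Assets can be **built** locally from recipes for arbitrary inputs, or
**pulled** pre-built from a remote archive server — both produce identical
layouts and content digests, so pipelines can locate any asset with a single
lookup regardless of how it was obtained.

## CLI

The configuration file is passed with `-c` or taken from the `REFASSETS`
environment variable:

```sh
export REFASSETS=~/genomes/config.yaml
refassets init                       # create an empty configuration
refassets build hg38/fasta --files fasta=hg38.fa.gz
refassets list                       # local genomes and assets
refassets seek hg38/fasta.chrom_sizes   # bare path, shell-substitutable
refassets tag hg38/fasta v2
refassets add hg38/annotations --path /data/anno --seek-keys gtf=genes.gtf
refassets remove hg38/fasta:v2
```

Seven subcommands are purely local (`init`, `list`, `seek`, `add`, `remove`,
`tag`, `build`); two talk to configured servers (`listr`, `pull`):

```sh
refassets init -s http://localhost:8000   # record server URLs at init
refassets listr                           # what is available remotely
refassets pull hg38/fasta                 # download, verify, unpack, register
```

`seek` prints the bare path and nothing else on stdout, so
`bt2=$(refassets seek hg38/bowtie2_index)` is safe. Diagnostics go to stderr.
Exit codes: 0 success, 1 domain error, 2 usage error, 3 network/integrity
error.

### Building

`refassets build GENOME/ASSET[:TAG] --files NAME=PATH --params NAME=VALUE`.
Requirements for any recipe: `refassets build GENOME/ASSET --requirements`.
The `fasta` recipe is fully internal (uncompressed sequence + FAI index +
chromosome sizes from a plain or gzipped FASTA). The aligner-index recipes
(`bowtie2_index`, `hisat2_index`, `bwa_index`) are declarative command
templates for locally installed tools, declared in
`src/refassets/recipes.yaml`; running them requires `--allow-execution`.
Builds are atomic: outputs land in a temporary sibling directory and are
renamed into place only after the digest and provenance log are written.

## Library API

```python
from refassets import (
    load_config, seek, parse_registry_path,
    build_asset, BuildRequest,
)
config = load_config("config.yaml")
path = seek(config, parse_registry_path("hg38/fasta.fai"))
```

## Serving and pulling

```python
from refassets import load_config
from refassets.server import archive_assets, serve
config = load_config("config.yaml")
entries = archive_assets(config)   # one gzip tarball per (asset, tag)
server = serve(entries, config, port=8000)
```

`archive_assets` writes a manifest beside the configuration file and is
idempotent (unchanged assets are skipped). The server is read-only and
exposes, under `/v2` (unprefixed paths redirect):

| endpoint | payload |
| --- | --- |
| `/v2/genomes` | JSON list of genomes |
| `/v2/assets` | JSON mapping genome → `asset:tag` entries |
| `/v2/asset/{g}/{a}/archive?tag=` | tarball bytes |
| `/v2/asset/{g}/{a}/digest?tag=` | asset content digest |
| `/v2/asset/{g}/{a}/recipe?tag=` | canonical recipe text |
| `/v2/asset/{g}/{a}/log?tag=` | build provenance log |
| `/v2/asset/{g}/{a}/attributes?tag=` | size, digests, contents, seek keys |
| `/v2/openapi.json` | OpenAPI 3.0 schema of all of the above |

`pull` streams the tarball, verifies its bytes against the advertised archive
digest, unpacks, recomputes and verifies the asset digest, and only then
registers the asset; any failure leaves the configuration and genome folder
byte-identical to their prior state.

## Provenance

Every asset carries a content digest: SHA-256 over the sorted sequence of
`(relative path, per-file SHA-256)` pairs, each fed as `path\0hexdigest\n`
(UTF-8). Files named `_build_log*` are excluded, so the digest can be recorded
inside the build log (`_build_log.yaml`) that every build writes: inputs and
their digests, software versions, timestamps, and the final asset digest.
The digest is independent of absolute location, directory enumeration order,
and timestamps; an empty directory digests to the SHA-256 of empty input.

## Configuration file format

```yaml
config_version: "1.0"
genome_folder: /abs/path/genomes
genome_servers:          # ordered; first success wins on pull
  - http://localhost:8000
genomes:
  hg38:
    assets:
      fasta:
        default_tag: default
        tags:
          default:
            asset_path: hg38/fasta/default   # relative to genome_folder
            seek_keys: {dir: ., fasta: hg38.fa, fai: hg38.fa.fai,
                        chrom_sizes: hg38.chrom.sizes}
            asset_digest: <64-char hex>
            build_log: _build_log.yaml
```

Mutations take an exclusive advisory lock on `<config>.lock`; writes are
atomic. Hand-edits that keep the schema valid load fine (e.g. absolute
`asset_path` for assets on other filesystems).

## Synthetic data

`refassets.fixtures` generates all test inputs: seeded FASTA records
(`ACGTN` alphabet, MT19937 PRNG — byte-identical across reruns), populated
configurations, and in-process ephemeral archive servers on OS-assigned
ports. No test downloads anything.
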