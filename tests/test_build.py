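import gzip
import shutil
from pathlib import Path

import pytest
from pyfaidx import Faidx

from refassets import BuildRequest, build_asset, build_fasta, list_local, seek
from refassets.build import (
    Recipe,
    _validate_recipe,
    describe_requirements,
    get_recipe,
    list_recipes,
    render_command,
)
from refassets.exceptions import BuildError, RecipeError
from refassets.fixtures import write_fasta
from refassets.provenance import read_build_log
from refassets.registry import AssetRegistryPath, parse_registry_path

from conftest import snapshot_tree


def oracle_fai(fasta: Path, workdir: Path) -> bytes:
    """Independent FAI via pyfaidx on a copy of the input."""
    workdir.mkdir(exist_ok=True)
    copy = workdir / fasta.name
    shutil.copy(fasta, copy)
    Faidx(str(copy))
    return (workdir / (fasta.name + ".fai")).read_bytes()


class TestRecipeCatalog:
    def test_contains_fasta(self):
        assert "fasta" in {name for name, _ in list_recipes()}

    def test_contains_declarative_index_recipes(self):
        names = {name for name, _ in list_recipes()}
        assert {"bowtie2_index", "hisat2_index", "bwa_index"} <= names

    def test_every_recipe_has_requirements_text(self):
        for _, summary in list_recipes():
            assert summary


class TestDescribeRequirements:
    def test_fasta_requires_file_named_fasta(self):
        reqs = describe_requirements("fasta")
        assert [f["name"] for f in reqs["files"]] == ["fasta"]

    def test_bowtie2_requires_fasta_asset(self):
        assert describe_requirements("bowtie2_index")["assets"] == ["fasta"]

    def test_unknown_recipe_lists_known_names(self):
        with pytest.raises(RecipeError) as exc:
            describe_requirements("martian_index")
        assert "fasta" in str(exc.value)


class TestBuildFasta:
    def test_spec_example_single_record(self, tmp_path):
        src = tmp_path / "tiny.fa"
        src.write_text(">chr1\nACGT\n")
        out = build_fasta(src, tmp_path / "out")
        assert Path(out["fai"]).read_text() == "chr1\t4\t6\t4\t5\n"
        assert Path(out["chrom_sizes"]).read_text() == "chr1\t4\n"

    def test_gzip_and_plain_identical_outputs(self, tmp_path):
        text = write_fasta(
            tmp_path / "p.fa", 3, (30, 60), line_width=10, seed=4
        ).read_bytes()
        gz = tmp_path / "p.fa.gz"
        with gzip.open(gz, "wb") as fh:
            fh.write(text)
        out_plain = build_fasta(tmp_path / "p.fa", tmp_path / "o1", "g")
        out_gz = build_fasta(gz, tmp_path / "o2", "g")
        for key in ("fasta", "fai", "chrom_sizes"):
            assert (
                Path(out_plain[key]).read_bytes() == Path(out_gz[key]).read_bytes()
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_fai_matches_oracle(self, tmp_path, seed):
        fa = write_fasta(
            tmp_path / "in.fa",
            n_records=5,
            length_range=(1, 200),
            line_width=(seed * 13) % 80 + 1,
            seed=seed,
        )
        out = build_fasta(fa, tmp_path / "out")
        assert Path(out["fai"]).read_bytes() == oracle_fai(fa, tmp_path / "oracle")

    def test_duplicate_name_errors(self, tmp_path):
        src = tmp_path / "dup.fa"
        src.write_text(">chr1\nAC\n>chr1\nGT\n")
        with pytest.raises(BuildError, match="duplicate"):
            build_fasta(src, tmp_path / "out")

    def test_ragged_lines_error(self, tmp_path):
        src = tmp_path / "ragged.fa"
        src.write_text(">chr1\nACGT\nAC\nGTGT\n")
        with pytest.raises(BuildError, match="ragged"):
            build_fasta(src, tmp_path / "out")

    def test_empty_file_errors(self, tmp_path):
        src = tmp_path / "empty.fa"
        src.write_text("")
        with pytest.raises(BuildError):
            build_fasta(src, tmp_path / "out")

    def test_line_structure_preserved(self, tmp_path):
        fa = write_fasta(tmp_path / "in.fa", 2, (40, 50), line_width=7, seed=9)
        out = build_fasta(fa, tmp_path / "out")
        assert Path(out["fasta"]).read_bytes() == fa.read_bytes()


class TestBuildAsset:
    def test_all_seek_keys_resolve_to_files(self, built_config):
        for key in ("fasta", "fai", "chrom_sizes", "dir"):
            path = seek(built_config, parse_registry_path(f"hg38/fasta.{key}"))
            assert Path(path).exists(), key

    def test_missing_required_file_errors_before_write(
        self, fresh_config
    ):
        before = snapshot_tree(fresh_config.genome_folder)
        with pytest.raises(BuildError, match="fasta"):
            build_asset(
                fresh_config, BuildRequest(AssetRegistryPath("hg38", "fasta"))
            )
        assert snapshot_tree(fresh_config.genome_folder) == before
        assert list_local(fresh_config) == {}

    def test_rebuild_without_force_errors(self, built_config, fasta_input):
        with pytest.raises(BuildError, match="exists"):
            build_asset(
                built_config,
                BuildRequest(
                    AssetRegistryPath("hg38", "fasta"),
                    files={"fasta": str(fasta_input)},
                ),
            )

    def test_determinism_same_input_same_digest(self, fresh_config, fasta_input):
        digests = []
        for tag in ("a", "b"):
            _, entry = build_asset(
                fresh_config,
                BuildRequest(
                    AssetRegistryPath("hg38", "fasta", tag),
                    files={"fasta": str(fasta_input)},
                ),
            )
            digests.append(entry.asset_digest)
        assert digests[0] == digests[1]

    def test_build_log_written_with_matching_digest(self, built_config):
        rp = parse_registry_path("hg38/fasta.dir")
        log = read_build_log(seek(built_config, rp))
        entry = built_config.get_tag_entry(parse_registry_path("hg38/fasta"))
        assert log.asset_digest == entry.asset_digest
        assert log.recipe_name == "fasta"
        assert log.inputs and log.inputs[0][0] == "fasta"

    def test_command_template_refused_without_allow_execution(
        self, built_config
    ):
        with pytest.raises(BuildError, match="external execution"):
            build_asset(
                built_config,
                BuildRequest(AssetRegistryPath("hg38", "bowtie2_index")),
            )

    def test_required_asset_missing_instructs_build_first(self, fresh_config):
        with pytest.raises(BuildError, match="build or pull"):
            build_asset(
                fresh_config,
                BuildRequest(AssetRegistryPath("hg38", "bowtie2_index")),
            )

    def test_interrupted_build_restores_state(
        self, fresh_config, fasta_input, monkeypatch
    ):
        import refassets.build as build_mod

        before_tree = snapshot_tree(fresh_config.genome_folder)

        def boom(*args, **kwargs):
            raise RuntimeError("simulated crash mid-build")

        monkeypatch.setitem(build_mod.INTERNAL_PROCEDURES, "fasta", boom)
        with pytest.raises(RuntimeError):
            build_asset(
                fresh_config,
                BuildRequest(
                    AssetRegistryPath("hg38", "fasta"),
                    files={"fasta": str(fasta_input)},
                ),
            )
        assert snapshot_tree(fresh_config.genome_folder) == before_tree
        assert list_local(fresh_config) == {}

    def test_internal_outputs_exactly_declared(self, built_config):
        asset_dir = Path(
            seek(built_config, parse_registry_path("hg38/fasta.dir"))
        )
        files = {p.name for p in asset_dir.iterdir() if p.is_file()}
        assert files == {
            "hg38.fa",
            "hg38.fa.fai",
            "hg38.chrom.sizes",
            "_build_log.yaml",
        }


class TestRenderCommand:
    def test_substitution(self):
        recipe = get_recipe("bowtie2_index")
        request = BuildRequest(AssetRegistryPath("hg38", "bowtie2_index"))
        cmd = render_command(
            recipe,
            request,
            {
                "fasta": "/g/f.fa",
                "genome": "hg38",
                "asset_dir": "/g/hg38/bowtie2_index/default",
                "tag": "default",
            },
        )
        assert "/g/f.fa" in cmd
        assert "/g/hg38/bowtie2_index/default/hg38" in cmd

    def test_defaults_substituted_when_params_omitted(self):
        recipe = get_recipe("bowtie2_index")
        cmd = render_command(
            recipe,
            BuildRequest(AssetRegistryPath("hg38", "bowtie2_index")),
            {"fasta": "/f", "genome": "g", "asset_dir": "/d", "tag": "t"},
        )
        assert "--threads 1" in cmd

    def test_undeclared_placeholder_rejected_at_registration(self):
        bad = Recipe(
            name="bad",
            version="0",
            description="",
            procedure="command_template",
            command_template="tool {mystery_input}",
            outputs={"bad": "{genome}"},
            default_seek_key="bad",
        )
        with pytest.raises(RecipeError, match="mystery_input"):
            _validate_recipe(bad)
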