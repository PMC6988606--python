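import hashlib
import io
import tarfile
from pathlib import Path

import pytest
import requests

from refassets import BuildRequest, build_asset, write_config
from refassets.exceptions import RefAssetsError
from refassets.fixtures import write_fasta
from refassets.provenance import compute_asset_digest, serialize_recipe
from refassets.build import get_recipe
from refassets.registry import AssetRegistryPath
from refassets.server import archive_assets, archive_root_for, manifest_path_for

from conftest import snapshot_tree


@pytest.fixture
def two_asset_config(fresh_config, fasta_input, tmp_path):
    build_asset(
        fresh_config,
        BuildRequest(
            AssetRegistryPath("hg38", "fasta"), files={"fasta": str(fasta_input)}
        ),
    )
    other = write_fasta(tmp_path / "mm10.fa", 2, (30, 60), seed=21)
    build_asset(
        fresh_config,
        BuildRequest(AssetRegistryPath("mm10", "fasta"), files={"fasta": str(other)}),
    )
    write_config(fresh_config)
    return fresh_config


class TestArchive:
    def test_one_tarball_per_asset_tag(self, two_asset_config):
        entries = archive_assets(two_asset_config)
        assert len(entries) == 2
        root = archive_root_for(two_asset_config)
        assert all((root / e.archive_path).is_file() for e in entries)
        assert manifest_path_for(two_asset_config).is_file()

    def test_unpacked_tarball_digest_matches(self, two_asset_config, tmp_path):
        entries = archive_assets(two_asset_config)
        root = archive_root_for(two_asset_config)
        for i, entry in enumerate(entries):
            dest = tmp_path / f"unpack{i}"
            with tarfile.open(root / entry.archive_path) as tar:
                tar.extractall(dest, filter="data")
            unpacked = sorted(
                p.relative_to(dest).as_posix()
                for p in dest.rglob("*")
                if p.is_file()
            )
            assert unpacked == sorted(entry.contents)
            assert str(compute_asset_digest(dest)) == entry.asset_digest

    def test_rearchive_is_idempotent(self, two_asset_config):
        entries = archive_assets(two_asset_config)
        root = archive_root_for(two_asset_config)
        mtimes = {e.archive_path: (root / e.archive_path).stat().st_mtime_ns
                  for e in entries}
        again = archive_assets(two_asset_config)
        assert [e.to_dict() for e in again] == [e.to_dict() for e in entries]
        for e in again:
            assert (root / e.archive_path).stat().st_mtime_ns == mtimes[e.archive_path]

    def test_missing_files_error_names_registry_path(self, two_asset_config):
        import shutil

        tag_dir = Path(two_asset_config.genome_folder) / "mm10/fasta/default"
        shutil.rmtree(tag_dir)
        with pytest.raises(RefAssetsError, match="mm10/fasta:default"):
            archive_assets(two_asset_config)

    def test_empty_config_refused(self, fresh_config):
        with pytest.raises(RefAssetsError, match="no assets"):
            archive_assets(fresh_config)


class TestServe:
    def test_genomes_endpoint(self, served):
        server, _, _ = served
        resp = requests.get(f"{server.base_url}/v2/genomes")
        assert resp.status_code == 200
        assert resp.json() == ["hg38"]

    def test_assets_endpoint(self, served):
        server, _, _ = served
        assert requests.get(f"{server.base_url}/v2/assets").json() == {
            "hg38": ["fasta:default"]
        }

    def test_archive_bytes_match_advertised_digest(self, served):
        server, entries, _ = served
        resp = requests.get(
            f"{server.base_url}/v2/asset/hg38/fasta/archive", params={"tag": "default"}
        )
        assert resp.headers["Content-Type"] == "application/octet-stream"
        assert hashlib.sha256(resp.content).hexdigest() == entries[0].archive_digest

    def test_archive_tag_defaults_to_default_tag(self, served):
        server, entries, _ = served
        resp = requests.get(f"{server.base_url}/v2/asset/hg38/fasta/archive")
        assert hashlib.sha256(resp.content).hexdigest() == entries[0].archive_digest

    def test_recipe_endpoint_is_serialize_recipe_output(self, served):
        server, _, _ = served
        resp = requests.get(f"{server.base_url}/v2/asset/hg38/fasta/recipe")
        assert resp.text == serialize_recipe(get_recipe("fasta"))

    def test_log_endpoint_serves_build_log(self, served):
        server, _, config = served
        resp = requests.get(f"{server.base_url}/v2/asset/hg38/fasta/log")
        assert resp.status_code == 200
        assert "asset_digest" in resp.text

    def test_digest_and_attributes(self, served):
        server, entries, _ = served
        digest = requests.get(
            f"{server.base_url}/v2/asset/hg38/fasta/digest"
        ).json()
        assert digest == {"asset_digest": entries[0].asset_digest}
        attrs = requests.get(
            f"{server.base_url}/v2/asset/hg38/fasta/attributes"
        ).json()
        assert attrs["archive_size"] == entries[0].archive_size
        assert attrs["contents"] == entries[0].contents
        assert "fasta" in attrs["seek_keys"]

    @pytest.mark.parametrize(
        "url,level",
        [
            ("/v2/asset/mm39/fasta/digest", "genome"),
            ("/v2/asset/hg38/bowtie2_index/digest", "asset"),
            ("/v2/asset/hg38/fasta/digest?tag=v9", "tag"),
        ],
    )
    def test_not_found_reports_machine_readable_level(self, served, url, level):
        server, _, _ = served
        resp = requests.get(server.base_url + url)
        assert resp.status_code == 404
        assert resp.json()["level"] == level

    def test_unprefixed_paths_redirect(self, served):
        server, _, _ = served
        resp = requests.get(f"{server.base_url}/genomes", allow_redirects=False)
        assert resp.status_code == 307
        assert resp.headers["Location"] == "/v2/genomes"
        assert requests.get(f"{server.base_url}/genomes").json() == ["hg38"]

    def test_openapi_document_lists_all_endpoints(self, served):
        server, _, _ = served
        doc = requests.get(f"{server.base_url}/v2/openapi.json").json()
        assert doc["openapi"].startswith("3.0")
        for path in (
            "/v2/genomes",
            "/v2/assets",
            "/v2/asset/{genome}/{asset}/archive",
            "/v2/asset/{genome}/{asset}/digest",
            "/v2/asset/{genome}/{asset}/recipe",
            "/v2/asset/{genome}/{asset}/log",
            "/v2/asset/{genome}/{asset}/attributes",
        ):
            assert path in doc["paths"]

    def test_serving_is_read_only(self, served, tmp_path):
        server, _, config = served
        config_dir = Path(config.path).parent
        before = snapshot_tree(config_dir)
        for url in ("/v2/genomes", "/v2/assets", "/v2/asset/hg38/fasta/archive",
                    "/v2/asset/hg38/fasta/attributes", "/v2/asset/hg38/fasta/log"):
            requests.get(server.base_url + url)
        assert snapshot_tree(config_dir) == before
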