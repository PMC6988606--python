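# Packaged recipe manifest.  Each entry declares how one asset kind is
# produced: required input files, prerequisite assets, parameters with
# defaults, and the seek keys its outputs expose.  `procedure: internal`
# recipes are implemented in code; `procedure: command_template` recipes
# are declarative shell templates for locally installed tools and are
# never executed unless execution is explicitly allowed.
#
# Template placeholders may reference declared file inputs, parameters,
# prerequisite assets (resolved to their seek paths), and the builtin
# context names {genome}, {asset_dir} and {tag}.
recipes:
  fasta:
    version: "0.1.0"
    description: >-
      Uncompressed genome sequence with FAI index and chromosome sizes
      table, from a plain or gzip-compressed FASTA input.
    procedure: internal
    required_files:
      - name: fasta
        description: genome sequence, FASTA, optionally gzip-compressed
    required_assets: []
    required_params: []
    outputs:
      fasta: "{genome}.fa"
      fai: "{genome}.fa.fai"
      chrom_sizes: "{genome}.chrom.sizes"
    default_seek_key: fasta
  bowtie2_index:
    version: "0.1.0"
    description: Bowtie2 alignment index built from the genome sequence.
    procedure: command_template
    command_template: >-
      bowtie2-build --threads {threads} {fasta} {asset_dir}/{genome}
    required_files: []
    required_assets: [fasta]
    required_params:
      - name: threads
        default: "1"
        description: number of build threads
    outputs:
      bowtie2_index: "{genome}"
    default_seek_key: bowtie2_index
  hisat2_index:
    version: "0.1.0"
    description: HISAT2 alignment index built from the genome sequence.
    procedure: command_template
    command_template: >-
      hisat2-build -p {threads} {fasta} {asset_dir}/{genome}
    required_files: []
    required_assets: [fasta]
    required_params:
      - name: threads
        default: "1"
        description: number of build threads
    outputs:
      hisat2_index: "{genome}"
    default_seek_key: hisat2_index
  bwa_index:
    version: "0.1.0"
    description: BWA alignment index built from the genome sequence.
    procedure: command_template
    command_template: >-
      bwa index -p {asset_dir}/{genome} {fasta}
    required_files: []
    required_assets: [fasta]
    required_params: []
    outputs:
      bwa_index: "{genome}"
    default_seek_key: bwa_index
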