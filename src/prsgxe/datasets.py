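"""Packaged data fixtures."""

from __future__ import annotations

from importlib import resources

from .geno_io import GwasSummary, read_gwas_summary


def refined_snp_table_path():
    """Path to the packaged refined-SNP fixture (57 rsIDs with their
    original-GWAS p-values; coordinates, alleles and weights are
    placeholders since the source table publishes only rsID and p)."""
    return resources.files("prsgxe.data") / "refined_snp_table.tsv"


def load_refined_snp_table() -> GwasSummary:
    """Parse the packaged refined-SNP fixture with the standard reader."""
    with resources.as_file(refined_snp_table_path()) as p:
        return read_gwas_summary(p)
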