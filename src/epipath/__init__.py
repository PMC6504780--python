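"""epipath: case/control SNP-SNP interaction scanning, haplotype
association, and permutation-based pathway enrichment."""

from importlib.resources import files as _files

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a packaged data fixture (TSV/BED/GMT)."""
    return _files("epipath").joinpath("data", name)
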