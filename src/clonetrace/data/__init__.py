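"""Packaged case-study fixtures: the published variant grids transcribed to TSV.

* ``sector_grid_variants.tsv`` / ``sector_grid_samples.tsv`` -- targeted-sequencing
  VAFs of the primary tumor (GBM1) and recurrent gliosarcoma (SGS1)
  across bulk sectors and derived cultures, with the sample sheet.
* ``cohort_variants.tsv`` -- key variants of the additional gliosarcoma
  cohort (GBM2/3, SGS2/3, PGS1/2).
* ``tmz_context_variants.tsv`` -- the ex vivo temozolomide experiments:
  one row per variant with printed trinucleotide context and a
  ``tmz_emergent`` flag (1 = detected only after TMZ exposure).
"""

from importlib import resources
from pathlib import Path


def _path(name: str) -> Path:
    return Path(resources.files(__name__) / name)


def sector_grid_variants_path() -> Path:
    return _path("sector_grid_variants.tsv")


def sector_grid_samples_path() -> Path:
    return _path("sector_grid_samples.tsv")


def cohort_variants_path() -> Path:
    return _path("cohort_variants.tsv")


def tmz_context_path() -> Path:
    return _path("tmz_context_variants.tsv")


def load_sector_grid():
    """(calls, sample_sheet) for the multi-sector case-study grid."""
    from .. import variant_io

    calls = variant_io.read_variant_table(sector_grid_variants_path())
    sheet = variant_io.SampleSheet.read_tsv(sector_grid_samples_path())
    return calls, sheet


def load_cohort():
    from .. import variant_io

    return variant_io.read_variant_table(cohort_variants_path())


def load_tmz_contexts():
    """Annotated ex vivo TMZ variant table with normalized contexts."""
    from .. import signature

    return signature.read_context_table(tmz_context_path())
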