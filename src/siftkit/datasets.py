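"""Bundled small data fixtures.

* ``synthetic_5ht5a_mapping.csv`` — a SYNTHETIC stand-in for a GPCRdb
  generic-number mapping of the serotonin 5-HT5A receptor: the generic labels
  are the 25 binding-site positions discussed in the 5-HT5A literature
  (2x64 ... 7x42, including the questionable 5x46), but the chain/residue
  numbers are invented, since real structure numbering cannot be bundled.
  Use it for panel construction and round-trip tests, not for annotating real
  PDB entries.
* ``mutagenesis_5ht5a.csv`` — published single-residue mutagenesis outcomes
  for 5-HT5A ligand binding, transcribed at the level of effect categories
  (loss / decrease / mixed) per generic position.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def _data_path(name: str) -> Path:
    with resources.as_file(resources.files("siftkit") / "data" / name) as p:
        return Path(p)


def generic_mapping_path() -> Path:
    """Path of the synthetic 5-HT5A generic-number mapping CSV."""
    return _data_path("synthetic_5ht5a_mapping.csv")


def mutagenesis_path() -> Path:
    """Path of the transcribed 5-HT5A mutagenesis effect table."""
    return _data_path("mutagenesis_5ht5a.csv")
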