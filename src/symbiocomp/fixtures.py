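"""Packaged reference tables.

Three small tables transcribed from the published whitefly / *Candidatus
Portiera aleyrodidarum* transcriptome study ship with the package so that the
full analysis can run with no downloads:

* ``assembly_summary`` — sequencing/assembly summary counts (key/value),
* ``pathway_expression`` — amino-acid biosynthesis genes with EC number,
  unitig id and RPKM, split by partner (symbiont vs host insect),
* ``transporter_homologs`` — whitefly homologs of the five aphid amino-acid
  transporters most implicated in host-symbiont exchange, with RPKM.

In ``pathway_expression`` a ``-`` cell means *not detected in that partner*;
it is parsed as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["FixtureTable", "load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("assembly_summary", "pathway_expression", "transporter_homologs")


@dataclass(frozen=True)
class FixtureTable:
    """A named, read-only tabular fixture."""

    name: str
    frame: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FixtureTable)
            and self.name == other.name
            and self.frame.equals(other.frame)
        )


def _read_packaged_tsv(filename: str) -> pd.DataFrame:
    ref = resources.files("symbiocomp.data").joinpath(filename)
    with ref.open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle, sep="\t", na_values=["-"], keep_default_na=True)


def _validate_pathway_expression(frame: pd.DataFrame) -> None:
    has_sym = frame["symbiont_rpkm"].notna()
    has_ins = frame["insect_rpkm"].notna()
    if not (has_sym ^ has_ins).all():
        bad = frame.loc[~(has_sym ^ has_ins), "unitig"].tolist()
        raise ValueError(
            f"pathway_expression rows must carry exactly one RPKM value: {bad}"
        )
    if frame["ec"].isna().any() or frame["unitig"].isna().any():
        raise ValueError("every pathway_expression row needs an EC number and unitig")


def load_fixture(name: str) -> FixtureTable:
    """Load one of the packaged tables by name.

    Numeric cells are parsed as numbers and ``-`` cells as missing.  Two loads
    return equal (and independent) structures.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}"
        )
    frame = _read_packaged_tsv(f"{name}.tsv")
    if name == "pathway_expression":
        _validate_pathway_expression(frame)
    return FixtureTable(name=name, frame=frame)
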