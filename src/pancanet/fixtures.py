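"""Packaged reference gene lists for the pan-cancer consensus.

``TABLE1`` is the published 47-gene pan-cancer consensus — genes called
differentially expressed across both microarray and RNA-seq multi-cancer
panels — with each gene's direction (over/under in tumor) and its
hub-bottleneck-switch topology label in the corresponding first-shell
interaction network (NA = the gene did not connect to its network).

The companion lists are the genes that failed to connect to the over- and
under-expression networks, the 18 genes shared by the three kidney-cancer
cohorts in the survival screen, and the 19 HBS genes shared by the
pancreatic and liver cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import OVER, UNDER

# (gene, direction, topology)
TABLE1: tuple[tuple[str, str, str], ...] = (
    ("ANLN", OVER, "HBS"),
    ("ASPM", OVER, "HBS"),
    ("ATAD2", OVER, "HS"),
    ("ATF3", UNDER, "HBS"),
    ("BIRC5", OVER, "HBS"),
    ("BUB1", OVER, "HBS"),
    ("BUB1B", OVER, "HBS"),
    ("CDC25A", OVER, "S"),
    ("CDCA5", OVER, "HS"),
    ("CDK1", OVER, "HBS"),
    ("CENPE", OVER, "HS"),
    ("CENPF", OVER, "HS"),
    ("CEP55", OVER, "HBS"),
    ("CTHRC1", OVER, "NA"),
    ("CYBRD1", UNDER, "B"),
    ("DEPDC1", OVER, "HS"),
    ("ECT2", OVER, "HS"),
    ("EZH2", OVER, "B"),
    ("FERMT2", UNDER, "HB"),
    ("GINS2", OVER, "HS"),
    ("HELLS", OVER, "HS"),
    ("HHIP", UNDER, "NA"),
    ("HMMR", OVER, "HS"),
    ("KIF11", OVER, "HBS"),
    ("KIF20A", OVER, "HBS"),
    ("KIF2C", OVER, "HBS"),
    ("KLF4", UNDER, "HBS"),
    ("LIFR", UNDER, "B"),
    ("MAD2L1", OVER, "HBS"),
    ("MCM6", OVER, "HBS"),
    ("METTL7A", UNDER, "NA"),
    ("MT1E", UNDER, "NA"),
    ("MT2A", UNDER, "NA"),
    ("NDRG2", UNDER, "NTR"),
    ("NEK2", OVER, "HBS"),
    ("PBK", OVER, "HBS"),
    ("PLPP3", UNDER, "NA"),
    ("PRC1", OVER, "HBS"),
    ("PRR11", OVER, "H"),
    ("RCAN1", UNDER, "B"),
    ("RRM2", OVER, "HBS"),
    ("SELENOP", UNDER, "NA"),
    ("SOX4", OVER, "NA"),
    ("TOP2A", OVER, "HBS"),
    ("TPX2", OVER, "HBS"),
    ("UBE2C", OVER, "HBS"),
    ("ZBTB16", UNDER, "HBS"),
)

# Consensus genes that did not connect to their first-shell networks.
UNCONNECTED_OVER: tuple[str, ...] = ("SOX4", "CTHRC1")
UNCONNECTED_UNDER: tuple[str, ...] = (
    "HHIP", "MT1E", "METTL7A", "MT2A", "SELENOP", "PLPP3"
)

# Genes associated with worse survival in all three kidney cancer cohorts.
PAN_KIDNEY_18: tuple[str, ...] = (
    "ANLN", "ASPM", "BIRC5", "BUB1", "BUB1B", "CDCA5", "CENPE", "CEP55",
    "DEPDC1", "HMMR", "KIF20A", "KIF2C", "NEK2", "PRC1", "RRM2", "TOP2A",
    "TPX2", "UBE2C",
)

# HBS genes shared by the pancreatic and liver survival screens.
PAAD_LIHC_HBS_19: tuple[str, ...] = (
    "ANLN", "ASPM", "BIRC5", "BUB1", "BUB1B", "CDK1", "CEP55", "KIF11",
    "KIF20A", "KIF2C", "MAD2L1", "MCM6", "NEK2", "PBK", "PRC1", "RRM2",
    "TOP2A", "TPX2", "UBE2C",
)


def table1_frame() -> pd.DataFrame:
    """The 47-gene fixture as a frame (gene, direction, topology)."""
    return pd.DataFrame(TABLE1, columns=["gene", "direction", "topology"])


@dataclass(frozen=True)
class FixtureStats:
    """Summary counts over the 47-gene fixture, optionally restricted to a
    supplied gene list."""

    n_genes: int
    by_direction: dict[str, int]
    by_topology: dict[str, int]
    n_hbs: int
    hbs_fraction: float
    unknown_genes: tuple[str, ...] = ()


def fixture_stats(gene_list: Iterable[str] | None = None) -> FixtureStats:
    """Counts by direction and topology, plus the HBS fraction.

    With a gene list, only fixture rows for those genes are counted;
    supplied ids absent from the fixture are listed as unknown, not counted.
    """
    frame = table1_frame()
    unknown: tuple[str, ...] = ()
    if gene_list is not None:
        wanted = list(gene_list)
        known = set(frame["gene"])
        unknown = tuple(sorted(set(wanted) - known))
        frame = frame[frame["gene"].isin(wanted)]
    n = len(frame)
    n_hbs = int((frame["topology"] == "HBS").sum())
    return FixtureStats(
        n_genes=n,
        by_direction=frame["direction"].value_counts().to_dict(),
        by_topology=frame["topology"].value_counts().to_dict(),
        n_hbs=n_hbs,
        hbs_fraction=(n_hbs / n) if n else 0.0,
        unknown_genes=unknown,
    )
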