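"""Conversion of 16S gene-fraction profiles into cell-fraction profiles.

The share of 16S rRNA gene copies a genus contributes ("gene percentage")
overestimates genera with many rRNA operons per genome and underestimates
genera with few, because operon copy number varies roughly 1-15 across
prokaryotes.  Given a table of per-species operon copy numbers (rrnDB-style),
the correction divides each genus's gene fraction by its mean copy number
and renormalises:

    cell_fraction(g) = (gene_fraction(g) / k_g) / sum_h (gene_fraction(h) / k_h)

Genera absent from the table fall back to the table-wide mean copy number
and are marked as imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from amplicomm.taxonomy import CommunityProfile


class CopyNumberError(ValueError):
    """Malformed or unusable copy-number data."""


@dataclass
class CopyNumberTable:
    """Genus -> per-species 16S rRNA operon copy numbers.

    ``global_mean`` is the arithmetic mean over every species-level value in
    the table and is the imputation fallback for genera the table lacks.
    """

    species_copies: dict[str, list[float]]

    def __post_init__(self) -> None:
        if not self.species_copies:
            raise CopyNumberError("copy-number table is empty")
        for genus, values in self.species_copies.items():
            if not values or any(v < 1 for v in values):
                raise CopyNumberError(f"genus {genus!r} has a copy number < 1 (or none)")

    @property
    def global_mean(self) -> float:
        values = [v for vs in self.species_copies.values() for v in vs]
        return float(np.mean(values))

    def __contains__(self, genus: str) -> bool:
        return genus in self.species_copies

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CopyNumberTable":
        """Read a (genus, species, copy_number) TSV.

        Duplicate (genus, species) rows are averaged at the species level
        first; each genus then keeps one value per species.
        """
        df = pd.read_csv(path, sep="\t", comment="#")
        needed = {"genus", "species", "copy_number"}
        if not needed.issubset(df.columns):
            raise CopyNumberError(f"copy-number TSV needs columns {sorted(needed)}")
        per_species = df.groupby(["genus", "species"])["copy_number"].mean()
        table: dict[str, list[float]] = {}
        for (genus, _), value in per_species.items():
            table.setdefault(genus, []).append(float(value))
        return cls(table)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (genus, f"sp{i + 1}", value)
            for genus, values in sorted(self.species_copies.items())
            for i, value in enumerate(values)
        ]
        pd.DataFrame(rows, columns=["genus", "species", "copy_number"]).to_csv(
            path, sep="\t", index=False
        )


def genus_copy_number(genus: str, table: CopyNumberTable) -> tuple[float, bool]:
    """Mean copy number for a genus, or the global mean when absent.

    Returns ``(copies, imputed)``; ``imputed`` is True when the table-wide
    mean was used.
    """
    values = table.species_copies.get(genus)
    if values is None:
        return table.global_mean, True
    return float(np.mean(values)), False


def gene_to_cell(
    profile: CommunityProfile,
    table: CopyNumberTable,
) -> tuple[CommunityProfile, pd.DataFrame]:
    """Convert a genus-rank gene-fraction profile to cell fractions.

    Mass not resolved to genus level (the profile's ``unassigned`` bucket)
    is excluded before renormalising: the correction is defined over genera
    only, and the excluded mass is reported in the returned report's
    ``attrs["excluded_mass"]``.  The report lists, per genus: gene fraction,
    copy number used, imputation flag, cell fraction, and the discrepancy
    100 * cell_fraction / gene_fraction (a genus unaffected by the
    correction sits at exactly 100%).
    """
    if profile.scope != "gene":
        raise ValueError("gene_to_cell expects a gene-fraction profile")
    if profile.rank != "genus":
        raise ValueError("copy-number correction is defined at genus rank")
    genera = sorted(profile.fractions)
    gene = np.array([profile.fractions[g] for g in genera], dtype=np.float64)
    total = gene.sum()
    if total <= 0:
        raise ValueError("profile has no genus-level mass to correct")
    gene_norm = gene / total

    copies = np.empty(len(genera))
    imputed = np.empty(len(genera), dtype=bool)
    for i, g in enumerate(genera):
        copies[i], imputed[i] = genus_copy_number(g, table)
    if np.any(copies <= 0):
        raise CopyNumberError("non-positive copy number in table")

    weighted = gene_norm / copies
    cell = weighted / weighted.sum()

    report = pd.DataFrame(
        {
            "genus": genera,
            "gene_fraction": gene_norm,
            "copy_number_used": copies,
            "imputed": imputed,
            "cell_fraction": cell,
            "discrepancy_percent": 100.0 * np.divide(
                cell, gene_norm, out=np.zeros_like(cell), where=gene_norm > 0
            ),
        }
    )
    report.attrs["excluded_mass"] = profile.unassigned
    cell_profile = CommunityProfile(
        scope="cell",
        rank="genus",
        fractions={g: float(c) for g, c in zip(genera, cell)},
        unassigned=0.0,
        total_assigned=profile.total_assigned,
        n_reads=profile.total_assigned,
    )
    return cell_profile, report


def top_genera_comparison(report: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k genera by gene fraction with paired gene% / cell% columns.

    The paired view makes over/underestimation visible: a genus with fewer
    operons than the community average has cell% > gene% (discrepancy above
    100%), one with more has cell% < gene%.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if report.empty:
        raise ValueError("empty correction report")
    top = report.sort_values(
        ["gene_fraction", "genus"], ascending=[False, True]
    ).head(k)
    out = top[["genus", "copy_number_used", "imputed", "discrepancy_percent"]].copy()
    out.insert(1, "gene_percent", 100.0 * top["gene_fraction"])
    out.insert(2, "cell_percent", 100.0 * top["cell_fraction"])
    return out.reset_index(drop=True)
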