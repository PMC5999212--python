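"""In-memory containers shared across the pipeline.

Genotypes are biallelic dosages: the count of copies of the designated
alternate allele in a diploid genotype (0, 1 or 2), with ``NaN`` for a
missing call.  Individuals carry a population label composed of a hatchery
line (``P1`` founders, ``INT`` integrated, ``SEG`` segregated) and a
generation index, because every QC and divergence computation is stratified
by population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINES = ("P1", "INT", "SEG")
TRAITS = ("age", "return_day", "spawn_day", "length_cm", "weight_kg", "dgc")


def population_label(line: str, generation: int) -> str:
    """Canonical population key, e.g. ``INT_F2`` or ``P1_F0``."""
    return f"{line}_F{generation}"


@dataclass
class GenotypeMatrix:
    """Individuals x loci dosage matrix with population metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by individual id, one column per locus, values in
        {0, 1, 2} or NaN (missing call).
    samples
        DataFrame indexed by individual id with at least columns ``line``,
        ``generation`` and ``sex``; a ``population`` column is derived if
        absent.
    """

    dosages: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.samples.index):
            self.samples = self.samples.loc[self.dosages.index]
        if "population" not in self.samples.columns:
            self.samples = self.samples.assign(
                population=[
                    population_label(l, g)
                    for l, g in zip(self.samples["line"], self.samples["generation"])
                ]
            )
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")

    # -- basic accessors -------------------------------------------------
    @property
    def loci(self) -> pd.Index:
        return self.dosages.columns

    @property
    def individuals(self) -> pd.Index:
        return self.dosages.index

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.samples["population"]))

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        d = self.dosages
        if individuals is not None:
            d = d.loc[individuals]
        if loci is not None:
            d = d[list(loci)]
        return GenotypeMatrix(d, self.samples.loc[d.index])

    def population_mask(self, population: str) -> np.ndarray:
        return (self.samples["population"] == population).to_numpy()

    # -- per-population summaries ---------------------------------------
    def genotype_counts(self, population: str | None = None) -> pd.DataFrame:
        """Per-locus counts of (hom-ref, het, hom-alt) genotypes.

        Returns a DataFrame indexed by locus with columns ``n0, n1, n2``.
        """
        d = self.dosages
        if population is not None:
            d = d.loc[self.population_mask(population)]
        arr = d.to_numpy(dtype=float)
        out = pd.DataFrame(
            {
                "n0": (arr == 0).sum(axis=0),
                "n1": (arr == 1).sum(axis=0),
                "n2": (arr == 2).sum(axis=0),
            },
            index=d.columns,
        )
        return out

    def allele_freq(self, population: str | None = None) -> pd.Series:
        """Alternate-allele frequency per locus among called genotypes."""
        d = self.dosages
        if population is not None:
            d = d.loc[self.population_mask(population)]
        arr = d.to_numpy(dtype=float)
        called = ~np.isnan(arr)
        denom = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(arr, axis=0) / denom
        return pd.Series(freq, index=d.columns, name="freq")


@dataclass
class QcReport:
    """Bookkeeping for the QC cascade; counts must reconcile exactly."""

    loci_in: int = 0
    loci_after_maf: int = 0
    loci_removed_maf: int = 0
    individuals_in: int = 0
    individuals_removed: int = 0
    loci_removed_missingness: int = 0
    loci_removed_hwe: int = 0
    loci_out: int = 0
    maf: pd.Series | None = None
    hwe_pvalues: pd.DataFrame | None = None
    imputation_freq_correlation: float | None = None
    messages: list[str] = field(default_factory=list)

    def log(self, msg: str) -> None:
        self.messages.append(msg)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "loci_in": self.loci_in,
            "loci_removed_maf": self.loci_removed_maf,
            "loci_after_maf": self.loci_after_maf,
            "individuals_in": self.individuals_in,
            "individuals_removed": self.individuals_removed,
            "loci_removed_missingness": self.loci_removed_missingness,
            "loci_removed_hwe": self.loci_removed_hwe,
            "loci_out": self.loci_out,
        }
        if self.imputation_freq_correlation is not None:
            rows["imputation_freq_correlation"] = self.imputation_freq_correlation
        return pd.DataFrame({"value": rows})
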