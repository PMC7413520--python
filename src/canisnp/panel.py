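"""Core domain types for diallelic SNP panel data.

The panel model is deliberately minimal: every locus carries exactly two
observed alleles, and a genotype at a locus is stored as the *dosage* of the
locus's reference allele (``allele_a``): 2 = homozygous A, 1 = heterozygous,
0 = homozygous B, -1 = missing.  Dosage coding makes numeric encodings and
simulation deterministic and keeps the in-memory container a plain integer
DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "SnpLocus",
    "PanelDefinition",
    "GenotypeMatrix",
    "PopulationFrequencyTable",
    "SuccessTable",
    "load_bundled_panel",
    "FixtureError",
    "WOLF",
    "DOG",
]

WOLF = "wolf"
DOG = "dog"

#: genotype states in fixed (HOM_A, HET, HOM_B) order; used throughout for
#: probability triples.
GENOTYPE_STATES = ("hom_a", "het", "hom_b")
#: dosage value of each state, same order.
STATE_DOSAGE = np.array([2, 1, 0], dtype=np.int8)
MISSING = np.int8(-1)


class FixtureError(RuntimeError):
    """Raised when a bundled data file is corrupted or inconsistent."""


class Genotype(IntEnum):
    """Genotype call at a diallelic locus, as dosage of ``allele_a``."""

    HOM_B = 0
    HET = 1
    HOM_A = 2
    MISSING = -1


@dataclass(frozen=True)
class SnpLocus:
    """A diallelic SNP locus with its two observed alleles.

    ``allele_a`` is the reference allele for dosage coding: by convention the
    first allele of the genotype column order in the bundled frequency table.
    """

    locus_id: str
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        for a in (self.allele_a, self.allele_b):
            if len(a) != 1 or a.upper() not in "ACGT":
                raise ValueError(f"{self.locus_id}: invalid allele symbol {a!r}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.locus_id}: the two alleles must differ")

    def genotype_string(self, dosage: int) -> str:
        """Two-character genotype string for a dosage value ('--' if missing)."""
        if dosage == Genotype.HOM_A:
            return self.allele_a * 2
        if dosage == Genotype.HET:
            return self.allele_a + self.allele_b
        if dosage == Genotype.HOM_B:
            return self.allele_b * 2
        return "--"

    def parse_genotype(self, text: str) -> int:
        """Parse an unordered two-character genotype string to a dosage."""
        text = text.strip()
        if text in ("--", "", "NA"):
            return int(Genotype.MISSING)
        if len(text) != 2:
            raise ValueError(f"{self.locus_id}: malformed genotype {text!r}")
        dosage = 0
        for ch in text:
            if ch == self.allele_a:
                dosage += 1
            elif ch != self.allele_b:
                raise ValueError(
                    f"{self.locus_id}: allele {ch!r} not in declared pair "
                    f"({self.allele_a}/{self.allele_b})"
                )
        return dosage


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered collection of :class:`SnpLocus`."""

    loci: tuple[SnpLocus, ...]

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus_id in panel")

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[SnpLocus]:
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> SnpLocus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.locus_ids

    def subset(self, locus_ids: Sequence[str]) -> "PanelDefinition":
        """New panel restricted to ``locus_ids``, keeping the given order."""
        return PanelDefinition(tuple(self[i] for i in locus_ids))


@dataclass
class GenotypeMatrix:
    """Individuals x loci genotype calls with population labels.

    ``dosage`` is an int8 DataFrame (rows = individuals, columns = panel
    locus ids, values in {-1, 0, 1, 2}); ``populations`` is a Series aligned
    on the same index.  This is the exchange object between every analysis
    stage.
    """

    panel: PanelDefinition
    dosage: pd.DataFrame
    populations: pd.Series

    def __post_init__(self) -> None:
        if list(self.dosage.columns) != self.panel.locus_ids:
            raise ValueError("dosage columns must equal panel locus ids, in order")
        if not self.dosage.index.equals(self.populations.index):
            raise ValueError("populations index must match dosage index")
        if self.dosage.index.has_duplicates:
            raise ValueError("duplicate individual ids")
        vals = self.dosage.to_numpy()
        if not np.isin(vals, [-1, 0, 1, 2]).all():
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        self.dosage = self.dosage.astype(np.int8)
        self.populations = self.populations.astype(str)

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.dosage)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.dosage.columns)

    def population_counts(self) -> dict[str, int]:
        return self.populations.value_counts().to_dict()

    # -- slicing -------------------------------------------------------------
    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            panel=self.panel.subset(locus_ids),
            dosage=self.dosage[list(locus_ids)].copy(),
            populations=self.populations.copy(),
        )

    def subset_individuals(self, individual_ids: Sequence[str]) -> "GenotypeMatrix":
        ids = list(individual_ids)
        return GenotypeMatrix(
            panel=self.panel,
            dosage=self.dosage.loc[ids].copy(),
            populations=self.populations.loc[ids].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.panel, self.dosage.copy(), self.populations.copy())

    @classmethod
    def concat(cls, matrices: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        if not matrices:
            raise ValueError("nothing to concatenate")
        panel = matrices[0].panel
        for m in matrices[1:]:
            if m.panel.locus_ids != panel.locus_ids:
                raise ValueError("panels differ between matrices")
        return cls(
            panel=panel,
            dosage=pd.concat([m.dosage for m in matrices]),
            populations=pd.concat([m.populations for m in matrices]),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Order-insensitive equality on individuals; loci must match in order."""
        if self.panel.locus_ids != other.panel.locus_ids:
            return False
        if set(self.individual_ids) != set(other.individual_ids):
            return False
        ids = sorted(self.individual_ids)
        return self.dosage.loc[ids].equals(other.dosage.loc[ids]) and self.populations.loc[
            ids
        ].equals(other.populations.loc[ids])


@dataclass
class PopulationFrequencyTable:
    """Per (population, locus) genotype-state and allele probabilities.

    ``table`` has a (population, locus_id) MultiIndex with columns
    ``hom_a, het, hom_b, p_a, p_b, n``.  Probability triples are over the
    (HOM_A, HET, HOM_B) states of the locus's allele pair; ``p_a`` is the
    frequency of ``allele_a``.
    """

    panel: PanelDefinition
    table: pd.DataFrame

    REQUIRED = ("hom_a", "het", "hom_b", "p_a", "p_b", "n")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"frequency table missing columns: {sorted(missing)}")
        self.table = self.table.sort_index()

    @property
    def populations(self) -> list[str]:
        return sorted(self.table.index.get_level_values(0).unique())

    @property
    def locus_ids(self) -> list[str]:
        return self.panel.locus_ids

    def genotype_probs(self, population: str) -> pd.DataFrame:
        """Loci x (hom_a, het, hom_b) probabilities, in panel order."""
        sub = self.table.loc[population]
        return sub.loc[self.panel.locus_ids, ["hom_a", "het", "hom_b"]]

    def allele_a_freq(self, population: str) -> pd.Series:
        return self.table.loc[population].loc[self.panel.locus_ids, "p_a"]

    def sample_size(self, population: str, locus_id: str) -> float:
        return float(self.table.loc[(population, locus_id), "n"])

    def validate(self, tol: float = 0.002) -> None:
        """Check probability normalization and allele/genotype consistency.

        ``tol`` absorbs rounding of tables printed to three decimals.
        """
        g = self.table[["hom_a", "het", "hom_b"]].to_numpy(float)
        sums = g.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol):
            bad = self.table.index[np.abs(sums - 1.0) > tol].tolist()
            raise FixtureError(f"genotype probabilities do not sum to 1: {bad}")
        implied = g[:, 0] + g[:, 1] / 2.0
        pa = self.table["p_a"].to_numpy(float)
        if np.any(np.abs(implied - pa) > tol):
            bad = self.table.index[np.abs(implied - pa) > tol].tolist()
            raise FixtureError(f"allele frequency inconsistent with genotypes: {bad}")
        pb = self.table["p_b"].to_numpy(float)
        if np.any(np.abs(pa + pb - 1.0) > tol):
            raise FixtureError("allele frequencies do not sum to 1")

    def subset(self, locus_ids: Sequence[str]) -> "PopulationFrequencyTable":
        mask = self.table.index.get_level_values(1).isin(locus_ids)
        return PopulationFrequencyTable(self.panel.subset(locus_ids), self.table[mask].copy())


@dataclass
class SuccessTable:
    """One-time genotyping success proportions per locus and population."""

    rates: pd.DataFrame  # index locus_id, one column per population
    sample_sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.rates.to_numpy(float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("success rates must lie in [0, 1]")

    @property
    def populations(self) -> list[str]:
        return list(self.rates.columns)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.rates.index)

    def rate(self, locus_id: str, population: str) -> float:
        return float(self.rates.loc[locus_id, population])


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

#: reference-group sample sizes behind the bundled frequency table
REFERENCE_SAMPLE_SIZES = {WOLF: 80, DOG: 90}
#: full study sample sizes behind the bundled success table
SUCCESS_SAMPLE_SIZES = {WOLF: 97, DOG: 108}


def _data_path(name: str):
    return resources.files("canisnp.data").joinpath(name)


def load_bundled_panel() -> tuple[PanelDefinition, PopulationFrequencyTable, SuccessTable]:
    """Load the bundled 13-locus wolf/dog panel.

    Returns the full pre-QC panel (13 loci), the reference genotype/allele
    frequency table (12 loci — the locus that failed genotyping QC has no
    published frequencies), and the one-time genotyping success table
    (13 loci x {wolf, dog}).
    """
    try:
        loci_df = pd.read_csv(_data_path("panel_loci.csv"), dtype=str)
        succ_df = pd.read_csv(_data_path("genotyping_success.csv"), index_col="locus_id")
        freq_df = pd.read_csv(_data_path("reference_frequencies.csv"))
    except Exception as exc:  # pragma: no cover - corrupted install
        raise FixtureError(f"cannot read bundled panel data: {exc}") from exc

    panel = PanelDefinition(
        tuple(SnpLocus(r.locus_id, r.allele_a, r.allele_b) for r in loci_df.itertuples())
    )
    if len(panel) != 13:
        raise FixtureError(f"bundled panel must have 13 loci, found {len(panel)}")

    freq_loci = [l for l in panel.locus_ids if l in set(freq_df["locus_id"])]
    if len(freq_loci) != 12:
        raise FixtureError("bundled frequency table must cover exactly 12 loci")
    freqs = PopulationFrequencyTable(
        panel=panel.subset(freq_loci),
        table=freq_df.set_index(["population", "locus_id"])[
            ["hom_a", "het", "hom_b", "p_a", "p_b", "n"]
        ],
    )
    freqs.validate(tol=0.002)

    if list(succ_df.index) != panel.locus_ids:
        raise FixtureError("success table loci do not match panel")
    success = SuccessTable(rates=succ_df, sample_sizes=dict(SUCCESS_SAMPLE_SIZES))
    return panel, freqs, success


def load_printed_between_differentials() -> pd.Series:
    """Per-locus published wolf-vs-dog allele-frequency differentials.

    Kept alongside the frequency fixture so tests can check the computed
    differentials against the published column.
    """
    df = pd.read_csv(_data_path("reference_frequencies.csv"))
    return df.drop_duplicates("locus_id").set_index("locus_id")["between_diff"]
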