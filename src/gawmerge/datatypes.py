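"""Core genotype containers shared by every pipeline stage.

Conventions, fixed once at read/simulation time and never revisited:

* positions are 1-based, variants sorted by (chrom, pos);
* alleles are single upper-case bases; REF != ALT;
* unphased genotypes count ALT alleles in {0, 1, 2}, missing is -1;
* haplotype alleles are 0 (REF) / 1 (ALT); haplotypes come in ordered
  pairs (2*i, 2*i+1) per sample;
* dosages are expected ALT counts in [0, 2] and are never missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing unphased genotype
MISSING: int = -1

ARRAY = "array"
WGS = "wgs"

_VALID_BASES = frozenset("ACGT")


class GawmergeError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(GawmergeError):
    """A configuration field is invalid; the message names the field."""


class FormatError(GawmergeError):
    """An input file violates the format contract."""


@dataclass(frozen=True)
class VariantTable:
    """Ordered table of biallelic SNP records.

    Wraps a :class:`pandas.DataFrame` with columns
    ``chrom, pos, ref, alt, id, filter_flags`` where ``filter_flags``
    holds a frozenset of FILTER labels (``PASS`` or empty means clean).
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("chrom", "pos", "ref", "alt", "id", "filter_flags")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ConfigError(f"VariantTable missing columns: {missing}")
        df = self.df
        if len(df) > 1:
            order = df.sort_values(["chrom", "pos"], kind="mergesort").index
            if not np.array_equal(order.to_numpy(), df.index.to_numpy()):
                raise FormatError("variants must be sorted by (chrom, pos)")
        keys = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (chrom,pos,ref,alt) key in VariantTable")
        for ref, alt in zip(df["ref"], df["alt"]):
            if ref == alt:
                raise FormatError(f"ref equals alt ({ref})")
            if set(ref) - _VALID_BASES or set(alt) - _VALID_BASES:
                raise FormatError(f"non-ACGT allele {ref}/{alt}")

    # -- construction -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str],
        pos: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[str],
        ids: Sequence[str] | None = None,
        filter_flags: Sequence[Iterable[str]] | None = None,
    ) -> "VariantTable":
        n = len(pos)
        if ids is None:
            ids = [f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(chrom, pos, ref, alt)]
        if filter_flags is None:
            flags = [frozenset()] * n
        else:
            flags = [frozenset(f) for f in filter_flags]
        df = pd.DataFrame(
            {
                "chrom": list(chrom),
                "pos": np.asarray(pos, dtype=np.int64),
                "ref": list(ref),
                "alt": list(alt),
                "id": list(ids),
                "filter_flags": flags,
            }
        )
        return cls(df.reset_index(drop=True))

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def keys(self) -> list[tuple[str, int, str, str]]:
        d = self.df
        return list(zip(d["chrom"], d["pos"].astype(int), d["ref"], d["alt"]))

    def subset(self, index: np.ndarray | Sequence[int]) -> "VariantTable":
        idx = np.asarray(index)
        return VariantTable(self.df.iloc[idx].reset_index(drop=True))

    def equals(self, other: "VariantTable") -> bool:
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        for c in ("chrom", "pos", "ref", "alt"):
            if not (a[c].to_numpy() == b[c].to_numpy()).all():
                return False
        return True


def _check_platform(platform: np.ndarray) -> np.ndarray:
    platform = np.asarray(platform, dtype=object)
    bad = set(platform) - {ARRAY, WGS}
    if bad:
        raise ConfigError(f"unknown platform labels: {sorted(bad)}")
    return platform


@dataclass
class GenotypeMatrix:
    """Samples x variants unphased ALT-allele counts with platform labels."""

    variants: VariantTable
    sample_ids: list[str]
    platform: np.ndarray  # per-sample, "array" or "wgs"
    values: np.ndarray  # int8, (n_samples, n_variants), -1 missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.platform = _check_platform(self.platform)
        n, m = self.values.shape
        if n != len(self.sample_ids) or n != len(self.platform):
            raise ConfigError("sample dimension mismatch in GenotypeMatrix")
        if m != len(self.variants):
            raise ConfigError("variant dimension mismatch in GenotypeMatrix")
        legal = np.isin(self.values, (MISSING, 0, 1, 2))
        if not legal.all():
            raise FormatError("genotype values outside {0,1,2,missing}")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample IDs")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(
            self.variants,
            [self.sample_ids[i] for i in idx],
            self.platform[idx],
            self.values[idx],
        )

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(
            self.variants.subset(idx),
            list(self.sample_ids),
            self.platform,
            self.values[:, idx],
        )

    def alt_frequency(self) -> np.ndarray:
        """Per-variant ALT allele frequency over non-missing genotypes."""
        vals = np.where(self.values == MISSING, 0, self.values).astype(float)
        obs = (self.values != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs > 0, vals.sum(axis=0) / (2.0 * obs), np.nan)


@dataclass
class HaplotypePanel:
    """Phased haplotypes, two ordered rows per sample.

    Invariant: at every site where the source genotype was observed,
    ``hap(2i) + hap(2i+1)`` equals that genotype.
    """

    variants: VariantTable
    sample_ids: list[str]
    platform: np.ndarray
    haplotypes: np.ndarray  # uint8, (2*n_samples, n_variants)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.platform = _check_platform(self.platform)
        h, m = self.haplotypes.shape
        if h % 2 != 0:
            raise ConfigError("haplotype count must be even")
        if h != 2 * len(self.sample_ids) or len(self.platform) != len(self.sample_ids):
            raise ConfigError("sample dimension mismatch in HaplotypePanel")
        if m != len(self.variants):
            raise ConfigError("variant dimension mismatch in HaplotypePanel")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise FormatError("haplotype alleles must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> np.ndarray:
        """Collapse to unphased ALT counts, shape (n_samples, n_variants)."""
        h = self.haplotypes.astype(np.int8)
        return h[0::2] + h[1::2]

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            self.variants, list(self.sample_ids), self.platform, self.genotypes()
        )

    def subset_variants(self, index: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(index)
        return HaplotypePanel(
            self.variants.subset(idx),
            list(self.sample_ids),
            self.platform,
            self.haplotypes[:, idx],
        )

    def subset_samples(self, index: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(index)
        hap_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return HaplotypePanel(
            self.variants,
            [self.sample_ids[i] for i in idx],
            self.platform[idx],
            self.haplotypes[hap_idx],
        )


@dataclass
class DosageMatrix:
    """Imputed expected ALT dosages plus per-variant quality metrics.

    ``er2`` (leave-one-out empirical R-squared) is defined only where
    ``genotyped`` is set; elsewhere it is NaN.
    """

    variants: VariantTable
    sample_ids: list[str]
    platform: np.ndarray
    dosages: np.ndarray  # float64, (n_samples, n_variants)
    genotyped: np.ndarray  # bool, per variant
    r2_all: np.ndarray
    r2_array: np.ndarray
    r2_wgs: np.ndarray
    er2: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.platform = _check_platform(self.platform)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or n != len(self.platform):
            raise ConfigError("sample dimension mismatch in DosageMatrix")
        if m != len(self.variants):
            raise ConfigError("variant dimension mismatch in DosageMatrix")
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9
        ):
            raise FormatError("dosages outside [0, 2]")
        self.dosages = np.clip(self.dosages, 0.0, 2.0)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        for name in ("r2_all", "r2_array", "r2_wgs", "er2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if np.isfinite(self.er2[~self.genotyped]).any():
            raise ConfigError("ER2 defined for a non-genotyped variant")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, index: np.ndarray) -> "DosageMatrix":
        idx = np.asarray(index)
        return DosageMatrix(
            self.variants.subset(idx),
            list(self.sample_ids),
            self.platform,
            self.dosages[:, idx],
            self.genotyped[idx],
            self.r2_all[idx],
            self.r2_array[idx],
            self.r2_wgs[idx],
            self.er2[idx],
        )
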