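"""Core in-memory containers.

A :class:`HaplotypePanel` is a phased, biallelic haplotype matrix with a
variant table and per-sample region metadata — the reference-panel object
the whole pipeline revolves around.  Genotypes are stored site-major
(``(n_sites, n_samples)``), encoded ``{0, 1, 2}`` with ``-1`` for missing;
imputed dosages are real-valued in ``[0, 2]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyPanelError

#: Sentinel for a missing genotype call.
MISSING = -1

VARIANT_COLUMNS = ["id", "contig", "pos", "ref", "alt"]


def _check_variants(variants: pd.DataFrame, n_sites: int) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table lacks columns {missing}")
    if len(variants) != n_sites:
        raise ValueError(
            f"variant table has {len(variants)} rows for {n_sites} sites"
        )


@dataclass
class HaplotypePanel:
    """Phased haplotypes: sample ``k`` owns columns ``2k`` and ``2k+1``."""

    haplotypes: np.ndarray  # (n_sites, 2 * n_samples), int8 in {0, 1}
    variants: pd.DataFrame  # columns: id, contig, pos, ref, alt
    samples: pd.DataFrame  # columns: sample, region

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D (sites x haplotypes)")
        n_sites, n_haps = self.haplotypes.shape
        _check_variants(self.variants, n_sites)
        if not {"sample", "region"} <= set(self.samples.columns):
            raise ValueError("sample table needs 'sample' and 'region' columns")
        if n_haps != 2 * len(self.samples):
            raise ValueError(
                f"{n_haps} haplotype columns for {len(self.samples)} samples"
            )
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def sample_columns(self, index: int) -> tuple[int, int]:
        """Haplotype-column pair owned by sample ``index``."""
        return 2 * index, 2 * index + 1

    def haplotype_labels(self) -> list[str]:
        out = []
        for name in self.samples["sample"]:
            out.extend([f"{name}_h0", f"{name}_h1"])
        return out

    # -- derived views --------------------------------------------------
    def genotypes(self) -> "GenotypeMatrix":
        """Diploid genotypes as the per-sample haplotype sum (no missing)."""
        g = (
            self.haplotypes[:, 0::2].astype(np.int8)
            + self.haplotypes[:, 1::2].astype(np.int8)
        )
        return GenotypeMatrix(g, self.variants.copy(), self.samples.copy())

    def alt_freq(self) -> np.ndarray:
        """Non-reference (alt) allele frequency per site, in the panel."""
        return self.haplotypes.mean(axis=1)

    def subset(self, sample_idx=None, site_idx=None) -> "HaplotypePanel":
        """Restrict to selected samples and/or sites (indices or bool masks)."""
        h = self.haplotypes
        variants = self.variants
        samples = self.samples
        if site_idx is not None:
            site_idx = np.asarray(site_idx)
            if site_idx.dtype == bool:
                site_idx = np.flatnonzero(site_idx)
            h = h[site_idx, :]
            variants = variants.iloc[site_idx]
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            if sample_idx.dtype == bool:
                sample_idx = np.flatnonzero(sample_idx)
            cols = np.empty(2 * len(sample_idx), dtype=np.intp)
            cols[0::2] = 2 * sample_idx
            cols[1::2] = 2 * sample_idx + 1
            h = h[:, cols]
            samples = samples.iloc[sample_idx]
        if h.shape[0] == 0 or h.shape[1] == 0:
            raise EmptyPanelError("subset selected no sites or no samples")
        return HaplotypePanel(h.copy(), variants.copy(), samples.copy())


@dataclass
class GenotypeMatrix:
    """Diploid genotypes in ``{0, 1, 2}`` with ``MISSING`` (= -1) allowed."""

    genotypes: np.ndarray  # (n_sites, n_samples), int8
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (sites x samples)")
        _check_variants(self.variants, self.genotypes.shape[0])
        if self.genotypes.shape[1] != len(self.samples):
            raise ValueError("genotype columns do not match sample table")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.genotypes != MISSING

    def sample_call_rate(self) -> np.ndarray:
        return self.called_mask().mean(axis=0)

    def subset(self, sample_idx=None, site_idx=None) -> "GenotypeMatrix":
        g = self.genotypes
        variants = self.variants
        samples = self.samples
        if site_idx is not None:
            site_idx = np.asarray(site_idx)
            if site_idx.dtype == bool:
                site_idx = np.flatnonzero(site_idx)
            g = g[site_idx, :]
            variants = variants.iloc[site_idx]
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            if sample_idx.dtype == bool:
                sample_idx = np.flatnonzero(sample_idx)
            g = g[:, sample_idx]
            samples = samples.iloc[sample_idx]
        return GenotypeMatrix(g.copy(), variants.copy(), samples.copy())


@dataclass
class DosageMatrix:
    """Imputed dosages in ``[0, 2]`` plus the typed-site mask.

    ``typed_mask`` marks the array-typed (observed) sites; everything else
    was imputed.  Typed-site dosages equal the observed genotype.
    """

    dosages: np.ndarray  # (n_sites, n_samples), float64
    typed_mask: np.ndarray  # (n_sites,), bool
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.typed_mask = np.asarray(self.typed_mask, dtype=bool)
        _check_variants(self.variants, self.dosages.shape[0])
        if self.typed_mask.shape[0] != self.dosages.shape[0]:
            raise ValueError("typed mask length does not match site count")
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9
        ):
            raise ValueError("dosages outside [0, 2]")


def variant_stats(gm: GenotypeMatrix, hwe: bool = False) -> pd.DataFrame:
    """Per-variant allele counts, frequencies, call rate and (optionally) HWE p.

    Returns a frame aligned with ``gm.variants`` carrying ``ac`` (alt allele
    count), ``an`` (called allele number), ``alt_freq``, ``maf``, ``call_rate``
    and, when ``hwe=True``, the exact-test p-value ``hwe_p``.
    """
    g = gm.genotypes
    called = g != MISSING
    an = 2 * called.sum(axis=1)
    ac = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    call_rate = called.mean(axis=1)
    out = pd.DataFrame(
        {
            "ac": ac,
            "an": an,
            "alt_freq": alt_freq,
            "maf": maf,
            "call_rate": call_rate,
        }
    )
    if hwe:
        from .panel_qc import hwe_exact_test  # local import avoids a cycle

        n_aa = ((g == 0) & called).sum(axis=1)
        n_ab = (g == 1).sum(axis=1)
        n_bb = (g == 2).sum(axis=1)
        out["hwe_p"] = [
            hwe_exact_test(int(a), int(h), int(b)) if a + h + b > 0 else np.nan
            for a, h, b in zip(n_aa, n_ab, n_bb)
        ]
    return out
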